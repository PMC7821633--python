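import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from evoexpr.disorder import partition_regions, sdr
from evoexpr.synthetic import SynthConfig, synth_expression_study, synth_gene_universe


class TestConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(age_grade_proportions=(0.5, 0.5, 0.5))

    def test_bad_rho_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(rho_age_expression={"PCG": 1.5})

    def test_infeasible_modules_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_genes=300, n_modules=3, module_sizes=(150, 150, 150))


class TestGeneUniverse:
    def test_same_seed_reproduces_output(self):
        cfg = SynthConfig(seed=5, n_genes=120, module_sizes=(20, 20, 20))
        a = synth_gene_universe(cfg)
        b = synth_gene_universe(cfg)
        assert a[0].to_newick() == b[0].to_newick()
        assert [r.domains for r in a[1]] == [r.domains for r in b[1]]
        assert {p: t.labels for p, t in a[2].items()} == {p: t.labels for p, t in b[2].items()}
        pd.testing.assert_frame_equal(a[3].table, b[3].table)

    def test_zero_rate_region_is_all_ordered(self):
        sdr_map = {
            g: {"KRAB": 0.0, "C2H2_array": 0.1, "other_domains": 0.1, "linker": 0.1}
            for g in ("old", "mid", "young")
        }
        cfg = SynthConfig(seed=1, n_genes=120, module_sizes=(20, 20, 20), kzfp_region_sdr=sdr_map)
        _, records, tracks, _, _ = synth_gene_universe(cfg)
        for rec in records:
            if rec.is_kzfp:
                regions = partition_regions(rec)
                assert sdr(tracks[rec.protein_id], regions["KRAB"]) == 0

    def test_planted_sdr_recovered_within_binomial_bound(self):
        """Pooled KRAB+linker residues exceed 1e4; empirical rate within 0.02."""
        cfg = SynthConfig(
            seed=2, n_genes=600, kzfp_fraction=0.8,
            znf_grade_proportions=(1 / 3, 1 / 3, 1 / 3),
            module_sizes=(30, 30, 30),
        )
        _, records, tracks, ages, truth = synth_gene_universe(cfg)
        pooled = {}
        for rec in records:
            if not rec.is_kzfp:
                continue
            grade = ages.table.at[rec.gene_id, "znf_grade"]
            regions = partition_regions(rec)
            for region in ("KRAB", "linker"):
                n = len(regions[region])
                if n == 0:
                    continue
                d = int(sdr(tracks[rec.protein_id], regions[region]) * n)
                tot_n, tot_d = pooled.get((grade, region), (0, 0))
                pooled[(grade, region)] = (tot_n + n, tot_d + d)
        for (grade, region), (n, d) in pooled.items():
            assert n > 10_000
            target = cfg.kzfp_region_sdr[grade][region]
            assert abs(d / n - target) < 0.02

    def test_is_kzfp_iff_krab_and_c2h2(self):
        cfg = SynthConfig(seed=3, n_genes=150, module_sizes=(20, 20, 20))
        _, records, _, ages, truth = synth_gene_universe(cfg)
        assert {r.gene_id for r in records if r.is_kzfp} == set(truth["kzfp_genes"])
        for rec in records:
            has_krab = any(d.is_krab for d in rec.domains)
            has_zf = any(d.is_c2h2 for d in rec.domains)
            assert rec.is_kzfp == (has_krab and has_zf)


class TestExpressionStudy:
    def test_planted_spearman_recovered_at_full_size(self):
        cfg = SynthConfig(seed=4, n_genes=2000)
        _, _, _, ages, truth_u = synth_gene_universe(cfg)
        datasets, truth = synth_expression_study(cfg, ages)
        kz = set(truth["kzfp_genes"])
        oldness = truth["oldness"]
        pcg = [g for g in oldness.index if g not in kz]
        rhos = []
        for ds in datasets:
            for s in ds.sample_ids:
                rhos.append(spearmanr(oldness[pcg], ds.tpm.loc[pcg, s])[0])
        assert abs(np.mean(rhos) - cfg.rho_age_expression["PCG"]) < 0.1

    def test_zero_snr_erases_module_correlation_structure(self):
        cfg = SynthConfig(
            seed=6, n_genes=600, module_sizes=(100, 100, 100), module_snr=0.0,
            samples_per_dataset=40, n_datasets=5, batch_location_sd=0.0,
            batch_scale_sd=0.0, category_sd=0.0,
        )
        _, _, _, ages, _ = synth_gene_universe(cfg)
        datasets, truth = synth_expression_study(cfg, ages)
        log_tpm = np.log2(pd.concat([ds.tpm for ds in datasets], axis=1) + 1)
        log_tpm = log_tpm.loc[log_tpm.std(axis=1) > 0]
        labels = truth["module_labels"].reindex(log_tpm.index).dropna()
        m1 = log_tpm.loc[labels.index[labels == 1]].to_numpy()
        m2 = log_tpm.loc[labels.index[labels == 2]].to_numpy()
        C = np.corrcoef(np.vstack([m1, m2]))
        n1 = len(m1)
        within = np.concatenate([C[:n1, :n1][np.triu_indices(n1, 1)],
                                 C[n1:, n1:][np.triu_indices(len(m2), 1)]])
        between = C[:n1, n1:].ravel()
        assert abs(within.mean() - between.mean()) < 0.05

    def test_disabled_batch_effects_leave_batch_means_equal(self):
        cfg = SynthConfig(
            seed=7, n_genes=400, module_sizes=(60, 60, 60), batch_location_sd=0.0,
            batch_scale_sd=0.0, category_sd=0.0, module_snr=0.0,
            n_datasets=4, samples_per_dataset=30,
        )
        _, _, _, ages, _ = synth_gene_universe(cfg)
        datasets, _ = synth_expression_study(cfg, ages)
        means = np.array([np.log2(ds.tpm + 1).to_numpy().mean() for ds in datasets])
        assert means.std() < 0.05

    def test_counts_follow_tpm_scale(self):
        cfg = SynthConfig(seed=8, n_genes=200, module_sizes=(30, 30, 30))
        _, _, _, ages, _ = synth_gene_universe(cfg)
        datasets, _ = synth_expression_study(cfg, ages)
        ds = datasets[0]
        assert (ds.counts.to_numpy() >= 0).all()
        # Poisson counts track TPM closely at high abundance
        high = ds.tpm.to_numpy() > 50
        ratio = ds.counts.to_numpy()[high] / ds.tpm.to_numpy()[high]
        assert 5 < np.median(ratio) < 200

    def test_trend_module_factor_decreases_with_stage(self):
        cfg = SynthConfig(seed=9, n_genes=300, module_sizes=(40, 40, 40))
        _, _, _, ages, _ = synth_gene_universe(cfg)
        datasets, truth = synth_expression_study(cfg, ages)
        stage = pd.concat([ds.samples["stage_order"] for ds in datasets])
        factor = truth["factors"][truth["trend_module"]]
        rho = spearmanr(factor, stage.to_numpy())[0]
        assert rho < -0.8
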