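"""End-to-end orchestration: synthetic (or file-based) inputs through age
grading, SDR, profiling, representation, correlation screens, batch-adjusted
clustering, module detection and wTO, with a manifest of outputs.

Every stage writes a TSV under the output directory; the manifest records
parameters and SHA-256 hashes so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batch as batch_mod
from . import coexpression as coex
from . import io_formats as iof
from . import profiles as prof
from . import stats
from .disorder import region_sdr_table
from .evo_age import GradeScheme
from .synthetic import SynthConfig, synth_study
from .types import AgeTable, ExpressionDataset


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "evoexpr_out"
    seed: int = 0
    synth: SynthConfig | None = None
    # file-mode inputs (ignored in synth mode)
    tree_path: str | None = None
    gene_records_path: str | None = None
    tracks_path: str | None = None
    ages_path: str | None = None
    datasets: list[dict] | None = None  # each: counts/tpm/meta paths
    # thresholds, all at their published defaults
    expressed_count: int = 10
    min_cv: float = 0.08
    min_fraction: float = 0.8
    display_cutoff: float = 0.2
    coexpr: coex.CoexprConfig = dataclasses.field(
        default_factory=lambda: coex.CoexprConfig()
    )
    run_wto: bool = True
    run_modules: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "coexpr" in raw:
            raw["coexpr"] = coex.CoexprConfig(**raw["coexpr"])
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every enabled stage; returns the manifest dict (also written to
    ``manifest.json``). A failing stage aborts with its name in the error."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "outputs": {}, "parameters": _params_dict(cfg)}

    stage = "inputs"
    try:
        if cfg.synth is not None:
            synth_cfg = dataclasses.replace(cfg.synth, seed=cfg.seed)
            tree, records, tracks, ages, datasets, truth = synth_study(synth_cfg)
        else:
            tree = iof.read_species_tree(_require(cfg.tree_path, "tree_path"))
            records = iof.read_gene_records(_require(cfg.gene_records_path, "gene_records_path"))
            tracks = iof.read_disorder_tracks(_require(cfg.tracks_path, "tracks_path"))
            ages = iof.read_age_table(_require(cfg.ages_path, "ages_path"))
            datasets = [
                iof.read_expression_dataset(d["counts"], d["tpm"], d["meta"])
                for d in (cfg.datasets or [])
            ]
            truth = None

        stage = "age"
        _write(out, manifest, "ages.tsv", _age_frame(ages))

        stage = "sdr"
        sdr_rows = region_sdr_table(records, tracks)
        sdr_df = pd.DataFrame([dataclasses.asdict(r) for r in sdr_rows])
        _write(out, manifest, "sdr.tsv", sdr_df)

        stage = "profile"
        profiles = prof.profile_table(datasets, cfg.expressed_count)
        _write(out, manifest, "profiles.tsv", profiles)

        stage = "represent"
        kzfp = {r.gene_id for r in records if r.is_kzfp}
        rep = representation_by_grade(profiles, ages, kzfp)
        _write(out, manifest, "representation.tsv", rep)

        stage = "correlate"
        corr = correlation_screen(datasets, ages, kzfp, cfg.display_cutoff)
        _write(out, manifest, "correlations.tsv", corr)

        stage = "cluster"
        merged, batches = merge_log_tpm(datasets)
        kzfp_rows = [g for g in merged.index if g in kzfp]
        adj = batch_mod.eb_batch_adjust(_drop_constant(merged), batches)
        zs = batch_mod.zscore_rows(adj.values.loc[[g for g in kzfp_rows if g in adj.values.index]], drop_constant=True)
        _, order = batch_mod.hier_cluster(zs, axis="columns")
        _write(out, manifest, "cluster_order.tsv", pd.DataFrame({"sample": order}))
        _write(out, manifest, "cluster_zscores.tsv", zs.rename_axis("gene_id").reset_index())

        module_set = None
        if cfg.run_modules:
            stage = "modules"
            log_tpm = merged
            flags = pd.concat(
                [prof.expressed_call(ds.counts, cfg.expressed_count) for ds in datasets], axis=1
            )
            keep = prof.cv_filter(
                pd.concat([ds.tpm for ds in datasets], axis=1), flags, cfg.min_cv
            )
            filtered = log_tpm.loc[[g for g in log_tpm.index if g in set(keep)]]
            A = coex.adjacency(_drop_constant(filtered), cfg.coexpr.power)
            T = coex.tom(A)
            module_set = coex.detect_modules(T, cfg.coexpr, expr=filtered.loc[T.index])
            mods = module_set.labels.rename("module").rename_axis("gene_id").reset_index()
            _write(out, manifest, "modules.tsv", mods)
            comp = coex.module_composition(module_set, kzfp)
            _write(out, manifest, "module_composition.tsv", comp)
            stage = "trends"
            stage_order = pd.concat([ds.samples["stage_order"] for ds in datasets])
            trends = []
            for m in module_set.module_ids:
                rho, flag = coex.module_trend(
                    module_set.eigengenes[m], stage_order, cfg.coexpr.trend_cutoff
                )
                trends.append((m, rho, flag))
            _write(
                out, manifest, "module_trends.tsv",
                pd.DataFrame(trends, columns=["module", "stage_rho", "early_high_late_low"]),
            )

        if cfg.run_wto and module_set is not None and module_set.module_ids:
            stage = "wto"
            trends_df = pd.read_csv(out / "module_trends.tsv", sep="\t", comment="#")
            target = int(trends_df.sort_values("stage_rho")["module"].iloc[0])
            nodes = module_set.members(target)
            net = coex.wto(
                merged, nodes, cfg.coexpr, rng=np.random.default_rng(cfg.seed + 17)
            )
            _write(out, manifest, "wto_edges.tsv", net.edges)
            manifest["wto_threshold"] = net.threshold
            manifest["wto_module"] = target
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


# ------------------------------------------------------------------- helpers


def merge_log_tpm(datasets: list[ExpressionDataset]) -> tuple[pd.DataFrame, pd.Series]:
    """Column-concatenated log2(TPM+1) over datasets sharing a gene index,
    with per-sample batch ids (one batch per dataset)."""
    mats, batches = [], {}
    for ds in datasets:
        mats.append(ds.log_tpm())
        for s in ds.sample_ids:
            batches[s] = ds.samples.at[s, "batch_id"]
    merged = pd.concat(mats, axis=1)
    if merged.isna().any().any():
        raise ValueError("datasets do not share a gene universe")
    return merged, pd.Series(batches)


def _drop_constant(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(axis=1, ddof=0)
    return matrix.loc[sd > 0]


def representation_by_grade(
    profiles: pd.DataFrame, ages: AgeTable, marked: set[str]
) -> pd.DataFrame:
    """Representation of the marked family per (dataset, age grade, level),
    Bonferroni-corrected as one family per dataset (one heatmap each)."""
    rows = []
    for dataset_id, sub in profiles.groupby("dataset_id"):
        cells = []
        for grade in ("old", "mid", "young"):
            genes = set(ages.table.index[ages.table["age_grade"] == grade])
            stratum = sub[sub["gene_id"].isin(genes)]
            expressed = stratum[stratum["level"] != prof.NOT_EXPRESSED]
            N = len(expressed)
            K = expressed["gene_id"].isin(marked).sum()
            for level in ("L", "M", "H"):
                in_class = expressed[expressed["level"] == level]
                n = len(in_class)
                k = in_class["gene_id"].isin(marked).sum()
                if N == 0 or n == 0:
                    continue
                cells.append(stats.representation(int(k), int(n), int(K), int(N), stratum=grade, cls=level))
        for c in stats.representation_table(cells):
            rows.append((dataset_id, c.stratum, c.cls, c.N, c.K, c.n, c.k,
                         c.p_over, c.p_under, c.direction, c.p_corrected, c.strength, c.symbol))
    return pd.DataFrame(
        rows,
        columns=["dataset_id", "stratum", "level", "N", "K", "n", "k",
                 "p_over", "p_under", "direction", "p_corrected", "strength", "symbol"],
    )


def correlation_screen(
    datasets: list[ExpressionDataset],
    ages: AgeTable,
    marked: set[str],
    display_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Spearman screen of gene oldness vs per-sample TPM, split KZFP / PCG."""
    scheme = GradeScheme()
    max_rank = len(scheme.taxa) - 1
    oldness = ages.table["age_taxon"].map(lambda t: max_rank - scheme.age_rank(t))
    groups = pd.Series(
        ["KZFP" if g in marked else "PCG" for g in ages.table.index],
        index=ages.table.index,
    )
    frames = []
    for ds in datasets:
        scr = stats.spearman_screen(oldness, ds.tpm, groups, display_cutoff)
        scr.insert(0, "dataset_id", ds.dataset_id)
        frames.append(scr)
    return pd.concat(frames, ignore_index=True)


def _age_frame(ages: AgeTable) -> pd.DataFrame:
    return ages.table.rename_axis("gene_id").reset_index().fillna("")


def _write(out: Path, manifest: dict, name: str, df: pd.DataFrame) -> None:
    path = out / name
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest["outputs"][name] = digest


def _params_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _require(value, name):
    if value is None:
        raise ValueError(f"missing input: {name}")
    p = Path(value)
    if not p.exists():
        raise FileNotFoundError(f"{name}: {value}")
    return p
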