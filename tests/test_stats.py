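import math

import numpy as np
import pandas as pd
import pytest

from evoexpr import stats

from oracles import hypergeom_tails, mann_whitney_exact


class TestRepresentation:
    def test_worked_example(self):
        cell = stats.representation(k=4, n=4, K=5, N=10)
        assert cell.p_over == pytest.approx(5 / 210, abs=1e-12)
        assert cell.direction == "over"
        assert cell.strength == pytest.approx(-math.log10(5 / 210), abs=1e-3)
        assert cell.strength == pytest.approx(1.623, abs=1e-3)

    def test_full_draw_is_degenerate(self):
        cell = stats.representation(k=5, n=10, K=5, N=10)
        assert cell.p_over == 1.0
        assert cell.strength == pytest.approx(0.0)

    def test_no_marked_genes(self):
        cell = stats.representation(k=0, n=4, K=0, N=10)
        assert cell.p_under == 1.0

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            stats.representation(k=5, n=4, K=5, N=10)

    def test_matches_enumeration_oracle_on_random_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 25))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, n - (N - K)), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            cell = stats.representation(k, n, K, N)
            up, low = hypergeom_tails(k, n, K, N)
            assert cell.p_over == pytest.approx(up, abs=1e-9)
            assert cell.p_under == pytest.approx(low, abs=1e-9)
            assert (cell.strength > 0) == (k > n * K / N)

    def test_table_correction_is_bonferroni(self):
        cells = [stats.representation(4, 4, 5, 10), stats.representation(1, 4, 5, 10)]
        corrected = stats.representation_table(cells)
        assert corrected[0].p_corrected == pytest.approx(2 * 5 / 210)
        assert all(c.p_corrected >= (c.p_over if c.direction == "over" else c.p_under) for c in corrected)

    def test_symbols_follow_cutoffs(self):
        assert stats._symbol(0.2, "over") == "+"
        assert stats._symbol(0.01, "over") == "++"
        assert stats._symbol(1e-12, "over") == "+++"
        assert stats._symbol(0.01, "under") == "--"


class TestFisher:
    def test_worked_table(self):
        # [[3,1],[1,3]] one-sided greater
        p = stats.fisher_excess(k=3, n=4, K=4, N=8)
        assert p == pytest.approx(17 / 70, abs=1e-12)

    def test_zero_marked_gives_p_one(self):
        assert stats.fisher_excess(k=0, n=4, K=4, N=8) == pytest.approx(1.0)

    def test_agrees_with_hypergeometric_upper_tail(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            N = int(rng.integers(2, 30))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, n - (N - K)), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            assert stats.fisher_excess(k, n, K, N) == pytest.approx(
                stats.representation(k, n, K, N).p_over, abs=1e-9
            )


class TestMannWhitney:
    def test_worked_example(self):
        u, p = stats.mann_whitney([1, 2], [3, 4, 5])
        assert u == 0
        assert p == pytest.approx(0.2, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = stats.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney([], [1.0])

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            u, p = stats.mann_whitney(x, y)
            u_o, p_o = mann_whitney_exact(x, y)
            assert u == u_o
            assert p == pytest.approx(p_o, abs=1e-12)


class TestSpearman:
    def test_hand_computed_rho(self):
        rho, _ = stats.spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_perfect_monotone(self):
        rho, _ = stats.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_display_cutoff_is_strict(self):
        genes = [f"g{i}" for i in range(5)]
        values = pd.Series([1, 2, 3, 4, 5], index=genes, dtype=float)
        # permutation with sum d^2 = 16 gives rho exactly 0.2
        abundance = pd.DataFrame(
            {"s_rho02": [3, 1, 4, 5, 2], "s_mono": [1, 2, 3, 4, 5]},
            index=genes, dtype=float,
        )
        groups = pd.Series("PCG", index=genes)
        out = stats.spearman_screen(values, abundance, groups, display_cutoff=0.2)
        out = out.set_index("sample")
        assert out.loc["s_rho02", "rho"] == pytest.approx(0.2)
        assert not out.loc["s_rho02", "display"]
        assert out.loc["s_mono", "display"]


class TestCorrections:
    def test_bonferroni_scales_by_m(self):
        assert stats.bonferroni([0.01] * 5).tolist() == [0.05] * 5

    def test_bh_step_up_hand_computation(self):
        np.testing.assert_allclose(stats.bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_test_is_identity(self):
        assert stats.bonferroni([0.3])[0] == pytest.approx(0.3)
        assert stats.bh([0.3])[0] == pytest.approx(0.3)

    def test_adjusted_above_raw_below_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        for adj in (stats.bonferroni(p), stats.bh(p)):
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stats.bh([0.5, 1.2])


class TestOra:
    def test_term_equal_to_background_gives_p_one(self):
        bg = {f"g{i}" for i in range(10)}
        out = stats.ora({"g0", "g1"}, {"all": set(bg)}, bg)
        assert out.loc[out.term == "all", "p"].iloc[0] == pytest.approx(1.0)

    def test_toy_enrichment_matches_enumeration(self):
        bg = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(5)}
        term = {f"g{i}" for i in range(4)}  # 4 hits inside the set
        out = stats.ora(gene_set, {"t": term, "all": set(bg)}, bg).set_index("term")
        up, _ = hypergeom_tails(4, 5, 4, 10)
        assert out.loc["t", "p"] == pytest.approx(up, abs=1e-12)
        assert out.loc["t", "p"] == pytest.approx(5 / 210, abs=1e-12)

    def test_unannotated_genes_excluded_from_background(self):
        bg = {f"g{i}" for i in range(12)}
        annotations = {"t": {f"g{i}" for i in range(4)}, "u": {f"g{i}" for i in range(4, 10)}}
        out = stats.ora({"g0", "g1"}, annotations, bg)
        assert (out["N"] == 10).all()  # g10, g11 removed before counting

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            stats.ora(set(), {}, set())
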