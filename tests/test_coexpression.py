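import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from evoexpr import coexpression as coex

from oracles import tom_triple_loop, wto_triple_loop


def frame(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])])


def random_adjacency(rng, n, signed=False):
    A = rng.uniform(-1 if signed else 0, 1, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


class TestAdjacency:
    def test_power_one_is_absolute_correlation(self):
        rng = np.random.default_rng(0)
        X = frame(rng.normal(size=(5, 30)))
        A = coex.adjacency(X, power=1.0).to_numpy()
        C = np.abs(np.corrcoef(X.to_numpy()))
        np.fill_diagonal(C, 0.0)
        np.testing.assert_allclose(A, C, atol=1e-12)

    def test_perfect_pair_has_unit_adjacency(self):
        x = np.arange(10.0)
        A = coex.adjacency(frame([x, 2 * x + 1]), power=12.0)
        assert A.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_profiles_shrink_to_zero(self):
        rng = np.random.default_rng(1)
        A = coex.adjacency(frame(rng.normal(size=(10, 200))), power=12.0).to_numpy()
        assert A.max() < 0.01

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError):
            coex.adjacency(frame([[1.0] * 5, [1, 2, 3, 4, 5]]), power=6)


class TestTom:
    def test_two_genes_reduce_to_adjacency(self):
        A = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]])
        assert coex.tom(A).iloc[0, 1] == pytest.approx(0.4)

    def test_three_gene_worked_example(self):
        A = pd.DataFrame([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]], dtype=float)
        T = coex.tom(A)
        assert T.iloc[1, 2] == pytest.approx(0.25 / 1.5)

    def test_vectorized_equals_triple_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            A = random_adjacency(rng, 20)
            T = coex.tom(pd.DataFrame(A)).to_numpy()
            np.testing.assert_allclose(T, tom_triple_loop(A), atol=1e-12)

    def test_entries_bounded(self):
        rng = np.random.default_rng(3)
        T = coex.tom(pd.DataFrame(random_adjacency(rng, 15))).to_numpy()
        assert (T >= 0).all() and (T <= 1 + 1e-12).all()


class TestWtoMatrix:
    def test_three_node_worked_example(self):
        A = np.array([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]])
        W = coex.wto_matrix(A)
        assert W[0, 1] == pytest.approx(0.5)
        assert W[1, 2] == pytest.approx(1 / 6)

    def test_two_node_network_reduces_to_adjacency(self):
        a = 0.7
        W = coex.wto_matrix(np.array([[0, a], [a, 0]]))
        assert W[0, 1] == pytest.approx(a)

    def test_anticorrelated_pair_keeps_negative_sign(self):
        W = coex.wto_matrix(np.array([[0, -0.6], [-0.6, 0]]))
        assert W[0, 1] == pytest.approx(-0.6)

    def test_vectorized_equals_triple_loop_signed(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            A = random_adjacency(rng, 20, signed=True)
            np.testing.assert_allclose(coex.wto_matrix(A), wto_triple_loop(A), atol=1e-12)


class TestModules:
    def _planted(self, rng, sizes=(8, 8), n_samples=100, within=0.95):
        rows = []
        for s in sizes:
            f = rng.normal(size=n_samples)
            noise = np.sqrt(1 / within**2 - 1)
            rows += [f + noise * rng.normal(size=n_samples) for _ in range(s)]
        return frame(rows)

    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(5)
        X = self._planted(rng)
        T = coex.tom(coex.adjacency(X, power=6))
        cfg = coex.CoexprConfig(power=6, min_module_size=4)
        ms = coex.detect_modules(T, cfg, expr=X)
        truth = [0] * 8 + [1] * 8
        assert len(ms.module_ids) == 2
        assert adjusted_rand_score(truth, ms.labels) == pytest.approx(1.0)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = self._planted(rng)
        cfg = coex.CoexprConfig(power=6, min_module_size=4)
        T = coex.tom(coex.adjacency(X, power=6))
        ms1 = coex.detect_modules(T, cfg)
        perm = list(rng.permutation(T.index))
        ms2 = coex.detect_modules(T.loc[perm, perm], cfg)
        assert adjusted_rand_score(ms1.labels.reindex(perm), ms2.labels) == pytest.approx(1.0)

    def test_single_module_fallback_warns(self):
        rng = np.random.default_rng(7)
        X = frame(rng.normal(size=(6, 50)))
        T = coex.tom(coex.adjacency(X, power=2))
        with pytest.warns(UserWarning):
            ms = coex.detect_modules(T, coex.CoexprConfig(min_module_size=10))
        assert set(ms.labels) == {1}

    def test_eigengene_explains_planted_module_variance(self):
        rng = np.random.default_rng(8)
        X = self._planted(rng, sizes=(12,))
        assert coex.eigengene_variance_explained(X) >= 0.5
        eig = coex.module_eigengene(X)
        corrs = [np.corrcoef(eig, row)[0, 1] for _, row in X.iterrows()]
        assert np.mean(corrs) > 0  # sign convention


class TestTrendAndComposition:
    def test_strictly_decreasing_eigengene_has_rho_minus_one(self):
        eig = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        stage = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        rho, flag = coex.module_trend(eig, stage)
        assert rho == pytest.approx(-1.0)
        assert flag

    def test_too_few_stages_rejected(self):
        eig = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            coex.module_trend(eig, pd.Series([1, 1], index=list("ab")))

    def test_composition_of_whole_universe_module_is_null(self):
        labels = pd.Series(1, index=[f"g{i}" for i in range(10)])
        ms = coex.ModuleSet(labels=labels, eigengenes=pd.DataFrame())
        out = coex.module_composition(ms, {"g0", "g1", "g2"})
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["percent"].iloc[0] == pytest.approx(out["background_percent"].iloc[0])

    def test_composition_matches_fisher_and_bonferroni(self):
        labels = pd.Series([1] * 4 + [2] * 6, index=[f"g{i}" for i in range(10)])
        marked = {f"g{i}" for i in range(5)}  # 4 of 5 marked genes in module 1
        ms = coex.ModuleSet(labels=labels, eigengenes=pd.DataFrame())
        out = coex.module_composition(ms, marked).set_index("module")
        from evoexpr.stats import bonferroni, fisher_excess

        p1 = fisher_excess(4, 4, 5, 10)
        assert out.loc[1, "p"] == pytest.approx(p1, abs=1e-12)
        assert out.loc[1, "p"] == pytest.approx(5 / 210, abs=1e-12)
        assert out.loc[1, "p_bonferroni"] == pytest.approx(bonferroni([p1, out.loc[2, "p"]])[0])


class TestWtoNetwork:
    def test_planted_block_kept_and_noise_filtered(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=60)
        rows = [f + 0.3 * rng.normal(size=60) for _ in range(8)]
        rows += [rng.normal(size=60) for _ in range(8)]
        X = frame(rows)
        cfg = coex.CoexprConfig(n_bootstrap=500, n_null_rounds=20)
        net = coex.wto(X, config=cfg, rng=np.random.default_rng(10))
        kept = net.kept_edges()
        block = {f"g{i}" for i in range(8)}
        within = kept[kept.node_a.isin(block) & kept.node_b.isin(block)]
        assert len(within) == 28  # all block pairs survive
        outside = kept[~(kept.node_a.isin(block) & kept.node_b.isin(block))]
        assert len(outside) <= 2

    def test_symmetric_and_bounded_for_unit_correlations(self):
        rng = np.random.default_rng(11)
        A = random_adjacency(rng, 12, signed=True)
        W = coex.wto_matrix(A)
        np.testing.assert_allclose(W, W.T, atol=1e-12)

    def test_constant_node_rejected(self):
        X = frame([[1.0] * 6, list(range(6))])
        with pytest.raises(ValueError):
            coex.wto(X, config=coex.CoexprConfig(n_bootstrap=5))


class TestSoftPower:
    def test_accepts_structured_data(self, small_study):
        datasets = small_study["datasets"]
        merged = pd.concat([ds.log_tpm() for ds in datasets], axis=1)
        p = coex.pick_soft_power(merged.iloc[:300], powers=(2, 4, 6, 8, 12))
        assert p in (2, 4, 6, 8, 12)
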