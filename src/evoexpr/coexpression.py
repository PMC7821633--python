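"""Co-expression modules and signed weighted topological overlap (wTO).

Module detection follows the WGCNA recipe: an unsigned adjacency
``|cor|^beta`` on log2(TPM+1) profiles, the topological overlap measure
(TOM), average-linkage clustering of 1-TOM, and a simplified dynamic cut
(an iterative height scan honoring the deep-split granularity) with small
clusters merged into their closest module. The wTO network keeps the sign
of the Pearson correlation and filters edges by a bootstrap sign-stability
p-value (BH-adjusted) plus an empirical random-wTO quantile rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import bh, bonferroni, fisher_excess, spearman


@dataclass
class CoexprConfig:
    power: float = 12.0
    deep_split: int = 4
    min_module_size: int = 150
    n_bootstrap: int = 1000
    random_wto_probability: float = 0.10
    bh_alpha: float = 0.001
    n_null_rounds: int = 30
    trend_cutoff: float = -0.5

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")


@dataclass
class ModuleSet:
    """Gene -> module labels (1..M; 0 = unassigned) with module eigengenes."""

    labels: pd.Series
    eigengenes: pd.DataFrame  # samples x modules, unit-norm columns

    @property
    def module_ids(self) -> list[int]:
        return [m for m in sorted(self.labels.unique()) if m != 0]

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class WtoNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # node_a, node_b, wto, p_raw, p_bh, kept
    threshold: float = field(default=np.nan)

    def kept_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["kept"]]


# ----------------------------------------------------------------- adjacency


def adjacency(log_tpm: pd.DataFrame, power: float = 12.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor(i,j)|^power, zero diagonal."""
    X = log_tpm.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if (X.std(axis=1) == 0).any():
        bad = list(log_tpm.index[X.std(axis=1) == 0][:3])
        raise ValueError(f"constant gene profile(s): {bad}")
    A = np.abs(np.corrcoef(X)) ** power
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=log_tpm.index, columns=log_tpm.index)


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    M = A.to_numpy(dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(M) != 0):
        raise ValueError("adjacency diagonal must be zero")
    k = M.sum(axis=1)
    shared = M @ M  # diagonal of A is zero, so the u=i,j terms vanish
    kmin = np.minimum.outer(k, k)
    T = (shared + M) / (kmin + 1.0 - M)
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=A.index, columns=A.columns)


def pick_soft_power(
    log_tpm: pd.DataFrame,
    powers=tuple(range(1, 21)),
    r2_cutoff: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest power with scale-free topology fit R^2 >= cutoff.

    The fit regresses log10 p(k) on log10 k over connectivity bins; if no
    power reaches the cutoff the power with the best fit is returned.
    """
    X = log_tpm.to_numpy(dtype=float)
    X = X[X.std(axis=1) > 1e-12]
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(X))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    best, best_r2 = powers[0], -np.inf
    for p in powers:
        k = (corr**p).sum(axis=1)
        r2 = _scale_free_r2(k, n_bins)
        if r2 >= r2_cutoff:
            return p
        if r2 > best_r2:
            best, best_r2 = p, r2
    return best


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    """Fit of log10 p(k) vs log10 k over equal-width connectivity bins."""
    k = k[k > 0]
    if k.size < n_bins or k.min() == k.max():
        return -np.inf
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    occupied = [i for i in range(n_bins) if (idx == i).any()]
    if len(occupied) < 3:
        return -np.inf
    centers = np.array([k[idx == i].mean() for i in occupied])
    freqs = np.array([(idx == i).mean() for i in occupied])
    x, y = np.log10(centers), np.log10(freqs)
    if x.std() == 0 or y.std() == 0:
        return -np.inf
    return float(np.corrcoef(x, y)[0, 1] ** 2)


# ------------------------------------------------------------- module finding


def detect_modules(
    T: pd.DataFrame,
    config: CoexprConfig,
    expr: pd.DataFrame | None = None,
) -> ModuleSet:
    """Cut the average-linkage tree of 1 - TOM into modules.

    The cut height is chosen by scanning all merge heights and keeping the
    partition with the most clusters of size >= ``min_module_size``;
    deep_split >= 2 prefers the finest such cut, lower values the coarsest.
    Clusters below the minimum size are merged into the valid module they
    are most similar to (mean TOM, or eigengene correlation when an
    expression matrix is supplied).
    """
    genes = list(T.index)
    D = 1.0 - T.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = np.unique(Z[:, 2])

    best_labels, best_score, best_h = None, -1, None
    prefer_finer = config.deep_split >= 2
    for h in heights:
        lab = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(lab)
        score = int((sizes[1:] >= config.min_module_size).sum())
        better = score > best_score or (
            score == best_score
            and best_h is not None
            and ((h < best_h) if prefer_finer else (h > best_h))
        )
        if better:
            best_labels, best_score, best_h = lab, score, h
    if best_score <= 0:
        warnings.warn("no cluster reaches min_module_size; returning one module")
        labels = pd.Series(1, index=genes)
        return ModuleSet(labels=labels, eigengenes=_eigengenes(labels, expr))

    labels = pd.Series(best_labels, index=genes)
    sizes = labels.value_counts()
    valid = sorted(sizes.index[sizes >= config.min_module_size])
    Tm = T.to_numpy(dtype=float)
    for small in sorted(sizes.index[sizes < config.min_module_size]):
        members = labels == small
        sims = {
            m: Tm[np.ix_(members.to_numpy(), (labels == m).to_numpy())].mean()
            for m in valid
        }
        labels[members] = max(sorted(sims), key=lambda m: sims[m])
    # relabel 1..M in decreasing size order for stable ids
    order = labels.value_counts().sort_values(ascending=False).index
    remap = {old: i + 1 for i, old in enumerate(order)}
    labels = labels.map(remap)
    return ModuleSet(labels=labels, eigengenes=_eigengenes(labels, expr))


def _eigengenes(labels: pd.Series, expr: pd.DataFrame | None) -> pd.DataFrame:
    if expr is None:
        return pd.DataFrame()
    cols = {}
    for m in sorted(labels.unique()):
        if m == 0:
            continue
        cols[m] = module_eigengene(expr.loc[labels.index[labels == m]])
    return pd.DataFrame(cols)


def module_eigengene(expr: pd.DataFrame) -> pd.Series:
    """First principal component over samples of the z-scored member profiles.

    Unit norm; sign fixed so the mean correlation with member profiles is
    positive.
    """
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    Xz = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    _, _, vt = np.linalg.svd(Xz, full_matrices=False)
    eig = vt[0]
    if np.mean([np.corrcoef(eig, row)[0, 1] for row in Xz]) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def eigengene_variance_explained(expr: pd.DataFrame) -> float:
    """Fraction of member-profile variance carried by the first PC."""
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    Xz = (X[sd > 0] - X[sd > 0].mean(axis=1, keepdims=True)) / sd[sd > 0, None]
    s = np.linalg.svd(Xz, compute_uv=False)
    return float(s[0] ** 2 / (s**2).sum())


def module_trend(
    eigengene: pd.Series,
    stage_order: pd.Series,
    trend_cutoff: float = -0.5,
) -> tuple[float, bool]:
    """Spearman correlation of the module eigengene with developmental stage.

    Returns (rho, early_high_late_low): the flag marks modules whose
    expression falls along development (rho below the cutoff).
    """
    stage = pd.Series(stage_order).reindex(eigengene.index)
    if stage.nunique() < 3:
        raise ValueError("need >= 3 distinct stages")
    rho, _ = spearman(eigengene.to_numpy(), stage.to_numpy())
    return rho, rho < trend_cutoff


def module_composition(
    modules: ModuleSet,
    marked: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-module excess of a marked gene family (one-sided Fisher test).

    Compares each module's marked-gene percentage against the background of
    all analysed genes; p-values are Bonferroni-corrected across modules.
    """
    labels = modules.labels
    N = len(labels)
    K = sum(1 for g in labels.index if g in marked)
    rows = []
    for m in modules.module_ids:
        members = modules.members(m)
        if not members:
            raise ValueError(f"empty module {m}")
        n = len(members)
        k = sum(1 for g in members if g in marked)
        p = fisher_excess(k, n, K, N, alternative="greater")
        rows.append((m, n, k, 100.0 * k / n, p))
    df = pd.DataFrame(rows, columns=["module", "size", "marked", "percent", "p"])
    df["p_bonferroni"] = bonferroni(df["p"]) if len(df) else []
    df["significant_excess"] = df["p_bonferroni"] < alpha
    df["background_percent"] = 100.0 * K / N if N else np.nan
    return df


# ------------------------------------------------------------------------ wTO


def wto_matrix(A_signed: np.ndarray) -> np.ndarray:
    """Signed weighted topological overlap of a signed adjacency (zero diag):
    w_ij = (a_ij + sum_u a_iu a_uj) / (min(k_i, k_j) + 1 - |a_ij|) with
    k_i = sum_u |a_iu|."""
    k = np.abs(A_signed).sum(axis=1)
    shared = A_signed @ A_signed
    kmin = np.minimum.outer(k, k)
    W = (A_signed + shared) / (kmin + 1.0 - np.abs(A_signed))
    np.fill_diagonal(W, 0.0)
    return W


def _signed_adjacency(X: np.ndarray) -> np.ndarray:
    A = np.corrcoef(X)
    np.fill_diagonal(A, 0.0)
    return A


def wto(
    log_tpm: pd.DataFrame,
    nodes: list[str] | None = None,
    config: CoexprConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> WtoNetwork:
    """Signed wTO network with bootstrap significance filtering.

    Per-edge p-values measure sign stability under resampling of samples
    with replacement (two-sided around zero), adjusted by
    Benjamini-Hochberg. The random-wTO threshold is the (1 - p_random)
    quantile of |wTO| under a sample-permutation null. An edge is kept when
    |wTO| exceeds the threshold and its BH p is below ``bh_alpha``.
    """
    config = config or CoexprConfig()
    rng = np.random.default_rng(rng)
    sub = log_tpm.loc[list(nodes)] if nodes is not None else log_tpm
    X = sub.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    if (X.std(axis=1) == 0).any():
        bad = list(sub.index[X.std(axis=1) == 0][:3])
        raise ValueError(f"constant profile(s) among nodes: {bad}")

    W = wto_matrix(_signed_adjacency(X))
    iu = np.triu_indices(n_genes, k=1)
    w_obs = W[iu]

    B = config.n_bootstrap
    n_nonneg = np.zeros(w_obs.shape, dtype=int)
    n_nonpos = np.zeros(w_obs.shape, dtype=int)
    for _ in range(B):
        cols = rng.integers(0, n_samples, size=n_samples)
        Xb = X[:, cols]
        if (Xb.std(axis=1) == 0).any():  # degenerate resample; recount as tie
            n_nonneg += 1
            n_nonpos += 1
            continue
        wb = wto_matrix(_signed_adjacency(Xb))[iu]
        n_nonneg += wb >= 0
        n_nonpos += wb <= 0
    p_raw = np.minimum(1.0, 2.0 * np.minimum(n_nonneg, n_nonpos) / B)
    p_adj = bh(p_raw)

    null_pool = []
    for _ in range(config.n_null_rounds):
        Xp = np.array([row[rng.permutation(n_samples)] for row in X])
        null_pool.append(np.abs(wto_matrix(_signed_adjacency(Xp))[iu]))
    threshold = float(
        np.quantile(np.concatenate(null_pool), 1.0 - config.random_wto_probability)
    )

    kept = (np.abs(w_obs) > threshold) & (p_adj < config.bh_alpha)
    names = list(sub.index)
    edges = pd.DataFrame(
        {
            "node_a": [names[i] for i in iu[0]],
            "node_b": [names[j] for j in iu[1]],
            "wto": w_obs,
            "p_raw": p_raw,
            "p_bh": p_adj,
            "kept": kept,
        }
    )
    return WtoNetwork(nodes=names, edges=edges, threshold=threshold)
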