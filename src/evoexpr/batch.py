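"""Cross-dataset batch adjustment, z-scoring and hierarchical clustering.

Batch adjustment is parametric empirical-Bayes location/scale correction:
each gene is standardized, per-batch gene-wise location and scale effects
are estimated, shrunk toward batch-level priors (normal prior for the
location, inverse-gamma for the scale), then removed. With shrinkage
disabled it reduces to exact per-batch centering and scaling in the
standardized space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform


@dataclass
class AdjustedMatrix:
    values: pd.DataFrame
    batches: pd.Series
    gamma: pd.DataFrame  # per-batch location effects (standardized space)
    delta2: pd.DataFrame  # per-batch squared scale effects


def eb_batch_adjust(
    matrix: pd.DataFrame,
    batch_ids: pd.Series,
    shrinkage: bool = True,
    mean_only: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> AdjustedMatrix:
    """Remove batch effects from a genes x samples matrix.

    Requires >= 2 batches and >= 2 samples per batch (a singleton batch has
    no within-batch scale). Scale estimates use population (1/n) variances
    so that adjustment of identical batches is exactly the identity.
    """
    batch_ids = pd.Series(batch_ids).reindex(matrix.columns)
    if batch_ids.isna().any():
        raise ValueError("batch id missing for some samples")
    batches = sorted(batch_ids.unique())
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    sizes = batch_ids.value_counts()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"singleton batch(es), scale undefined: {bad}")

    X = matrix.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    masks = {b: (batch_ids == b).to_numpy() for b in batches}
    n_b = {b: int(masks[b].sum()) for b in batches}

    # standardization: grand mean weighted by batch sizes; pooled variance of
    # residuals around batch means
    batch_means = np.column_stack([X[:, masks[b]].mean(axis=1) for b in batches])
    weights = np.array([n_b[b] / n_samples for b in batches])
    alpha = batch_means @ weights
    resid = X.copy()
    for i, b in enumerate(batches):
        resid[:, masks[b]] -= batch_means[:, [i]]
    sigma2 = (resid**2).mean(axis=1)
    if (sigma2 <= 0).any():
        raise ValueError("gene with zero pooled variance; drop constant genes first")
    sigma = np.sqrt(sigma2)
    Z = (X - alpha[:, None]) / sigma[:, None]

    gamma_hat = np.column_stack([Z[:, masks[b]].mean(axis=1) for b in batches])
    delta2_hat = np.column_stack([Z[:, masks[b]].var(axis=1, ddof=0) for b in batches])
    # genes (numerically) constant within a batch have no within-batch
    # scale; leave their scale untouched (location is still removed)
    delta2_hat[delta2_hat <= 1e-12] = 1.0

    if mean_only:
        gamma_star, delta2_star = gamma_hat.copy(), np.ones_like(delta2_hat)
        if shrinkage:
            for i, b in enumerate(batches):
                gamma_star[:, i] = _shrink_mean_only(gamma_hat[:, i], n_b[b])
    elif not shrinkage:
        gamma_star, delta2_star = gamma_hat, delta2_hat
    else:
        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta2_hat)
        for i, b in enumerate(batches):
            g, d2 = _eb_iterate(
                Z[:, masks[b]], gamma_hat[:, i], delta2_hat[:, i], max_iter, tol
            )
            gamma_star[:, i] = g
            delta2_star[:, i] = d2

    adj = np.empty_like(Z)
    for i, b in enumerate(batches):
        adj[:, masks[b]] = (Z[:, masks[b]] - gamma_star[:, [i]]) / np.sqrt(
            delta2_star[:, [i]]
        )
    out = adj * sigma[:, None] + alpha[:, None]
    return AdjustedMatrix(
        values=pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
        batches=batch_ids,
        gamma=pd.DataFrame(gamma_star, index=matrix.index, columns=batches),
        delta2=pd.DataFrame(delta2_star, index=matrix.index, columns=batches),
    )


def _eb_iterate(Zb, gamma_hat, delta2_hat, max_iter, tol):
    """Standard parametric EB iteration for one batch (method-of-moments
    hyperpriors; normal prior on location, inverse-gamma on scale)."""
    n = Zb.shape[1]
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1)
    if s2 <= 0 or tau2 <= 0:  # degenerate priors: no information to shrink with
        return gamma_hat, delta2_hat
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2
    g = gamma_hat.copy()
    d2 = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + d2 * gamma_bar) / (n * tau2 + d2)
        ssq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d2_new = (b_prior + 0.5 * ssq) / (n / 2 + a_prior - 1)
        change = max(np.abs(g_new - g).max(), np.abs(d2_new - d2).max())
        g, d2 = g_new, d2_new
        if change < tol:
            break
    return g, d2


def _shrink_mean_only(gamma_hat, n):
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    if tau2 <= 0:
        return gamma_hat
    return (n * tau2 * gamma_hat + gamma_bar) / (n * tau2 + 1)


def batch_variance_fraction(matrix: pd.DataFrame, batch_ids: pd.Series) -> pd.Series:
    """Per-gene fraction of variance explained by the batch factor
    (between-batch sum of squares over total)."""
    batch_ids = pd.Series(batch_ids).reindex(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    grand = X.mean(axis=1, keepdims=True)
    total = ((X - grand) ** 2).sum(axis=1)
    between = np.zeros(X.shape[0])
    for b in batch_ids.unique():
        mask = (batch_ids == b).to_numpy()
        between += mask.sum() * (X[:, mask].mean(axis=1) - grand[:, 0]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, between / total, 0.0)
    return pd.Series(frac, index=matrix.index)


def zscore_rows(matrix: pd.DataFrame, drop_constant: bool = False) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sd 1 (sample sd, ddof=1)."""
    sd = matrix.std(axis=1, ddof=1)
    if (sd == 0).any():
        if drop_constant:
            matrix = matrix.loc[sd > 0]
            sd = sd[sd > 0]
        else:
            bad = list(matrix.index[sd == 0][:3])
            raise ValueError(f"constant row(s), z-score undefined: {bad}")
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def hier_cluster(
    matrix: pd.DataFrame,
    axis: str = "columns",
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering with 1 - Pearson correlation distance.

    Clusters the samples (``axis='columns'``) or genes (``axis='rows'``).
    Items are processed in sorted label order so ties break deterministically.
    Returns the scipy linkage matrix and the dendrogram leaf order (labels).
    """
    data = matrix.T if axis == "columns" else matrix
    data = data.sort_index()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if data.isna().any().any():
        raise ValueError("NaN in matrix")
    labels = list(data.index)
    corr = np.corrcoef(data.to_numpy(dtype=float))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=method)
    order = dendrogram(Z, no_plot=True)["leaves"]
    return Z, [labels[i] for i in order]
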