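"""Hypothesis-testing machinery: signed hypergeometric representation,
Fisher excess tests, Mann-Whitney comparisons, Spearman screens, multiple
testing corrections and generic over-representation analysis (ORA).

Representation of a marked family (e.g. KZFPs) within a class (e.g. the
medium-abundance genes of one stratum) is scored with one-sided
hypergeometric tails in both directions; the reported strength is
-log10 of the directional p-value, signed positive for over- and negative
for under-representation, with symbols +/++/+++ (or -/--/---) at the
P >= 0.05 / P < 0.05 / P < 1e-10 cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SYMBOL_CUTOFF = 0.05
SYMBOL_STRONG_CUTOFF = 1e-10


@dataclass(frozen=True)
class AssociationCell:
    """One representation test: marked genes k of a class of size n, against
    K marked among N total."""

    stratum: str
    cls: str
    N: int
    K: int
    n: int
    k: int
    p_over: float
    p_under: float
    direction: str  # "over" | "under"
    p_corrected: float | None
    strength: float
    symbol: str


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and n <= N and K <= N and n - k <= N - K):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")


def representation(k: int, n: int, K: int, N: int, stratum: str = "", cls: str = "") -> AssociationCell:
    """Signed hypergeometric over/under-representation of a marked family.

    ``p_over`` = P(X >= k), ``p_under`` = P(X <= k) for X ~ HG(N, K, n).
    Direction is over when k exceeds the expectation n*K/N, under otherwise.
    Strength is -log10 of the directional p, positive for over, negative
    for under; the symbol uses the same cutoffs as the strength heatmaps.
    """
    _check_counts(k, n, K, N)
    hg = sps.hypergeom(N, K, n)
    p_over = float(hg.sf(k - 1))
    p_under = float(hg.cdf(k))
    p_over = min(p_over, 1.0)
    p_under = min(p_under, 1.0)
    direction = "over" if N > 0 and k > n * K / N else "under"
    cell = AssociationCell(
        stratum=stratum, cls=cls, N=N, K=K, n=n, k=k,
        p_over=p_over, p_under=p_under, direction=direction,
        p_corrected=None, strength=0.0, symbol="",
    )
    p_dir = p_over if direction == "over" else p_under
    return replace(cell, strength=_signed_strength(p_dir, direction), symbol=_symbol(p_dir, direction))


def _signed_strength(p: float, direction: str) -> float:
    s = -math.log10(max(p, 1e-300))
    return s if direction == "over" else -s


def _symbol(p: float, direction: str) -> str:
    ch = "+" if direction == "over" else "-"
    if p < SYMBOL_STRONG_CUTOFF:
        return ch * 3
    if p < SYMBOL_CUTOFF:
        return ch * 2
    return ch


def representation_table(cells: list[AssociationCell]) -> list[AssociationCell]:
    """Bonferroni-correct a family of representation cells (one analysis run,
    e.g. all cells of one heatmap) and recompute strengths/symbols from the
    corrected directional p-values."""
    m = len(cells)
    out = []
    for c in cells:
        p_dir = c.p_over if c.direction == "over" else c.p_under
        p_corr = min(1.0, m * p_dir)
        out.append(
            replace(c, p_corrected=p_corr, strength=_signed_strength(p_corr, c.direction),
                    symbol=_symbol(p_corr, c.direction))
        )
    return out


def fisher_excess(k: int, n: int, K: int, N: int, alternative: str = "greater") -> float:
    """Fisher exact p for excess of marked genes in a class (2x2 with fixed
    margins derived from k, n, K, N)."""
    _check_counts(k, n, K, N)
    table = [[k, K - k], [n - k, (N - K) - (n - k)]]
    return float(sps.fisher_exact(table, alternative=alternative)[1])


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test (U statistic of x, p-value).

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise (scipy's automatic policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def spearman_screen(
    values: pd.Series,
    abundance: pd.DataFrame,
    groups: pd.Series,
    display_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Per-sample, per-group Spearman screen of a gene property vs abundance.

    ``values``: gene property (e.g. age rank, SDR) indexed by gene;
    ``abundance``: genes x samples TPM; ``groups``: gene -> group label
    (e.g. KZFP / PCG). Returns one row per (sample, group) with rho, p and a
    display flag set when |rho| is strictly over ``display_cutoff``.
    """
    rows = []
    for group in sorted(groups.unique()):
        genes = groups.index[groups == group]
        genes = [g for g in genes if g in values.index and g in abundance.index]
        sub_vals = values.loc[genes]
        for sample in abundance.columns:
            pair = pd.DataFrame({"x": sub_vals, "y": abundance.loc[genes, sample]}).dropna()
            if len(pair) < 3:
                continue
            rho, p = spearman(pair["x"], pair["y"])
            rows.append((sample, group, rho, p, abs(rho) > display_cutoff))
    return pd.DataFrame(rows, columns=["sample", "group", "rho", "p", "display"])


def bonferroni(p_list) -> np.ndarray:
    """Bonferroni family-wise correction: min(1, m*p)."""
    p = _check_p(p_list)
    return np.minimum(1.0, len(p) * p)


def bh(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment with monotonicity."""
    p = _check_p(p_list)
    return multipletests(p, method="fdr_bh")[1]


def _check_p(p_list) -> np.ndarray:
    p = np.asarray(p_list, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return p


def ora(
    gene_set: set[str],
    term_annotations: dict[str, set[str]],
    background: set[str],
    correction: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set in annotation terms.

    Genes without any term annotation are removed from both the background
    and the gene set before counting, then each term is tested with the
    upper hypergeometric tail against the annotated background.
    """
    if not background:
        raise ValueError("empty background")
    if not gene_set <= background:
        raise ValueError("gene set not contained in background")
    annotated = set().union(*term_annotations.values()) if term_annotations else set()
    bg = background & annotated
    gs = gene_set & annotated
    N, n = len(bg), len(gs)
    rows = []
    for term, genes in sorted(term_annotations.items()):
        K = len(genes & bg)
        k = len(genes & gs)
        p = float(sps.hypergeom(N, K, n).sf(k - 1)) if K else 1.0
        rows.append((term, N, K, n, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"])
    if len(df):
        df["p_adj"] = bonferroni(df["p"]) if correction == "bonferroni" else bh(df["p"])
    return df
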