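"""Expressed calls, expression width, abundance grading and expression filters.

A gene is called expressed in a sample when its read count is strictly over
10. Expression width is the number of samples in a declared sample universe
where the gene is expressed. Within each dataset, expressed genes are graded
into low/medium/high abundance by the lower and upper quartiles of their TPM
values: L below Q1, H above Q3, M in between (genes exactly at a quartile
are M).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionDataset

EXPRESSED_COUNT_THRESHOLD = 10
NOT_EXPRESSED = "not_expressed"


def expressed_call(counts: pd.DataFrame, threshold: int = EXPRESSED_COUNT_THRESHOLD) -> pd.DataFrame:
    """Boolean expressed flags: count strictly greater than ``threshold``."""
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative read count")
    return counts > threshold


def expression_width(flags: pd.DataFrame) -> pd.Series:
    """Number of samples (columns of the flag matrix) each gene is expressed in."""
    return flags.sum(axis=1).astype(int)


def abundance_grade(tpm: pd.Series | np.ndarray) -> pd.Series:
    """Grade expressed genes' TPMs into L/M/H by lower/upper quartiles.

    Quartiles use linear interpolation between order statistics. L is
    strictly below Q1 and H strictly above Q3, so boundary values grade M.
    Requires at least 4 values.
    """
    tpm = pd.Series(tpm) if not isinstance(tpm, pd.Series) else tpm
    if len(tpm) < 4:
        raise ValueError(f"need >= 4 expressed genes to grade, got {len(tpm)}")
    q1, q3 = np.quantile(tpm.to_numpy(dtype=float), [0.25, 0.75])
    out = pd.Series("M", index=tpm.index, dtype=object)
    out[tpm < q1] = "L"
    out[tpm > q3] = "H"
    return out


def dataset_abundance_grades(
    ds: ExpressionDataset,
    threshold: int = EXPRESSED_COUNT_THRESHOLD,
    per_sample: bool = False,
) -> pd.DataFrame | pd.Series:
    """L/M/H/not_expressed grades for one dataset.

    By default a gene counts as expressed in the dataset when expressed in at
    least one of its samples, its abundance is its mean TPM over the
    dataset's samples, and quartiles are taken over all expressed genes —
    one grade per gene per dataset. With ``per_sample=True`` grading is done
    independently within each sample column instead.
    """
    flags = expressed_call(ds.counts, threshold)
    if per_sample:
        out = pd.DataFrame(NOT_EXPRESSED, index=ds.gene_ids, columns=ds.sample_ids, dtype=object)
        for s in ds.sample_ids:
            expressed = flags[s]
            if expressed.sum() >= 4:
                out.loc[expressed, s] = abundance_grade(ds.tpm.loc[expressed, s])
        return out
    expressed = flags.any(axis=1)
    out = pd.Series(NOT_EXPRESSED, index=ds.counts.index, dtype=object)
    if expressed.sum() >= 4:
        out[expressed] = abundance_grade(ds.tpm.loc[expressed].mean(axis=1))
    return out


def expression_fraction_filter(flags: pd.DataFrame, min_fraction: float = 0.8) -> list[str]:
    """Genes expressed in at least ``min_fraction`` of samples (inclusive)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if flags.shape[1] == 0:
        raise ValueError("empty sample set")
    frac = flags.sum(axis=1) / flags.shape[1]
    return list(flags.index[frac >= min_fraction])


def cv_filter(
    tpm: pd.DataFrame,
    flags: pd.DataFrame,
    min_cv: float = 0.08,
    min_expressed: int = 1,
) -> list[str]:
    """Genes with an index of dispersion (variance/mean of TPM) over ``min_cv``
    and expressed in at least ``min_expressed`` samples.

    Note the dispersion statistic is variance/mean, not the usual sd/mean
    coefficient of variation. Zero-mean genes are excluded (ratio undefined).
    """
    mean = tpm.mean(axis=1)
    var = tpm.var(axis=1, ddof=1)
    n_expr = flags.reindex(index=tpm.index).sum(axis=1)
    keep = (mean > 0) & (var / mean.where(mean > 0) > min_cv) & (n_expr >= min_expressed)
    return list(tpm.index[keep])


def profile_table(
    datasets: list[ExpressionDataset],
    threshold: int = EXPRESSED_COUNT_THRESHOLD,
) -> pd.DataFrame:
    """One row per gene x dataset: width within the dataset and L/M/H level.

    The study-wide expression width of a gene is the sum of its per-dataset
    widths (the sample universe is the union of all datasets' samples).
    """
    rows = []
    for ds in datasets:
        flags = expressed_call(ds.counts, threshold)
        width = expression_width(flags)
        level = dataset_abundance_grades(ds, threshold)
        for gid in ds.gene_ids:
            rows.append((gid, ds.dataset_id, ds.species, int(width[gid]), level[gid]))
    return pd.DataFrame(
        rows, columns=["gene_id", "dataset_id", "species", "width", "level"]
    )
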