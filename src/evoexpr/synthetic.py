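"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of the real inputs — a species tree with
named taxa, region-annotated KZFP and PCG proteins with per-residue
disorder tracks, and a multi-dataset expression study — so that every
downstream stage (age grading, SDR recovery, abundance grading,
representation tests, correlation screens, batch-adjusted clustering,
module detection and wTO filtering) has a known truth to score against.

Planted structure, all configurable:

* per-region disorder rates by zinc-finger age grade (old-finger KZFPs get
  disordered KRAB domains and linkers, younger ones are structured);
* KZFP expression concentrated at medium abundance; PCG abundance rising
  with gene age (a positive oldness-abundance rank correlation), absent in
  the KZFP stratum;
* co-expression modules as a loading x factor model, one module following
  an early-high late-low trend along developmental stage;
* per-dataset batch location/scale offsets and a shared per-category
  signature that survives batch adjustment.

Every generator is a pure function of its config (single RNG stream,
mandatory seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evo_age import DEFAULT_TAXA, GradeScheme
from .io_formats import parse_species_tree
from .types import (
    AgeTable,
    CATEGORIES,
    DisorderTrack,
    Domain,
    ExpressionDataset,
    GeneRecord,
    SpeciesTree,
)

GRADES = ("old", "mid", "young")

#: Disorder rates per (zinc-finger grade, region) for KZFPs: old-finger
#: KZFPs carry disordered KRAB domains and linkers, the rest are structured.
DEFAULT_KZFP_SDR = {
    "old": {"KRAB": 0.30, "C2H2_array": 0.05, "other_domains": 0.10, "linker": 0.45},
    "mid": {"KRAB": 0.02, "C2H2_array": 0.02, "other_domains": 0.05, "linker": 0.10},
    "young": {"KRAB": 0.02, "C2H2_array": 0.02, "other_domains": 0.05, "linker": 0.10},
}

#: Whole-protein disorder rates for PCGs by gene-age grade (younger proteins
#: are more disordered).
DEFAULT_PCG_SDR = {"old": 0.15, "mid": 0.25, "young": 0.40}


@dataclass
class SynthConfig:
    seed: int = 0
    n_species: int = 12
    n_genes: int = 2000
    kzfp_fraction: float = 0.10
    age_grade_proportions: tuple[float, float, float] = (0.40, 0.30, 0.30)
    znf_grade_proportions: tuple[float, float, float] = (0.10, 0.40, 0.50)
    kzfp_region_sdr: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_KZFP_SDR.items()})
    pcg_sdr: dict = field(default_factory=lambda: dict(DEFAULT_PCG_SDR))
    # expression study
    n_datasets: int = 3
    samples_per_dataset: int = 20
    batch_location_sd: float = 1.0
    batch_scale_sd: float = 0.15
    category_sd: float = 1.0
    rho_age_expression: dict = field(default_factory=lambda: {"PCG": 0.5, "KZFP": 0.0})
    kzfp_abundance_sd: float = 0.3
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    gene_noise_sd: float = 1.5  # cross-gene residual spread in the planted-correlation classes
    cell_noise_sd: float = 0.5
    depth_mean: float = 30.0
    depth_sd: float = 0.2
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (160, 160, 160)
    module_snr: float = 2.0
    trend_module: int = 1  # module planted with the early-high late-low pattern
    width_profile: dict = field(default_factory=dict)  # (family, grade) -> baseline offset

    def __post_init__(self) -> None:
        for name, props in (
            ("age_grade_proportions", self.age_grade_proportions),
            ("znf_grade_proportions", self.znf_grade_proportions),
        ):
            if abs(sum(props) - 1.0) > 1e-9 or any(p < 0 for p in props):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        for rho in self.rho_age_expression.values():
            if not -1 <= rho <= 1:
                raise ValueError("rho_age_expression values must be in [-1, 1]")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        n_kzfp = round(self.n_genes * self.kzfp_fraction)
        if sum(self.module_sizes) > self.n_genes - n_kzfp:
            raise ValueError("modules do not fit among non-KZFP genes")
        if self.n_species < len(DEFAULT_TAXA) + 1:
            raise ValueError(f"need >= {len(DEFAULT_TAXA) + 1} species for the taxon ladder")


# ------------------------------------------------------------- gene universe


def synth_species_tree(cfg: SynthConfig) -> SpeciesTree:
    """Ladder tree through the default taxon backbone: each internal taxon
    holds one species leaf plus the next-younger taxon; remaining species
    fill the youngest clade."""
    taxa = DEFAULT_TAXA
    species = [f"sp{i:02d}" for i in range(1, cfg.n_species + 1)]
    n_outer = len(taxa) - 1
    inner = species[n_outer:]
    newick = "(" + ",".join(inner) + f"){taxa[-1]}"
    for i in range(len(taxa) - 2, -1, -1):
        newick = f"({species[i]},{newick}){taxa[i]}"
    return parse_species_tree(newick + ";")


def synth_gene_universe(
    cfg: SynthConfig,
) -> tuple[SpeciesTree, list[GeneRecord], dict[str, DisorderTrack], AgeTable, dict]:
    """Generate the gene universe: tree, annotated records, disorder tracks,
    age table and a truth dict with the planted grades and SDR targets."""
    rng = np.random.default_rng(cfg.seed)
    tree = synth_species_tree(cfg)
    scheme = GradeScheme()
    taxa_by_grade = {g: [t for t in scheme.taxa if scheme.grade_of(t) == g] for g in GRADES}

    n_kzfp = round(cfg.n_genes * cfg.kzfp_fraction)
    records: list[GeneRecord] = []
    tracks: dict[str, DisorderTrack] = {}
    age_rows = []
    truth_sdr: dict[tuple[str, str], float] = {}

    age_grades = rng.choice(GRADES, size=cfg.n_genes, p=cfg.age_grade_proportions)
    znf_grades = rng.choice(GRADES, size=n_kzfp, p=cfg.znf_grade_proportions)

    for i in range(cfg.n_genes):
        gid = f"g{i:05d}"
        pid = f"p{i:05d}"
        is_kzfp = i < n_kzfp
        age_grade = str(age_grades[i])
        age_taxon = str(rng.choice(taxa_by_grade[age_grade]))
        if is_kzfp:
            znf_grade = str(znf_grades[i])
            znf_taxon = str(rng.choice(taxa_by_grade[znf_grade]))
            rec, labels = _make_kzfp(gid, pid, znf_grade, cfg, rng)
            rec.gene_age_taxon = age_taxon
            rec.znf_divergence_taxon = znf_taxon
            for region, rate in cfg.kzfp_region_sdr[znf_grade].items():
                truth_sdr[(gid, region)] = rate
            age_rows.append((gid, age_taxon, age_grade, znf_taxon, znf_grade))
        else:
            length = int(rng.integers(300, 800))
            rate = cfg.pcg_sdr[age_grade]
            rec = GeneRecord(gid, "sp01", pid, length, [], gene_age_taxon=age_taxon)
            labels = _bernoulli_labels(length, rate, rng)
            truth_sdr[(gid, "whole_protein")] = rate
            age_rows.append((gid, age_taxon, age_grade, None, None))
        records.append(rec)
        tracks[pid] = DisorderTrack(pid, labels)

    age_df = pd.DataFrame(
        age_rows,
        columns=["gene_id", "age_taxon", "age_grade", "znf_divergence_taxon", "znf_grade"],
    ).set_index("gene_id")
    truth = {
        "scheme": scheme,
        "kzfp_genes": [r.gene_id for r in records if r.is_kzfp],
        "region_sdr": truth_sdr,
    }
    return tree, records, tracks, AgeTable(age_df), truth


def _make_kzfp(gid, pid, znf_grade, cfg, rng) -> tuple[GeneRecord, str]:
    """One KRAB domain, a contiguous C2H2 finger array near the C-terminus
    and a linker between them; one in five carries an extra SCAN domain."""
    n_fingers = int(rng.integers(4, 12))
    krab_len = 70
    linker_len = int(rng.integers(30, 120))
    lead = int(rng.integers(1, 30))
    tail = int(rng.integers(0, 25))
    krab_start = lead + 1
    domains = []
    if rng.random() < 0.2 and lead >= 25:  # SCAN-box upstream of the KRAB domain
        domains.append(Domain("SCAN", 2, 21, False, False))
    domains.append(Domain("KRAB", krab_start, krab_start + krab_len - 1, True, False))
    zf_start = krab_start + krab_len + linker_len
    for f in range(n_fingers):
        s = zf_start + 28 * f
        domains.append(Domain("zf-C2H2", s, s + 27, False, True))
    length = zf_start + 28 * n_fingers - 1 + tail
    rec = GeneRecord(gid, "sp01", pid, length, domains)
    rates = cfg.kzfp_region_sdr[znf_grade]
    from .disorder import partition_regions

    regions = partition_regions(rec)
    labels = np.array(list(_bernoulli_labels(length, rates["other_domains"], rng)))
    for region in ("KRAB", "C2H2_array", "linker"):
        idx = np.array(sorted(regions[region]), dtype=int) - 1
        if idx.size:
            labels[idx] = np.where(rng.random(idx.size) < rates[region], "D", "O")
    return rec, "".join(labels)


def _bernoulli_labels(length: int, rate: float, rng) -> str:
    return "".join(np.where(rng.random(length) < rate, "D", "O"))


# ---------------------------------------------------------- expression study


def synth_expression_study(
    cfg: SynthConfig, ages: AgeTable
) -> tuple[list[ExpressionDataset], dict]:
    """Generate the multi-dataset expression study for the gene universe.

    log2(TPM) follows a factor model: gene baseline (+ age trend for PCGs,
    medium-abundance concentration for KZFPs) + module loading x factor
    + category signature + per-batch location/scale offsets + noise.
    Counts are Poisson(TPM x per-sample depth factor).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    scheme: GradeScheme = GradeScheme()
    genes = list(ages.table.index)
    n_genes = len(genes)
    is_kzfp = ages.table["znf_grade"].notna().to_numpy()

    # oldness score: taxa ranks run oldest -> youngest, so invert
    max_rank = len(scheme.taxa) - 1
    oldness = np.array([max_rank - scheme.age_rank(t) for t in ages.table["age_taxon"]], dtype=float)

    # baselines
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_genes)
    base[is_kzfp] = cfg.baseline_mean + rng.normal(0.0, cfg.kzfp_abundance_sd, size=is_kzfp.sum())

    # planted oldness-abundance rank correlation per class; the residual sd
    # counts every other cross-gene variance source within a sample
    resid_sd = math.sqrt(
        cfg.gene_noise_sd**2
        + cfg.cell_noise_sd**2
        + cfg.category_sd**2
        + cfg.batch_location_sd**2
    )
    for family, mask in (("PCG", ~is_kzfp), ("KZFP", is_kzfp)):
        rho = cfg.rho_age_expression.get(family, 0.0)
        if rho == 0.0 or not mask.any():
            continue
        r = 2.0 * math.sin(math.pi * rho / 6.0)  # target Pearson for this Spearman
        slope = r / math.sqrt(1.0 - r**2) * resid_sd
        z = (oldness[mask] - oldness[mask].mean()) / oldness[mask].std()
        base[mask] = base[mask].mean() + slope * z + rng.normal(0.0, cfg.gene_noise_sd, size=mask.sum())
    for (family, grade), offset in cfg.width_profile.items():
        fam_mask = is_kzfp if family == "KZFP" else ~is_kzfp
        sel = fam_mask & (ages.table["age_grade"] == grade).to_numpy()
        base[sel] += offset

    # module membership among non-KZFP genes
    module_labels = np.zeros(n_genes, dtype=int)
    pcg_idx = np.flatnonzero(~is_kzfp)
    pos = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        module_labels[pcg_idx[pos : pos + size]] = m
        pos += size

    # samples: one batch per dataset; every dataset spans the same
    # developmental course, its samples running through the six categories in
    # development order (stage_order 1..S), so category is crossed with batch
    sample_meta = []
    n_cat = len(CATEGORIES)
    for d in range(cfg.n_datasets):
        for s in range(cfg.samples_per_dataset):
            cat = CATEGORIES[(s * n_cat) // cfg.samples_per_dataset]
            sample_meta.append(
                (f"d{d}_s{s:02d}", f"D{d}", cat, s + 1, f"batch{d}")
            )
    meta = pd.DataFrame(
        sample_meta, columns=["sample_id", "dataset_id", "category", "stage_order", "batch_id"]
    ).set_index("sample_id")
    n_samples = len(meta)
    stage = meta["stage_order"].to_numpy(dtype=float)

    # module factors: the trend module decreases along stage order, others
    # are i.i.d. standard normal per sample
    factors = np.zeros((cfg.n_modules + 1, n_samples))
    for m in range(1, cfg.n_modules + 1):
        if m == cfg.trend_module:
            z = (stage - stage.mean()) / stage.std()
            factors[m] = -z + rng.normal(0.0, 0.1, size=n_samples)
        else:
            factors[m] = rng.normal(0.0, 1.0, size=n_samples)

    # category signatures shared across datasets
    cats = sorted(set(meta["category"]))
    cat_sig = {c: rng.normal(0.0, cfg.category_sd, size=n_genes) for c in cats}

    X = base[:, None] + rng.normal(0.0, cfg.cell_noise_sd, size=(n_genes, n_samples))
    X += cfg.module_snr * factors[module_labels, :]
    for j, (_, row) in enumerate(meta.iterrows()):
        X[:, j] += cat_sig[row["category"]]

    # batch location/scale offsets per (gene, dataset)
    for d in range(cfg.n_datasets):
        cols = (meta["dataset_id"] == f"D{d}").to_numpy()
        loc = rng.normal(0.0, cfg.batch_location_sd, size=n_genes)
        scale = np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=n_genes))
        mu = X[:, cols].mean(axis=1, keepdims=True)
        X[:, cols] = mu + scale[:, None] * (X[:, cols] - mu) + loc[:, None]

    tpm_all = np.maximum(np.exp2(X) - 1.0, 0.0)
    datasets = []
    for d in range(cfg.n_datasets):
        cols = (meta["dataset_id"] == f"D{d}").to_numpy()
        sub_meta = meta.loc[cols, ["category", "stage_order", "batch_id"]]
        tpm = pd.DataFrame(tpm_all[:, cols], index=genes, columns=sub_meta.index)
        depth = np.exp(rng.normal(np.log(cfg.depth_mean), cfg.depth_sd, size=cols.sum()))
        counts = pd.DataFrame(
            rng.poisson(tpm.to_numpy() * depth[None, :]),
            index=genes,
            columns=sub_meta.index,
        )
        datasets.append(
            ExpressionDataset(f"D{d}", "sp01", counts, tpm, sub_meta)
        )

    truth = {
        "module_labels": pd.Series(module_labels, index=genes),
        "trend_module": cfg.trend_module,
        "factors": factors,
        "rho_age_expression": dict(cfg.rho_age_expression),
        "oldness": pd.Series(oldness, index=genes),
        "kzfp_genes": [g for g, k in zip(genes, is_kzfp) if k],
        "categories": meta["category"],
        "batches": meta["batch_id"],
    }
    return datasets, truth


def synth_study(cfg: SynthConfig):
    """Convenience wrapper: full universe plus expression study."""
    tree, records, tracks, ages, truth_u = synth_gene_universe(cfg)
    datasets, truth_e = synth_expression_study(cfg, ages)
    return tree, records, tracks, ages, datasets, {**truth_u, **truth_e}
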