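# evoexpr

Integrative analysis of KRAB zinc-finger proteins (KZFPs): evolutionary-age
grading, structural-disorder ratios, expression breadth and abundance
grading, signed enrichment statistics, batch-corrected clustering, and
co-expression networks — as a tested, reusable Python pipeline.

## The scientific problem

KZFPs are the largest transcription-factor family in mammals. Each member
couples a KRAB repressor domain to an array of C2H2 zinc fingers, and the
family expanded so quickly that any one genome carries members of very
different evolutionary ages. Relating a gene's age (the taxon where it, or
the key residues of its zinc fingers, originated) to the structural disorder
of its protein regions and to its expression breadth and abundance across
development requires a chain of small, well-defined analyses:

* **Gene/domain age.** A domain family's age is the most recent common
  ancestor (MRCA) of the species carrying it in a rooted species tree, then
  coarsened to three grades: *old* (cellular organisms – Opisthokonta),
  *mid* (Eumetazoa – Vertebrata), *young* (Mammalia and younger).
* **Structural disorder ratio (SDR).** For a protein region *R* with
  per-residue order/disorder labels, `SDR(R) = #D / |R|`. KZFPs are
  partitioned into KRAB domain, C2H2 finger array, other domains and the
  linker between KRAB and fingers; SDR 0 is "completely structured".
* **Expression profiling.** A gene is *expressed* in a sample when its read
  count is strictly over 10; its *width* is the number of samples where it is
  expressed. Within a dataset, expressed genes are graded L/M/H by the lower
  and upper quartiles of their TPM.
* **Representation.** Excess or deficit of KZFPs in a class is scored with
  one-sided hypergeometric tails; the strength is `±log10(p)`
  (Bonferroni-corrected), displayed as `+ / ++ / +++` at the
  `P ≥ 0.05 / P < 0.05 / P < 1e-10` cutoffs (and `−` for deficits).
* **Clustering.** Cross-dataset batch effects are removed by parametric
  empirical-Bayes location/scale adjustment, profiles are z-scored and
  hierarchically clustered (1 − Pearson, average linkage).
* **Co-expression.** Modules come from the WGCNA recipe on log2(TPM+1)
  (adjacency `|cor|^β` with β = 12, topological overlap, tree cut with a
  minimum module size of 150); module edges are refined with signed weighted
  topological overlap (wTO), bootstrap sign-stability p-values (BH < 0.001)
  and an empirical random-wTO quantile rule (probability 0.10).

A bundled synthetic-data generator plants all of these signals (per-region
disorder rates by finger age, KZFP medium-abundance concentration, an
age–abundance rank correlation for ordinary protein-coding genes that is
absent in KZFPs, co-expression modules with an early-high late-low
developmental trend, and batch/category structure), so every stage can be
validated against a known truth.

## Worked example

```python
import pandas as pd
from evoexpr.synthetic import SynthConfig, synth_study
from evoexpr import profiles as prof, stats
from evoexpr.coexpression import CoexprConfig, adjacency, tom, detect_modules, module_trend

cfg = SynthConfig(seed=7, n_genes=800, module_sizes=(160, 160, 160))
tree, records, tracks, ages, datasets, truth = synth_study(cfg)
kzfp = {r.gene_id for r in records if r.is_kzfp}

# KZFP representation across abundance classes in one dataset
ds = datasets[0]
level = prof.dataset_abundance_grades(ds)
expressed = level[level != "not_expressed"]
N, K = len(expressed), sum(g in kzfp for g in expressed.index)
cells = [stats.representation(
    sum(g in kzfp for g in expressed[expressed == lv].index),
    int((expressed == lv).sum()), N=N, K=K, cls=lv) for lv in "LMH"]
for c in stats.representation_table(cells):
    print(f"{c.cls}: k={c.k} n={c.n} corrected p={c.p_corrected:.4g} "
          f"strength={c.strength:+.2f} {c.symbol}")

# co-expression modules and their developmental trend
merged = pd.concat([d.log_tpm() for d in datasets], axis=1)
flags = pd.concat([prof.expressed_call(d.counts) for d in datasets], axis=1)
keep = prof.cv_filter(pd.concat([d.tpm for d in datasets], axis=1), flags)
filtered = merged.loc[[g for g in merged.index if g in set(keep)]]
ms = detect_modules(tom(adjacency(filtered, 12)), CoexprConfig(), expr=filtered)
stage = pd.concat([d.samples["stage_order"] for d in datasets])
for m in ms.module_ids:
    rho, early = module_trend(ms.eigengenes[m], stage)
    print(f"module {m}: {len(ms.members(m))} genes, stage rho={rho:+.3f}"
          + ("  <- early-high late-low" if early else ""))
```

prints

```
L: k=17 n=198 corrected p=0.7603 strength=-0.12 -
M: k=62 n=397 corrected p=3.379e-07 strength=+6.47 ++
H: k=1 n=198 corrected p=2.358e-09 strength=-8.63 --
module 1: 473 genes, stage rho=-0.990  <- early-high late-low
module 2: 163 genes, stage rho=-0.199
module 3: 162 genes, stage rho=+0.043
```

KZFPs are strongly over-represented at medium abundance (62 of the 397
medium-graded genes, corrected p ≈ 3e-7) and depleted at high abundance,
and one detected module tracks the planted early-high late-low
developmental pattern (eigengene vs stage Spearman ρ ≈ −0.99).

The same stages are available from the command line
(`evoexpr synth | age | sdr | profile | represent | correlate | cluster |
modules | wto | run`); `evoexpr run --config cfg.yaml` executes the whole
pipeline and writes a manifest with output hashes so reruns are
byte-identical.

## Layout

```
src/evoexpr/
  types.py         core containers (SpeciesTree, GeneRecord, ExpressionDataset, ...)
  io_formats.py    TSV/Newick readers and writers with validation
  synthetic.py     synthetic study generator with planted ground truth
  evo_age.py       MRCA ages and old/mid/young grade schemes
  disorder.py      region partitioning and SDR
  profiles.py      expressed calls, width, L/M/H grading, filters
  stats.py         hypergeometric/Fisher/Mann-Whitney/Spearman machinery
  batch.py         empirical-Bayes batch adjustment, z-scoring, clustering
  coexpression.py  adjacency/TOM/modules/eigengenes/wTO
  pipeline.py      orchestration and manifests
  cli.py           click command-line interface
```

See `docs/methods.md` for the modelling choices and their rationale.
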