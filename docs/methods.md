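# Methods

This note records the models and procedures implemented in `evoexpr`, the
parameters that matter, the numerical choices made where the conventions
are genuinely open, and what the synthetic study does and does not emulate.

## Evolutionary age

A domain family's origin is taken as the most recent common ancestor of the
species in which the family is observed — the oldest clade that must
contain every occurrence under a single-origin assumption (standard
phylostratigraphy). Horizontal transfer and secondary loss are not
modelled; losses make ages conservative (too young never, too old
possibly).

Ages (taxa) are coarsened by a `GradeScheme`: an ordered taxon backbone
(oldest first) with two boundaries, `old_until` (default Opisthokonta) and
`young_from` (default Mammalia). Old covers cellular organisms through
Opisthokonta, mid covers Eumetazoa through Vertebrata, young covers
Mammalia and younger. The exact roster of taxa between the boundaries is
species-dependent and deliberately configurable; the default backbone is a
minimal eleven-taxon ladder. Grade mapping is monotone by construction: an
older taxon can never map to a younger grade. Zinc-finger divergence taxa
of KZFPs are graded with the same scheme; requesting a finger grade for a
non-KZFP is an error, not a missing value, because the quantity is
undefined there.

## Regions and structural disorder

The representative protein of a gene is the longest isoform (enforced at
ingestion: one protein per gene). Domain coordinates are 1-based inclusive;
overlapping hits are resolved by keeping the longer hit, a choice the input
format documents in its header because upstream scanners differ here.

For a KZFP the residue universe is partitioned into: KRAB (union of all
KRAB intervals), C2H2 array (union of all finger intervals), other domains,
and the linker — residues strictly between the last KRAB residue and the
first finger residue in sequence order (the gap is used in whichever
orientation the two occur), minus any domain residues. An adjacent
KRAB/finger pair leaves an empty linker, and the SDR of an empty region is
reported as missing, never as zero, since "completely structured" (SDR = 0)
is a meaningful biological category.

SDR is computed with exact rational arithmetic (`fractions.Fraction`), so
the whole-protein SDR equals the residue-weighted combination of disjoint
region SDRs identically, not merely to rounding. SDR grades use bins
{0}, (0, 0.1], (0.1, 0.5], (0.5, 1]. Only the zero bin is fixed by the
definition of "completely structured"; the inner edges are a convention,
are configurable, and are recorded in output metadata.

## Expression profiling

* Expressed call: read count strictly greater than 10. The threshold is a
  count, not a rate, so library depth influences calls; the synthetic
  generator reproduces this by sampling counts at a finite depth.
* Width: number of samples in a declared sample universe with an expressed
  call. The universe (one dataset, one category, the whole study) is the
  caller's choice and widths are monotone in it.
* Abundance grades: per dataset, quartiles of TPM over all expressed genes;
  L strictly below Q1, H strictly above Q3, boundary values M. Quantiles
  use linear interpolation between order statistics (the common scientific
  default; recorded in output metadata). By default a gene's dataset
  abundance is its mean TPM over the dataset's samples with "expressed
  anywhere in the dataset" as the inclusion rule; a per-sample variant is
  available by flag.
* The dispersion filter for co-expression is variance/mean of raw TPM
  > 0.08 — an index of dispersion, not the usual sd/mean coefficient of
  variation, implemented exactly as named in its source convention and
  flagged here to avoid confusion. It is applied to raw TPM (configurable);
  genes must also be expressed in at least one sample. Zero-mean genes are
  excluded because the ratio is undefined.

## Association statistics

Representation of a marked family in a class uses both one-sided
hypergeometric tails: `p_over = P(X ≥ k)`, `p_under = P(X ≤ k)`. The
reported direction is over iff `k > nK/N`; the strength is `−log10 p` of
the directional p, signed positive for over, negative for under. Symbols
(`+`/`++`/`+++`, `−`/`−−`/`−−−`) switch at P ≥ 0.05, P < 0.05 and
P < 1e-10. A family of cells analysed together (one heatmap) is
Bonferroni-corrected as one family, and strengths/symbols are recomputed
from corrected p-values; a single cell is reported uncorrected. One-tailed
tests per direction are used throughout (the tail convention is ≥ k
inclusive).

Fisher's excess test is the same upper hypergeometric tail expressed as a
2×2 table; it backs the per-module composition test (module percentage of
marked genes vs the analysed-gene background, Bonferroni across modules).
Mann–Whitney comparisons use exact enumeration for small tie-free samples
and the tie-corrected normal approximation otherwise (scipy's policy).
Spearman screens use average ranks for ties and flag samples with |ρ|
strictly over 0.2 for display. The generic over-representation analysis
removes genes without any term annotation from both the background and the
query set before counting. Bonferroni is `min(1, m·p)`; BH is the standard
step-up with enforced monotonicity (statsmodels).

## Batch adjustment and clustering

Batch adjustment is parametric empirical-Bayes location/scale correction:
genes are standardized against a size-weighted grand mean and the pooled
within-batch variance; per-batch gene-wise location (γ) and scale (δ²)
effects are estimated and shrunk toward batch-level moments priors (normal
for γ, inverse-gamma for δ²) by the usual fixed-point iteration; effects
are then removed and the gene rescaled. Numerical choices:

* Within-batch variances use the population (1/n) estimator so that
  adjusting two identical batches is exactly the identity.
* With shrinkage disabled the procedure reduces to exact per-batch
  centering and scaling; batch means then agree to machine precision and
  the batch factor explains none of the remaining variance.
* A gene that is numerically constant inside one batch (common when a gene
  is silent in an entire dataset) has no within-batch scale; its scale
  factor is left untouched (location is still removed). Without this guard
  the 1/√δ̂ rescaling amplifies float roundoff of order 1e-33 into O(1)
  artefacts.
* Singleton batches and single-batch designs are errors.

Rows are z-scored with the sample (n−1) standard deviation. Hierarchical
clustering uses 1 − Pearson distance with average linkage; items are
processed in sorted label order so ties break deterministically, and both
gene-wise and sample-wise clustering are supported.

## Co-expression modules and wTO

Unsigned adjacency `|cor|^β` (β = 12 by default; a scan picks the smallest
β with scale-free fit R² ≥ 0.8 when requested) feeds the standard
topological overlap measure, and modules are cut from the average-linkage
tree of 1 − TOM. The full dynamic hybrid cut is approximated by an
iterative height scan: every merge height is evaluated, the partition with
the most clusters of at least `min_module_size` (default 150) wins, and the
deep-split setting (default 4) decides whether ties prefer the finest or
the coarsest such cut. Sub-threshold clusters are merged into the valid
module they are most similar to (mean TOM, or eigengene correlation when
expression is available). This is a documented simplification of the
reference implementation's tree cut; module counts on real data will not
match it exactly, and module identities rather than counts are the tested
contract. Module eigengenes are the first principal component of the
z-scored member profiles, unit-norm, sign-fixed so mean member correlation
is positive. The module trend statistic is the Spearman correlation of the
eigengene with developmental stage order; "early-high late-low" is declared
below −0.5 (configurable).

The signed wTO of a correlation matrix A (zero diagonal) is
`w_ij = (a_ij + Σ_u a_iu a_uj) / (min(k_i, k_j) + 1 − |a_ij|)` with
`k_i = Σ_u |a_iu|`. Edge significance combines two filters:

* a sign-stability p-value from B bootstrap resamples of samples (default
  1000): twice the smaller tail fraction of resampled wTO values at or
  across zero, without add-one smoothing (the BH < 0.001 criterion must be
  attainable at finite B), BH-adjusted across edges;
* an empirical random-wTO threshold: the (1 − 0.10) quantile of |wTO|
  pooled over sample-permutation nulls (30 rounds by default), which
  destroys all gene-gene correlation while keeping marginals.

An edge is kept when it passes both. Under a global null the kept fraction
is far below the 0.10 quantile rule alone because the BH filter dominates.
Degenerate bootstrap resamples (a constant profile) are counted as ties in
both tails. The RNG seed is mandatory.

## Synthetic study

The generator emulates the statistical structure of a multi-species,
multi-dataset KZFP study at desk scale; the default configuration is the
study condition used by the tests and the acceptance script.

* Universe: 2000 genes, 10% KZFPs, on a 12-species ladder tree through the
  default taxon backbone. Gene-age grades are drawn at 40/30/30
  (old/mid/young); zinc-finger grades at 10/40/50, reflecting that roughly
  half of KZFPs are mammal-specific and only a small minority carry old
  fingers. KZFP architectures: one 70-residue KRAB domain, 4–11 contiguous
  28-residue fingers near the C-terminus, a 30–120 residue linker, one in
  five with an extra SCAN box.
* Disorder: per-region Bernoulli labels. Old-finger KZFPs get disordered
  KRAB (rate 0.30) and linker (0.45); younger KZFPs are structured
  (0.02/0.10); PCG whole-protein rates fall with age grade (0.40/0.25/0.15,
  young to old) — younger proteins are more disordered.
* Expression: log2 TPM as baseline + planted effects + factor model +
  batch/category structure + noise; counts are Poisson(TPM × depth) with a
  per-sample lognormal depth factor around 30 reads per TPM unit. Poisson
  rather than negative binomial is the default because the strict ">10
  reads" call only needs correct behaviour near the threshold;
  overdispersion would only widen the expressed-call boundary. Three
  datasets (one batch each) of 20 samples span the six sample categories in
  development order, so category is crossed with batch. Batch location
  offsets (sd 1.0) and mild scale offsets (lognormal sd 0.15) are planted
  per gene and dataset; per-category gene signatures (sd 1.0) are shared
  across datasets and carry the clustering signal.
* Planted contrasts: KZFP baselines concentrate near the population median
  (sd 0.3), producing medium-abundance over-representation. For PCGs the
  baseline carries an oldness term calibrated through the Gaussian-copula
  relation r = 2 sin(πρ/6) against the total cross-gene residual sd, so the
  per-sample Spearman between age and abundance lands near the target
  (+0.5 by default, within ±0.1 at 2000 genes); KZFPs get no age term.
  Three 160-gene modules live among the PCGs with loading 2.0 on their
  factors; one factor declines monotonically with stage order (the
  early-high late-low module), the others are i.i.d. per sample.
* Truth: module membership, the trend module and its factor, planted
  correlation targets, grades and per-region disorder rates — enough to
  score every downstream stage.

What the generator does not emulate: read-level sequencing noise, gene
length and GC effects in TPM, overdispersed counts (available by extending
the depth model), phylogenetic correlation of gene ages, multi-isoform
proteins, or overlapping domain architectures beyond the resolved-overlap
convention. Passing tests therefore demonstrate correctness of the
computational chain and recoverability of planted effects at realistic
sizes, not biological validity on real data.

Module recovery is scored as the adjusted Rand index over genes with
planted module membership. Background genes are excluded from the score on
purpose: their category-driven expression patterns are genuine correlation
structure that a module detector may legitimately group, and the planted
labels say nothing about them.

## Problem sizes

The test suite and acceptance script run the study at 2000 genes × 60
samples with 20 (tests) or 10 (script) replicates, the exact-test oracle
grid at N ≤ 30, network oracles at 20 nodes × 50 draws, and the wTO null at
50 nodes with 200 bootstraps; these sizes were chosen so the binomial and
rank-statistic tolerances stated in the tests hold with comfortable margin.

## Known limitations

* The tree cut is a simplification of WGCNA's dynamic hybrid algorithm
  (see above); deep-split values act only through the tie-breaking
  direction of the height scan.
* The EB batch model assumes a location/scale batch effect per gene;
  covariate-preserving designs (beyond batch) are out of scope.
* Representation strengths are computed from Bonferroni-corrected
  p-values when cells form a family, which makes strengths conservative
  relative to raw-p reporting.
* `domain_age` trusts the presence set; contamination or annotation errors
  in a single distant species pull ages older with no robustness weighting.
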