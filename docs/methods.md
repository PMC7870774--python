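# Methods

## The similarity framework

Given gene- and isoform-level expected counts for a reference group
("control", e.g. in vivo liver, ~24 samples) and a small test group (an in
vitro model at one time point, 2–7 replicates), the pipeline computes, per
comparison:

1. **non-DEGs** — genes with BH-adjusted Wald p (q) strictly above 0.05 and
   baseMean strictly above 10. The count of non-DEGs is the similarity
   metric: it weights every gene equally and grows as a model's expression
   program converges to the reference.
2. **DEGs** — the mirror set (q < 0.05, baseMean > 10). |log2FC| = 1 is a
   direction/display annotation only, never a membership criterion, so a
   significant gene with a small effect is still a DEG (flagged
   `small_effect`). Genes exactly at either boundary, or excluded from
   testing, belong to neither set.
3. **DTU genes** — genes whose isoform-usage composition shifts between
   groups (see the cascade below), and **non-DEG^DTU−** = non-DEGs minus DTU
   genes.
4. **Pathway coverage** — 100 · |list ∩ pathway| / |pathway| per pathway, or
   the node-mode analogue.

Comparisons are always two-group; multi-factor designs, batch covariates and
shrunken LFC estimators are out of scope.

## DE engine

The engine is a deliberately simplified re-implementation of the standard
negative-binomial workflow, built so that the downstream *decision logic*
(thresholding q and baseMean) is reproduced without cloning a full DE
package. Known divergences from reference implementations: no Cox–Reid
adjusted likelihood, no dispersion outlier refitting, no Cook's-distance
gene exclusion, no independent filtering beyond the stated baseMean
threshold.

- **Size factors.** Median-of-ratios: sⱼ = median over genes with positive
  geometric mean of countᵍʲ / geomeanᵍ, then rescaled to unit geometric mean
  across samples. The rescaling pins the arbitrary overall scale and makes
  normalization an exact fixed point (re-estimating on normalized counts
  returns factors of exactly 1); reference implementations leave the scale
  free, a global-constant difference that cancels in all ratio-based
  statistics and shifts baseMean only by that constant. Size factors are
  estimated jointly per comparison (control ∪ test), re-estimated for every
  bootstrap combination; this per-comparison choice is configurable but is
  the default because each model/time point is compared to the reference
  individually.
- **Dispersions.** On normalized counts x = y/s with group mean q,
  Var(x) = q·mean(1/s) + α·q² within a group, so the moment estimator pools
  (v − m·mean(1/s)) over the two groups weighted by degrees of freedom and
  divides by the pooled m². Gene-wise estimates (clipped to [1e-8, 20]) are
  shrunk toward a parametric trend α(μ) = a₀ + a₁/μ fitted by iterated
  weighted least squares with gamma-style weights (coefficients clipped
  non-negative), combining in log space with weight 0.6 on the trend. The
  fixed weight is a simplicity choice: with ~2000 genes the trend is stable,
  and the blend keeps enough gene-wise signal for genuinely noisy genes
  while damping the moment estimator's sampling noise at n_test = 3. Genes
  with zero counts everywhere get no dispersion and are excluded from
  testing (q undefined).
- **Wald test.** Per gene, the group means are fitted by Newton iteration on
  the NB log-likelihood with known dispersion and size-factor offsets
  (vectorized across genes; the score is monotone in log q, so the iteration
  is safe with a step clip). The statistic is
  z = (ln q_test − ln q_control) / √(1/I_c + 1/I_t) with I = Σ μ/(1+αμ),
  referred to the standard normal, two-sided. A group with all-zero counts
  is replaced by the pseudo-mean 0.5/Σs so the degenerate direction stays
  finite and significant when the other group is large. The reported
  log2FoldChange adds a 0.5 pseudo-count to both fitted group means
  (reporting only — the test statistic never sees it), keeping volcano
  coordinates finite.
- **BH adjustment.** Standard step-up with the max-rank convention for ties,
  applied over genes with defined p within one comparison.

Calibration was verified by simulation rather than assumed: under a global
null (2000 genes, 24 vs 3) the Wald p-values are uniform by KS test and the
DEG fraction is consistent with the nominal level (see
`tests/test_acceptance.py` and `scripts/acceptance.py`, which recompute
these numbers).

## Bootstrap replicate selection

Models contribute different replicate counts, which biases any count-based
metric; the pipeline therefore evaluates **every** k-subset (default k = 3)
of a model's replicates against the full reference group — size factors and
dispersions re-estimated per combination, since each combination is a fresh
comparison — and keeps the subset with the most non-DEGs. DEG counts are
reported alongside for the complementary view; non-DEG count is the
authoritative criterion, and the two orderings coincide only when the
tested-gene universes match. Ties break to the lexicographically smallest
replicate-id tuple, making the selection deterministic and order-invariant.
A model with k−1 replicates can proceed under an explicit
`allow_fewer_replicates` flag (one study model lost a replicate to a
sequencing-depth filter); fewer than that is an error.

## DTU cascade

Filter order is fixed: low-expression (counts) → similar-usage
(percentages) → detection (percentages) → synchronization → single-isoform
prune. Each filter is evaluated on the full table and an isoform failing
several filters is attributed to the earliest step, so the trace's removal
sets are disjoint and auditable.

- **Low expression**: mean CPM < 1 in either group removes the isoform
  (strict; exactly 1.0 is retained). CPM is count / per-sample isoform
  total × 10⁶ on normalized counts; the ratio is invariant to per-sample
  scaling, so raw-vs-normalized is numerically moot under size-factor
  normalization (a config switch exists regardless).
- **Similar usage**: |mean control usage − mean test usage| ≤ 10 percentage
  points removes the isoform (inclusive boundary, per the stated "less than
  equal to").
- **Detection**: detection means usage > 0 (equivalently count > 0). An
  isoform undetected in strictly more than 20 % of either group's samples is
  discarded; a group with n < 5 must detect it in every sample.
- **Synchronization/pruning**: removals from the count view and the
  percentage view are unioned, then genes left with one surviving isoform
  are dropped entirely. Usage percentages are **never renormalized** after
  removals — the ANOVA runs on original percentages, preserving the
  similar-usage filter's semantics.
- **ANOVA**: classical equal-variance one-way F with group as the single
  two-level factor (F = t² of the pooled t-test), on usage percentages,
  which are linear unlike counts. Degenerate rows (zero within-group
  variance in both groups) take the limit convention p = 1 for equal means,
  p = 0 otherwise.
- **Calling**: per gene the dominant isoform is the argmax of mean control
  usage among survivors (ties: lexicographically smallest id); the gene is
  DTU iff that isoform's raw p < 0.01. The stricter raw threshold, with no
  multiplicity adjustment, compensates for the higher error rate of
  isoform-level quantification. A `dominant_switched` column flags genes
  whose test-dominant isoform differs from the control-dominant one, for
  inspection only.

A caveat worth stating: the similar-usage filter and the ANOVA see the same
data, so isoforms that survive the filter are *selected* for large observed
differences. Among post-filter survivors the conditional false-call rate is
therefore structurally inflated; the meaningful false-call rate is per
simulated gene (calls / all genes entering the cascade), which the strict
α = 0.01 keeps well below 2 % in DTU-free simulations.

## Pathway coverage

Gene mode: 100 · |list ∩ pathway| / |pathway|. Node mode: a protein node is
covered when any of its member genes is listed; genes may belong to several
nodes (gene–protein mapping is many-to-many), and GMT members not named by
the node map become singleton nodes. Node coverage is therefore ≥ gene
coverage, and the coverages of a DEG list and its complementary non-DEG
list can sum to more than 100 % — coverage of one is not the inverse of the
other. The denominator is always the pathway, never the query list. The
package reads any GMT; it does not fetch pathway databases (licensing and
version drift), so tests use a programmatically built collection.

## QC

Pairwise Spearman correlation of sample columns (average-rank ties; pairs
with a constant column are undefined and reported missing). The per-model
variation coefficient is 100 · sd/mean (sample sd, n−1) of the correlations
between the model's replicates and all reference samples; this
cross-correlation basis is an interpretive choice — the quantity is
discussed alongside model-vs-reference correlation medians — and is
switchable to intra-model replicate pairs. Because the definition is a
documented guess, no published value is asserted against it.

## Simulator

The generator emulates the study design, not any specific dataset:

| parameter | default | meaning |
| --- | --- | --- |
| n_genes | 2000 | genes (scaled down from genome size for test-time tractability) |
| n_control / n_test | 24 / 3 | reference vs model replicates |
| library_size_range | (5e5, 2e6) | log-uniform per-sample depth (scaled-down sequencing depth) |
| dispersion trend | α(μ) = 0.05 + 2/μ | standard bulk mean-dispersion shape |
| expression_sdlog | 1.2 | log-normal spread of relative expression |
| frac_de / lfc | 0.3, N(0, 1.5²) with \|lfc\| ≥ 1 | DE genes and effect sizes |
| frac_dtu / shift | 0.1, 30 points | DTU genes; usage moved off the control-dominant isoform |
| isoforms per gene | categorical 1..5 (0.35/0.25/0.20/0.12/0.08) | isoform-count mix |

Gene counts are gamma-Poisson (NB) with mean = relative expression × library
size (× 2^lfc in the test group for DE genes). Isoform counts are a
multinomial split of the realized gene count by per-group usage vectors
(Dirichlet(1.5) sorted so isoform 1 is control-dominant), so gene totals
equal isoform sums exactly — a gene can be non-DE yet DTU, the phenomenon
the pipeline isolates. DTU genes move the shift (floored at the dominant
usage, remainder redistributed proportionally) in the test group only; DE
and DTU gene sets are drawn disjointly by default. Everything derives from
one seed and is bitwise reproducible.

What the simulator does **not** emulate: mapping/quantification uncertainty
(expected counts are treated as exact), correlated genes, GC/length bias,
batch structure, donor-level biological variability beyond NB dispersion,
and isoform-count overdispersion beyond the multinomial split. Passing
recovery tests therefore demonstrates correctness of the decision logic and
reasonable power under the assumed generative model, not performance on
real sequencing data.

## Numerical choices and degenerate inputs

- Expected counts stay fractional; nothing is rounded before statistics.
- Zero-total gene-samples get all-zero usage (quantifier convention); the
  detection filter removes such isoforms later.
- Gene-id universes must be identical across samples of a comparison —
  mismatch is an error listing the symmetric difference, because silent
  intersection would change non-DEG counts.
- Ensembl-style id-version stripping is off by default and exposed as
  `strip_id_version`.
- Newton fits cap steps at ±3 in log space and run to 1e-12; BH uses a
  stable mergesort; the Spearman matrix is symmetrized against rounding and
  the diagonal set to exactly 1.
- Empty cascade survivor sets yield an empty DTU call set (warning), and
  non-DEG^DTU− then equals the non-DEG set.

## Problem sizes used in tests

The suite runs simulations at 2000 genes (calibration, recovery; five seeds
for recovery averages), 1500 genes for the exhaustive 35-combination
bootstrap verification, and 250–400 genes for structural/pipeline tests —
sizes chosen so the full suite completes in well under a minute of compute
per module while keeping Monte-Carlo error small relative to the asserted
margins.
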