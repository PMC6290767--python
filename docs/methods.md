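# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the test suite demonstrates.

## Count model and normalization

All count-level inference assumes miRNA read counts are negative-binomially
distributed with variance μ + φμ² (dispersion φ ≥ 0; φ = 0 is Poisson).
This single parameterization is shared by the synthetic generator, the
dispersion estimator and the exact test, so there is no silent convention
mismatch between modules.

CPM is counts · 10⁶ divided by the sample's total read count over **all**
tabulated miRNAs.  The denominator is fixed before the abundance filter, so
removing low-abundance rows never changes surviving miRNAs' CPM values;
`CountMatrix` therefore carries its original library sizes through row
filtering.  Thresholds are strict as documented: samples must *exceed*
45,000 reads; a miRNA is dropped iff its raw count is below 50 in strictly
more than 20 % of samples.

## Consensus differential expression

* **Wilcoxon rank-sum** (via `scipy.stats.mannwhitneyu`): exact null
  distribution when the pooled sample size is ≤ 30 and there are no ties,
  otherwise the normal approximation with tie and continuity corrections.
  All-identical inputs return p = 1 with a warning.
* **Student's t**: pooled-variance two-sample t with df = n₁ + n₂ − 2, by
  default on log₂(CPM + 1) (the log transform stabilizes variance over the
  10²–10⁵ CPM range; raw-CPM scale is available via `t_scale="cpm"`).
  Zero pooled variance returns p = 1 (equal means) or p = 0 with a warning.
* **NB exact test**: counts are linearly scaled to the geometric-mean
  library size and rounded (pseudo-counts); group sums S₁, S₂ are compared
  under a common-mean NB model with per-group-sum dispersion φ/n_g.
  Because both group sums then share the same NB success probability
  1/(1 + φμ), the conditional law of S₁ given S₁ + S₂ is exactly
  BetaBinomial(S₁+S₂, n₁/φ, n₂/φ); the two-sided p value is the total
  probability of outcomes no more likely than the observed one.  At φ = 0
  this reduces to the exact conditional binomial test
  (`scipy.stats.binomtest`).  Compared with edgeR's classic exact test,
  quantile-based library equalization is replaced by linear scaling and
  conditional-likelihood dispersion by the method-of-moments φ — a
  deliberate simplification that preserves the conditional-NB structure of
  the test.
* **Dispersion**: per miRNA, within-group pooled variance s² and pooled
  mean m̄ on scaled counts give φᵢ = max(0, (s² − m̄)/m̄²); the common φ is
  the median over miRNAs with positive mean, clipped to [0, 10].  On the
  synthetic harness (500 miRNAs, 12 v 12) this recovers φ = 0.2 within
  [0.1, 0.3] and estimates ≤ 0.02 for Poisson data.
* **BH adjustment** is applied per test column, across the miRNAs that
  survived the abundance filter.  Consensus uses the *unadjusted* p values
  (all three ≤ 0.05) together with the fold-change threshold; q values are
  reported for annotation.

Numerical choices for the exact test: for totals above 20,000 (with φ > 0
and both n_g/φ > 1) the beta-binomial is replaced by its Beta(n₁/φ, n₂/φ)
mixing limit with a density-matched double tail (two `betainc` evaluations
plus a bracketed root-find).  At that scale the binomial component of the
beta-binomial contributes < 10 % of the spread, and spot checks against
full enumeration at S = 30,000–100,000 agree to a few percent — far below
anything that moves a 0.05 decision.  Probability ties in the enumerated
double tail are resolved with a 10⁻⁸ relative log-tolerance so symmetric
configurations give p = 1 exactly.

**Fold-change display.**  The signed FC column mirrors the field's table
convention: the CPM ratio rounded to one decimal when ≥ 1, otherwise the
negated reciprocal of the *rounded* ratio (0.296 → 0.3 → −3.3), with
round-half-away-from-zero.  Ratios below 0.05 would round to 0.0, so the
reciprocal of the unrounded ratio is used there.  When a group mean is
zero, a 0.5-CPM pseudo-offset enters both means for display only.  One
published table row (miR-323b-3p, printed −2.4) is consistent with neither
the direct-ratio nor the reciprocal-of-rounded convention derived from its
printed CPM means; it is treated as a transcription artifact and not used
as a worked example.

## Univariate markers

Logistic regressions are fitted by IRLS (≤ 25 iterations, deviance change
< 10⁻⁸).  Separation is flagged — not penalized — when the cap is reached
or the deviance collapses below 10⁻⁶; a constant predictor collapses to
the intercept-only model.  AUROC is the Mann–Whitney statistic of the
in-sample model probabilities (equal to max(A, 1 − A) of the raw predictor,
which is why down-regulated markers still score above 0.5).  The DeLong CI
uses placement values with sample variances (ddof = 1) and the standard
normal quantile, clipped to [0, 1]; empirical coverage on Gaussian scores
(true AUROC 0.8, 50 v 50, 2,000 replicates) is ≈ 0.94.

LOO-CV reports two errors: `loo_cost`, the mean squared difference between
the 0/1 outcome and the predicted probability (the default cost of the
standard R cross-validation routine — published "error rates" of this kind
are typically not integer multiples of 1/n, which identifies them as
squared-error costs rather than misclassification proportions), and
`loo_misclass`, the 0/1 error at threshold 0.5.  A fold whose training
labels collapse to one class predicts from the intercept-only model.  The
constant-predictor closed form (n = 8, balanced) is 16/49 ≈ 0.3265,
verified against R `boot::cv.glm`.

## Stability selection

Partitions are stratified per class: round(0.7 · n_class) samples
(round-half-to-even) to discovery, the rest to validation; with 12 v 12
cohorts this gives 8 + 8 vs 4 + 4.  Inside each of the 100 repeats the
*same* consensus rule and thresholds are applied to the discovery set; the
tally counts DE selection (not forest importance), and the stable set is
the strictly-greater-than-75 % tier, ordered by count then id.  The
abundance filter is applied once to the full cohort, not per repeat
(filtering is preprocessing, not part of the resampled procedure).
Per-repeat RNG streams derive from (scheme seed, repeat index), so the
loop is bit-reproducible and any repeat can be replayed in isolation.

## Random-forest panel

Trees are sklearn Gini trees (500 per forest, mtry = ⌊√p⌋, minimum node
size 1); everything out-of-bag is computed in-package from the per-tree
bootstrap membership: OOB vote fractions, OOB error (vote fraction > 0.5
predicts case; exact 0.5 ties go to control with a warning), and unscaled
mean-decrease-accuracy importance (per-tree OOB accuracy drop after
permuting one feature's OOB values, averaged over trees).  "Perfect
accuracy" of a subset means OOB accuracy = 1, which implies OOB-probability
AUROC = 1; OOB was chosen over resubstitution because it is the unbiased
estimate of predictive power, and 1 − OOB error is what the pipeline
reports as *predictive power*.  Exhaustive subset evaluation is guarded at
20 features (2²⁰ − 1 forests); the full pipeline enumerates subsets of the
top 7 stable features (by selection frequency, ties lexicographic),
mirroring the panel size of the reference workflow while keeping the
enumeration exhaustive.

## Synthetic cohorts

The generator emulates: two arms of ≥ 2 samples (default 12 v 12), a
baseline abundance profile with log₁₀ CPM uniform on [1.7, 4.5], common NB
dispersion (default 0.15), log-normal library sizes (meanlog = ln 2·10⁶,
sdlog = 0.4 — plausible small-RNA depth; only the 45,000 floor is
externally specified) and planted signed fold changes applied to the
case-group proportions with renormalization, so compositional spillover
onto null miRNAs exists, as in real CPM data.  Planted carriers draw their
baseline from log₁₀ CPM ∈ [2.3, 4.5]: in the emulated study every
dysregulated miRNA passed the 50-read abundance filter (printed CPMs run
from ~82 upward), so effects are planted in the abundance range where they
are observable.  Because the emulated cohorts are post-QC by definition
("achieved" the read floor), columns whose realized total falls below the
floor are redrawn from the same stream — the count law conditioned on
total ≥ floor — keeping generation deterministic.

The default design plants 26 effects with the published signed FC
spectrum (11 up: 3.0…2.0; 15 down: −2.0…−3.3) among 300 miRNAs.  What the
generator does **not** model: sequencing error, isomiRs, adapter
artifacts, batch or run effects, miRNA–miRNA correlation beyond
compositional coupling, and biological heterogeneity within arms.
Synthetic effects are therefore cleaner than serum data: the stable panel
typically classifies the synthetic cohort perfectly out-of-bag, so
passing tests demonstrate correctness and calibration of the machinery,
not clinical performance.

## Problem sizes and determinism

Default analysis sizes — 300 miRNAs, 24 samples, 100 partitions, 500-tree
forests, 127-subset enumeration — run in a few minutes on one CPU; the
test suite scales some fixtures down (fewer miRNAs, repeats or trees)
while keeping the frozen 12 v 12 cohort for the recovery checks.  All
randomness flows from explicit integer seeds through named
`numpy.random.default_rng([seed, offset])` streams; identical seeds give
bit-identical cohorts, partitions, forests and stage files.

## Known limitations

* The NB exact test's large-total Beta limit is an approximation (see
  above); exact enumeration is available by raising the cutoff constant.
* The GEO series-matrix dialect accepts generic matrix layout only
  (comment lines skipped, floats allowed); normalized matrices disable the
  count-based exact test and consensus falls back to the remaining two
  tests with a warning.
* Cross-cohort normalization for validation samples from different
  sequencing runs is not modeled; per-sample CPM is assumed sufficient.
* No TMM/upper-quartile normalization, tagwise dispersion, GLM-based DE,
  or batch correction — the pipeline reproduces a fixed published
  workflow, not a general DE framework.
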