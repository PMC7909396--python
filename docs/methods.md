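# Methods

## Model and rationale

The package tests, gene by gene, whether expression differs between a
case and a control group. The working model for a *heterogeneous*
disease is that the case group mixes patient subtypes: its mean may
shift, but its variance is typically inflated relative to the controls
(SD ratio r = s₁/s₀ > 1), or its distribution is an outright mixture.
Pooled-variance statistics dilute a real mean shift with the inflated
case variance; the half statistics (half t, half SAM) therefore scale
the mean difference by the control-group SD only:

    th = (X̄₁ − X̄₀) / (s₀ √(1/n₁ + 1/n₀))          df = n₀ − 1
    dh = (X̄₁ − X̄₀) / (s₀ √(1/n₁ + 1/n₀) + c₀)

Under the null of equal distributions and normality, th is exactly
t-distributed with n₀ − 1 degrees of freedom (the numerator's variance
equals the denominator's scale because both groups share one variance);
dh is not t-distributed for any c₀ > 0 and needs resampling or
simulation for its null.

Both score tests (SAM and half SAM) are also sensitive to a pure
variance difference: when md = 0 but r > 1 the numerator's sampling
variance grows while the frozen additive constant c₀ does not, so |d|
inflates relative to its homoscedastic null. This is a feature for
heterogeneous-disease screening (a subtype-driven gene may shift
variance more than mean), but it means a "rejection" is evidence of
*distributional* difference, not specifically of a mean shift.

## Fudge factor c₀

Low-variance genes make raw ratio statistics explode; SAM-type scores
damp them with an additive denominator constant. The estimator:

1. Per gene, form the numerator X̄₁ − X̄₀ and the denominator scatter
   (s₀ √(1/n₁+1/n₀) for half SAM; the sₚ analogue for SAM — each score
   uses the scatter that actually appears in its own denominator).
2. Candidates are the percentiles 0, 5, …, 100 of the scatter
   distribution.
3. For each candidate, compute the scores, partition genes into up to
   100 equal-count scatter-quantile windows (never fewer than two genes
   per window), and take the median absolute deviation (MAD) of the
   scores within each window.
4. Choose the candidate minimizing the coefficient of variation of the
   window MADs; ties break to the lowest percentile for determinism.

The criterion asks that the score's spread be as constant as possible
across the scatter range, the standard operationalization of SAM's
"minimize the coefficient of variation" rule. The estimator requires at
least 20 genes, rejects all-zero scatter vectors, and is exactly scale
equivariant (scaling the data by k scales c₀ by k and leaves every score
unchanged), which the suite verifies to 1e-10.

## Permutation inference (data analysis)

For observed data the SAM-type scores are calibrated by relabeling the
samples, preserving group sizes; the statistic is recomputed in full per
relabeling (including s₀ from the permuted "control" group), with c₀
frozen at its observed-data estimate — the score is a fixed functional;
only the labels are random under the null. Two-sided add-one p-values:

* per-gene (default): p = (1 + #{|d*_b| ≥ |d|}) / (B + 1);
* pooled (SAM convention): one null pooled over all genes and
  permutations, resolution 1/(1 + B·G) — required when BH-FDR thresholds
  sit below 1/(B+1).

When B reaches the number of distinct assignments C(n, n₁), the engine
enumerates all of them (logged). A within-group bootstrap (groups
mean-centered so the null holds) is available as an alternative
resampling mode. Tie counting is exact: the observed labeling is pushed
through the same BLAS path as the null columns, so exhaustive
enumeration reproduces a brute-force oracle bit for bit. Genes with a
zero denominator and c₀ = 0 are flagged undefined, logged, excluded from
DEG calls. FDR control is Benjamini–Hochberg step-up (via statsmodels),
with NaN p-values excluded.

Permutation calibration has a structural limitation under the very
heteroscedasticity the half statistics target: permuted "control" groups
absorb high-variance case samples, widening the null and making the test
conservative when r > 1. That motivates the second calibration below.

## Monte Carlo calibration (simulation studies)

The power engine evaluates, per scenario (distribution family, md, r),
the rejection rate of each statistic at significance level α:

* t statistics: parametric two-sided critical values (df = n₁+n₀−2 and
  n₀−1).
* SAM-type scores: a **simulated-null calibration** — the md = 0, r = 1
  scenario of the same family is run once; the per-dataset c₀ estimates
  are frozen at their median, and the two-sided critical value is the
  (1−α) quantile of |score| under that null with the frozen c₀. Both
  constants are then applied unchanged to every cell of the grid.

Freezing c₀ at the null value matters twice over. Re-estimating c₀ on
each alternative dataset (a) contaminates the estimate when every gene
carries the effect, and (b) cancels the variance-detection property:
at md = 0, equal group sizes give Var(X̄₁−X̄₀) = (s₁²+s₀²)/n =
E[sₚ²(1/n₁+1/n₀)], so a c₀ that rescales with the data keeps the SAM
score calibrated at any r, while a frozen c₀ lets the score detect
variance inflation. Label-permutation calibration (per-gene or pooled)
remains available in the engine via `calibration="permutation"`.

## Synthetic data generator

Control entries are drawn i.i.d. with mean μ₀ and SD s₀, case entries
with mean μ₀ + md and SD r·s₀, from one of:

* **normal**;
* **uniform** — moment-matched U(μ ± √3·σ), the symmetric non-normal
  family (only mean and SD are design quantities);
* **gamma_right** — Gamma(shape) rescaled/shifted to the target moments;
  default shape 4 (skewness 1): visibly skewed with finite moments, and
  exposed in the config for sensitivity analysis;
* **gamma_left** — the reflection of gamma_right about its mean (same
  moments, negated skewness);
* **mixture** — case group only: default 0.5·N(μ₀, s₀²) +
  0.5·N(μ₀ + 2·md, s₀²), components drawn independently per entry, so
  the marginal case mean shift is md while individual patients split
  into an "unaffected" and a "strongly shifted" subgroup; fully
  configurable via `MixtureSpec`.

Study defaults are the standard grid: 1000 genes per dataset,
n₀ = n₁ = 10, s₀ = 15, md ∈ {0, 10, 15}, r ∈ {1, 1.5, 2}, α = 0.05,
B = 200 permutations when permutation calibration is requested, and
μ₀ = 100 (immaterial: every statistic is location invariant, and the
suite checks rates are bit-identical for μ₀ ∈ {0, 100}). `reps` counts
gene-level tests; the acceptance script uses 100 datasets × 1000 genes
per cell, a scale at which the binomial Monte Carlo SE of a rate near
30% is about 0.15 points. Unequal group sizes are supported (n₀ ≠ n₁ in
the config).

What the generator does **not** emulate: gene–gene correlation (genes
are independent, so Monte Carlo SEs understate dataset-to-dataset
variability of discovery counts on real arrays), per-gene variance
heterogeneity beyond the case/control ratio, intensity-dependent
mean–variance trends, and count-type (negative binomial) noise. Passing
the suite therefore certifies the statistics and their calibration under
the stated sampling models, not performance on any particular platform.

## Numerical choices

* Sample SDs use the n−1 denominator throughout (matching the weights in
  the pooled-variance formula).
* Zero denominators with c₀ = 0 yield NaN scores flagged `undefined`,
  never exceptions; they are excluded from p-value ranking and DEG
  calls.
* Fudge-factor ties break to the lowest percentile; window count is
  min(100, ⌊G/2⌋).
* Add-one p-value estimators never return 0; in exhaustive mode the
  same convention applies (the observed assignment is among the
  enumerated ones), keeping p ≥ 1/(B+1) uniformly.
* Permutation variance computation uses the E[x²]−m² form with negative
  values clipped at 0 before the square root.
* All randomness flows through `numpy.random.Generator`; every public
  entry point takes a seed or generator, and identical seeds give
  bit-identical results.

## Known limitations

* The half statistics assume the *control* group is the homogeneous
  reference; with a heterogeneous control group they lose their
  rationale.
* Per-gene permutation p-values at small B cannot reach BH thresholds
  below 1/(B+1); use the pooled null or a larger B for FDR work.
* The score tests conflate mean and variance differences by design;
  follow-up inspection of group SDs is advised for any hit.
* The simulated-null calibration assumes the analyst can simulate from
  a credible null family; for observed data only the permutation and
  bootstrap calibrations apply.
* Multi-class, paired, survival and quantitative-outcome designs are out
  of scope, as are microarray preprocessing and count-model-specific
  (negative binomial) inference.
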