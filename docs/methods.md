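# Methods

This note records the statistical model, its assumptions, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Model

For each maturity indicator (hand/wrist, third molar, distal femur,
clavicle) and each sex separately, the ordinal stage S observed on an image
is modelled conditionally on chronological age A, and the age density given
a stage is obtained by Bayes' theorem under a uniform prior on a bounded
support:

P(A | S = s) ∝ P(S = s | A) on [a, b], normalised to unit area.

Two ordinal families are implemented, each with logit or probit link F and
parallel (shared) or non-parallel (per-boundary) slopes:

- **cumulative**: P(S ≤ j | a) = F(α_j + β_j a); category probabilities are
  successive differences.
- **continuation ratio** (ascending): boundary hazards
  h_j(a) = P(S = j | S ≥ j, a) = F(α_j + β_j a);
  P(S = j | a) = h_j(a) Π_{k<j} (1 − h_k(a)), the last stage being the
  remainder.  The ascending ("conditioning on S ≥ j") direction is a
  convention; the descending form is a relabelling of the same family.

Age enters untransformed.  With two stages (distal femur open/closed) all
eight candidates collapse to binary regression; the test suite asserts this
equivalence exactly for fixed coefficients and to optimiser precision for
independent fits.

## Priors

The uniform prior encodes no age information; its support does.  Defaults,
per indicator and sex (years):

| indicator    | male      | female    | rationale |
|--------------|-----------|-----------|-----------|
| hand/wrist   | 7–21      | 7–20      | end of the second-to-last skeletal-age grade |
| third molar  | 7–21      | 7–21      | age at which half the population reaches stage H |
| distal femur | 15–21     | 15–21     | range over which the open/closed dichotomy is informative |
| clavicle     | 10–32     | 10–30     | age at which half the population reaches stage 5 |

Combined (third molar + one skeletal site) supports: clavicle 10–26.0
(dental curves are evaluated up to 26 in this combination, the data being
truncated there), hand/wrist 7–21, distal femur 15–21 with dental stages
restricted to D–H.  Lower bounds of combinations are the larger of the two
single-indicator lower bounds; this is configurable.  Skeletal indicators
are never combined with each other: conditional independence given age is
assumed only between dental and skeletal maturation.

Raising an upper bound reallocates prior mass upward and can only lower
P(A < t | s); this monotonicity is property-tested.

## Population recreation

Published studies are ingested in four aggregate formats and expanded to
individual-level populations:

- **type 2** (stage counts per integer age cohort): ages drawn uniformly on
  the cohort interval [k, k+1), intersected with a per-stage global age
  range when reported.  Cohorts are half-open to avoid double counting.
- **type 3a** (per-stage n, mean, SD, optional range): a normal, or a
  truncated normal whose *truncated* mean and SD match the reported values
  (two-equation root find; residuals above 1e-6 raise an infeasibility
  error — note no truncated normal on [a, b] can reach the uniform SD limit
  (b − a)/√12).
- **type 3b** (per-stage five-number summary): a truncated normal fitted by
  least squares between theoretical and reported quantiles.  The objective
  uses the quartiles plus the reported extremes placed at the expected
  order-statistic positions 1/(n+1) and n/(n+1); a quartiles-only mode is
  available (`include_extremes=False`) since which variant a given study
  effectively constrains is not always knowable.  When no explicit range is
  reported the extremes serve as the truncation bounds.  Weights are equal
  across the matched quantiles.
- **type 4** (cohort means/SDs of chronological and skeletal age plus
  Pearson r): two-step bivariate-normal sampling — CA from N(μ_CA, σ_CA),
  then skeletal age from the conditional normal given CA — followed by
  discretisation to the **nearest** label on the skeletal-age grid.
  Nearest-label is the minimal-assumption rule; it attenuates the sample
  correlation slightly on coarse grids (visible in the tests, which either
  allow a small slack or use a dense grid).

Individual-level (type 1) tables are ingested as-is; figure-digitised data
are treated as already-extracted type 1 input.  An ensemble of recreations
(default 10,000; tests and examples use far fewer) propagates recreation
uncertainty: one model fit per recreated population, with the 50th
percentile of any downstream statistic as the estimate and the
2.5th/97.5th percentiles as its 95% interval.  This reads the recreation
ensemble itself as the bootstrap; an additional within-population
resampling level is not applied.

## Fitting and selection

Maximum likelihood by L-BFGS-B with analytic gradients for both links, on
standardised age for conditioning (coefficients are mapped back to the age
scale).  Starts are moment-based: boundary intercepts from marginal stage
proportions, slopes at zero; up to three jittered restarts (fixed internal
seed, so fits are deterministic given data) are tried when the first
attempt is not stationary.  Tolerances: `ftol` 1e-12, `gtol` 1e-8.  Hard
parameter boxes are deliberately *not* passed to the optimiser (they can
abort its first line search when the initial gradient is steep); runaway
standardised coefficients beyond ±200 are instead capped afterwards with a
complete-separation warning.  Non-parallel cumulative models can cross
their boundary curves and imply negative category probabilities; the
objective adds a smooth quadratic penalty below a 1e-12 floor, and
evaluation floors at zero and renormalises, keeping the Bayes inversion
well defined.  The continuation-ratio construction cannot go negative and
carries no penalty.

Model choice: every candidate is fitted to every population of the
ensemble; the candidate with the lowest **median AIC** (AIC = 2k − 2logL)
wins.  Populations where a fit fails are dropped from that candidate's
median and counted.  A simulation study (20 replicates × 200 populations of
300 individuals from a 3-stage continuation-ratio truth with boundary
slopes −2.4 and −0.7) verifies that the true family is recovered in the
majority of replicates.

The cumulative-logit-parallel likelihood is cross-checked against
statsmodels' `OrderedModel` on the same data; the two log-likelihoods agree
to well under 0.1.

## Posterior quantities

Densities live on a fixed grid (default step 0.01 years, configurable;
at least 100 steps are required across any support) and all integrals are
trapezoid sums, making results bit-reproducible.  P(A < t) integrates the
piecewise-linear density exactly up to t; one-year cohort masses are
differences of that function and sum to one; prediction intervals are
equal-tailed (quantiles at (1 ± level)/2 by inverse interpolation of the
gridded CDF) — a highest-density variant was considered and not adopted, as
equal-tailed intervals are directly comparable across stages and the
posteriors are unimodal in practice.  A normaliser below 1e-300 raises a
degenerate-posterior error rather than returning garbage.

## Classification and validation

P(A < t | s) above the 0.35 cutoff classifies an individual as below the
threshold; below the cutoff, as above.  The asymmetric cutoff trades
specificity for fewer minors classified as adults.  A probability exactly
at the cutoff classifies as "above": the cutoff's own asymmetry already
provides the protective bias, ties are measure-zero, and a documented rule
beats an undefined one.  Note the resulting monotonicity runs with the
cutoff: *raising* the cutoff can only add "above" classifications.

Metrics use "above the threshold" as the positive class: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), PPV, NPV, accuracy.  Empty denominators
are reported as undefined, never as zero.  Ages exactly at a threshold
count as above it.  The minimum validation sample size for a binary
outcome at prevalence p, margin m and normal quantile z is
n = (z/m)² p(1−p), truncated to an integer — truncation, not ceiling,
reproduces the conventional 195 at p = 0.15, m = 0.05, z = 1.96.  An
optional ROC sweep is provided as a diagnostic; 0.35 remains the operating
rule.

## Synthetic ground truth

The generator draws ages from a chosen law (uniform, triangular, or a
two-piece uniform mixture) and stages from a known stage-given-age model,
so every pipeline stage has an exact oracle.  Indicator presets use
hand-tuned continuation-ratio coefficients with the right stage counts
(8, 6, 2, 5) and transitions at plausible ages — they are test fixtures,
not estimates of any real population.  `summarize` inverts each recreation
format, enabling round-trip checks; `generate_age_mimicry_pair` yields two
populations sharing one transition truth under different age laws, and the
end-to-end check that their posteriors agree (P(A < 18) gaps below 0.03 at
n = 10⁴) demonstrates the design rationale for the two-step procedure.

What passing these tests does **not** show: that the presets resemble real
maturation data, that real studies satisfy the per-stage normality or
conditional-independence assumptions, or anything about staging error by
human readers — real validation requires independent staged populations,
which are deliberately out of scope here.

## Problem sizes

Rejection-sampling oracles use 10⁶ draws (empirical-CDF noise well below
the 0.02 tolerance the tests assert); recovery fits use n = 5000;
recreation round trips use n = 10⁴; the selection study uses 20 × 200
populations; bootstrap examples use 100–200 recreations.  The
parameter-recovery check is a majority vote over five replicate datasets
because a per-coefficient 3-SE check over ten correlated estimates fails by
chance a few percent of the time even for a calibrated estimator (a 30-replicate calibration run
showed mean z ≈ 0, SD ≈ 1 for every coefficient).

## Known limitations

- Stage curves are evaluated beyond the age range of the fitting data when
  a combined support requires it (clavicle + molar up to 26); this is an
  explicit extrapolation of the parametric model.
- Nearest-label discretisation for type 4 is one of several defensible
  conventions and attenuates correlations on coarse grids.
- The quantile objective for type 3b assumes the reported five numbers are
  consistent with a single truncated normal; strongly non-normal stage-age
  distributions will fit poorly and are better excluded upstream (the
  chi-square uniformity screen covers only the age distribution).
- No dependence modelling between skeletal indicators is attempted; such
  combinations are refused rather than approximated.
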