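"""From an observed stage to P(age below 15/18/21) with uncertainty.

The fitted stage-given-age curve is inverted with Bayes' theorem under a
uniform prior on the indicator's age support, giving a posterior age
density for the observed stage.  Integrating it yields the probability of
being below each legal threshold, one-year cohort masses, and prediction
intervals; an ensemble of recreated populations gives a bootstrap interval
for the threshold probability.
"""

from pathlib import Path

import thresholdage as ta

DATA = Path(__file__).parent / "data"

summary = ta.read_summary(DATA / "summary_type2.yaml")
spec = ta.ModelSpec("continuation_ratio", "logit", "non_parallel")
support = ta.default_support("third_molar", "male")

pop = ta.recreate(summary, seed=21)
model = ta.fit(spec, pop)

stage = "F"
post = ta.posterior_age_given_stage(model, stage, support)
print(f"third molar stage {stage}, male, uniform prior on "
      f"[{support.lower:g}, {support.upper:g}] years")
for t in (15.0, 18.0, 21.0):
    p = ta.prob_below(post, t)
    print(f"  P(age < {t:g}) = {p:.2f}   margin of error = {min(p, 1-p):.2f}")
lo75, hi75 = ta.prediction_interval(post, 0.75)
lo95, hi95 = ta.prediction_interval(post, 0.95)
print(f"  75% PI: {lo75:.1f}-{hi75:.1f} y   95% PI: {lo95:.1f}-{hi95:.1f} y")

print("\none-year cohort masses (share of the posterior in [k, k+1)):")
for k, mass in ta.cohort_probabilities(post).items():
    if mass > 0.005:
        print(f"  [{k},{k + 1}): {mass:.3f}")

# bootstrap across recreations: median is the reported estimate, the
# 2.5/97.5 percentiles its 95% interval
ensemble = ta.simulate_population_ensemble(summary, n_pops=100, seed=22)
est = ta.bootstrap_threshold_estimate(ensemble, spec, stage, support, 18.0)
print(f"\nbootstrap over {est.n_fits} recreated populations:")
print(f"  P(age < 18 | stage {stage}) = {est.median_probability_below:.2f} "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}), "
      f"margin of error {est.margin_of_error:.2f}")
print("the margin of error is the posterior mass on the minority side of",
      "the threshold — the error rate of a below/above statement")
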