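"""Validate threshold classification on an independent population.

Each individual's true stage gives a posterior probability of being below
the threshold; probabilities above the 0.35 cutoff classify the individual
as below it (the low cutoff deliberately protects against classifying
minors as adults).  Against known ages this yields sensitivity/specificity/
PPV/NPV/accuracy per threshold.
"""

import thresholdage as ta

spec = ta.ModelSpec("continuation_ratio", "logit", "non_parallel")
support = ta.default_support("third_molar", "male")

model = ta.fit(spec, ta.generate_population(
    ta.preset_truth("third_molar", "male", n=5000, seed=41)))
validation = ta.generate_population(
    ta.preset_truth("third_molar", "male", n=800, seed=42))

counts, report = ta.evaluate(validation, model, support,
                             thresholds=(15.0, 18.0), cutoff=0.35)
for t in (15.0, 18.0):
    c = counts[t]
    print(f"{t:g}-year threshold  (TP={c.tp} FN={c.fn} TN={c.tn} FP={c.fp}):")
    for name, value in report[t].items():
        shown = f"{value:.2f}" if value is not None else "-"
        print(f"  {name:<12} {shown}")
print("sensitivity: individuals above the threshold identified as above;")
print("specificity: individuals below identified as below; '-' marks a")
print("metric with no individuals in its denominator")

n = ta.min_validation_sample_size(prevalence=0.15, margin=0.05, z=1.96)
print(f"\nminimum validation sample size at a 15% expected misclassification"
      f" rate and 5% margin: {n} individuals per sex")
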