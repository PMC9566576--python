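"""Classify raw-meat species from synthetic polar-extract spectra.

Simulates the default raw-meat study set (379 samples: 175 pork, 105 beef,
61 lamb, 38 poultry), pretreats the spectra (1000 buckets over 0.50-9.50 ppm,
water exclusion, TSP normalization, log transform), and validates the
PCA/LDA/nearest-class-mean classifier with a 10-fold cross-validation
embedded in 10 Monte-Carlo resampling runs.  The aggregated confusion matrix
sums the 100 fold-level matrices; its diagonal percentages are the per-class
accuracies.
"""

import nmrmeat as nm

sset = nm.simulate_dataset(nm.default_raw_config(seed=1), kind="raw")
fm = nm.preprocess_set(sset, nm.default_polar_spec())
print(f"feature matrix: {fm.n_samples} samples x {fm.n_buckets} retained buckets")

result = nm.run_mccv(fm, plan=nm.CVPlan(n_folds=10, n_mc=10, seed=2))
agg = result.aggregate

print("\naggregated confusion matrix (true class x assigned class):")
print(agg.to_dataframe())
print("\nper-class accuracy (%):")
for label, acc in zip(agg.labels, agg.per_class_accuracy):
    print(f"  {label:8s} {acc:6.2f}")
print(f"overall accuracy: {agg.overall_accuracy:.2f}% over {agg.total} assignments")
print(
    "\nEach sample is tested once per CV and there are 10 Monte-Carlo runs, so "
    "row totals are 10x the class sample counts; accuracies near 100% mean the "
    "species fingerprints separate cleanly in the discriminant space."
)
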