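"""Mid-level data fusion and robustness against two-species mixtures.

Builds paired polar and non-polar blocks for the same 379 samples, compares
single-block cross-validated accuracies with the fused model (per-block PCA
scores concatenated, one LDA on the joint space), then challenges the fused
model with mixture spectra.  A mixture should fit *no* species class: every
per-class chi-square membership p-value should fall below 0.05.
"""

import nmrmeat as nm
from nmrmeat.simulate import simulate_mixture

polar = nm.simulate_dataset(nm.default_raw_config(seed=1), kind="raw")
nonpolar = nm.simulate_paired_nonpolar_block(polar, nm.default_nonpolar_config(seed=1))
fm_p = nm.preprocess_set(polar, nm.default_polar_spec())
fm_n = nm.preprocess_set(nonpolar, nm.default_nonpolar_spec())

plan = nm.CVPlan(seed=2)
for name, res in [
    ("polar", nm.run_mccv(fm_p, plan=plan)),
    ("nonpolar", nm.run_mccv(fm_n, plan=plan)),
    ("fused", nm.run_fused_mccv(fm_p, fm_n, plan=plan)),
]:
    agg = res.aggregate
    per = ", ".join(f"{c} {a:.1f}" for c, a in zip(agg.labels, agg.per_class_accuracy))
    print(f"{name:8s} overall {agg.overall_accuracy:6.2f}%   per-class: {per}")
print(
    "\nThe non-polar block separates beef and lamb poorly by design; fusing the "
    "two blocks recovers the polar block's accuracy for every class."
)

fc = nm.fit_fused_classifier(fm_p, fm_n)
p_by_id = {s.sample_id: s for s in polar}
n_by_id = {s.sample_id: s for s in nonpolar}
pairs = [
    ("beef-000", "pork-000", 0.5),
    ("poultry-000", "pork-001", 0.5),
    ("poultry-001", "pork-002", 0.09),  # 9% admixture: hardest case
]
mix_p = nm.SpectrumSet([simulate_mixture(p_by_id[a], p_by_id[b], f) for a, b, f in pairs])
mix_n = nm.SpectrumSet([simulate_mixture(n_by_id[a], n_by_id[b], f) for a, b, f in pairs])
pvals = nm.fused_membership_pvalues(
    fc, nm.preprocess_set(mix_p, nm.default_polar_spec()),
    nm.preprocess_set(mix_n, nm.default_nonpolar_spec()),
)
print("\nper-class membership p-values of the mixtures (fused model):")
print(pvals.round(4))
print(
    "\nBalanced mixtures are rejected by every class (all p < 0.05).  A 9% "
    "admixture shifts the spectrum by much less than the majority class's "
    "within-class spread, so it still fits that class — detecting such low "
    "admixture levels is beyond a class-membership test at these variances."
)
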