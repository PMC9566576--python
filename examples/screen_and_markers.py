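"""Find spectral regions and marker buckets that separate the species.

Two complementary views on the same feature matrix:

* a per-bucket Kruskal-Wallis scan across the four species, with the
  family-wise level alpha = 0.001 Šidák-corrected over the number of retained
  buckets — flags every region carrying species information;
* a two-class PCA/LDA marker report (pork vs lamb), ranking buckets by their
  |LD1 loading| — names the buckets actually driving the discrimination,
  with box-whisker summaries per class.
"""

import nmrmeat as nm

sset = nm.simulate_dataset(nm.default_raw_config(seed=1), kind="raw")
fm = nm.preprocess_set(sset, nm.default_polar_spec())

scan = nm.scan_buckets(fm, alpha=0.001)
print(
    f"Kruskal-Wallis scan: {int(scan.significant.sum())} of {scan.k} buckets "
    f"significant at the Sidak-corrected level {scan.alpha_sid:.3g}"
)
sig = scan.significant_centers()
print(f"significant regions span {sig.min():.3f} to {sig.max():.3f} ppm")
for ppm in (1.340, 4.120):  # lactate: identical level in every species
    near = abs(scan.bucket_centers - ppm) < 0.009
    print(f"  lactate bucket near {ppm:.3f} ppm significant? {bool(scan.significant[near].any())}")

report = nm.two_class_marker_report(fm, classes=("pork", "lamb"), top_k=8)
print("\npork vs lamb: top buckets by |LD1 loading|")
print(report[["bucket_center", "ld1_loading", "direction_class"]].to_string(index=False))
print(
    "\nThe 'direction_class' column says which species a bucket elevates: "
    "choline (3.212 ppm) and hypoxanthine (8.19/8.23 ppm) point toward pork, "
    "O-acetyl-carnitine (2.14 ppm) toward lamb; the carnosine (8.500/7.239 ppm) "
    "and anserine (8.536/3.842 ppm) buckets rank just behind them."
)
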