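"""Per-cell intensity quantification on rendered synthetic images.

Renders well-separated untreated cells into two 8-bit channels (marker
background ~100, reporter background ~10), segments the marker channel
with the naive baseline, evaluates segmentation by IoU against the truth
masks, measures per-cell intensities on both channels through the same
masks, and tests the marker/reporter correlation (leakage only).
"""

import numpy as np

import shmirkit as sk

spec = sk.CoexprSpec(seed=7)
cells, regions, _ = sk.simulate_cell_table(spec)
untreated = cells[~cells["treated"]]

chat, reporter, labels, placed = sk.render_images(untreated, spec, seed=3, max_cells=25)
print(f"rendered {int(labels.max())} cells on a {chat.pixels.shape} grid")

chat_n, info = sk.normalize_background(chat, sk.NormalizationSpec())
print(f"marker background: {info.background_before:.1f} -> "
      f"{info.background_after:.1f} (target 100, {info.n_clamped} px clamped)")

predicted = sk.naive_segment(chat_n, threshold=125, min_area=30)
truth = sk.masks_from_labels(labels)
report = sk.iou_evaluate(predicted, truth)
print(f"naive segmentation: {len(predicted)} objects, mean IoU = {report.mean_iou:.3f}")
print("  (>= 0.7 is the working bar for a usable segmentation)")

meas_chat = sk.measure_cells(chat, truth, background=100.0)
meas_rep = sk.measure_cells(reporter, truth, background=10.0)
print(f"measured {len(meas_chat)} cells; "
      f"median marker amplitude {meas_chat['mean_intensity'].median():.1f}, "
      f"median reporter amplitude {meas_rep['mean_intensity'].median():.1f}")

corr = sk.intensity_correlation(meas_chat["mean_intensity"], meas_rep["mean_intensity"])
print(f"marker/reporter correlation: r = {corr.r:.3f}, p = {corr.p:.3g}")
print("  positive r in untreated tissue reflects the small channel leakage")
print("  (weak at 25 cells; it is clearly resolved at a few hundred cells)")

rng = np.random.default_rng(0)
ks = sk.ks_median_shift(
    rng.normal(90, 30, 500), rng.normal(105, 30, 500), m_comparisons=6
)
print(f"\nKS on a planted 0.5 SD intensity shift (n=500/500): D = {ks.D:.3f}, "
      f"Bonferroni p = {ks.p_adj:.3g} "
      f"(medians {ks.median_treated:.0f} vs {ks.median_untreated:.0f})")
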