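"""Per-cell fluorescence quantification from label masks, background
normalisation, distribution-shift tests, and IoU segmentation evaluation.

Images are 8-bit single-channel grids (0-255).  The segmenter itself is
pluggable: any tool producing label masks can feed :func:`measure_cells`
and :func:`iou_evaluate`; :func:`naive_segment` is a thresholding baseline
for synthetic renders, not a replacement for a trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

__all__ = [
    "ChannelImage",
    "CellMask",
    "NormalizationSpec",
    "NormalizationInfo",
    "KSResult",
    "CorrelationResult",
    "IoUReport",
    "normalize_background",
    "measure_cells",
    "masks_from_labels",
    "labels_from_masks",
    "ks_median_shift",
    "intensity_correlation",
    "iou_evaluate",
    "naive_segment",
]


@dataclass
class ChannelImage:
    """One 8-bit channel plus a binary mask of the compartment
    (caudate/putamen) pixels used for background estimation."""

    pixels: np.ndarray
    channel: str  # 'ChAT' | 'reporter' (free-form accepted)
    region_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.region_mask is None:
            self.region_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.region_mask = np.asarray(self.region_mask).astype(bool)
            if self.region_mask.shape != self.pixels.shape:
                raise ValueError("region_mask shape must match pixels")


@dataclass(frozen=True)
class CellMask:
    """One cell's pixel set, as parallel row/column index arrays."""

    cell_id: int | str
    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=np.intp))
        object.__setattr__(self, "cols", np.asarray(self.cols, dtype=np.intp))
        if self.rows.size == 0 or self.rows.shape != self.cols.shape:
            raise ValueError("mask must be non-empty with matching index arrays")

    @property
    def area(self) -> int:
        return int(self.rows.size)

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass(frozen=True)
class NormalizationSpec:
    """Background targets: marker (ChAT) compartment background is brought
    to ~100 gray levels, reporter background (measured away from the
    injection site) to ~10."""

    chat_background_target: float = 100.0
    reporter_background_target: float = 10.0

    def target_for(self, channel: str) -> float:
        t = (
            self.chat_background_target
            if channel.lower() in ("chat", "ache", "marker")
            else self.reporter_background_target
        )
        if t <= 0:
            raise ValueError("background target must be positive")
        return t


@dataclass
class NormalizationInfo:
    scale: float
    background_before: float
    background_after: float
    n_clamped: int


def normalize_background(
    img: ChannelImage,
    spec: NormalizationSpec | float | None = None,
    background_mask: np.ndarray | None = None,
) -> tuple[ChannelImage, NormalizationInfo]:
    """Rescale so the background-mask mean hits the channel's target.

    All pixels are multiplied by target/background and rounded; values
    above 255 are clamped (count reported) to preserve the 8-bit range.
    Renormalising an already-normalised image is a no-op within rounding.
    """
    if spec is None:
        spec = NormalizationSpec()
    target = spec if isinstance(spec, (int, float)) else spec.target_for(img.channel)
    mask = img.region_mask if background_mask is None else np.asarray(background_mask, bool)
    bg = float(img.pixels[mask].mean()) if mask.any() else 0.0
    if bg <= 0:
        raise ValueError("background mean must be positive")
    scale = target / bg
    scaled = np.rint(img.pixels.astype(float) * scale)
    n_clamped = int((scaled > 255).sum())
    scaled = np.clip(scaled, 0, 255).astype(np.uint8)
    out = ChannelImage(scaled, img.channel, img.region_mask)
    info = NormalizationInfo(
        scale=scale,
        background_before=bg,
        background_after=float(out.pixels[mask].mean()),
        n_clamped=n_clamped,
    )
    return out, info


def masks_from_labels(label_img: np.ndarray) -> list[CellMask]:
    """Convert a label image (0 = background, k = cell k) to masks."""
    label_img = np.asarray(label_img)
    out = []
    for lab in np.unique(label_img):
        if lab == 0:
            continue
        rows, cols = np.nonzero(label_img == lab)
        out.append(CellMask(int(lab), rows, cols))
    return out


def labels_from_masks(masks: Sequence[CellMask], shape: tuple[int, int]) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.int32)
    for i, m in enumerate(masks, start=1):
        lab[m.rows, m.cols] = i
    return lab


def measure_cells(
    img: ChannelImage,
    masks: Sequence[CellMask],
    background: float = 0.0,
) -> pd.DataFrame:
    """Per-cell mean intensity (background-subtracted, floored at 0) and
    area in pixels.

    Masks outlined on the marker channel are transferable unchanged to the
    reporter channel: the same pixel sets are measured on both images.
    """
    h, w = img.pixels.shape
    rows = []
    for m in masks:
        if m.rows.min() < 0 or m.rows.max() >= h or m.cols.min() < 0 or m.cols.max() >= w:
            raise ValueError(f"mask {m.cell_id!r} out of image bounds")
        mean = float(img.pixels[m.rows, m.cols].mean()) - background
        rows.append({"cell_id": m.cell_id, "mean_intensity": max(mean, 0.0), "area_px": m.area})
    return pd.DataFrame(rows, columns=["cell_id", "mean_intensity", "area_px"])


# ---------------------------------------------------------------------------
# distribution tests

@dataclass
class KSResult:
    D: float
    p_raw: float
    p_adj: float
    median_treated: float
    median_untreated: float


def ks_median_shift(treated_values, untreated_values, m_comparisons: int = 1) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test with Bonferroni correction.

    ``m_comparisons`` is the explicit Bonferroni family size (no hidden
    default beyond 1); medians of both samples are reported so the shift
    direction is visible.
    """
    t = np.asarray(treated_values, dtype=float)
    u = np.asarray(untreated_values, dtype=float)
    if t.size < 2 or u.size < 2:
        raise ValueError("need at least 2 values per sample")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    res = stats.ks_2samp(t, u, method="asymp")
    p_raw = float(res.pvalue)
    return KSResult(
        D=float(res.statistic),
        p_raw=p_raw,
        p_adj=min(1.0, m_comparisons * p_raw),
        median_treated=float(np.median(t)),
        median_untreated=float(np.median(u)),
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float


def intensity_correlation(chat_means, reporter_means) -> CorrelationResult:
    """Pearson correlation of paired per-cell marker and reporter means,
    with the least-squares line for plotting."""
    x = np.asarray(chat_means, dtype=float)
    y = np.asarray(reporter_means, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    lr = stats.linregress(x, y)
    return CorrelationResult(
        r=float(lr.rvalue), p=float(lr.pvalue),
        slope=float(lr.slope), intercept=float(lr.intercept),
    )


# ---------------------------------------------------------------------------
# segmentation evaluation

@dataclass
class IoUReport:
    per_object: dict          # truth cell_id -> IoU (0 for unmatched)
    mean_iou: float
    matching: list[tuple]     # (truth_id, predicted_id or None, iou)


def iou_evaluate(predicted: Sequence[CellMask], truth: Sequence[CellMask]) -> IoUReport:
    """Greedy max-overlap matching of predicted to ground-truth objects.

    Pairs are matched in descending overlap order, each object used at
    most once; matched pairs score |intersection| / |union|, unmatched
    truth objects score 0.  The mean is over truth objects.
    """
    if not truth:
        raise ValueError("empty ground-truth set")
    t_sets = {m.cell_id: m.pixel_set() for m in truth}
    p_sets = {m.cell_id: m.pixel_set() for m in predicted}
    overlaps = []
    for tid, ts in t_sets.items():
        for pid, ps in p_sets.items():
            inter = len(ts & ps)
            if inter:
                overlaps.append((inter, tid, pid))
    overlaps.sort(key=lambda x: (-x[0], str(x[1]), str(x[2])))
    used_t: set = set()
    used_p: set = set()
    matching = []
    per_object = {}
    for inter, tid, pid in overlaps:
        if tid in used_t or pid in used_p:
            continue
        used_t.add(tid)
        used_p.add(pid)
        union = len(t_sets[tid] | p_sets[pid])
        iou = inter / union
        per_object[tid] = iou
        matching.append((tid, pid, iou))
    for tid in t_sets:
        if tid not in per_object:
            per_object[tid] = 0.0
            matching.append((tid, None, 0.0))
    return IoUReport(
        per_object=per_object,
        mean_iou=float(np.mean(list(per_object.values()))),
        matching=matching,
    )


def naive_segment(img: ChannelImage, threshold: float, min_area: int = 1) -> list[CellMask]:
    """Baseline segmenter: 8-connected components of supra-threshold
    pixels with area >= min_area."""
    if not (0 < threshold < 255):
        raise ValueError("threshold must lie in (0, 255)")
    binary = img.pixels > threshold
    lab = measure.label(binary, connectivity=2)
    out = []
    next_id = 1
    for region in measure.regionprops(lab):
        if region.area < min_area:
            continue
        coords = region.coords
        out.append(CellMask(next_id, coords[:, 0], coords[:, 1]))
        next_id += 1
    return out
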