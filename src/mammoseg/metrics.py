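"""Overlap-based segmentation evaluation against a reference mask.

The evaluation is TN-free: in an ROI the true-negative count is dominated
by background and says nothing about the mass contour, so only the pixel
counts TP (reference AND segmentation), FP (segmentation only) and FN
(reference only) enter. Six ratios are derived:

    Hitting         = TP / (TP + FN)      fraction of the reference found
    Missing         = FN / (TP + FN)      fraction of the reference missed
    OverHitting     = FP / (TP + FN)      false area, relative to reference
    RelativeHitting = TP / (TP + FP)      precision of the segmentation
    RelativeMissing = FN / (TP + FP)      missed area, relative to output
    Kappa           = 2*Hitting / (2*Hitting + Missing + OverHitting)

Kappa is algebraically the Dice coefficient 2*TP / (2*TP + FP + FN). All
ratios are computed unrounded; :meth:`SegMetrics.rounded` gives the 2-decimal
half-away-from-zero report view.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .raster_io import round_half_away

__all__ = ["ConfusionCounts", "SegMetrics", "confusion", "compute_metrics", "dice"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts of the reference/segmentation overlap (TN unused)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class SegMetrics:
    hitting: float
    missing: float
    over_hitting: float
    relative_hitting: float
    relative_missing: float
    kappa: float

    def rounded(self, decimals: int = 2) -> "SegMetrics":
        """Report view: every ratio rounded half-away-from-zero."""
        return SegMetrics(**{f.name: round_half_away(getattr(self, f.name), decimals)
                             for f in fields(self)})

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(ref: np.ndarray, seg: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/FN between a reference mask and a segmentation mask."""
    r = np.asarray(ref)
    s = np.asarray(seg)
    if r.shape != s.shape:
        raise ValueError(f"reference shape {r.shape} != segmentation shape {s.shape}")
    r = r > 0
    s = s > 0
    return ConfusionCounts(tp=int((r & s).sum()),
                           fp=int((s & ~r).sum()),
                           fn=int((r & ~s).sum()))


def compute_metrics(c: ConfusionCounts) -> SegMetrics:
    """Derive the six overlap ratios from unrounded arithmetic.

    Requires a nonempty reference (tp+fn > 0) and a nonempty segmentation
    (tp+fp > 0).
    """
    ref_area = c.tp + c.fn
    seg_area = c.tp + c.fp
    if ref_area == 0:
        raise ValueError("empty reference mask: tp + fn == 0")
    if seg_area == 0:
        raise ValueError("empty segmentation mask: tp + fp == 0")
    hitting = c.tp / ref_area
    missing = c.fn / ref_area
    over = c.fp / ref_area
    return SegMetrics(
        hitting=hitting,
        missing=missing,
        over_hitting=over,
        relative_hitting=c.tp / seg_area,
        relative_missing=c.fn / seg_area,
        kappa=2.0 * hitting / (2.0 * hitting + missing + over),
    )


def dice(ref: np.ndarray, seg: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    c = confusion(ref, seg)
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2.0 * c.tp / denom
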