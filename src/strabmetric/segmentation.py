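"""Segmenter contract, reference threshold segmenter, mask utilities and
confusion-matrix evaluation metrics.

A segmenter is anything with ``segment(image, target) -> bool mask`` for
``target in {"sclera", "limbus"}``; a trained model can be slotted in behind
the same contract.  :class:`ThresholdSegmenter` is the reference
implementation for synthetic scenes: it bands intensities, opens away specks
and thin interpolation rims, and fills holes (e.g. the reflex punched into
the limbus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize

from .errors import DegenerateMaskError, SpecificationError

__all__ = [
    "Segmenter", "ThresholdSegmenter", "segment_threshold", "resize_mask",
    "ConfusionCounts", "SegmentationMetrics", "confusion_counts",
    "segmentation_metrics", "split_eyes",
]

SEGMENT_TARGETS = ("sclera", "limbus")


@runtime_checkable
class Segmenter(Protocol):
    """Pluggable segmentation contract."""

    def segment(self, image: np.ndarray, target: str) -> np.ndarray: ...


def _to_gray01(image: np.ndarray) -> np.ndarray:
    """Coerce to a single-channel float image in [0, 1]."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    elif img.ndim != 2:
        raise SpecificationError(f"expected a 2D or 3D image, got ndim={img.ndim}")
    img = img.astype(np.float64)
    if img.size and img.max() > 1.0:
        img = img / 255.0
    return img


@dataclass(frozen=True)
class ThresholdSegmenter:
    """Intensity-band segmenter matched to the synthetic render levels.

    The "sclera" band covers the whole eyeball disk (sclera, limbus and
    reflex intensities) because the eyeball outline is what the registration
    and sclera modeling stages need.
    """

    sclera_band: tuple[float, float] = (0.25, 1.001)
    limbus_band: tuple[float, float] = (0.25, 0.55)
    opening_radius: int = 2
    min_area: int = 40

    def segment(self, image: np.ndarray, target: str) -> np.ndarray:
        if target not in SEGMENT_TARGETS:
            raise SpecificationError(
                f"unknown segmentation target {target!r}; expected one of "
                f"{SEGMENT_TARGETS}")
        img = _to_gray01(image)
        lo, hi = self.sclera_band if target == "sclera" else self.limbus_band
        mask = (img >= lo) & (img < hi)
        if self.opening_radius > 0:
            mask = ndimage.binary_opening(mask, structure=disk(self.opening_radius))
        if self.min_area > 0 and mask.any():
            labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
            if n:
                areas = np.bincount(labels.ravel())
                areas[0] = 0
                mask = areas[labels] >= self.min_area
        return ndimage.binary_fill_holes(mask)


def segment_threshold(image: np.ndarray, target: str,
                      **options) -> np.ndarray:
    """Functional wrapper around :class:`ThresholdSegmenter`."""
    return ThresholdSegmenter(**options).segment(image, target)


def resize_mask(mask: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample of a binary mask to ``out_shape`` (H, W)."""
    h, w = int(out_shape[0]), int(out_shape[1])
    if h <= 0 or w <= 0:
        raise SpecificationError(f"output shape must be positive, got {out_shape}")
    mask = np.asarray(mask)
    if mask.shape == (h, w):
        return mask.astype(bool).copy()
    out = resize(mask.astype(np.float64), (h, w), order=0,
                 anti_aliasing=False, preserve_range=True)
    return out > 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class SegmentationMetrics:
    """Percent metrics; a zero-denominator ratio is ``None``, never 0."""

    accuracy_pct: float | None
    sensitivity_pct: float | None
    specificity_pct: float | None
    dsc_pct: float | None

    def rounded(self, ndigits: int = 2) -> "SegmentationMetrics":
        rnd = lambda v: None if v is None else round(v, ndigits)
        return SegmentationMetrics(rnd(self.accuracy_pct), rnd(self.sensitivity_pct),
                                   rnd(self.specificity_pct), rnd(self.dsc_pct))


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-by-pixel confusion counts between two equal-shape binary masks."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise SpecificationError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio_pct(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def segmentation_metrics(c: ConfusionCounts,
                         dice_variant: str = "standard") -> SegmentationMetrics:
    """Accuracy, sensitivity, specificity and Dice, in percent.

    ``dice_variant="standard"`` computes 2TP/(2TP+FP+FN); the
    ``"total_normalized"`` variant (2TP over all pixels) is retained for
    auditability but is not a Dice coefficient.
    """
    if c.total <= 0:
        raise SpecificationError("confusion counts are empty")
    if dice_variant == "standard":
        dsc = _ratio_pct(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    elif dice_variant == "total_normalized":
        dsc = _ratio_pct(2 * c.TP, c.total)
    else:
        raise SpecificationError(f"unknown dice variant {dice_variant!r}")
    return SegmentationMetrics(
        accuracy_pct=_ratio_pct(c.TP + c.TN, c.total),
        sensitivity_pct=_ratio_pct(c.TP, c.TP + c.FN),
        specificity_pct=_ratio_pct(c.TN, c.FP + c.TN),
        dsc_pct=dsc,
    )


def split_eyes(mask: np.ndarray, min_area: int = 40,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Split a two-eye mask into (image-left, image-right) components.

    Keeps the two largest 8-connected components with area >= ``min_area``;
    the component with the smaller centroid-x is the image-left eye.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n < 2:
        raise DegenerateMaskError(
            f"expected >=2 connected components, found {n}")
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    ids = [i for i in np.argsort(areas)[::-1][:2] if areas[i] >= min_area]
    if len(ids) < 2:
        raise DegenerateMaskError(
            f"fewer than 2 components with area >= {min_area}")
    comps = []
    for i in ids:
        comp = labels == i
        cx = np.nonzero(comp)[1].mean()
        comps.append((cx, comp))
    comps.sort(key=lambda t: t[0])
    return comps[0][1], comps[1][1]
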