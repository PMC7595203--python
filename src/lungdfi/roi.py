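"""Lung ROI masks, osseous exclusion and per-lung mean signals.

The transplanted (left) and native control (right) lung outlines come from
the phantom's ground-truth anatomy (in the original study they were drawn
manually by radiologists on the absorption images); ribs and spine are then
excluded algorithmically: threshold on a pre-smoothed absorption image
followed by a binary opening.  Because absorption and dark-field images stem
from the same exposure, one pixel set serves both modalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from skimage.morphology import disk

from .retrieval import ModalityImages

__all__ = [
    "LungMasks",
    "RoiMeans",
    "presmooth",
    "segment_bone",
    "mean_signal",
    "detect_pneumothorax",
    "build_lung_masks",
    "quantify_animal",
]

logger = logging.getLogger(__name__)

MIN_ROI_PIXELS = 50


@dataclass
class LungMasks:
    """Final per-lung ROI masks (lung outline minus segmented bone)."""

    transplanted_mask: np.ndarray
    control_mask: np.ndarray
    bone_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.transplanted_mask & self.control_mask):
            raise ValueError("transplanted and control masks overlap")
        if np.any((self.transplanted_mask | self.control_mask) & self.bone_mask):
            raise ValueError("final lung masks must exclude every bone pixel")


@dataclass
class RoiMeans:
    """Per-lung mean signals of one animal at one time point."""

    transplanted_absorption: float
    transplanted_darkfield: float
    control_absorption: float
    control_darkfield: float
    n_pixels_transplanted: int
    n_pixels_control: int


def presmooth(image: np.ndarray, scale: float = 2.0) -> np.ndarray:
    """Isotropic Gaussian low-pass used before bone thresholding.

    Mass-conserving on interior support; a constant image is a fixed point.
    """
    if scale <= 0:
        raise ValueError("smoothing scale must be positive")
    return gaussian_filter(np.asarray(image, dtype=np.float64), sigma=scale, mode="nearest")


def segment_bone(
    absorption: np.ndarray,
    threshold: float | None = None,
    morph_radius: int = 2,
    smooth_scale: float = 2.0,
    body_mask: np.ndarray | None = None,
    dilation_extra: int = 0,
) -> np.ndarray:
    """Segment ribs and spine from an absorption image.

    Threshold on the pre-smoothed image, then binary erosion followed by
    dilation (a morphological opening when ``dilation_extra`` is 0, which
    removes speckle; a positive extra radius adds a safety margin around
    bone edges instead).  When ``threshold`` is None an adaptive value is
    used: the midpoint between the in-body median (soft tissue) and the
    99.5th percentile (cortical bone plateau).
    """
    img = np.asarray(absorption, dtype=np.float64)
    finite = np.isfinite(img)
    sm = presmooth(np.where(finite, img, 0.0), smooth_scale)
    if threshold is None:
        sel = finite if body_mask is None else (finite & body_mask)
        lo, hi = np.percentile(img[sel], [50.0, 99.5])
        threshold = 0.5 * (lo + hi)
    raw = sm > threshold
    # r-fold erosion/dilation with the unit disk == opening by its r-fold
    # Minkowski sum: idempotent, and monotone in the radius
    mask = binary_erosion(raw, structure=disk(1), iterations=morph_radius)
    mask = binary_dilation(mask, structure=disk(1), iterations=morph_radius + dilation_extra)
    if mask.all() or not mask.any():
        logger.warning(
            "bone segmentation returned an %s mask; threshold %.3g is likely misconfigured",
            "all-true" if mask.all() else "empty", threshold,
        )
    return mask


def mean_signal(image: np.ndarray, mask: np.ndarray, label: str = "ROI") -> float:
    """Arithmetic mean of the signal over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    vals = np.asarray(image, dtype=np.float64)[mask]
    if vals.size == 0:
        raise ValueError(f"empty effective mask for {label}")
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite signal inside {label}")
    return float(vals.mean())


def detect_pneumothorax(
    modalities: ModalityImages,
    left_mask: np.ndarray,
    tau_darkfield: float = 0.3,
    tau_absorption: float = 0.5,
) -> bool:
    """Flag a left-sided pneumothorax.

    Air in the pleural space is hyper-transparent (low absorption) *and*
    scatter-free (near-zero dark-field); atelectasis shares the low
    dark-field but shows increased absorption, so both thresholds must fire.
    """
    mask = np.asarray(left_mask, dtype=bool) & modalities.quality_mask
    if not mask.any():
        return False
    df = float(np.nanmean(modalities.darkfield[mask]))
    ab = float(np.nanmean(modalities.absorption[mask]))
    return (df < tau_darkfield) and (ab < tau_absorption)


def build_lung_masks(
    modalities: ModalityImages,
    anatomy_masks: dict,
    bone_mask: np.ndarray | None = None,
    **bone_kwargs,
) -> LungMasks:
    """Combine ground-truth lung outlines with algorithmic bone exclusion."""
    if bone_mask is None:
        bone_mask = segment_bone(
            modalities.absorption, body_mask=anatomy_masks.get("body"), **bone_kwargs
        )
    ok = modalities.quality_mask
    left = anatomy_masks["left_lung"] & ~bone_mask & ok
    right = anatomy_masks["right_lung"] & ~bone_mask & ok
    return LungMasks(transplanted_mask=left, control_mask=right, bone_mask=bone_mask)


def quantify_animal(modalities: ModalityImages, masks: LungMasks, animal_id: str = "?") -> RoiMeans:
    """Per-lung mean absorption and dark-field signals over identical pixels."""
    out = {}
    for lung, mask in (("transplanted", masks.transplanted_mask), ("control", masks.control_mask)):
        n = int(mask.sum())
        if n < MIN_ROI_PIXELS:
            raise ValueError(
                f"{lung} lung ROI of animal {animal_id} has only {n} pixels "
                f"(minimum {MIN_ROI_PIXELS})"
            )
        out[lung] = (
            mean_signal(modalities.absorption, mask, f"{lung} lung of {animal_id}"),
            mean_signal(modalities.darkfield, mask, f"{lung} lung of {animal_id}"),
            n,
        )
    return RoiMeans(
        transplanted_absorption=out["transplanted"][0],
        transplanted_darkfield=out["transplanted"][1],
        control_absorption=out["control"][0],
        control_darkfield=out["control"][1],
        n_pixels_transplanted=out["transplanted"][2],
        n_pixels_control=out["control"][2],
    )
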