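"""Confluency measurement from single phase-contrast frames.

The pipeline mirrors the classic recipe: restore (suppress halo and
shade-off artifacts), threshold, dilate to capture thin cellular
processes, then report the set-pixel fraction as the confluency.

The default restoration is deliberately simple: invert the frame (cell
bodies are dark on a mid-gray background, so inversion makes them the
bright foreground), estimate the slowly varying background by grayscale
morphological opening with a disk much larger than any cell, subtract
it and clip negatives. The opening removes both constant offsets and
low-order shade-off fields, while the bright halos (dark after
inversion) fall below the background estimate and are clipped away. A
named-plugin registry allows a physics-based restoration to be dropped
in without touching callers.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, opening

from .frames import ConfluencyMask, FrameImage

#: dynamic-range floor below which a restored frame is treated as blank
#: (guards Otsu against degenerate single-mode histograms)
RANGE_FLOOR = 0.02


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs for the restore -> threshold -> dilate pipeline.

    ``background_kernel_px`` must exceed the largest expected cell
    diameter or the opening will eat cell bodies into the background
    estimate. ``dilation_radius_px`` follows the published full-scale
    default of 8 px; scale it with the image (2 px at quarter scale).
    """

    restoration: str = "simplified"
    background_kernel_px: int = 48
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.2
    dilation_radius_px: int = 8

    def __post_init__(self) -> None:
        if self.dilation_radius_px < 0:
            raise ValueError("dilation_radius_px must be >= 0")
        if self.background_kernel_px <= 0:
            raise ValueError("background_kernel_px must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


def _restore_none(inv: np.ndarray, params: SegmentationParams) -> np.ndarray:
    return inv - inv.min()


def _restore_simplified(inv: np.ndarray, params: SegmentationParams) -> np.ndarray:
    footprint = disk(params.background_kernel_px, decomposition="sequence")
    background = opening(inv, footprint)
    return np.clip(inv - background, 0.0, None)


RESTORATIONS: dict[str, Callable[[np.ndarray, SegmentationParams], np.ndarray]] = {
    "none": _restore_none,
    "simplified": _restore_simplified,
}


def register_restoration(name: str, fn: Callable[[np.ndarray, SegmentationParams], np.ndarray]) -> None:
    """Register a restoration plugin usable via ``SegmentationParams.restoration``."""
    RESTORATIONS[name] = fn


def restore_image(frame: FrameImage, params: SegmentationParams | None = None) -> FrameImage:
    """Invert the frame and remove the background, leaving a non-negative
    response that is (ideally) positive exactly on cell bodies."""
    params = params or SegmentationParams()
    try:
        fn = RESTORATIONS[params.restoration]
    except KeyError:
        raise ValueError(f"unknown restoration plugin {params.restoration!r}") from None
    inverted = 1.0 - frame.pixels
    restored = fn(inverted, params)
    return replace(frame, pixels=restored)


def threshold_mask(restored: FrameImage, params: SegmentationParams | None = None) -> ConfluencyMask:
    """Binarize a restored frame (Otsu by default, fixed value optionally).

    Frames whose dynamic range is below ``RANGE_FLOOR`` yield the empty
    mask: Otsu on a near-constant histogram would otherwise invent a
    foreground out of noise.
    """
    params = params or SegmentationParams()
    r = restored.pixels
    if r.max() - r.min() < RANGE_FLOOR:
        labels = np.zeros_like(r, dtype=bool)
    elif params.threshold_method == "fixed":
        labels = r > params.fixed_threshold
    else:
        labels = r > threshold_otsu(r)
    return ConfluencyMask(labels, provenance="computer", frame_ref=restored.fov_id)


def dilate_mask(mask: ConfluencyMask, radius_px: int) -> ConfluencyMask:
    """Dilate with a disk structuring element; radius 0 is the identity."""
    if radius_px < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius_px == 0:
        labels = mask.labels.copy()
    else:
        labels = dilation(mask.labels, disk(radius_px))
    return ConfluencyMask(labels, provenance=mask.provenance, frame_ref=mask.frame_ref)


def compute_confluency(mask: ConfluencyMask) -> float:
    """Fraction of pixels labeled as cell: |set| / |total|."""
    if mask.labels.size == 0:
        raise ValueError("empty mask grid")
    return float(np.count_nonzero(mask.labels)) / mask.labels.size


def average_confluency(values: Sequence[float]) -> float:
    """Arithmetic mean of per-FOV confluency values (the per-time-point summary)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot average an empty list of confluencies")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("confluency values must lie in [0, 1]")
    return float(vals.mean())


def segment_frame(frame: FrameImage, params: SegmentationParams | None = None
                  ) -> tuple[ConfluencyMask, float]:
    """Full restore -> threshold -> dilate pipeline; returns (mask, confluency)."""
    params = params or SegmentationParams()
    restored = restore_image(frame, params)
    mask = threshold_mask(restored, params)
    mask = dilate_mask(mask, params.dilation_radius_px)
    return mask, compute_confluency(mask)


def render_overlay(frame: FrameImage, mask: ConfluencyMask) -> np.ndarray:
    """Tint mask pixels green on the grayscale frame; returns RGB uint8.

    Off-mask pixels are the plain gray value replicated to three
    channels; on-mask pixels have the green channel lifted and red/blue
    halved so green strictly exceeds red exactly on mask pixels.
    """
    if mask.labels.shape != frame.pixels.shape:
        raise ValueError("mask/frame shape mismatch")
    g8 = np.round(np.clip(frame.pixels, 0, 1) * 255.0).astype(np.uint8)
    rgb = np.stack([g8, g8, g8], axis=-1)
    m = mask.labels
    dim = (g8[m].astype(np.uint16) // 2).astype(np.uint8)
    rgb[m, 0] = dim
    rgb[m, 2] = dim
    rgb[m, 1] = (dim.astype(np.uint16) + 128).clip(0, 255).astype(np.uint8)
    return rgb
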