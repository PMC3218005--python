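"""Frame and mask containers plus image I/O.

Intensities are stored as float64 in [0, 1]. Integer containers are
rescaled by their dtype range on load (uint8 -> /255, uint16 -> /65535);
float containers are assumed to already be in [0, 1] and are clipped.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


@dataclass
class FrameImage:
    """One grayscale phase-contrast frame with acquisition metadata.

    Coordinate convention: row-major, origin top-left, 0-based indices.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.3
    frame_index: int = 0
    fov_id: str = ""
    dish_id: str = ""
    timestamp_min: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("frame must be a non-empty 2-D intensity grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame intensities must be finite")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ConfluencyMask:
    """Binary cell/background labels congruent with a frame.

    ``provenance`` is "computer" for pipeline output, "human" for manually
    traced reference masks and "truth" for synthetic ground truth.
    """

    labels: np.ndarray
    provenance: str = "computer"
    frame_ref: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("mask must be a non-empty 2-D label grid")
        self.labels = lab.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _normalize_intensities(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # collapse trivial channel axes
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    return np.clip(arr.astype(float), 0.0, 1.0)


def load_frame(path: str | Path, **meta) -> FrameImage:
    """Read a single-channel TIFF or PNG frame, rescaling to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return FrameImage(_normalize_intensities(np.asarray(arr)), **meta)


def save_frame(path: str | Path, frame: FrameImage) -> None:
    """Write a frame as 8-bit PNG or 16-bit single-channel TIFF by suffix."""
    path = Path(path)
    vals = np.clip(frame.pixels, 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(vals * 65535.0).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(vals * 255.0).astype(np.uint8))


def save_mask(path: str | Path, mask: ConfluencyMask) -> None:
    """Write a binary mask as a {0, 255} PNG."""
    iio.imwrite(Path(path), (mask.labels.astype(np.uint8) * 255))


def load_mask(path: str | Path, provenance: str = "human") -> ConfluencyMask:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return ConfluencyMask(arr > (arr.dtype.type(127) if arr.dtype == np.uint8 else 0),
                          provenance=provenance, frame_ref=str(path))


def save_rgb(path: str | Path, rgb: np.ndarray) -> None:
    """Write an RGB uint8 image (overlays, evaluation maps) as PNG."""
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))
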