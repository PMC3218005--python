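"""Synthetic phase-contrast fixtures with known ground truth.

Stands in for the microscope: renders fields of randomly placed,
possibly overlapping elliptical cells as dark bodies ringed by bright
halos on a mid-gray background with a smooth shade-off field and
additive Gaussian noise — the minimal model reproducing the two
phase-contrast artifacts the restoration step must remove.  The truth
mask marks exactly the cell-body pixels (halo excluded), so the truth
confluency is the body pixel count over the total pixel count.

Also generates confluency growth curves (quadratic or logistic families
plus additive noise) and whole time-lapse datasets on disk whose true
per-FOV coverage tracks a growth curve by accreting cells over frames.

All randomness flows from one explicit integer seed per generator call;
identical parameters give bit-identical output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.draw import ellipse as _ellipse_px

from .frames import ConfluencyMask, FrameImage, save_frame, save_mask
from .prediction import ConfluencySeries


@dataclass(frozen=True)
class SyntheticImageParams:
    """Geometry, artifact amplitudes and noise of one synthetic frame.

    The default 348x260 frame is quarter-scale of a 1392x1040 camera;
    cell semi-axes default to 14-20 px (roughly 70-105 um at quarter
    scale), i.e. well-spread myoblast-like cells.  Intensities are in
    [0, 1] and the rendered image is clipped after summing background,
    shade-off, body and halo contributions.
    """

    width_px: int = 348
    height_px: int = 260
    n_cells: int = 40
    cell_radius_px: tuple[float, float] = (14.0, 20.0)
    cell_aspect_range: tuple[float, float] = (0.8, 1.0)
    background_level: float = 0.5
    body_contrast: float = -0.25
    halo_amplitude: float = 0.15
    halo_width_px: int = 3
    shade_off_amplitude: float = 0.08
    noise_sigma: float = 0.01
    reject_overlap: bool = False
    max_overlap_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must lie in [0, 1]")
        lo, hi = self.cell_radius_px
        if lo <= 0 or hi < lo:
            raise ValueError("cell_radius_px must be a positive (lo, hi) range")


@dataclass(frozen=True)
class SyntheticGrowthParams:
    """Parameters of a synthetic confluency growth curve.

    quadratic: c(k) = a2*k^2 + a1*k + c0 at frame k.
    logistic:  c(k) = K / (1 + (K - c0)/c0 * exp(-rate*k)).
    The clean curve is clipped to [0, 1]; per-frame N(0, noise_sigma)
    noise is added before a final clip.
    """

    family: str = "quadratic"
    a2: float = 1e-6
    a1: float = 1e-4
    c0: float = 0.05
    capacity: float = 0.9
    rate: float = 0.01
    frame_interval_min: float = 5.0
    n_frames: int = 600
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("quadratic", "logistic"):
            raise ValueError(f"unknown growth family {self.family!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.family == "logistic" and not (0.0 < self.c0 <= self.capacity):
            raise ValueError("logistic growth needs 0 < c0 <= capacity")

    def clean_value(self, k):
        """Noise-free model value at frame index k (scalar or array)."""
        k = np.asarray(k, dtype=float)
        if self.family == "quadratic":
            c = self.a2 * k**2 + self.a1 * k + self.c0
        else:
            ratio = (self.capacity - self.c0) / self.c0
            c = self.capacity / (1.0 + ratio * np.exp(-self.rate * k))
        return np.clip(c, 0.0, 1.0)


def _sample_cell(rng: np.random.Generator, params: SyntheticImageParams):
    a = rng.uniform(*params.cell_radius_px)
    b = a * rng.uniform(*params.cell_aspect_range)
    theta = rng.uniform(0.0, np.pi)
    r0 = rng.uniform(0, params.height_px)
    c0 = rng.uniform(0, params.width_px)
    return r0, c0, a, b, theta


def _place_cells(rng: np.random.Generator, params: SyntheticImageParams,
                 mask: np.ndarray, n_cells: int) -> int:
    """Union ``n_cells`` ellipse bodies into ``mask`` in place.

    With ``reject_overlap`` a candidate covering more than
    ``max_overlap_frac`` of already-occupied pixels is re-drawn (bounded
    retry budget), which keeps the realized coverage close to
    n_cells * mean cell area / frame area. Returns cells placed.
    """
    placed = 0
    attempts = 0
    budget = max(50 * max(n_cells, 1), 1000)
    shape = (params.height_px, params.width_px)
    while placed < n_cells and attempts < budget:
        attempts += 1
        r0, c0, a, b, theta = _sample_cell(rng, params)
        rr, cc = _ellipse_px(r0, c0, a, b, shape=shape, rotation=theta)
        if rr.size == 0:
            continue
        if params.reject_overlap and mask[rr, cc].mean() > params.max_overlap_frac:
            continue
        mask[rr, cc] = True
        placed += 1
    return placed


def _shade_off_field(rng: np.random.Generator, params: SyntheticImageParams) -> np.ndarray:
    """Smooth low-order polynomial illumination field, |field| <= amplitude."""
    if params.shade_off_amplitude == 0.0:
        return np.zeros((params.height_px, params.width_px))
    y = np.linspace(-1.0, 1.0, params.height_px)[:, None]
    x = np.linspace(-1.0, 1.0, params.width_px)[None, :]
    g = rng.uniform(-1.0, 1.0, size=5)
    field = g[0] * x + g[1] * y + g[2] * x * y + g[3] * x**2 + g[4] * y**2
    peak = np.abs(field).max()
    if peak > 0:
        field = field / peak * params.shade_off_amplitude
    return field


def _render(mask: np.ndarray, params: SyntheticImageParams,
            rng: np.random.Generator) -> np.ndarray:
    """Render a frame from a body mask: background + shade-off + dark
    bodies + halo ring (Gaussian radial profile) + noise, clipped."""
    img = np.full(mask.shape, params.background_level, dtype=float)
    img += _shade_off_field(rng, params)
    img[mask] += params.body_contrast
    if params.halo_amplitude != 0.0 and params.halo_width_px > 0 and mask.any():
        d = distance_transform_edt(~mask)
        halo = params.halo_amplitude * np.exp(-((d / params.halo_width_px) ** 2))
        halo[mask] = 0.0
        img += halo
    if params.noise_sigma > 0:
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_cell_image(params: SyntheticImageParams
                        ) -> tuple[FrameImage, ConfluencyMask]:
    """One synthetic frame plus its exact cell-body ground-truth mask."""
    rng = np.random.default_rng(params.seed)
    mask = np.zeros((params.height_px, params.width_px), dtype=bool)
    _place_cells(rng, params, mask, params.n_cells)
    pixels = _render(mask, params, rng)
    return (FrameImage(pixels), ConfluencyMask(mask, provenance="truth"))


def params_for_coverage(target_coverage: float,
                        base: SyntheticImageParams | None = None,
                        seed: int | None = None) -> SyntheticImageParams:
    """Parameters whose truth-mask coverage lands near ``target_coverage``.

    Sets n_cells from the mean analytic cell area and enables rejection
    placement so overlap does not erode the realized coverage.
    """
    if not (0.0 <= target_coverage < 1.0):
        raise ValueError("target_coverage must lie in [0, 1)")
    base = base or SyntheticImageParams()
    mean_r = 0.5 * sum(base.cell_radius_px)
    mean_aspect = 0.5 * sum(base.cell_aspect_range)
    mean_area = np.pi * mean_r * (mean_r * mean_aspect)
    n = int(round(target_coverage * base.width_px * base.height_px / mean_area))
    kwargs = {"n_cells": n, "reject_overlap": True}
    if seed is not None:
        kwargs["seed"] = seed
    return replace(base, **kwargs)


def generate_growth_series(params: SyntheticGrowthParams) -> ConfluencySeries:
    """Confluency series from the closed-form family plus seeded noise."""
    k = np.arange(params.n_frames)
    clean = params.clean_value(k)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        values = np.clip(clean + rng.normal(0.0, params.noise_sigma, size=clean.shape),
                         0.0, 1.0)
    else:
        values = clean
    return ConfluencySeries(k, k * params.frame_interval_min, values,
                            params.frame_interval_min)


def generate_timelapse_dataset(growth: SyntheticGrowthParams,
                               image: SyntheticImageParams,
                               n_fovs: int, out_dir: str | Path,
                               img_format: str = "png",
                               fovs_per_dish: int = 3) -> dict:
    """Write a per-FOV, per-frame image dataset tracking a growth curve.

    Each FOV keeps a persistent cell population; at every frame, cells
    are accreted (rejection placement) until the FOV's true coverage
    reaches the growth-series value for that frame, then the frame is
    rendered and written.  Layout: ``<out>/<dish>/<fov>/frame_<k>.png``
    with FOVs grouped ``fovs_per_dish`` to a dish.  A ``manifest.json``
    maps frames to files and a ``truth.csv`` records per-FOV true
    confluency (columns frame, fov, true_confluency).
    """
    if n_fovs < 1:
        raise ValueError("n_fovs must be >= 1")
    if img_format not in ("png", "tiff"):
        raise ValueError("img_format must be 'png' or 'tiff'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = generate_growth_series(growth)
    suffix = ".png" if img_format == "png" else ".tif"
    place_params = replace(image, reject_overlap=True)

    frames: dict[int, list[dict]] = {int(k): [] for k in series.frame_index}
    truth_rows = []
    for fov in range(n_fovs):
        dish_id = f"dish{fov // fovs_per_dish:02d}"
        fov_id = f"fov{fov:02d}"
        fov_dir = out_dir / dish_id / fov_id
        fov_dir.mkdir(parents=True, exist_ok=True)
        place_rng = np.random.default_rng([image.seed, fov])
        mask = np.zeros((image.height_px, image.width_px), dtype=bool)
        total_px = mask.size
        for pos, k in enumerate(series.frame_index):
            target = float(series.values[pos])
            guard = 0
            while mask.sum() / total_px < target and guard < 10000:
                _place_cells(place_rng, place_params, mask, 1)
                guard += 1
            render_rng = np.random.default_rng([image.seed, fov, int(k)])
            pixels = _render(mask, image, render_rng)
            fname = fov_dir / f"frame_{int(k):05d}{suffix}"
            save_frame(fname, FrameImage(pixels))
            save_mask(fov_dir / f"truth_{int(k):05d}.png",
                      ConfluencyMask(mask, provenance="truth"))
            truth = mask.sum() / total_px
            truth_rows.append((int(k), fov_id, truth))
            frames[int(k)].append({
                "file": str(fname.relative_to(out_dir)),
                "fov_id": fov_id, "dish_id": dish_id,
            })

    truth_df = pd.DataFrame(truth_rows, columns=["frame", "fov", "true_confluency"])
    truth_df.to_csv(out_dir / "truth.csv", index=False)
    manifest = {
        "run_id": f"synthetic-{growth.seed}-{image.seed}",
        "frame_interval_min": growth.frame_interval_min,
        "n_frames": growth.n_frames,
        "n_fovs": n_fovs,
        "image_format": img_format,
        "frames": {str(k): v for k, v in frames.items()},
        "truth_csv": "truth.csv",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
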