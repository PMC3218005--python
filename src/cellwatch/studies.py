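"""Canonical seeded studies: the package's reproducible desk experiments.

Each function wires the synthetic generator to the analysis modules
with fixed study conditions (growth-law coefficients, noise level,
series length, seed layout) and returns plain dictionaries of computed
numbers.  The test suite and the acceptance script both call these, so
the reported quantities are always recomputed from scratch.

Study conditions
----------------
* Monitoring cadence: 5-min frames, 300-frame fitting window, poly2
  family, 4-h forecast horizon, 0.5 threshold, 200-frame warm-up.
* Noise level sigma = 0.005 confluency units, the scale of frame-to-
  frame jitter in averaged 12-FOV confluency measurements.
* The variance study uses the reference quadratic (a2=1e-6, a1=1e-4,
  c0=0.05 per-frame) over 600 frames; the model-selection and
  subsampling studies use slower quadratics over longer series so the
  rolling-forecast RMSE is estimated from many independent stretches
  of fit noise (coefficients chosen to keep the clean curve inside
  [0, 1] for the whole run).
"""
from __future__ import annotations

import numpy as np

from .expansion import passages_to_target
from .notification import MonitorConfig, NotificationMonitor, NotificationEvent
from .prediction import (ConfluencySeries, FAMILIES, PredictionState, compare_models,
                         fit_growth_model, forecast, rolling_forecast,
                         subsample_compare, time_to_threshold)
from .synthetic import SyntheticGrowthParams, generate_growth_series

#: reference quadratic growth (per-frame units): crosses 0.5 near frame 623
REFERENCE_QUADRATIC = {"a2": 1e-6, "a1": 1e-4, "c0": 0.05}
#: slower quadratics for long-series Monte-Carlo studies
SELECTION_QUADRATIC = {"a2": 2e-7, "a1": 1e-4, "c0": 0.05}
SUBSAMPLING_QUADRATIC = {"a2": 5e-8, "a1": 1e-4, "c0": 0.05}

NOISE_SIGMA = 0.005


def make_quadratic_series(seed: int, n_frames: int, noise_sigma: float = NOISE_SIGMA,
                          coeffs: dict | None = None) -> ConfluencySeries:
    c = coeffs or REFERENCE_QUADRATIC
    return generate_growth_series(SyntheticGrowthParams(
        family="quadratic", a2=c["a2"], a1=c["a1"], c0=c["c0"],
        n_frames=n_frames, noise_sigma=noise_sigma, seed=seed))


def passage_planning_study() -> dict:
    """Passages to a 50-million-cell target from 4 dishes at ratio 1:8.

    Uses the two published per-dish yields (computer-directed
    19.92e4 cells/dish, human-directed 22.71e4 cells/dish).
    """
    computer = passages_to_target(50e6, 4, 19.92e4, ratio=8)
    human = passages_to_target(50e6, 4, 22.71e4, ratio=8)
    return {"computer_directed_passages": computer,
            "human_directed_passages": human,
            "target_cells": 50e6, "initial_dishes": 4, "ratio": 8}


def simulate_monitoring(series: ConfluencySeries,
                        config: MonitorConfig | None = None,
                        min_points: int = 10) -> dict:
    """Run the full series-level monitoring loop over one confluency series.

    At every frame: fit the trailing window, forecast one horizon ahead
    (stored until its target frame arrives, then folded into the
    forecast-error variance trace), search for a threshold crossing
    within the horizon, and feed the notifier.
    """
    config = config or MonitorConfig(frame_interval_min=series.frame_interval_min)
    h = int(round(config.horizon_min / series.frame_interval_min))
    monitor = NotificationMonitor(config)
    state = PredictionState()
    pending: dict[int, float] = {}
    events: list[NotificationEvent] = []
    variance_by_frame: dict[int, float] = {}
    crossings: list[float | None] = []
    for pos in range(len(series)):
        frame = int(series.frame_index[pos])
        now = float(series.time_min[pos])
        value = float(series.values[pos])
        if pos in pending:
            state.update(value, pending.pop(pos))
            variance_by_frame[frame] = state.variance
        crossing = None
        if pos + 1 >= min_points:
            fit = fit_growth_model(series.slice(max(0, pos + 1 - config.window_frames),
                                                pos + 1),
                                   window_frames=config.window_frames)
            pending[pos + h] = forecast(fit, now + config.horizon_min)
            crossing = time_to_threshold(fit, config.threshold, now,
                                         config.horizon_min)
        crossings.append(crossing)
        events.extend(monitor.update(frame, now, value, crossing))
    return {"events": events, "prediction_state": state,
            "variance_by_frame": variance_by_frame, "crossings": crossings,
            "config": config}


def notification_lead_time_study(n_frames: int = 700) -> dict:
    """Lead time between the advance alert and the measured crossing.

    Noise-free reference quadratic sampled at 5-min intervals; the
    measured crossing is the first frame whose value is at or above the
    0.5 threshold.
    """
    series = make_quadratic_series(seed=0, n_frames=n_frames, noise_sigma=0.0)
    out = simulate_monitoring(series)
    by_kind = {e.kind: e for e in out["events"]}
    if "PRE_ALERT" not in by_kind or "THRESHOLD_REACHED" not in by_kind:
        raise RuntimeError("fixture did not produce both notification events")
    lead_min = by_kind["THRESHOLD_REACHED"].time_min - by_kind["PRE_ALERT"].time_min
    return {"lead_min": float(lead_min),
            "lead_hours_rounded": int(round(lead_min / 60.0)),
            "pre_alert_time_min": by_kind["PRE_ALERT"].time_min,
            "threshold_time_min": by_kind["THRESHOLD_REACHED"].time_min,
            "confluency_at_threshold": by_kind["THRESHOLD_REACHED"].average_confluency}


def variance_warmup_study(base_seed: int = 0, n_seeds: int = 3,
                          n_frames: int = 600, warmup_frames: int = 200) -> dict:
    """Windowed forecast-error variance after the warm-up, noisy quadratic.

    For each seed, runs the rolling poly2 fit with 4-h-ahead forecasts
    on the reference quadratic plus sigma=0.005 noise and records the
    trailing-48-frame sample variance of (forecast - observation) at
    every frame from ``warmup_frames`` onward; reports the maximum over
    frames and seeds.
    """
    per_seed = []
    n_evaluated = 0
    for s in range(base_seed, base_seed + n_seeds):
        series = make_quadratic_series(seed=s, n_frames=n_frames)
        out = simulate_monitoring(series)
        late = {f: v for f, v in out["variance_by_frame"].items() if f >= warmup_frames}
        if not late:
            raise RuntimeError("no variance samples after warm-up")
        per_seed.append(max(late.values()))
        n_evaluated += len(late)
    return {"max_variance": float(max(per_seed)),
            "per_seed_max": [float(v) for v in per_seed],
            "n_frames_evaluated": n_evaluated,
            "seeds": list(range(base_seed, base_seed + n_seeds)),
            "warmup_frames": warmup_frames}


def model_selection_study(base_seed: int = 200, n_seeds: int = 20,
                          n_frames: int = 1500) -> dict:
    """How often poly2 wins the five-family forecast-RMSE comparison.

    Quadratic-truth series (slow coefficients, sigma=0.005); each seed
    produces a full compare_models table and the winner is the family
    with the lowest rolling-forecast RMSE at the 4-h horizon.
    """
    winners = []
    tables = []
    for s in range(base_seed, base_seed + n_seeds):
        series = make_quadratic_series(seed=s, n_frames=n_frames,
                                       coeffs=SELECTION_QUADRATIC)
        table = compare_models(series)
        winners.append(table.iloc[0]["family"])
        tables.append(table)
    wins = sum(1 for w in winners if w == "poly2")
    return {"poly2_wins": wins, "n_seeds": n_seeds,
            "win_fraction": wins / n_seeds, "winners": winners,
            "seeds": list(range(base_seed, base_seed + n_seeds)),
            "last_table": tables[-1]}


def subsampling_study(base_seed: int = 100, n_seeds: int = 20,
                      n_frames: int = 2500, stride: int = 6) -> dict:
    """Forecast-RMSE cost of fitting on every 6th frame only.

    Per seed, subsample_compare evaluates the full-resolution and
    strided poly2 models at common target frames; RMSEs are pooled
    across seeds (equal evaluation counts per seed) and the relative
    change reported.
    """
    sq_full, sq_str = [], []
    for s in range(base_seed, base_seed + n_seeds):
        series = make_quadratic_series(seed=s, n_frames=n_frames,
                                       coeffs=SUBSAMPLING_QUADRATIC)
        r_full, r_str = subsample_compare(series, stride=stride)
        sq_full.append(r_full ** 2)
        sq_str.append(r_str ** 2)
    rmse_full = float(np.sqrt(np.mean(sq_full)))
    rmse_strided = float(np.sqrt(np.mean(sq_str)))
    return {"rmse_full": rmse_full, "rmse_strided": rmse_strided,
            "relative_change": abs(rmse_strided - rmse_full) / rmse_full,
            "stride": stride, "n_seeds": n_seeds,
            "seeds": list(range(base_seed, base_seed + n_seeds))}
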