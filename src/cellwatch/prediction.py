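"""Sliding-window growth fitting, forecasting and threshold-crossing search.

A confluency time series (one averaged value per 5-min frame by default)
is fitted on a trailing window — 300 frames and a 2nd-order polynomial
in the standard configuration — and the fitted curve is evaluated 4 h
ahead.  The earliest time at which the fitted curve meets a confluency
threshold is located by closed-form root finding for polynomial
families (grid + bisection otherwise).  Forecast quality is tracked as
the trailing-window sample variance of (forecast - observation), and a
model-family comparison ranks candidate growth laws by the RMSE of
their rolling forecasts.

Model families
--------------
poly1/poly2/poly3
    polynomials in time (minutes), solved by least squares on a
    centered-and-scaled time axis for conditioning and mapped back.
logarithmic
    c(t) = a * ln(t - t0 + 1) + b with t0 the window start (minutes).
exponential
    c(t) = a * exp(b * (t - t_ref)) with t_ref the window end, fitted
    log-linearly; requires strictly positive observations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

FAMILIES = ("poly1", "poly2", "poly3", "logarithmic", "exponential")
N_PARAMS = {"poly1": 2, "poly2": 3, "poly3": 4, "logarithmic": 2, "exponential": 2}


class ModelFitError(RuntimeError):
    """A model family cannot be fitted to the given window (e.g. the
    exponential family on non-positive observations)."""


@dataclass
class ConfluencySeries:
    """Uniformly sampled confluency measurements.

    ``frame_index`` keeps the original acquisition numbering even after
    subsampling, so forecasts from differently strided views of the same
    run can be aligned frame-for-frame.
    """

    frame_index: np.ndarray
    time_min: np.ndarray
    values: np.ndarray
    frame_interval_min: float = 5.0

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.frame_index)
        if not (len(self.time_min) == len(self.values) == n) or n == 0:
            raise ValueError("frame_index, time_min and values must be equal-length, non-empty")
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("confluency values must be finite")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_values(cls, values: Sequence[float], frame_interval_min: float = 5.0,
                    start_frame: int = 0) -> "ConfluencySeries":
        values = np.asarray(values, dtype=float)
        idx = np.arange(start_frame, start_frame + len(values))
        return cls(idx, idx * frame_interval_min, values, frame_interval_min)

    def slice(self, lo: int, hi: int) -> "ConfluencySeries":
        return ConfluencySeries(self.frame_index[lo:hi], self.time_min[lo:hi],
                                self.values[lo:hi], self.frame_interval_min)

    def subsample(self, stride: int) -> "ConfluencySeries":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if stride >= len(self):
            raise ValueError("stride larger than the series")
        return ConfluencySeries(self.frame_index[::stride], self.time_min[::stride],
                                self.values[::stride],
                                self.frame_interval_min * stride)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"frame": self.frame_index, "time_min": self.time_min,
                      "confluency": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval_min: float | None = None
                 ) -> "ConfluencySeries":
        df = pd.read_csv(path)
        if frame_interval_min is None:
            dt = np.diff(df["time_min"].to_numpy())
            frame_interval_min = float(np.median(dt)) if len(dt) else 5.0
        return cls(df["frame"].to_numpy(), df["time_min"].to_numpy(),
                   df["confluency"].to_numpy(), frame_interval_min)


@dataclass
class GrowthFit:
    """A fitted growth law on one trailing window.

    ``coefficients`` are in original time units (minutes): ascending
    powers for polynomial families, (a, b, t0) for the logarithmic and
    (a, b, t_ref) for the exponential family.  ``predict`` returns the
    unclipped model value; use :func:`forecast` for reporting.
    """

    family: str
    coefficients: tuple
    window: tuple[int, int]
    time_origin_min: float
    in_window_rmse: float
    _poly: Polynomial | None = field(default=None, repr=False, compare=False)

    def predict(self, t_min):
        t = np.asarray(t_min, dtype=float)
        if self._poly is not None:
            out = self._poly(t)
        elif self.family == "logarithmic":
            a, b, t0 = self.coefficients
            out = a * np.log(np.maximum(t - t0 + 1.0, 1e-12)) + b
        elif self.family == "exponential":
            a, b, t_ref = self.coefficients
            out = a * np.exp(b * (t - t_ref))
        else:  # pragma: no cover - families are validated at fit time
            raise ValueError(f"unknown family {self.family!r}")
        return float(out) if np.isscalar(t_min) else out


def fit_growth_model(series: ConfluencySeries, window_frames: int = 300,
                     family: str = "poly2") -> GrowthFit:
    """Least-squares fit of ``family`` on the trailing window of ``series``.

    The window is clipped to the available frames when the series is
    shorter than ``window_frames``.  Polynomials are solved on a
    centered-and-scaled time axis and the coefficients mapped back to
    minutes, which is exact in theory and well-conditioned in practice.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    n = len(series)
    w = min(window_frames, n)
    if w < N_PARAMS[family]:
        raise ValueError(f"{family} needs at least {N_PARAMS[family]} points, got {w}")
    sub = series.slice(n - w, n)
    t, y = sub.time_min, sub.values
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in fitting window")

    poly = None
    if family.startswith("poly"):
        deg = int(family[4])
        poly = Polynomial.fit(t, y, deg)
        coefficients = tuple(poly.convert().coef)
        fitted = poly(t)
    elif family == "logarithmic":
        t0 = float(t[0])
        x = np.log(t - t0 + 1.0)
        A = np.column_stack([x, np.ones_like(x)])
        (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
        coefficients = (float(a), float(b), t0)
        fitted = a * x + b
    else:  # exponential
        if np.any(y <= 0):
            raise ModelFitError("exponential family requires strictly positive values")
        t_ref = float(t[-1])
        A = np.column_stack([t - t_ref, np.ones_like(t)])
        (b, loga), *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
        a = math.exp(loga)
        coefficients = (float(a), float(b), t_ref)
        fitted = a * np.exp(b * (t - t_ref))

    return GrowthFit(
        family=family,
        coefficients=coefficients,
        window=(int(sub.frame_index[0]), int(sub.frame_index[-1])),
        time_origin_min=float(t[0]),
        in_window_rmse=rmse(fitted, y),
        _poly=poly,
    )


def forecast(fit: GrowthFit, t_future_min: float) -> float:
    """Model value at ``t_future_min``, clipped to [0, 1] for reporting."""
    return float(np.clip(fit.predict(t_future_min), 0.0, 1.0))


def time_to_threshold(fit: GrowthFit, threshold: float, now_min: float,
                      horizon_min: float = 240.0) -> float | None:
    """Earliest t in (now, now + horizon] with fitted confluency >= threshold.

    Polynomial families are solved in closed form on the unclipped
    polynomial; other families fall back to a 1-min grid scan refined by
    bisection.  Returns ``now_min`` when the curve is already at or
    above the threshold, and ``None`` when no crossing occurs within the
    horizon.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if fit.predict(now_min) >= threshold:
        return float(now_min)
    t_end = now_min + horizon_min
    if fit._poly is not None:
        shifted = fit._poly - threshold
        roots = shifted.roots()
        real = np.sort(roots[np.abs(roots.imag) < 1e-8].real)
        for r in real:
            if now_min < r <= t_end + 1e-9:
                return float(min(r, t_end))
        return None
    # grid + bisection fallback for non-polynomial families
    t_prev = now_min
    t = now_min
    while t < t_end - 1e-12:
        t = min(t + 1.0, t_end)
        if fit.predict(t) >= threshold:
            lo, hi = t_prev, t
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if fit.predict(mid) >= threshold:
                    hi = mid
                else:
                    lo = mid
            return float(hi)
        t_prev = t
    return None


@dataclass
class PredictionState:
    """Per-frame forecast-error bookkeeping.

    ``update`` appends the signed error (forecast - observed); the
    variance trace at each step is the sample variance (ddof=1) of the
    trailing ``variance_window`` signed errors, 0 while fewer than two
    errors are available.  Squared errors are kept alongside.
    """

    variance_window: int = 48
    errors: list = field(default_factory=list)
    squared_errors: list = field(default_factory=list)
    variance_trace: list = field(default_factory=list)

    def update(self, observed: float, forecast_value: float) -> "PredictionState":
        err = float(forecast_value) - float(observed)
        self.errors.append(err)
        self.squared_errors.append(err * err)
        tail = np.asarray(self.errors[-self.variance_window:])
        var = float(np.var(tail, ddof=1)) if len(tail) >= 2 else 0.0
        self.variance_trace.append(var)
        return self

    @property
    def variance(self) -> float:
        return self.variance_trace[-1] if self.variance_trace else 0.0


def update_variance(state: PredictionState, observed: float,
                    forecast_H_earlier: float) -> PredictionState:
    """Functional alias for :meth:`PredictionState.update`."""
    return state.update(observed, forecast_H_earlier)


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root-mean-square difference between two equal-length series."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and observed must be equal-length 1-D, non-empty")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def rolling_forecast(series: ConfluencySeries, window_frames: int = 300,
                     horizon_min: float = 240.0, family: str = "poly2",
                     min_points: int | None = None,
                     target_positions: Iterable[int] | None = None) -> pd.DataFrame:
    """Fit on the trailing window at each frame and forecast one horizon ahead.

    Returns a DataFrame with one row per evaluable forecast: the position
    and original frame index at which the forecast was made and lands,
    the forecast (clipped), the later observation and the signed error.
    By default a forecast counts only once a full ``window_frames``-point
    window is available, so early-run transients with huge extrapolation
    variance do not dominate downstream RMSE summaries; pass a smaller
    ``min_points`` to include the growing-window start-up.  Windows where
    the family cannot be fitted are skipped and counted in
    ``df.attrs["n_failed"]``.
    """
    h = int(round(horizon_min / series.frame_interval_min))
    if h < 1:
        raise ValueError("horizon shorter than one frame interval")
    n = len(series)
    if min_points is None:
        min_points = window_frames
    minp = max(min_points, N_PARAMS[family])
    first_target = minp - 1 + h
    if target_positions is None:
        positions = range(first_target, n)
    else:
        positions = sorted(p for p in set(target_positions) if first_target <= p < n)
    rows, n_failed = [], 0
    for tgt in positions:
        i = tgt - h
        lo = max(0, i - window_frames + 1)
        try:
            fit = fit_growth_model(series.slice(lo, i + 1), window_frames=window_frames,
                                   family=family)
        except ModelFitError:
            n_failed += 1
            continue
        f = forecast(fit, float(series.time_min[tgt]))
        rows.append((i, int(series.frame_index[i]), tgt, int(series.frame_index[tgt]),
                     float(series.time_min[tgt]), f, float(series.values[tgt])))
    df = pd.DataFrame(rows, columns=["made_at_pos", "made_at_frame", "target_pos",
                                     "target_frame", "target_time_min",
                                     "forecast", "observed"])
    df["error"] = df["forecast"] - df["observed"]
    df.attrs["n_failed"] = n_failed
    return df


def compare_models(series: ConfluencySeries, families: Sequence[str] = FAMILIES,
                   window_frames: int = 300, horizon_min: float = 240.0) -> pd.DataFrame:
    """Rank model families by the RMSE of their rolling forecasts.

    Families that cannot be fitted anywhere get NaN RMSE and sort last.
    """
    rows = []
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown model family {fam!r}")
        df = rolling_forecast(series, window_frames, horizon_min, family=fam)
        if len(df) < 10:
            if df.attrs["n_failed"] > 0 and len(df) == 0:
                rows.append((fam, float("nan"), 0, "fit failed on all windows"))
                continue
            raise ValueError("series too short: fewer than 10 forecast evaluations")
        rows.append((fam, rmse(df["forecast"], df["observed"]), len(df), ""))
    out = pd.DataFrame(rows, columns=["family", "forecast_rmse", "n_eval", "note"])
    return out.sort_values("forecast_rmse", na_position="last").reset_index(drop=True)


def subsample_compare(series: ConfluencySeries, stride: int = 6,
                      window_frames: int = 300, horizon_min: float = 240.0,
                      family: str = "poly2") -> tuple[float, float]:
    """Forecast RMSE of the full-resolution vs every-``stride``-th-frame model.

    The strided model keeps the same window span in minutes
    (``window_frames // stride`` points).  Both models are evaluated at
    the common forecast target frames against the same observations, so
    the returned pair isolates the effect of subsampling.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    strided = series.subsample(stride) if stride > 1 else series
    w_str = max(window_frames // stride, N_PARAMS[family])
    df_str = rolling_forecast(strided, w_str, horizon_min, family=family)
    # map strided target frames back to positions in the full series
    frame_to_pos = {int(f): i for i, f in enumerate(series.frame_index)}
    targets_full = [frame_to_pos[f] for f in df_str["target_frame"] if f in frame_to_pos]
    df_full = rolling_forecast(series, window_frames, horizon_min, family=family,
                               target_positions=targets_full)
    common = sorted(set(df_full["target_frame"]) & set(df_str["target_frame"]))
    if not common:
        raise ValueError("no common forecast targets between full and strided series")
    df_full = df_full[df_full["target_frame"].isin(common)]
    df_str = df_str[df_str["target_frame"].isin(common)]
    return (rmse(df_full["forecast"], df_full["observed"]),
            rmse(df_str["forecast"], df_str["observed"]))
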