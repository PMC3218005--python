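# Methods notes

## Scope and data model

`cellwatch` implements a desk-scale confluency monitoring loop: synthetic
phase-contrast frames (or real ones dropped into the same directory layout)
are segmented into confluency masks, per-time-point averages are forecast
forward with a sliding-window polynomial fit, threshold crossings raise
one-shot notifications, and a passage calculator turns hemocytometer counts
into continue/stop decisions. All intensities live in [0, 1]; masks are
boolean grids congruent with their frames; time is the nominal acquisition
clock, frame_index × frame_interval_min (5 min by default), never file
mtimes.

## Synthetic image model

Cells are rendered as filled ellipses (semi-major axis uniform in 14–20 px,
aspect 0.8–1.0, arbitrary orientation) with a uniform dark body offset
(−0.25) on a mid-gray background (0.5), a bright halo that decays as a
Gaussian of the Euclidean distance from the cell boundary (amplitude +0.15,
width 3 px), a smooth random low-order polynomial shade-off field (|field| ≤
0.08) and i.i.d. Gaussian pixel noise (σ = 0.01). The default frame is
348×260 px, quarter-scale of a 1392×1040 camera at 1.3 µm/px; full scale is
one parameter away. The truth mask is the union of cell bodies — halo
excluded — so truth confluency is exactly the body-pixel fraction, and
coverage, not cell count, is the modeled quantity (overlap is allowed;
`params_for_coverage` uses rejection placement when a target coverage must
be hit).

This model reproduces the two artifacts the restoration stage must remove
(halo, shade-off) and nothing else. It deliberately omits optics (no PSF,
no partial coherence), intra-cell texture, soft edges, cell migration and
division, and focus drift. Consequently, passing the segmentation fidelity
tests shows the pipeline correctly removes additive smooth backgrounds and
annular halos around uniform bodies — it does not certify performance on
real micrographs, where cell-body contrast is weaker and human tracings
define the reference. Cell size/shape defaults are plausible for well-spread
myoblast-like cells but are conventions, not fits to data.

Time-lapse datasets keep one persistent cell population per FOV and accrete
cells each frame until the true coverage reaches the growth-series value, so
written truth CSVs track the curve monotonically when the curve is monotone.

## Segmentation

Restoration = inversion + background subtraction, where the background of
the inverted frame is its grayscale morphological opening with a disk of
radius `background_kernel_px` (default 48 px at quarter scale; it must
exceed the largest cell diameter or bodies leak into the background
estimate). Opening removes constant offsets exactly, hence the pipeline is
invariant to global intensity shifts, and tracks smooth shade-off fields to
within a small curvature-dependent residual. The restoration is a named
plugin; `restoration="none"` yields the inverted, min-subtracted frame.

Thresholding is Otsu by default with a fixed-value option. A dynamic-range
floor of 0.02 short-circuits blank frames to the empty mask: Otsu applied to
a single-mode histogram would otherwise hallucinate a foreground out of
noise.

Dilation uses a disk structuring element, radius 8 px at full scale. The
radius should scale with the image: the packaged quarter-scale fixture suite
uses radius 2. Dilation trades precision for recall by design — it annexes
a ring around each detected body to cover filopodia/lamellipodia that
threshold below detectability; on synthetic truth (bodies only) it is the
dominant precision cost, which is why the fixture-suite bar is precision ≥
0.75 rather than ≈ 1.

## Growth models and forecasting

Families: poly1/poly2/poly3 in minutes, fitted by least squares on a
centered-and-scaled time axis (numpy `Polynomial.fit`) with coefficients
mapped back to minutes — identical to raw-axis least squares in exact
arithmetic, far better conditioned at large frame counts; logarithmic
c(t) = a·ln(t − t0 + 1) + b anchored at the window start; exponential
c(t) = a·e^{b(t − t_ref)} anchored at the window end and fitted
log-linearly (requires positive data; windows violating this raise a fit
error and are skipped by rolling summaries). The anchored log/exp forms are
documented conventions; other anchorings change the fitted curve.

The operational monitor fits from 10 points up, growing to the full
300-frame window, but gates notifications on a 200-frame warm-up
(`min_frames`), below which extrapolation variance makes crossing estimates
unreliable. Forecasts are clipped to [0, 1] for reporting only; crossing
search uses the unclipped polynomial and closed-form roots (1-min grid +
bisection for non-polynomial families), returning "now" when the fit is
already at threshold and None when no crossing lies within the horizon.

Forecast-error tracking: signed errors (4-h-ahead forecast minus later
observation) enter a trailing window of 48 frames (4 h); the trace reports
their sample variance (ddof = 1, zero until two errors exist), with squared
errors logged alongside.

Model comparison (`compare_models`, `subsample_compare`) scores only
forecasts made from full windows. Growing-window start-up fits extrapolate
4 h from as few as 10 points; their variance is orders of magnitude above
the mature regime and, if included, dominates every family's RMSE and ranks
families by start-up behavior rather than by growth law. Restricting to
mature windows is the analysis-side analog of the operational warm-up gate.
`subsample_compare` additionally evaluates the full-resolution and strided
models at the common target frames against the same observations, so the
reported pair isolates the effect of subsampling from evaluation-set
differences. The strided model keeps the same window span in minutes
(300/stride points).

## Study conditions (studies.py)

All headline numbers are computed by seeded study functions; none are
stored. Conditions, fixed once:

- Reference quadratic growth: c(k) = 1e−6·k² + 1e−4·k + 0.05 per frame k
  (crosses 0.5 near frame 623, ≈ 52 h at 5-min frames); measurement noise
  σ = 0.005 confluency units, the scale of residual jitter in a 12-FOV
  average.
- Lead-time study: the noise-free reference quadratic over 700 frames.
  With an in-family noise-free fit the predicted crossing is exact, so the
  advance alert lands on the first 5-min frame within the 4-h horizon and
  leads the first measured above-threshold frame by exactly 240 min.
- Variance warm-up study: reference quadratic + noise, 600 frames, 3 seeds,
  maximum of the variance trace from frame 200 on. Analytically the
  forecast-error variance for a full 300-point window extrapolated 48
  frames is ≈ 1.1 σ² ≈ 2.8e−5, far below the 1e−3 reliability bound.
- Model selection: slower quadratic (a2 = 2e−7) over 1500 frames so the
  clean curve stays in [0, 1] and the RMSE per seed pools many independent
  stretches of fit noise; 20 seeds (200–219), five families, winner =
  lowest rolling-forecast RMSE.
- Subsampling: slowest quadratic (a2 = 5e−8) over 2500 frames, 20 seeds
  (100–119), stride 6, RMSE pooled across seeds. The expected RMSE ratio
  from window-size arithmetic is ≈ 1.20 (50-point vs 300-point windows over
  the same minutes), comfortably inside the <25 % bound with pooled
  estimation noise.
- Fixture suite for segmentation fidelity: coverages {0.15, 0.25, 0.35} ×
  seeds {0..4} at quarter scale, dilation radius 2.

The pipeline plumbing tests run compact conditions (3 FOVs, 120×90 frames,
20-frame window, 1-h horizon, 10-frame warm-up) chosen so an end-to-end run
covers both notification events in a few seconds; they exercise the same
code paths as the reference configuration.

## Numerical and degenerate-input choices

- Coordinates are row-major, origin top-left, 0-based; loaded integer
  images are rescaled by their dtype range.
- Otsu is skipped below the 0.02 dynamic-range floor (empty mask).
- `passages_to_target` uses the closed-form ceiling-of-logarithm count with
  an integer fix-up loop to absorb floating-point edge cases at exact
  equality (e.g. 4 × 25e4 = 1e6 exactly).
- The threshold-reached event disarms the advance alert; the reminder
  triggers on the first touch and never re-arms, so oscillation around the
  threshold yields one event.
- Missing or unreadable FOVs are skipped with a warning and the time-point
  average is taken over the FOVs present; a time point with no readable
  FOVs is dropped.
- Watch mode treats a frame as complete when a later frame exists on disk,
  flushing the trailing (possibly partial) frames only after the directory
  has been idle for `idle_polls` polls; on a static directory it produces
  byte-identical CSVs to batch mode.

## Known limitations

- The simplified restoration is not the physics-based (regularized
  quadratic-program) reconstruction used by dedicated phase-contrast
  restoration methods; on real micrographs its precision/recall is
  untested. The plugin registry exists so such a method can be swapped in.
- The latest-harvest-vs-target stopping rule is implemented; accumulating
  harvests across passages is a noted alternative that would stop no later.
- Confluency measures coverage only: no instance segmentation, tracking or
  mitosis detection.
- The SMTP channel is a configuration-gated stub and is never exercised by
  the tests; the log-file channel is the default delivery path.
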