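# cellwatch

Adaptive, vision-based monitoring of adherent cell cultures. `cellwatch`
measures cell confluency from phase-contrast time-lapse frames, forecasts when
the culture will cross a confluency threshold, raises an advance alert four
hours before that crossing plus a reminder at the crossing itself, and plans
serial-passage expansions toward a target cell yield. A synthetic-data module
emulates the microscope (phase-contrast artifacts, known ground-truth masks,
growth curves), so the whole system runs and is tested entirely at the desk.

Who it is for: cell-culture labs automating the "when do I subculture?"
decision for adherent lines such as C2C12 myoblasts, and anyone who needs a
testable reference implementation of confluency monitoring.

## Method

**Confluency measurement.** Each grayscale frame is *restored* — inverted
(cell bodies are dark on a mid-gray background) and flattened by subtracting a
background estimated with grayscale morphological opening, which suppresses
both the bright halo rings and the smooth shade-off field characteristic of
phase-contrast optics. Otsu thresholding of the restored response gives a
binary *confluency mask*, which is dilated with a disk structuring element
(radius 8 px at full camera scale) to capture thin cellular processes. The
confluency is

&nbsp;&nbsp;&nbsp;&nbsp;c = (# cell pixels) / (# pixels),

averaged over the fields of view of one time point (12 FOVs across 4 dishes
in the reference configuration). Masks are scored against reference masks by
pixel precision TP/(TP+FP) and recall TP/(TP+FN).

**Forecasting.** The averaged series c(t) is fitted on a trailing 300-frame
window with a 2nd-order polynomial (least squares on a centered time axis)
and evaluated 4 h ahead. The earliest t with ĉ(t) ≥ 0.5 inside the 4-h
horizon is found from the polynomial roots. Forecast quality is the sample
variance of (forecast − observation) over the trailing 48 frames; alerts are
gated until 200 frames have accumulated, the warm-up span below which
sliding-window forecasts are unreliable. A five-family comparison
(poly1/poly2/poly3, logarithmic, exponential) ranks growth laws by the RMSE
of their rolling 4-h forecasts.

**Passage planning.** With a 1:8 subculture ratio, the calculator stops the
experiment at the first passage p where
dishes₀ · 8^(p−1) · yield_per_dish ≥ target.

## Worked example

Passage planning toward 50 million cells from 4 dishes at the measured
computer-directed yield of 19.92×10⁴ cells/dish:

```sh
$ cellwatch expand start --target 5e7 --dishes 4
passage 1, 4 dishes -> Continue experiment
$ cellwatch expand harvest --cells-per-dish 199200
passage 1: 4 dishes x 199200 = 796800 cells -> Continue experiment
$ cellwatch expand harvest --cells-per-dish 199200
passage 2: 32 dishes x 199200 = 6.3744e+06 cells -> Continue experiment
$ cellwatch expand harvest --cells-per-dish 199200
passage 3: 256 dishes x 199200 = 5.09952e+07 cells -> Stop experiment
```

Three passages: 0.80 M, then 6.37 M, then 51.0 M cells, the first total at or
above the 50 M target.

Notification timing on a noise-free quadratic growth curve sampled every
5 min (the `studies` module wires generator and monitor together):

```pycon
>>> from cellwatch import studies
>>> studies.notification_lead_time_study()
{'lead_min': 240.0, 'lead_hours_rounded': 4, 'pre_alert_time_min': 2875.0,
 'threshold_time_min': 3115.0, 'confluency_at_threshold': 0.500429}
```

The advance alert fires at t = 2875 min, exactly 4 h before the first frame
whose measured confluency reaches 0.5 (t = 3115 min, value 0.5004).

End-to-end on images:

```sh
cellwatch simulate --out run_data --n-fovs 12 --n-frames 30 --seed 0
cellwatch run --input run_data --out run_out
cellwatch report --run-dir run_out
```

which writes `confluency.csv`, `predictions.csv`, `events.log`, `state.json`,
per-FOV overlay PNGs and a `report.png` summary plot.

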