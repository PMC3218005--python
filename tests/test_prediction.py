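"""Growth fitting, forecasting, crossing search and model comparison."""
import numpy as np
import pandas as pd
import pytest

from cellwatch.prediction import (ConfluencySeries, ModelFitError, PredictionState,
                                  compare_models, fit_growth_model, forecast, rmse,
                                  rolling_forecast, subsample_compare,
                                  time_to_threshold, update_variance)
from cellwatch.synthetic import SyntheticGrowthParams, generate_growth_series

TRUE_COEF_MIN = {  # a2*k^2 + a1*k + c0 in per-frame units, converted to minutes
    "c0": 0.05, "c1": 1e-4 / 5.0, "c2": 1e-6 / 25.0}


def _linear_series(slope_per_frame, value_now, n=100, interval=5.0):
    k = np.arange(n)
    vals = value_now + slope_per_frame * (k - (n - 1))
    return ConfluencySeries.from_values(np.clip(vals, 0, 1), interval)


class TestFitGrowthModel:
    def test_noise_free_quadratic_recovers_coefficients_exactly(self, quadratic_series):
        fit = fit_growth_model(quadratic_series, window_frames=300, family="poly2")
        c0, c1, c2 = fit.coefficients
        assert c0 == pytest.approx(TRUE_COEF_MIN["c0"], abs=1e-9)
        assert c1 == pytest.approx(TRUE_COEF_MIN["c1"], abs=1e-9)
        assert c2 == pytest.approx(TRUE_COEF_MIN["c2"], abs=1e-9)
        assert fit.in_window_rmse < 1e-12

    def test_constant_series_gives_flat_polynomial(self):
        s = ConfluencySeries.from_values(np.full(400, 0.3))
        fit = fit_growth_model(s)
        c0, c1, c2 = fit.coefficients
        assert c0 == pytest.approx(0.3, abs=1e-12)
        assert abs(c1) < 1e-12 and abs(c2) < 1e-12

    def test_noisy_fit_within_three_standard_errors_of_truth(self):
        """Cross-check against an independent normal-equations oracle in a
        centered time basis, with standard errors from (X'X)^-1 sigma^2."""
        sigma = 0.005
        s = generate_growth_series(SyntheticGrowthParams(
            a2=1e-6, a1=1e-4, c0=0.05, n_frames=300, noise_sigma=sigma, seed=13))
        fit = fit_growth_model(s, window_frames=300)
        t = s.time_min
        t_bar = t.mean()
        X = np.column_stack([(t - t_bar) ** j for j in range(3)])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ s.values)
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma ** 2)
        # truth mapped to the centered basis: b_j = p^(j)(t_bar) / j!
        c0, c1, c2 = (TRUE_COEF_MIN["c0"], TRUE_COEF_MIN["c1"], TRUE_COEF_MIN["c2"])
        truth_centered = np.array([c0 + c1 * t_bar + c2 * t_bar ** 2,
                                   c1 + 2 * c2 * t_bar, c2])
        # my fit mapped to the same basis via derivatives of the raw polynomial
        m0, m1, m2 = fit.coefficients
        mine_centered = np.array([m0 + m1 * t_bar + m2 * t_bar ** 2,
                                  m1 + 2 * m2 * t_bar, m2])
        assert np.allclose(mine_centered, beta_hat, atol=1e-9)
        assert np.all(np.abs(mine_centered - truth_centered) <= 3 * se)

    def test_short_series_clips_window(self):
        s = ConfluencySeries.from_values(np.linspace(0.1, 0.2, 50))
        fit = fit_growth_model(s, window_frames=300)
        assert fit.window == (0, 49)

    def test_too_few_points_rejected(self):
        s = ConfluencySeries.from_values([0.1, 0.2])
        with pytest.raises(ValueError):
            fit_growth_model(s, family="poly2")

    def test_unknown_family_rejected(self, quadratic_series):
        with pytest.raises(ValueError):
            fit_growth_model(quadratic_series, family="spline")

    def test_exponential_rejects_non_positive_values(self):
        s = ConfluencySeries.from_values(np.linspace(0.0, 0.5, 100))
        with pytest.raises(ModelFitError):
            fit_growth_model(s, family="exponential")

    def test_logarithmic_family_recovers_log_data(self):
        t = np.arange(200) * 5.0
        vals = 0.08 * np.log(t + 1.0) + 0.05
        s = ConfluencySeries(np.arange(200), t, vals)
        fit = fit_growth_model(s, window_frames=200, family="logarithmic")
        a, b, t0 = fit.coefficients
        assert a == pytest.approx(0.08, abs=1e-9)
        assert b == pytest.approx(0.05, abs=1e-9)


class TestForecast:
    def test_constant_fit_forecasts_constant(self):
        fit = fit_growth_model(ConfluencySeries.from_values(np.full(300, 0.3)))
        for horizon in (5.0, 240.0, 1000.0):
            assert forecast(fit, fit.time_origin_min + horizon) == pytest.approx(0.3)

    def test_linear_fit_horizon_algebra(self):
        s = _linear_series(0.001, 0.3)
        fit = fit_growth_model(s, window_frames=100, family="poly1")
        now = float(s.time_min[-1])
        assert forecast(fit, now + 48 * 5.0) == pytest.approx(0.348, abs=1e-9)

    def test_matches_independent_horner_evaluation(self, quadratic_series):
        fit = fit_growth_model(quadratic_series)
        c = fit.coefficients
        for t in (3500.0, 3600.0, 4000.0):
            horner = c[2]
            for coef in (c[1], c[0]):
                horner = horner * t + coef
            assert fit.predict(t) == pytest.approx(horner, abs=1e-12)

    def test_reported_forecast_is_clipped(self):
        s = _linear_series(0.001, 0.99)
        fit = fit_growth_model(s, window_frames=100, family="poly1")
        t_far = float(s.time_min[-1]) + 500.0
        assert forecast(fit, t_far) == 1.0
        assert fit.predict(t_far) > 1.0


class TestTimeToThreshold:
    def test_crossing_beyond_horizon_returns_none(self):
        s = _linear_series(0.0002, 0.46)  # reaches 0.5 at now + 200 frames
        fit = fit_growth_model(s, window_frames=100, family="poly1")
        now = float(s.time_min[-1])
        assert time_to_threshold(fit, 0.5, now, horizon_min=240.0) is None

    def test_linear_crossing_algebra(self):
        s = _linear_series(0.001, 0.46)  # (0.5-0.46)/0.001 = 40 frames = 200 min
        fit = fit_growth_model(s, window_frames=100, family="poly1")
        now = float(s.time_min[-1])
        t = time_to_threshold(fit, 0.5, now, horizon_min=240.0)
        assert t == pytest.approx(now + 200.0, abs=1e-6)

    def test_already_above_threshold_returns_now(self):
        fit = fit_growth_model(ConfluencySeries.from_values(np.full(300, 0.6)))
        assert time_to_threshold(fit, 0.5, 1495.0) == 1495.0

    def test_decreasing_fit_never_crosses(self):
        s = _linear_series(-0.001, 0.4)
        fit = fit_growth_model(s, window_frames=100, family="poly1")
        assert time_to_threshold(fit, 0.5, float(s.time_min[-1])) is None

    def test_invalid_threshold_rejected(self, quadratic_series):
        fit = fit_growth_model(quadratic_series)
        with pytest.raises(ValueError):
            time_to_threshold(fit, 0.0, 0.0)
        with pytest.raises(ValueError):
            time_to_threshold(fit, 1.5, 0.0)

    def test_closed_form_matches_dense_grid_scan(self):
        """Random noisy quadratic fits: root-finding vs a 0.1-min scan."""
        rng = np.random.default_rng(5)
        horizon = 480.0
        for trial in range(20):
            s = generate_growth_series(SyntheticGrowthParams(
                a2=rng.uniform(5e-7, 2e-6), a1=rng.uniform(0, 2e-4),
                c0=rng.uniform(0.2, 0.45), n_frames=300,
                noise_sigma=0.003, seed=int(rng.integers(1 << 30))))
            fit = fit_growth_model(s)
            now = float(s.time_min[-1])
            closed = time_to_threshold(fit, 0.5, now, horizon)
            scan = None
            for t in np.arange(now + 0.1, now + horizon + 0.05, 0.1):
                if fit.predict(t) >= 0.5:
                    scan = t
                    break
            if closed is None:
                assert scan is None
            else:
                assert scan is not None and abs(closed - scan) <= 0.1

    def test_crossing_consistency_for_increasing_fit(self):
        s = _linear_series(0.0005, 0.48)
        fit = fit_growth_model(s, window_frames=100, family="poly1")
        now = float(s.time_min[-1])
        t = time_to_threshold(fit, 0.5, now, 240.0)
        assert fit.predict(t) >= 0.5 - 1e-9
        assert fit.predict(t - 1.0) < 0.5


class TestVarianceTracking:
    def test_perfect_forecasts_give_zero_variance(self):
        state = PredictionState()
        for v in np.linspace(0.1, 0.5, 60):
            update_variance(state, v, v)
        assert np.allclose(state.variance_trace, 0.0)

    def test_alternating_errors_converge_to_squared_amplitude(self):
        e = 0.01
        state = PredictionState()
        for i in range(200):
            update_variance(state, 0.3, 0.3 + (e if i % 2 == 0 else -e))
        # sample variance of a full +/-e window: 48 e^2 / 47
        assert state.variance == pytest.approx(48 * e * e / 47, rel=1e-12)
        assert state.variance == pytest.approx(e * e, rel=0.05)

    def test_noise_free_quadratic_rolling_variance_is_tiny(self, quadratic_series):
        df = rolling_forecast(quadratic_series, min_points=10)
        state = PredictionState()
        for _, row in df.iterrows():
            update_variance(state, row["observed"], row["forecast"])
        assert max(state.variance_trace[60:]) < 1e-12

    def test_squared_errors_are_non_negative_and_logged(self):
        state = PredictionState()
        update_variance(state, 0.4, 0.35)
        assert state.squared_errors == [pytest.approx(0.0025)]


class TestRmse:
    def test_identical_series_zero(self):
        assert rmse([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 0.0

    def test_known_arithmetic(self):
        assert rmse([1.0, 2.0], [0.0, 2.0]) == pytest.approx(np.sqrt(0.5))

    def test_matches_naive_loop_oracle(self, rng):
        p = rng.random(57)
        o = rng.random(57)
        acc = 0.0
        for a, b in zip(p, o):
            acc += (a - b) ** 2
        assert rmse(p, o) == pytest.approx(np.sqrt(acc / 57), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestCompareModels:
    def test_polynomial_families_on_noiseless_quadratic(self):
        s = generate_growth_series(SyntheticGrowthParams(
            a2=1e-6, a1=1e-4, c0=0.05, n_frames=400, noise_sigma=0.0))
        table = compare_models(s).set_index("family")
        assert table.loc["poly2", "forecast_rmse"] <= 1e-9
        assert table.loc["poly3", "forecast_rmse"] <= 1e-9
        assert table.loc["poly1", "forecast_rmse"] > 1e-9

    def test_logarithmic_data_selects_logarithmic_family(self):
        t = np.arange(400) * 5.0
        vals = 0.08 * np.log(t + 1.0) + 0.05
        s = ConfluencySeries(np.arange(400), t, vals)
        table = compare_models(s).set_index("family")
        # the window-anchored log family cannot match the global curve
        # exactly, but it still out-forecasts every other family
        assert table["forecast_rmse"].idxmin() == "logarithmic"
        assert (table.loc["logarithmic", "forecast_rmse"]
                < table.drop(index="logarithmic")["forecast_rmse"].min())

    def test_table_sorted_ascending(self, noisy_quadratic_series):
        table = compare_models(noisy_quadratic_series)
        vals = table["forecast_rmse"].dropna().to_numpy()
        assert np.all(np.diff(vals) >= 0)

    def test_unknown_family_rejected(self, quadratic_series):
        with pytest.raises(ValueError):
            compare_models(quadratic_series, families=["poly2", "weird"])


class TestSubsampleCompare:
    def test_stride_one_returns_equal_values(self, noisy_quadratic_series):
        r_full, r_str = subsample_compare(noisy_quadratic_series, stride=1)
        assert r_full == r_str

    def test_noise_free_quadratic_both_tiny(self, quadratic_series):
        r_full, r_str = subsample_compare(quadratic_series, stride=6)
        assert r_full <= 1e-9 and r_str <= 1e-9

    def test_oversized_stride_rejected(self):
        s = ConfluencySeries.from_values(np.linspace(0.1, 0.3, 20))
        with pytest.raises(ValueError):
            subsample_compare(s, stride=25)


class TestConfluencySeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            ConfluencySeries(np.array([0, 0]), np.array([0.0, 5.0]),
                             np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            ConfluencySeries(np.array([0, 1]), np.array([0.0, 5.0]),
                             np.array([0.1, np.nan]))

    def test_csv_round_trip(self, tmp_path, noisy_quadratic_series):
        path = tmp_path / "series.csv"
        noisy_quadratic_series.to_csv(path)
        back = ConfluencySeries.from_csv(path)
        assert np.allclose(back.values, noisy_quadratic_series.values)
        assert back.frame_interval_min == 5.0

    def test_subsample_keeps_original_frame_indices(self, quadratic_series):
        sub = quadratic_series.subsample(6)
        assert sub.frame_index[1] == 6
        assert sub.frame_interval_min == 30.0
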