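"""Resolution detection, cleaning, SSM likelihood fitting and the smoother."""

import numpy as np
import pandas as pd
import pytest

from aqfusion.gapfill import (
    KalmanImputer,
    RegularSeries,
    SSMParams,
    _initial_conditions,
    _loglik,
    clean,
    detect_resolution,
    fit_ssm,
    kalman_smooth,
)
from tests._oracles import dense_conditioning, simulate_ssm


def _series(values, step="1h", start="2016-01-01"):
    return RegularSeries(start=pd.Timestamp(start), step=step,
                         values=np.asarray(values, dtype=float))


class TestDetectResolution:
    def test_hourly(self):
        ts = pd.date_range("2016-01-01", periods=11, freq="1h")
        assert detect_resolution(ts) == pd.Timedelta("1h")

    def test_mode_of_gaps(self):
        ts = pd.to_datetime(["2016-01-01 00:00", "2016-01-01 02:00",
                             "2016-01-01 04:00", "2016-01-01 08:00",
                             "2016-01-01 10:00"])
        assert detect_resolution(ts) == pd.Timedelta("2h")

    def test_random_deletion_keeps_hourly_mode(self):
        rng = np.random.default_rng(42)
        ts = pd.date_range("2016-01-01", periods=500, freq="1h")
        keep = rng.uniform(size=500) > 0.2
        keep[[0, -1]] = True
        got = detect_resolution(ts[keep])
        # brute-force gap histogram confirms 1h is modal after 20% deletion
        gaps = np.diff(ts[keep].asi8)
        uniq, counts = np.unique(gaps, return_counts=True)
        assert uniq[np.argmax(counts)] == 3600 * 10**9
        assert got == pd.Timedelta("1h")

    def test_tie_prefers_finer_resolution(self):
        # gaps 1h, 2h, 1h, 2h: tie between 1h and 2h resolves to 1h
        ts = pd.to_datetime(["2016-01-01 00:00", "2016-01-01 01:00",
                             "2016-01-01 03:00", "2016-01-01 04:00",
                             "2016-01-01 06:00"])
        assert detect_resolution(ts) == pd.Timedelta("1h")

    def test_errors(self):
        with pytest.raises(ValueError):
            detect_resolution(pd.to_datetime(["2016-01-01", "2016-01-02"]))
        ts = pd.date_range("2016-01-01", periods=5, freq="3h")
        with pytest.raises(ValueError, match="supported"):
            detect_resolution(ts)


class TestClean:
    def test_negative_and_unvalidated_become_missing(self):
        frame = pd.DataFrame({
            "timestamp": pd.date_range("2016-01-01", periods=3, freq="1h"),
            "value": [1.2, -0.5, 3.4],
            "validated": [1, 1, 1],
        })
        out = clean(frame, step="1h")
        np.testing.assert_array_equal(out.values, [1.2, np.nan, 3.4])

        frame["value"] = [1.2, 0.5, 3.4]
        frame["validated"] = [1, 0, 1]
        out = clean(frame, step="1h")
        np.testing.assert_array_equal(out.values, [1.2, np.nan, 3.4])

    def test_valid_nonnegative_unchanged(self):
        frame = pd.DataFrame({
            "timestamp": pd.date_range("2016-01-01", periods=4, freq="2h"),
            "value": [1.0, 2.0, 3.0, 4.0],
            "validated": [1, 1, 1, 1],
        })
        out = clean(frame, step="2h")
        np.testing.assert_array_equal(out.values, [1.0, 2.0, 3.0, 4.0])
        assert out.step == pd.Timedelta("2h")

    def test_absent_slots_become_missing(self):
        ts = pd.to_datetime(["2016-01-01 00:00", "2016-01-01 01:00",
                             "2016-01-01 04:00"])
        frame = pd.DataFrame({"timestamp": ts, "value": [1.0, 2.0, 5.0]})
        out = clean(frame, step="1h")
        np.testing.assert_array_equal(out.values, [1.0, 2.0, np.nan, np.nan, 5.0])

    def test_duplicate_grid_timestamps_rejected(self):
        ts = pd.to_datetime(["2016-01-01 00:00", "2016-01-01 00:00",
                             "2016-01-01 01:00"])
        frame = pd.DataFrame({"timestamp": ts, "value": [1.0, 1.5, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            clean(frame, step="1h")


class TestFitSSM:
    def test_parameter_recovery(self):
        """A=0.9, B=2 recovered from one long simulated series."""
        y = simulate_ssm(5000, 0.9, 2.0, seed=0)
        params = fit_ssm(_series(y))
        assert params.converged
        assert 0.85 <= params.A <= 0.95
        assert 1.8 <= params.B <= 2.2

    def test_optimum_beats_start_point(self):
        y = simulate_ssm(500, 0.7, 1.5, seed=3)
        values = _series(y).values
        mu0, p0 = _initial_conditions(values)
        params = fit_ssm(_series(y))
        at_start = _loglik([float(v) for v in values], 1.0, 1.0, 1.0, mu0, p0)
        assert params.loglik >= at_start

    def test_constant_series_degenerate_no_crash(self):
        params = fit_ssm(_series(np.full(50, 7.0)))
        assert params.B < 0.1 or not params.converged

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_ssm(_series([1.0] * 5 + [np.nan] * 20))

    def test_likelihood_matches_statsmodels(self):
        """Independent state-space implementation agrees on the likelihood."""
        sm = pytest.importorskip("statsmodels.tsa.statespace.kalman_smoother")
        y = simulate_ssm(80, 0.8, 1.5, seed=9)
        mu0, p0 = _initial_conditions(y)
        a, b, r = 0.85, 1.3, 1.0
        ks = sm.KalmanSmoother(k_endog=1, k_states=1)
        ks.bind(y.reshape(-1, 1).copy())
        ks["design"] = np.array([[1.0]])
        ks["obs_cov"] = np.array([[r]])
        ks["transition"] = np.array([[a]])
        ks["selection"] = np.array([[1.0]])
        ks["state_cov"] = np.array([[b * b]])
        ks.initialize_known(np.array([mu0]), np.array([[p0]]))
        res = ks.smooth()
        ours = _loglik([float(v) for v in y], a, b, r, mu0, p0)
        assert ours == pytest.approx(res.llf, abs=1e-8)

    def test_estimator_params_roundtrip(self):
        imp = KalmanImputer(prescale=True, tol=1e-5)
        assert imp.get_params()["prescale"] is True
        imp.set_params(prescale=False)
        assert imp.get_params()["prescale"] is False
        with pytest.raises(ValueError):
            imp.set_params(nonsense=1)


class TestKalmanSmooth:
    def test_no_missing_entries(self, hourly_series):
        values = hourly_series.values.copy()
        values[np.isnan(values)] = 20.0
        series = _series(values)
        imp = KalmanImputer().fit_transform(series)
        assert not imp.imputed_mask.any()
        np.testing.assert_array_equal(imp.filled_values, values)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_conditioning(self, seed):
        """Smoothed means/variances equal brute-force Gaussian conditioning."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        a = float(rng.uniform(-0.95, 0.98))
        b = float(rng.uniform(0.3, 2.5))
        y = simulate_ssm(n, min(abs(a), 0.95) + 1e-3, b, seed=seed + 100,
                         missing_rate=0.25)
        if np.isnan(y[:2]).all():
            y[0] = 1.0
        series = _series(y)
        params = SSMParams(A=a, B=b)
        imp = kalman_smooth(series, params)
        mu0, p0 = _initial_conditions(y)
        post_mean, post_var = dense_conditioning(y, a, b, 1.0, mu0, p0)
        miss = np.isnan(y)
        np.testing.assert_allclose(imp.filled_values[miss], post_mean[miss],
                                   atol=1e-8)
        np.testing.assert_allclose(imp.smoothed_variance, post_var, atol=1e-8)

    def test_single_interior_gap_oracle(self):
        y = simulate_ssm(30, 0.8, 1.2, seed=4, missing_rate=0.0)
        y[14] = np.nan
        imp = kalman_smooth(_series(y), SSMParams(A=0.8, B=1.2))
        mu0, p0 = _initial_conditions(y)
        post_mean, post_var = dense_conditioning(y, 0.8, 1.2, 1.0, mu0, p0)
        assert imp.filled_values[14] == pytest.approx(post_mean[14], abs=1e-8)
        assert imp.smoothed_variance[14] == pytest.approx(post_var[14], abs=1e-8)

    def test_white_noise_state_gap(self):
        """With A=0 a missing entry carries the prior: mean 0, variance B^2."""
        y = np.tile([3.0, -1.0, 2.0, 0.5], 10)
        y[17] = np.nan
        imp = kalman_smooth(_series(y), SSMParams(A=0.0, B=1.7))
        assert imp.filled_values[17] == pytest.approx(0.0, abs=1e-12)
        assert imp.smoothed_variance[17] == pytest.approx(1.7**2, abs=1e-12)

    def test_observed_entries_shrink_below_measurement_variance(self):
        y = simulate_ssm(60, 0.9, 1.5, seed=8)
        imp = kalman_smooth(_series(y), SSMParams(A=0.9, B=1.5))
        obs = ~np.isnan(y)
        assert (imp.smoothed_variance[obs] <= 1.0 + 1e-12).all()
        assert (imp.smoothed_variance >= 0).all()

    def test_monotone_information(self):
        """Deleting one more observation never decreases any smoothed variance."""
        y = simulate_ssm(40, 0.85, 1.0, seed=2, missing_rate=0.1)
        imp1 = kalman_smooth(_series(y), SSMParams(A=0.85, B=1.0))
        y2 = y.copy()
        drop = int(np.flatnonzero(~np.isnan(y2))[8])
        y2[drop] = np.nan
        imp2 = kalman_smooth(_series(y2), SSMParams(A=0.85, B=1.0))
        assert (imp2.smoothed_variance >= imp1.smoothed_variance - 1e-10).all()

    def test_gap_variance_peaks_in_middle(self):
        """Within an interior gap, uncertainty is largest mid-gap (0<A<1)."""
        y = np.full(60, np.nan)
        y[:20] = simulate_ssm(20, 0.8, 1.0, seed=5, missing_rate=0.0)
        y[41:] = simulate_ssm(19, 0.8, 1.0, seed=6, missing_rate=0.0)
        imp = kalman_smooth(_series(y), SSMParams(A=0.8, B=1.0))
        gap_var = imp.smoothed_variance[20:41]
        peak = int(np.argmax(gap_var))
        assert 8 <= peak <= 12  # middle of a 21-entry gap
        # unimodal: non-decreasing up to the peak, non-increasing after
        assert (np.diff(gap_var[: peak + 1]) >= -1e-10).all()
        assert (np.diff(gap_var[peak:]) <= 1e-10).all()

    def test_prescale_roundtrip_near_raw_fit(self):
        y = 1000.0 * simulate_ssm(300, 0.9, 2.0, seed=12)
        series = _series(y)
        imp = KalmanImputer(prescale=True).fit_transform(series)
        miss = np.isnan(y)
        assert np.isfinite(imp.filled_values).all()
        assert (imp.smoothed_variance[miss] > 0).all()

    def test_mean_parameter_bias_over_replicates(self):
        """Mean bias of the fitted A over 20 replicates stays below 0.02."""
        a_hats = [fit_ssm(_series(simulate_ssm(5000, 0.9, 2.0, seed=s))).A
                  for s in range(20)]
        assert abs(np.mean(a_hats) - 0.9) < 0.02
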