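"""ODBA pipeline: filtering, gravity alignment, rectified means, OLS fit."""

import numpy as np
import pytest

from stridespeed import (
    OdbaRegressor,
    StrideWindow,
    compute_odba,
    fit_odba_model,
    gravity_align,
    lowpass_filter,
    predict_odba,
)
from stridespeed.segmentation import attach_reference_speeds

from conftest import random_window


def literal_odba(window):
    """Independent straight-line re-implementation of the ODBA pipeline:
    explicit loops, scipy primitives, and scipy's own minimal-rotation
    construction instead of the package's."""
    from scipy.signal import butter, filtfilt
    from scipy.spatial.transform import Rotation

    b, a = butter(4, 10.0 / (window.sample_rate_hz / 2.0), btype="low")
    filtered = np.array([filtfilt(b, a, window.data[i]) for i in range(3)])
    mean_vec = np.array([filtered[i].mean() for i in range(3)])
    unit = mean_vec / np.linalg.norm(mean_vec)
    R, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [unit])
    aligned = np.stack([R.apply(filtered[:, j]) for j in range(101)], axis=1)
    total = 0.0
    for j in range(101):
        for i in range(3):
            total += abs(aligned[i, j] - aligned[i].mean())
    return total / 101.0


class TestLowpass:
    def test_dc_gain_is_unity(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, 100.0), x, atol=1e-9)

    @pytest.mark.parametrize(
        "freq,expect_kept", [(2.0, True), (40.0, False)]
    )
    def test_passband_kept_stopband_killed(self, freq, expect_kept):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_filter(x, 100.0)
        ratio = np.ptp(y[500:1500]) / np.ptp(x[500:1500])
        if expect_kept:
            assert ratio == pytest.approx(1.0, abs=0.02)
        else:
            assert ratio < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(np.zeros(100), 100.0, cutoff_hz=60.0)


class TestGravityAlign:
    def test_already_aligned_window_unchanged(self):
        data = np.zeros((6, 101))
        data[2] = 1.0
        win = StrideWindow(data=data, anchor_index=0)
        np.testing.assert_allclose(gravity_align(win).data, data, atol=1e-12)

    def test_x_gravity_rotates_onto_z(self):
        data = np.zeros((6, 101))
        data[0] = 1.0
        aligned = gravity_align(StrideWindow(data=data, anchor_index=0))
        np.testing.assert_allclose(aligned.accel[2], np.ones(101), atol=1e-12)
        np.testing.assert_allclose(aligned.accel[:2], 0.0, atol=1e-12)

    def test_per_sample_norms_preserved(self, rng):
        win = random_window(rng)
        aligned = gravity_align(win)
        np.testing.assert_allclose(
            np.linalg.norm(aligned.accel, axis=0),
            np.linalg.norm(win.accel, axis=0),
            rtol=1e-12,
        )
        np.testing.assert_array_equal(aligned.gyro, win.gyro)

    def test_mean_vector_lands_on_positive_z(self, rng):
        win = random_window(rng, gravity=0.9)
        m = gravity_align(win).accel.mean(axis=1)
        assert m[2] > 0
        np.testing.assert_allclose(m[:2], 0.0, atol=1e-12)

    def test_free_fall_window_rejected(self):
        data = np.zeros((6, 101))
        data[:3] = 1e-4
        with pytest.raises(ValueError, match="unobservable"):
            gravity_align(StrideWindow(data=data, anchor_index=0))


class TestComputeOdba:
    def test_constant_window_gives_zero(self):
        data = np.zeros((6, 101))
        data[:3] = np.array([[0.2], [0.1], [1.0]])
        win = StrideWindow(data=data, anchor_index=0)
        assert compute_odba(win) == pytest.approx(0.0, abs=1e-12)

    def test_rectified_sine_mean_two_a_over_pi(self):
        # az = 1 + A sin(2*pi*2t): whole periods over the 1 s window, well
        # inside the 10 Hz passband; mean |.| of a sine is 2A/pi
        A = 0.5
        t = np.arange(101) / 100.0
        data = np.zeros((6, 101))
        data[2] = 1.0 + A * np.sin(2 * np.pi * 2.0 * t)
        win = StrideWindow(data=data, anchor_index=0)
        assert compute_odba(win) == pytest.approx(2 * A / np.pi, rel=0.03)

    def test_odba_always_non_negative(self, rng):
        for _ in range(20):
            assert compute_odba(random_window(rng)) >= 0.0

    def test_agrees_with_literal_reimplementation(self, rng):
        for _ in range(100):
            win = random_window(rng)
            assert compute_odba(win) == pytest.approx(literal_odba(win), abs=1e-9)

    def test_invariant_to_constant_shift_parallel_to_mean(self, rng):
        # the gravity estimate is the mean of the *filtered* acceleration,
        # so exact invariance holds for shifts parallel to that vector
        win = random_window(rng)
        mean_vec = lowpass_filter(win.accel, win.sample_rate_hz).mean(axis=1)
        shifted = win.data.copy()
        shifted[:3] += 0.5 * (mean_vec / np.linalg.norm(mean_vec))[:, None]
        win2 = StrideWindow(data=shifted, anchor_index=0)
        assert compute_odba(win2) == pytest.approx(compute_odba(win), abs=1e-9)


def _dataset_from_windows(windows, speeds):
    return attach_reference_speeds(windows, speeds, protocol="straight")


class TestOdbaModel:
    def _windows_with_odba_span(self, rng, n):
        wins = [random_window(rng, scale=0.05 + 0.4 * i / n) for i in range(n)]
        odba = np.array([compute_odba(w) for w in wins])
        return wins, odba

    def test_exact_linear_data_recovered(self, rng):
        wins, odba = self._windows_with_odba_span(rng, 30)
        speeds = 2.0 + 3.0 * odba
        model = fit_odba_model(_dataset_from_windows(wins, speeds))
        assert model.intercept_ == pytest.approx(2.0, abs=1e-8)
        assert model.slope_ == pytest.approx(3.0, abs=1e-8)
        np.testing.assert_allclose(predict_odba(model, wins), speeds, atol=1e-8)

    def test_parameter_recovery_within_three_se(self, rng):
        n, a, b, sigma = 500, 1.5, 4.0, 0.1
        wins, odba = self._windows_with_odba_span(rng, n)
        speeds = a + b * odba + rng.normal(0.0, sigma, n)
        model = fit_odba_model(_dataset_from_windows(wins, speeds))
        x = odba - odba.mean()
        resid_sd = model.fit_diagnostics_["residual_sd"]
        se_slope = resid_sd / np.sqrt((x**2).sum())
        se_int = resid_sd * np.sqrt(1 / n + odba.mean() ** 2 / (x**2).sum())
        assert abs(model.slope_ - b) < 3 * se_slope
        assert abs(model.intercept_ - a) < 3 * se_int

    def test_prediction_is_affine_in_odba(self, rng):
        wins, odba = self._windows_with_odba_span(rng, 10)
        model = OdbaRegressor()
        model.intercept_, model.slope_ = 1.25, 2.5
        model.fit_diagnostics_ = {}
        np.testing.assert_allclose(
            model.predict(wins), 1.25 + 2.5 * odba, atol=1e-10
        )

    def test_single_stride_rejected(self, rng):
        wins, odba = self._windows_with_odba_span(rng, 1)
        with pytest.raises(ValueError, match="at least 2"):
            OdbaRegressor().fit(wins, [5.0])

    def test_degenerate_design_rejected(self):
        data = np.zeros((6, 101))
        data[2] = 1.0
        wins = [StrideWindow(data=data.copy(), anchor_index=0) for _ in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            OdbaRegressor().fit(wins, [4, 5, 6, 7, 8])

    def test_json_round_trip(self, tmp_path, rng):
        wins, odba = self._windows_with_odba_span(rng, 20)
        model = fit_odba_model(_dataset_from_windows(wins, 2.0 + 3.0 * odba))
        path = tmp_path / "odba.json"
        model.save(path)
        back = OdbaRegressor.load(path)
        np.testing.assert_allclose(back.predict(wins), model.predict(wins), atol=1e-12)

    def test_version_mismatch_named_in_error(self, tmp_path):
        import json

        path = tmp_path / "odba.json"
        path.write_text(json.dumps({"format": "stridespeed-odba", "version": 99}))
        with pytest.raises(ValueError, match="99"):
            OdbaRegressor.load(path)
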