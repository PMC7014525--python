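"""Signal-based speed baseline: overall dynamic body acceleration (ODBA).

ODBA is a classic accelerometry proxy for locomotor effort: after
low-pass filtering, aligning the Z-axis with gravity, and removing the
per-axis static component, the rectified dynamic accelerations of the
three axes are summed.  Averaged over a stride window it correlates with
speed, and a simple linear regression of speed on mean ODBA gives a
per-stride speed estimate.

Pipeline for one 6 x 101 window (acceleration channels only; gyroscope
rows pass through untouched):

1. zero-phase 4th-order Butterworth low-pass at 10 Hz;
2. rotate all acceleration samples by the single minimal rotation taking
   the window-mean acceleration vector onto +Z (gravity alignment);
3. subtract the per-axis window mean;
4. rectify (absolute value), sum the three axes per sample;
5. average over the window's samples -> mean ODBA in g.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

from .types import StrideDataset, StrideWindow

#: below this window-mean acceleration magnitude (g) the gravity direction
#: is considered unobservable (free-fall-like) and alignment fails
MIN_GRAVITY_MAG_G = 0.1


def lowpass_filter(
    signals: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 10.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis.

    Applied forward-backward (``filtfilt``) so the rectified means used by
    ODBA are not phase-shifted across the window boundary.
    """
    nyquist = sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz at "
            f"{sample_rate_hz} Hz sampling"
        )
    b, a = butter(order, cutoff_hz / nyquist, btype="low")
    return filtfilt(b, a, np.asarray(signals, dtype=float), axis=-1)


def _rotation_to_z(mean_vec: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking ``mean_vec`` onto +Z (Rodrigues)."""
    norm = np.linalg.norm(mean_vec)
    u = mean_vec / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(u, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # antiparallel: rotate pi about X (any axis normal to Z works)
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def gravity_align(window: StrideWindow) -> StrideWindow:
    """Rotate the window's acceleration so its mean vector lies on +Z.

    The gravity direction is estimated per window as the mean acceleration
    vector; one minimal (norm-preserving) rotation is applied to every
    acceleration sample.  Gyroscope rows are untouched.
    """
    accel = window.accel  # (3, 101)
    mean_vec = accel.mean(axis=1)
    if np.linalg.norm(mean_vec) < MIN_GRAVITY_MAG_G:
        raise ValueError(
            f"window-mean acceleration magnitude {np.linalg.norm(mean_vec):.3g} g "
            f"below {MIN_GRAVITY_MAG_G} g: gravity direction unobservable"
        )
    R = _rotation_to_z(mean_vec)
    rotated = R @ accel
    data = np.vstack([rotated, window.gyro])
    return StrideWindow(
        data=data, anchor_index=window.anchor_index,
        sample_rate_hz=window.sample_rate_hz,
    )


def compute_odba(window: StrideWindow, sample_rate_hz: float | None = None) -> float:
    """Mean ODBA of one stride window, in g (non-negative).

    Zero exactly when the filtered, gravity-aligned acceleration is
    constant per axis (mean subtraction annihilates constants).
    """
    fs = sample_rate_hz or window.sample_rate_hz
    filtered = lowpass_filter(window.accel, fs)
    fwin = StrideWindow(
        data=np.vstack([filtered, window.gyro]),
        anchor_index=window.anchor_index,
        sample_rate_hz=fs,
    )
    aligned = gravity_align(fwin).accel
    dynamic = aligned - aligned.mean(axis=1, keepdims=True)
    return float(np.abs(dynamic).sum(axis=0).mean())


def _windows_from_X(X) -> list[StrideWindow]:
    """Accept a StrideDataset, a list of windows, or an (n, 6, 101) /
    (n, 606) array, and return StrideWindow objects."""
    from .svm import inverse_featurize

    if isinstance(X, StrideDataset):
        return list(X.windows)
    if len(X) and isinstance(X[0], StrideWindow):
        return list(X)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 3:
        return [StrideWindow(data=a, anchor_index=0) for a in arr]
    if arr.ndim == 2:
        return [inverse_featurize(row) for row in arr]
    raise ValueError(f"cannot interpret input of shape {arr.shape} as stride windows")


class OdbaRegressor(RegressorMixin, BaseEstimator):
    """Linear regression of stride speed on mean ODBA.

    A scikit-learn style estimator: ``fit`` computes one mean-ODBA scalar
    per stride window and runs an ordinary least-squares fit of speed on
    ODBA; ``predict`` applies ``intercept_ + slope_ * ODBA``.

    Parameters
    ----------
    cutoff_hz, filter_order : low-pass filter settings (10 Hz, 4th order).
    sample_rate_hz : fallback sampling rate when input windows carry none.
    """

    def __init__(
        self,
        cutoff_hz: float = 10.0,
        filter_order: int = 4,
        sample_rate_hz: float = 100.0,
    ) -> None:
        self.cutoff_hz = cutoff_hz
        self.filter_order = filter_order
        self.sample_rate_hz = sample_rate_hz

    def _odba_features(self, X) -> np.ndarray:
        return np.array([compute_odba(w) for w in _windows_from_X(X)])

    def fit(self, X, y=None) -> "OdbaRegressor":
        if isinstance(X, StrideDataset) and y is None:
            y = X.speeds
        y = np.asarray(y, dtype=float)
        odba = self._odba_features(X)
        if len(odba) < 2:
            raise ValueError("need at least 2 strides to fit the ODBA model")
        if np.ptp(odba) == 0:
            raise ValueError("degenerate design: all ODBA values identical")
        lr = LinearRegression().fit(odba[:, None], y)
        self.intercept_ = float(lr.intercept_)
        self.slope_ = float(lr.coef_[0])
        resid = y - lr.predict(odba[:, None])
        self.fit_diagnostics_ = {
            "n": int(len(y)),
            "residual_sd": float(np.std(resid, ddof=2)) if len(y) > 2 else 0.0,
            "r2": float(lr.score(odba[:, None], y)),
        }
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * self._odba_features(X)

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "slope_")
        payload = {
            "format": "stridespeed-odba",
            "version": 1,
            "intercept": self.intercept_,
            "slope": self.slope_,
            "params": self.get_params(),
            "fit_diagnostics": self.fit_diagnostics_,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "OdbaRegressor":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "stridespeed-odba" or payload.get("version") != 1:
            raise ValueError(
                f"unsupported ODBA model file (format={payload.get('format')!r}, "
                f"version={payload.get('version')!r}; expected "
                f"'stridespeed-odba' v1)"
            )
        model = cls(**payload["params"])
        model.intercept_ = float(payload["intercept"])
        model.slope_ = float(payload["slope"])
        model.fit_diagnostics_ = payload["fit_diagnostics"]
        return model


def fit_odba_model(dataset: StrideDataset) -> OdbaRegressor:
    """Fit the speed-on-ODBA linear baseline on a stride dataset."""
    return OdbaRegressor().fit(dataset, dataset.speeds)


def predict_odba(model: OdbaRegressor, windows: Sequence[StrideWindow]) -> np.ndarray:
    """Predict per-stride speeds (m/s) with a fitted ODBA model."""
    return model.predict(windows)
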