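"""Support-vector regression from a flattened stride window to speed.

Each 6 x 101 window is flattened channel-major into a 606-dimensional
feature vector (all 101 ax samples, then ay, az, gx, gy, gz) and fed,
optionally standardized, to a nu-type support-vector regression with an
RBF kernel.  nu (0.75 by default) steers the fraction of training points
retained as support vectors — in nu-regression it lower-bounds that
fraction and caps the margin-error fraction — and the width of the
epsilon-insensitive tube is then determined automatically by the
optimizer; the cost constant defaults to 4.  Windows are deliberately not resampled or amplitude-
normalized, so stride duration information reaches the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import NuSVR
from sklearn.utils.validation import check_is_fitted

from .types import CHANNELS, N_FEATURES, WINDOW_LEN, StrideDataset, StrideWindow

_MODEL_FORMAT = "stridespeed-svr"
_MODEL_VERSION = 1


def featurize(window: StrideWindow) -> np.ndarray:
    """Flatten a 6 x 101 window channel-major into a 606-vector."""
    if window.data.shape != (len(CHANNELS), WINDOW_LEN):
        raise ValueError(f"expected 6 x {WINDOW_LEN} window, got {window.data.shape}")
    return window.data.ravel(order="C").copy()


def inverse_featurize(vector: np.ndarray) -> StrideWindow:
    """Reassemble a 606-vector into the original 6 x 101 window."""
    vector = np.asarray(vector, dtype=float).ravel()
    if vector.size != N_FEATURES:
        raise ValueError(f"feature length {vector.size} != {N_FEATURES}")
    return StrideWindow(
        data=vector.reshape(len(CHANNELS), WINDOW_LEN), anchor_index=0
    )


def _as_feature_matrix(X) -> np.ndarray:
    if isinstance(X, StrideDataset):
        return np.stack([featurize(w) for w in X.windows])
    if len(X) and isinstance(X[0], StrideWindow):
        return np.stack([featurize(w) for w in X])
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 3:
        return arr.reshape(arr.shape[0], -1)
    if arr.ndim == 2:
        if arr.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature length mismatch: got {arr.shape[1]}, expected {N_FEATURES}"
            )
        return arr
    raise ValueError(f"cannot interpret input of shape {arr.shape}")


@dataclass
class SvmConfig:
    """Hyperparameters of the window-to-speed SVR.

    nu : in (0, 1]; steers the support-vector fraction (0.75).
    cost : penalty constant C of the regression (4).
    kernel : kernel name, radial-basis by default.
    gamma : RBF width; "auto" means 1 / n_features = 1/606.
    scaling : standardize each feature to zero mean / unit variance using
        training-set statistics.
    """

    nu: float = 0.75
    cost: float = 4.0
    kernel: str = "rbf"
    gamma: float | str = "auto"
    scaling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")
        if self.cost <= 0:
            raise ValueError(f"cost must be > 0, got {self.cost}")


class WindowSVR(RegressorMixin, BaseEstimator):
    """nu-SVR mapping a flattened 6 x 101 stride window to speed in m/s.

    scikit-learn style: accepts StrideDataset, lists of StrideWindow, or
    arrays of shape (n, 6, 101) / (n, 606); composes with sklearn
    pipelines and model selection.  Deterministic given identical inputs
    and parameters.
    """

    def __init__(
        self,
        nu: float = 0.75,
        cost: float = 4.0,
        kernel: str = "rbf",
        gamma: float | str = "auto",
        scaling: bool = True,
    ) -> None:
        self.nu = nu
        self.cost = cost
        self.kernel = kernel
        self.gamma = gamma
        self.scaling = scaling

    @classmethod
    def from_config(cls, cfg: SvmConfig) -> "WindowSVR":
        return cls(nu=cfg.nu, cost=cfg.cost, kernel=cfg.kernel,
                   gamma=cfg.gamma, scaling=cfg.scaling)

    def fit(self, X, y=None) -> "WindowSVR":
        if isinstance(X, StrideDataset) and y is None:
            y = X.speeds
        feats = _as_feature_matrix(X)
        y = np.asarray(y, dtype=float)
        if feats.shape[0] < 2:
            raise ValueError("need at least 2 strides to train the SVR")
        if np.any(y <= 0):
            raise ValueError("training speeds must be > 0")
        if np.allclose(np.ptp(feats, axis=0), 0):
            raise ValueError("degenerate design: all feature vectors identical")
        SvmConfig(nu=self.nu, cost=self.cost, kernel=self.kernel,
                  gamma=self.gamma, scaling=self.scaling)  # validate
        steps = []
        if self.scaling:
            steps.append(("scale", StandardScaler()))
        steps.append(
            ("svr", NuSVR(nu=self.nu, C=self.cost, kernel=self.kernel,
                          gamma=self.gamma))
        )
        self.pipeline_ = Pipeline(steps).fit(feats, y)
        self.n_features_in_ = feats.shape[1]
        self.speed_range_ = (float(y.min()), float(y.max()))
        svr = self.pipeline_.named_steps["svr"]
        self.n_support_vectors_ = int(svr.support_.size)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        feats = _as_feature_matrix(X)
        if feats.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length mismatch: got {feats.shape[1]}, "
                f"expected {self.n_features_in_}"
            )
        return self.pipeline_.predict(feats)

    def save(self, path: str | Path) -> None:
        """Persist the fitted model (joblib payload with a format tag)."""
        check_is_fitted(self, "pipeline_")
        payload = {
            "format": _MODEL_FORMAT,
            "version": _MODEL_VERSION,
            "params": self.get_params(),
            "pipeline": self.pipeline_,
            "n_features_in": self.n_features_in_,
            "speed_range": self.speed_range_,
            "n_support_vectors": self.n_support_vectors_,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "WindowSVR":
        try:
            payload = joblib.load(path)
        except Exception as exc:
            raise ValueError(f"cannot read model file {path}: {exc}") from exc
        if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
            raise ValueError(f"{path} is not a {_MODEL_FORMAT} model file")
        if payload.get("version") != _MODEL_VERSION:
            raise ValueError(
                f"model version mismatch: file has {payload.get('version')!r}, "
                f"this build reads {_MODEL_VERSION}"
            )
        model = cls(**payload["params"])
        model.pipeline_ = payload["pipeline"]
        model.n_features_in_ = payload["n_features_in"]
        model.speed_range_ = tuple(payload["speed_range"])
        model.n_support_vectors_ = payload["n_support_vectors"]
        return model


def fit_svm(dataset: StrideDataset, cfg: SvmConfig | None = None) -> WindowSVR:
    """Train the window-to-speed SVR on a stride dataset."""
    return WindowSVR.from_config(cfg or SvmConfig()).fit(dataset, dataset.speeds)


def predict_svm(model: WindowSVR, windows: Sequence[StrideWindow]) -> np.ndarray:
    """Predict per-stride speeds (m/s) with a fitted SVR."""
    return model.predict(windows)


def save_model(model: WindowSVR, path: str | Path) -> None:
    model.save(path)


def load_model(path: str | Path) -> WindowSVR:
    return WindowSVR.load(path)
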