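"""Core containers for single-IMU stride-speed estimation.

The pipeline works on three objects: a raw six-channel inertial recording
(tri-axial accelerometer in g, tri-axial gyroscope in deg/s, nominally
100 Hz), fixed-length stride windows cut from it, and a dataset pairing
windows with per-stride reference speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np
import pandas as pd

#: canonical channel order used everywhere (rows of a window, feature blocks)
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")

#: samples per stride window: one anchor peak plus the next 100 samples,
#: i.e. 1 s of signal at 100 Hz kept un-resampled so duration information
#: survives into the feature vector.
WINDOW_LEN = 101

#: length of a flattened window feature vector (6 channels x 101 samples)
N_FEATURES = len(CHANNELS) * WINDOW_LEN

ACCEL_RANGE_G = 8.0
GYRO_RANGE_DPS = 2000.0


@dataclass
class ImuRecording:
    """A raw 6-channel inertial stream at a fixed sampling rate.

    Parameters
    ----------
    sample_rate_hz : float
        Sampling rate, nominally 100 Hz.
    accel : ndarray of shape (n_samples, 3)
        Acceleration in g, columns (ax, ay, az); az is the dorso-ventral
        axis used for stride anchoring.
    gyro : ndarray of shape (n_samples, 3)
        Angular rate in deg/s, columns (gx, gy, gz).
    meta : dict
        Free-form annotations (horse id, session, condition).
    """

    sample_rate_hz: float
    accel: np.ndarray
    gyro: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError(f"accel must be (n, 3), got {self.accel.shape}")
        if self.gyro.shape != self.accel.shape:
            raise ValueError(
                f"gyro shape {self.gyro.shape} != accel shape {self.accel.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def az(self) -> np.ndarray:
        """Dorso-ventral acceleration channel (stride anchor axis)."""
        return self.accel[:, 2]

    def channel(self, name: str) -> np.ndarray:
        i = CHANNELS.index(name)
        return self.accel[:, i] if i < 3 else self.gyro[:, i - 3]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class StrideWindow:
    """One fixed-length stride segment: a 6 x 101 matrix anchored at a
    dorso-ventral acceleration peak.

    Rows follow :data:`CHANNELS` order; columns are the anchor sample and
    the next 100 samples of the source recording, raw and un-resampled.
    """

    data: np.ndarray
    anchor_index: int
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(CHANNELS), WINDOW_LEN):
            raise ValueError(
                f"window must be {len(CHANNELS)} x {WINDOW_LEN}, got {self.data.shape}"
            )

    @property
    def accel(self) -> np.ndarray:
        """Acceleration rows, shape (3, 101), in g."""
        return self.data[:3]

    @property
    def gyro(self) -> np.ndarray:
        """Gyroscope rows, shape (3, 101), in deg/s."""
        return self.data[3:]

    @property
    def duration_s(self) -> float:
        return (WINDOW_LEN - 1) / self.sample_rate_hz


@dataclass
class StrideDataset:
    """Stride windows paired with reference speeds and provenance.

    ``meta`` carries one row per window with at least ``horse_id`` and
    ``source`` ("straight" or "curved"); synthetic data additionally keeps
    the hidden per-stride true speed in ``true_speed_mps``.
    """

    windows: list[StrideWindow]
    speeds: np.ndarray
    meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if len(self.windows) != len(self.speeds):
            raise ValueError(
                f"{len(self.windows)} windows but {len(self.speeds)} speeds"
            )
        if len(self.speeds) and (
            not np.all(np.isfinite(self.speeds)) or np.any(self.speeds <= 0)
        ):
            raise ValueError("reference speeds must be finite and > 0")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"horse_id": ["unknown"] * len(self.windows),
                 "source": ["straight"] * len(self.windows)}
            )
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != len(self.windows):
            raise ValueError("meta must have one row per window")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[StrideWindow]:
        return iter(self.windows)

    def subset(self, idx: Sequence[int] | np.ndarray) -> "StrideDataset":
        idx = np.asarray(idx, dtype=int)
        return StrideDataset(
            windows=[self.windows[i] for i in idx],
            speeds=self.speeds[idx],
            meta=self.meta.iloc[idx],
        )

    def window_array(self) -> np.ndarray:
        """Stack windows into an array of shape (n, 6, 101)."""
        return np.stack([w.data for w in self.windows])
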