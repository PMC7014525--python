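"""Plain-text I/O for IMU recordings and stride datasets.

Recording CSV dialect: an optional ``# sample_rate_hz=<f>`` comment line,
then a header ``t,ax,ay,az,gx,gy,gz`` and one row per sample (seconds, g,
deg/s).  Stride-dataset CSV: one row per stride with ``horse_id,source,
speed_mps`` followed by the 606 feature columns ``f000..f605`` in canonical
channel-major flattening order (see :func:`stridespeed.svm.featurize`).
Both formats round-trip within printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ACCEL_RANGE_G,
    CHANNELS,
    GYRO_RANGE_DPS,
    N_FEATURES,
    WINDOW_LEN,
    ImuRecording,
    StrideDataset,
    StrideWindow,
)

RECORDING_COLUMNS = ("t",) + CHANNELS
FEATURE_COLUMNS = [f"f{i:03d}" for i in range(N_FEATURES)]
DATASET_COLUMNS = ["horse_id", "source", "speed_mps"] + FEATURE_COLUMNS

#: maximum allowed timestamp deviation, as a fraction of the nominal sample
#: period — tolerates logger jitter without silently accepting gaps
TIME_JITTER_TOL = 0.10


@dataclass(frozen=True)
class Finding:
    """One validation finding: which rule failed, where."""

    rule: str
    channel: str | None = None
    index: int | None = None
    message: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" [{self.channel}@{self.index}]" if self.channel else ""
        return f"{self.rule}{loc}: {self.message}"


def read_recording(path: str | Path, fmt: str = "csv") -> ImuRecording:
    """Read an IMU recording from the documented CSV dialect.

    The sampling rate is taken from a ``# sample_rate_hz=`` metadata
    comment if present, otherwise inferred from the time column; timestamp
    uniformity is checked against ``TIME_JITTER_TOL``.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported recording format: {fmt!r}")
    path = Path(path)
    meta_rate = None
    with path.open() as fh:
        head = fh.readline()
        if head.startswith("#"):
            if "sample_rate_hz=" in head:
                meta_rate = float(head.split("sample_rate_hz=")[1].strip())
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no samples")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: timestamps not strictly increasing")
        period = float(np.median(dt))
        if np.max(np.abs(dt - period)) > TIME_JITTER_TOL * period:
            raise ValueError(
                f"{path}: non-uniform timestamps beyond "
                f"{TIME_JITTER_TOL:.0%} of the nominal period"
            )
        inferred = 1.0 / period
    else:
        inferred = meta_rate if meta_rate is not None else 100.0
    rate = meta_rate if meta_rate is not None else inferred
    return ImuRecording(
        sample_rate_hz=rate,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        meta={"path": str(path)},
    )


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording to the documented CSV dialect (re-readable by
    :func:`read_recording`; values round-trip within printed precision)."""
    if rec.n_samples == 0:
        raise ValueError("refusing to write a recording with 0 samples")
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sample_rate_hz
    df = pd.DataFrame({"t": t})
    for i, name in enumerate(CHANNELS):
        df[name] = rec.accel[:, i] if i < 3 else rec.gyro[:, i - 3]
    with path.open("w") as fh:
        fh.write(f"# sample_rate_hz={rec.sample_rate_hz:g}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def validate_recording(rec: ImuRecording) -> list[Finding]:
    """Check a recording against the sensor spec; pure, never mutates.

    Out-of-range samples (accelerometer beyond +/-8 g, gyroscope beyond
    +/-2000 deg/s) are reported as findings, not clipped or rejected: the
    ranges are sensor specifications, not data filters.
    """
    findings: list[Finding] = []
    if not rec.sample_rate_hz > 0:
        findings.append(
            Finding("sample_rate", message=f"sample_rate_hz={rec.sample_rate_hz} not > 0")
        )
    for i, name in enumerate(CHANNELS):
        sig = rec.accel[:, i] if i < 3 else rec.gyro[:, i - 3]
        limit = ACCEL_RANGE_G if i < 3 else GYRO_RANGE_DPS
        unit = "g" if i < 3 else "deg/s"
        bad = np.flatnonzero(np.abs(sig) > limit)
        for j in bad:
            findings.append(
                Finding(
                    "sensor_range",
                    channel=name,
                    index=int(j),
                    message=f"{sig[j]:g} {unit} outside +/-{limit:g} {unit}",
                )
            )
    nonfinite = ~np.isfinite(rec.accel).all(axis=1) | ~np.isfinite(rec.gyro).all(axis=1)
    for j in np.flatnonzero(nonfinite):
        findings.append(Finding("finite", index=int(j), message="non-finite sample"))
    return findings


def write_stride_dataset(dataset: StrideDataset, path: str | Path) -> None:
    """Write a stride dataset as one CSV row per stride.

    Columns: ``horse_id, source, speed_mps, f000..f605`` (channel-major
    flattening), plus any extra provenance columns present in the meta
    table (e.g. ``true_speed_mps`` for synthetic data).
    """
    from .svm import featurize  # local import to avoid a cycle

    rows = np.stack([featurize(w) for w in dataset.windows]) if len(dataset) else \
        np.empty((0, N_FEATURES))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.insert(0, "speed_mps", dataset.speeds)
    df.insert(0, "source", dataset.meta["source"].to_numpy())
    df.insert(0, "horse_id", dataset.meta["horse_id"].to_numpy())
    extra = [c for c in dataset.meta.columns if c not in ("horse_id", "source")]
    for c in extra:
        df[c] = dataset.meta[c].to_numpy()
    df.to_csv(path, index=False, float_format="%.9g")


def read_stride_dataset(path: str | Path) -> StrideDataset:
    """Read a stride dataset written by :func:`write_stride_dataset`."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: wrong column count, missing {len(missing)} column(s) "
            f"starting with {missing[0]!r}"
        )
    speeds = df["speed_mps"].to_numpy(dtype=float)
    if len(speeds) and np.any(speeds <= 0):
        bad = int(np.flatnonzero(speeds <= 0)[0])
        raise ValueError(f"{path}: non-positive speed at data row {bad}")
    feats = df[FEATURE_COLUMNS].to_numpy(dtype=float)
    windows = [
        StrideWindow(data=feats[i].reshape(len(CHANNELS), WINDOW_LEN), anchor_index=0)
        for i in range(len(df))
    ]
    meta_cols = ["horse_id", "source"] + [
        c for c in df.columns if c not in DATASET_COLUMNS
    ]
    return StrideDataset(windows=windows, speeds=speeds, meta=df[meta_cols].copy())
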