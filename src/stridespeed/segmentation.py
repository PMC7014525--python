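"""Stride segmentation on the dorso-ventral acceleration axis.

A "stride" here is operational: the maximum peak on the raw Z (dorso-
ventral) acceleration channel anchors a fixed window of that sample plus
the next 100, i.e. 6 channels x 101 samples at 100 Hz.  Windows are never
resampled, so a fast canter packs more movement cycles into its window
than a slow one — that duration information is what the downstream
regression exploits.  A window may therefore contain more than one real
stride at high speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .types import ImuRecording, StrideDataset, StrideWindow, WINDOW_LEN


@dataclass
class SegmentationConfig:
    """Peak-detector and windowing settings.

    min_peak_separation_s : minimum spacing between anchor peaks; the
        default 0.35 s sits below the shortest plausible canter stride.
    min_prominence : minimum Z-axis peak prominence in g.
    window_len : samples per window (anchor + window_len - 1 following).
    allow_overlap : if False, peaks falling inside the previous window are
        skipped (sensitivity-analysis mode); by default overlapping windows
        are kept, one per detected peak.
    """

    min_peak_separation_s: float = 0.35
    min_prominence: float = 1.0
    window_len: int = WINDOW_LEN
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if self.min_peak_separation_s < 0:
            raise ValueError("min_peak_separation_s must be >= 0")


def detect_stride_peaks(
    rec: ImuRecording, cfg: SegmentationConfig | None = None
) -> np.ndarray:
    """Find stride anchor peaks on the raw dorso-ventral acceleration.

    Returns strictly increasing sample indices of local maxima of ``az``
    meeting the prominence and separation constraints; peaks too close to
    the end of the recording to fit a full window are dropped.  Detection
    runs on raw, unfiltered acceleration and is prominence-based, hence
    invariant to a constant offset on the channel.
    """
    cfg = cfg or SegmentationConfig()
    distance = max(1, int(round(cfg.min_peak_separation_s * rec.sample_rate_hz)))
    peaks, _ = find_peaks(rec.az, prominence=cfg.min_prominence, distance=distance)
    peaks = peaks[peaks + cfg.window_len - 1 < rec.n_samples]
    if not cfg.allow_overlap and len(peaks):
        kept = [int(peaks[0])]
        for p in peaks[1:]:
            if p >= kept[-1] + cfg.window_len:
                kept.append(int(p))
        peaks = np.asarray(kept, dtype=int)
    return np.asarray(peaks, dtype=int)


def extract_windows(
    rec: ImuRecording,
    peaks: Sequence[int] | np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> list[StrideWindow]:
    """Cut one 6 x window_len window per anchor peak.

    Window columns are the raw samples ``anchor .. anchor + window_len - 1``
    (inclusive) of all six channels, a pure slice of the recording — no
    resampling, filtering or normalization.
    """
    cfg = cfg or SegmentationConfig()
    windows = []
    for p in peaks:
        p = int(p)
        if p < 0 or p + cfg.window_len - 1 >= rec.n_samples:
            raise ValueError(
                f"peak {p} leaves fewer than {cfg.window_len} samples "
                f"in a {rec.n_samples}-sample recording"
            )
        block = np.vstack(
            [rec.accel[p : p + cfg.window_len].T, rec.gyro[p : p + cfg.window_len].T]
        )
        windows.append(
            StrideWindow(data=block, anchor_index=p, sample_rate_hz=rec.sample_rate_hz)
        )
    return windows


def curve_average_speed(radius_m: float, transit_time_s: float) -> float:
    """Average speed over a circular curve of known radius.

    distance = 2*pi*r; speed = distance / transit time.
    """
    if radius_m <= 0:
        raise ValueError(f"radius must be > 0, got {radius_m}")
    if transit_time_s <= 0:
        raise ValueError(f"transit time must be > 0, got {transit_time_s}")
    return 2.0 * np.pi * radius_m / transit_time_s


def attach_reference_speeds(
    windows: Sequence[StrideWindow],
    reference: float | Sequence[float] | np.ndarray,
    protocol: str = "straight",
    horse_id: str = "unknown",
) -> StrideDataset:
    """Pair windows with reference speeds to form a training/test dataset.

    In the straight-path protocol each window gets its own reference speed
    (element-wise pairing).  In the curved-path protocol a single average
    speed — e.g. from :func:`curve_average_speed` — is broadcast to every
    stride in the curve group.
    """
    import pandas as pd

    n = len(windows)
    if protocol == "straight":
        speeds = np.asarray(reference, dtype=float).ravel()
        if len(speeds) != n:
            raise ValueError(
                f"straight protocol needs one speed per window: "
                f"{len(speeds)} speeds for {n} windows"
            )
    elif protocol == "curved":
        avg = float(np.asarray(reference, dtype=float).ravel()[0]) if np.ndim(
            reference
        ) else float(reference)
        speeds = np.full(n, avg)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    if len(speeds) and np.any(speeds <= 0):
        raise ValueError("reference speeds must be > 0")
    meta = pd.DataFrame({"horse_id": [horse_id] * n, "source": [protocol] * n})
    return StrideDataset(windows=list(windows), speeds=speeds, meta=meta)
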