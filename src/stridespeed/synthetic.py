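"""Synthetic canter-like IMU signals with known per-stride ground truth.

The generator emulates the structure of saddle-mounted accelerometer and
gyroscope data at canter: a dominant dorso-ventral (Z) oscillation at the
stride frequency riding on 1 g of gravity, with a second harmonic giving
the cycle the asymmetric multi-peaked shape of an asymmetric gait, and
correlated harmonics on the remaining five channels.  Both stride
frequency and oscillation amplitude increase affinely with speed, so a
fixed 101-sample window carries speed information in two ways: how many
cycles it contains (duration information) and how large they are.

Two reference protocols are emulated: straight-path strides carry their
own true speed (as a camera tracking system would measure), while
curved-path stride groups are labelled with one average speed broadcast
to every stride in the curve (as a chronometer over a known 2*pi*r
distance would), with the true within-curve speed fluctuation retained
as hidden truth.

Per-recording amplitude and frequency jitter stand in for inter-horse
and inter-session variability; they are what makes the amplitude-only
ODBA baseline noisier than a model that can also read cycle count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .segmentation import SegmentationConfig, detect_stride_peaks, extract_windows
from .types import ImuRecording, StrideDataset

#: fixed canter cycle shape as a function of phase (second harmonic makes
#: the cycle asymmetric while keeping a single maximum per period)
_H2_COEF = 0.25
_H2_PHASE = 0.8


def _cycle_shape(phi: np.ndarray) -> np.ndarray:
    return np.sin(phi) + _H2_COEF * np.sin(2 * phi + _H2_PHASE)


def _peak_phase() -> float:
    """Phase of the cycle maximum, located once on a dense grid."""
    grid = np.linspace(0.0, 2 * np.pi, 20001)
    return float(grid[np.argmax(_cycle_shape(grid))])


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic canter world.

    speed_range_mps : speeds drawn uniformly from this interval; [4, 9]
        spans the competition band (350-400 m/min is 5.8-6.7 m/s) with
        margin on both sides.
    freq_intercept_hz, freq_slope : stride frequency model
        f = 1.4 + 0.12 * v (Hz), keeping canter-plausible 1.9-2.5 Hz over
        the speed range.
    amp_intercept_g, amp_slope : dorso-ventral peak amplitude model
        a = 0.5 + 0.25 * v (g).
    accel_noise_sd_g, gyro_noise_sd_dps : white measurement noise.
    amp_jitter_rel, freq_jitter_hz : per-recording (horse/session)
        multiplicative amplitude jitter and additive frequency jitter.
    curve_fraction : probability that a recording follows the curved
        protocol (about a tenth of strides, as on a jumping course).
    curve_speed_fluct_rel : relative amplitude of the slow within-curve
        speed fluctuation hidden by the broadcast average label.
    ref_speed_rel_sd : relative accuracy of the straight-path reference
        (1.4% of measured distance).
    curve_timing_jitter_s : SD of the chronometer trigger error on the
        curve transit time.
    """

    speed_range_mps: tuple[float, float] = (4.0, 9.0)
    freq_intercept_hz: float = 1.4
    freq_slope: float = 0.12
    amp_intercept_g: float = 0.5
    amp_slope: float = 0.25
    accel_noise_sd_g: float = 0.05
    gyro_noise_sd_dps: float = 5.0
    gravity_g: float = 1.0
    sample_rate_hz: float = 100.0
    curve_fraction: float = 0.1
    amp_jitter_rel: float = 0.05
    freq_jitter_hz: float = 0.03
    curve_speed_fluct_rel: float = 0.02
    ref_speed_rel_sd: float = 0.014
    curve_timing_jitter_s: float = 0.05
    straight_duration_s: float = 5.0
    curve_duration_s: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.speed_range_mps
        if not 0 < lo < hi:
            raise ValueError(f"speed range must be positive, got {self.speed_range_mps}")
        for v in (lo, hi):
            f = self.freq_intercept_hz + self.freq_slope * v
            if not 0.5 < f < 4.0:
                raise ValueError(f"stride frequency {f:.2f} Hz at {v} m/s "
                                 "outside the plausible (0.5, 4) Hz band")
        if self.accel_noise_sd_g < 0 or self.gyro_noise_sd_dps < 0:
            raise ValueError("noise SDs must be >= 0")

    def stride_freq_hz(self, speed_mps) -> np.ndarray:
        return self.freq_intercept_hz + self.freq_slope * np.asarray(speed_mps)

    def amplitude_g(self, speed_mps) -> np.ndarray:
        return self.amp_intercept_g + self.amp_slope * np.asarray(speed_mps)


def simulate_canter(
    speed_mps: float,
    duration_s: float,
    cfg: SimulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
    fluct_rel: float = 0.0,
    amp_scale: float = 1.0,
    freq_offset_hz: float = 0.0,
) -> tuple[ImuRecording, dict]:
    """Simulate one canter recording at a commanded speed.

    Returns the recording and a ground-truth dict with the true Z-axis
    oscillation peak samples (restricted to peaks usable as full-window
    anchors), the instantaneous true speed at each peak, and the nominal
    stride frequency.  ``fluct_rel`` adds a slow sinusoidal speed
    fluctuation over the recording (used by the curve protocol);
    ``amp_scale`` and ``freq_offset_hz`` carry per-recording jitter.
    Identical seeds give identical recordings.
    """
    cfg = cfg or SimulationConfig()
    if duration_s <= 0:
        raise ValueError(f"duration must be > 0, got {duration_s}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = cfg.sample_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    v_t = speed_mps * (1.0 + fluct_rel * np.sin(2 * np.pi * t / duration_s))
    f_t = cfg.stride_freq_hz(v_t) + freq_offset_hz
    a_t = cfg.amplitude_g(v_t) * amp_scale
    phi = 2 * np.pi * cumulative_trapezoid(f_t, t, initial=0.0)

    az = cfg.gravity_g + a_t * _cycle_shape(phi)
    ax = a_t * (0.35 * np.sin(phi + 1.1) + 0.15 * np.sin(2 * phi + 0.3))
    ay = a_t * 0.25 * np.sin(phi + 2.3)
    gyro_amp = 10.0 + 4.0 * v_t
    gx = gyro_amp * np.sin(phi + 0.5)
    gy = 0.8 * gyro_amp * np.sin(2 * phi + 1.7)
    gz = 1.2 * gyro_amp * np.sin(phi + 2.9)

    accel = np.column_stack([ax, ay, az])
    gyro = np.column_stack([gx, gy, gz])
    if cfg.accel_noise_sd_g > 0:
        accel = accel + rng.normal(0.0, cfg.accel_noise_sd_g, accel.shape)
    if cfg.gyro_noise_sd_dps > 0:
        gyro = gyro + rng.normal(0.0, cfg.gyro_noise_sd_dps, gyro.shape)

    # true peak times: the cycle shape is a fixed function of phase, so
    # peaks sit exactly where phi crosses the shape's argmax (mod 2*pi)
    phi_star = _peak_phase()
    k_max = int(np.floor((phi[-1] - phi_star) / (2 * np.pi)))
    peak_phases = phi_star + 2 * np.pi * np.arange(k_max + 1)
    peak_phases = peak_phases[peak_phases >= phi[0]]
    t_peaks = np.interp(peak_phases, phi, t)
    idx = np.round(t_peaks * fs).astype(int)
    usable = (idx >= 1) & (idx + 100 < n)
    truth = {
        "peak_indices": idx[usable],
        "peak_speeds": np.interp(t_peaks[usable], t, v_t),
        "stride_freq_hz": float(cfg.stride_freq_hz(speed_mps) + freq_offset_hz),
    }
    rec = ImuRecording(
        sample_rate_hz=fs, accel=accel, gyro=gyro,
        meta={"speed_mps": speed_mps, "synthetic": True},
    )
    return rec, truth


def simulate_dataset(
    n_strides: int,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    seg_cfg: SegmentationConfig | None = None,
) -> StrideDataset:
    """Simulate a labelled stride dataset through the real pipeline.

    Recordings are drawn one at a time (speed uniform over the configured
    range, per-recording amplitude/frequency jitter, one of ten horse
    ids), segmented with :func:`detect_stride_peaks` /
    :func:`extract_windows`, and labelled per protocol: straight-path
    windows get their true per-stride speed, curve groups get the group
    average broadcast to all member strides.  The hidden per-stride truth
    is kept in the ``true_speed_mps`` meta column; ``group`` identifies
    the source recording.
    """
    cfg = cfg or SimulationConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    rng = np.random.default_rng(seed)
    windows, speeds, meta_rows = [], [], []
    group = 0
    attempts = 0
    while len(windows) < n_strides:
        attempts += 1
        if attempts > 50 * max(1, n_strides):
            raise RuntimeError(
                "configuration yields no detectable strides "
                "(check prominence vs amplitude model)"
            )
        curved = rng.random() < cfg.curve_fraction
        lo, hi = cfg.speed_range_mps
        if curved:
            # keep within-curve fluctuation (and hence the broadcast
            # average) inside the configured speed range by construction
            f = cfg.curve_speed_fluct_rel
            v0 = rng.uniform(lo / (1.0 - f), hi / (1.0 + f))
        else:
            v0 = rng.uniform(lo, hi)
        amp_scale = max(0.5, 1.0 + rng.normal(0.0, cfg.amp_jitter_rel))
        freq_offset = rng.normal(0.0, cfg.freq_jitter_hz)
        duration = cfg.curve_duration_s if curved else cfg.straight_duration_s
        fluct = cfg.curve_speed_fluct_rel if curved else 0.0
        rec, truth = simulate_canter(
            v0, duration, cfg, seed=rng, fluct_rel=fluct,
            amp_scale=amp_scale, freq_offset_hz=freq_offset,
        )
        peaks = detect_stride_peaks(rec, seg_cfg)
        if len(peaks) == 0:
            continue
        wins = extract_windows(rec, peaks, seg_cfg)
        # true speed at each detected anchor: nearest ground-truth peak
        true_v = np.array(
            [truth["peak_speeds"][np.argmin(np.abs(truth["peak_indices"] - p))]
             for p in peaks]
        )
        ref = np.full(len(wins), float(np.mean(true_v))) if curved else true_v
        horse = f"h{rng.integers(0, 10):02d}"
        src = "curved" if curved else "straight"
        windows.extend(wins)
        speeds.extend(ref)
        meta_rows.extend(
            {"horse_id": horse, "source": src, "group": group,
             "true_speed_mps": tv} for tv in true_v
        )
        group += 1
    meta = pd.DataFrame(meta_rows[:n_strides])
    return StrideDataset(
        windows=windows[:n_strides],
        speeds=np.asarray(speeds[:n_strides]),
        meta=meta,
    )


def reference_absolute_error(distance_m: float, rel_accuracy: float = 0.014) -> float:
    """Absolute distance error (m) of the straight-path reference system:
    its accuracy is a fixed fraction (1.4%) of the measured distance."""
    if distance_m <= 0:
        raise ValueError("distance must be > 0")
    return rel_accuracy * distance_m


def reference_error_injection(
    dataset: StrideDataset,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
) -> StrideDataset:
    """Perturb reference speeds with the reference systems' error models.

    Straight-path speeds are multiplied by ``1 + e`` with
    ``e ~ N(0, ref_speed_rel_sd**2)`` (camera system, 1.4% of distance);
    curved-path groups share one timing perturbation: the average speed is
    rescaled by ``T / (T + dt)`` with ``dt ~ N(0, curve_timing_jitter_s**2)``
    and ``T`` the curve transit time, the same factor for every stride of
    the group.  With both error scales at zero the dataset is unchanged.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    speeds = dataset.speeds.copy()
    src = dataset.meta["source"].to_numpy()
    straight = src == "straight"
    if cfg.ref_speed_rel_sd > 0 and straight.any():
        speeds[straight] *= 1.0 + rng.normal(0.0, cfg.ref_speed_rel_sd,
                                             straight.sum())
    curved = ~straight
    if cfg.curve_timing_jitter_s > 0 and curved.any():
        groups = (dataset.meta["group"].to_numpy() if "group" in dataset.meta
                  else np.zeros(len(dataset), dtype=int))
        T = cfg.curve_duration_s
        for g in np.unique(groups[curved]):
            dt = rng.normal(0.0, cfg.curve_timing_jitter_s)
            sel = curved & (groups == g)
            speeds[sel] *= T / (T + dt)
    return StrideDataset(
        windows=list(dataset.windows), speeds=speeds, meta=dataset.meta.copy()
    )
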