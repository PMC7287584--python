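"""Synthetic 3-min walk generator with ground-truth gait events.

Emulates the measurement setup of a laboratory over-ground walking protocol:
a summed force-plate array sampled at 1000 Hz, plus a waist-worn and an
ankle-worn IMU at 400 Hz, all sharing one time base and carrying a 1.5 V
square sync pulse at the end of the recording.  Right-foot stride durations
follow a stationary AR(1) process (default white: mean 1040 ms, SD 19.6 ms,
the stride statistics of healthy community-dwelling older adults), and every
emitted signal is consistent with the returned ground-truth event times, so
detector recovery can be scored exactly.

Signal construction, briefly:

* vertical force — a 0.75×BW support baseline plus two raised-cosine humps
  per step and a sharp ~30 ms transient starting exactly at each heel-strike.
  The transient rides on the first hump so their supra-threshold run merges
  and peaks within ~5 ms of the heel-strike, placing the maximal jerk at the
  true event; the second hump forms a separate low-jerk run.  Hump areas are
  chosen so the time-averaged vertical force ≈ body weight.
* waist IMU — earth-frame vertical acceleration is a smooth per-step
  oscillation plus a sharp positive peak at each heel-strike (both feet);
  the sensor frame is tilted about the x axis with a slow sinusoidal sway,
  the gyroscope carries the exact angular rate of that motion, and specific
  force includes gravity.
* ankle IMU — the sagittal (y) gyro channel shows a large positive mid-swing
  lobe per right stride with sharp negative troughs exactly at heel-strike
  and toe-off; remaining channels are gravity plus small noise.

Same seed ⇒ bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .signal_io import (
    STANDARD_GRAVITY,
    ForcePlateRecording,
    ImuRecording,
    write_forceplate,
    write_imu,
)

__all__ = [
    "GaitSimParams",
    "GroundTruth",
    "generate_stride_plan",
    "synthesize_forceplate",
    "synthesize_waist_imu",
    "synthesize_ankle_imu",
    "earth_vertical_acceleration",
    "simulate_session",
    "write_session",
]

# step-profile shape constants (fractions of step duration; amplitudes in BW)
_BASELINE_BW = 0.75
_HUMP_AMP_BW = 0.45
_HUMP1_CENTER, _HUMP1_WIDTH = 0.13, 0.45
_HUMP2_CENTER, _HUMP2_WIDTH = 0.60, 0.66
_TRANSIENT_RISE_S = 0.005          # u·e^(1-u) impact shape, u = t/rise
_TRANSIENT_SUPPORT_S = 0.030

_WAIST_OSC_G = 0.12                # per-step smooth oscillation amplitude
_WAIST_PEAK_G = 0.35               # heel-strike peak amplitude
_WAIST_PEAK_SIGMA_S = 0.010
_WAIST_SWAY_DEG = 2.0
_WAIST_SWAY_HZ = 0.25

_ANKLE_SWING_DPS = 300.0           # mid-swing lobe height
_ANKLE_TROUGH_DPS = 120.0          # event trough depth
_ANKLE_TROUGH_SIGMA_S = 0.012

_SYNC_LEAD_S = 0.3                 # pulse rises this long before the end
_SYNC_VOLTS = 1.5


@dataclass(frozen=True)
class GaitSimParams:
    """Simulation conditions.

    Stride-duration defaults reproduce the target cohort: mean 1040 ms with
    19.6 ms stationary SD, white by default (``ar1_phi=0``; the AR
    coefficient is exposed to probe entropy sensitivity to temporal
    structure).  ``duty_factor`` is the stance fraction of the stride per
    foot; ``transient_amp_N`` is the heel-strike impact height added to the
    vertical force.
    """

    mean_stride_ms: float = 1040.0
    stride_sd_ms: float = 19.6
    ar1_phi: float = 0.0
    duration_s: float = 180.0
    body_mass_kg: float = 70.0
    duty_factor: float = 0.62
    transient_amp_N: float = 350.0
    noise_force_N: float = 5.0
    noise_acc_g: float = 0.02
    waist_tilt_deg: float = 8.0
    seed: int = 0
    force_rate_hz: float = 1000.0
    imu_rate_hz: float = 400.0
    right_fy_positive: bool = True
    imu_clock_offset_s: float = 0.0
    sync_pulse: bool = True

    def __post_init__(self) -> None:
        if self.mean_stride_ms <= 0:
            raise ValueError("mean_stride_ms must be positive")
        if self.stride_sd_ms < 0:
            raise ValueError("stride_sd_ms must be non-negative")
        if not -1 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        if not 0.5 < self.duty_factor < 0.75:
            raise ValueError("duty_factor must lie in (0.5, 0.75)")
        if self.duration_s < 0 or self.body_mass_kg <= 0:
            raise ValueError("invalid duration or body mass")

    @property
    def body_weight_N(self) -> float:
        return self.body_mass_kg * STANDARD_GRAVITY


@dataclass
class GroundTruth:
    """True event times (s, sorted) and right-stride durations (ms)."""

    right_hs: np.ndarray
    left_hs: np.ndarray
    right_to: np.ndarray
    left_to: np.ndarray
    stride_durations_ms: np.ndarray

    def all_heelstrikes(self) -> np.ndarray:
        return np.sort(np.concatenate([self.right_hs, self.left_hs]))

    def to_dict(self) -> dict:
        return {
            "right_hs": self.right_hs.tolist(),
            "left_hs": self.left_hs.tolist(),
            "right_to": self.right_to.tolist(),
            "left_to": self.left_to.tolist(),
            "stride_durations_ms": self.stride_durations_ms.tolist(),
        }


def _rng(params: GaitSimParams, stream: int) -> np.random.Generator:
    # independent, reproducible stream per signal
    return np.random.default_rng(np.random.SeedSequence([int(params.seed), stream]))


def generate_stride_plan(params: GaitSimParams) -> GroundTruth:
    """Draw the right-foot stride plan and derive all event times.

    Durations follow d_k = μ + φ(d_{k−1} − μ) + ε_k with
    ε ~ N(0, σ²(1−φ²)), so the stationary SD equals ``stride_sd_ms``.  Left
    heel-strikes trail the right by half a stride (± small timing jitter);
    toe-offs fall ``duty_factor`` × stride after the same-foot heel-strike.
    """
    rng = _rng(params, 0)
    mu = params.mean_stride_ms / 1000.0
    sigma = params.stride_sd_ms / 1000.0
    phi = params.ar1_phi
    t_start = 0.5
    t_end = params.duration_s - max(_SYNC_LEAD_S, 0.5) - 0.2

    durations: list[float] = []
    right_hs = [t_start]
    d_prev = mu
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    while True:
        d = mu + phi * (d_prev - mu) + rng.normal(0.0, innov_sd) if sigma > 0 else mu
        d = max(d, 0.3 * mu)  # guard against absurd draws at extreme SDs
        if right_hs[-1] + d > t_end:
            break
        durations.append(d)
        right_hs.append(right_hs[-1] + d)
        d_prev = d

    right_hs = np.array(right_hs)
    durations_arr = np.array(durations)
    if len(durations_arr) == 0:
        empty = np.empty(0)
        return GroundTruth(right_hs[:0], empty, empty, empty, empty)

    jitter = rng.normal(0.0, 0.005, size=len(durations_arr))
    left_hs = right_hs[:-1] + (0.5 + jitter) * durations_arr
    right_to = right_hs[:-1] + params.duty_factor * durations_arr
    left_to = left_hs + params.duty_factor * durations_arr
    left_to = left_to[left_to < t_end]

    return GroundTruth(
        right_hs=right_hs,
        left_hs=np.sort(left_hs),
        right_to=np.sort(right_to),
        left_to=np.sort(left_to),
        stride_durations_ms=np.diff(right_hs) * 1000.0,
    )


def _steps(truth: GroundTruth) -> np.ndarray:
    """Successive heel-strike times of both feet (step boundaries)."""
    return truth.all_heelstrikes()


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    out = np.zeros_like(t)
    lo, hi = center - width / 2.0, center + width / 2.0
    m = (t > lo) & (t < hi)
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t[m] - center) / width))
    return out


def _transient(t: np.ndarray, onset: float, amp: float) -> np.ndarray:
    """Impact transient A·u·e^(1−u) starting exactly at ``onset``."""
    out = np.zeros_like(t)
    m = (t >= onset) & (t < onset + _TRANSIENT_SUPPORT_S)
    u = (t[m] - onset) / _TRANSIENT_RISE_S
    out[m] = amp * u * np.exp(1.0 - u)
    return out


def _aux_channel(t: np.ndarray, duration_s: float, enabled: bool) -> np.ndarray | None:
    if not enabled or len(t) == 0:
        return None
    aux = np.zeros_like(t)
    aux[t >= duration_s - _SYNC_LEAD_S] = _SYNC_VOLTS
    return aux


def synthesize_forceplate(truth: GroundTruth, params: GaitSimParams) -> ForcePlateRecording:
    """Summed 3-D ground reaction force at ``force_rate_hz``."""
    fs = params.force_rate_hz
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    bw = params.body_weight_N

    fz = np.full(n, _BASELINE_BW * bw)
    fy = np.zeros(n)
    steps = _steps(truth)
    right_sign = 1.0 if params.right_fy_positive else -1.0

    for k in range(len(steps)):
        h = steps[k]
        s_dur = steps[k + 1] - h if k + 1 < len(steps) else (steps[k] - steps[k - 1] if k > 0 else 0.5)
        lo = max(int((h - s_dur) * fs), 0)
        hi = min(int((h + 1.5 * s_dur) * fs) + 1, n)
        tw = t[lo:hi]
        fz[lo:hi] += _HUMP_AMP_BW * bw * _raised_cosine(tw, h + _HUMP1_CENTER * s_dur, _HUMP1_WIDTH * s_dur)
        fz[lo:hi] += _HUMP_AMP_BW * bw * _raised_cosine(tw, h + _HUMP2_CENTER * s_dur, _HUMP2_WIDTH * s_dur)
        fz[lo:hi] += _transient(tw, h, params.transient_amp_N)

    # mediolateral force: per-stance lobe whose sign codes the foot,
    # front-loaded (×(1−s)) so the first 150 ms after a heel-strike are
    # dominated by the newly landed foot.
    for foot, hs_times in (("right", truth.right_hs), ("left", truth.left_hs)):
        sign = right_sign if foot == "right" else -right_sign
        for h in hs_times:
            stance = params.duty_factor * params.mean_stride_ms / 1000.0
            lo = max(int(h * fs), 0)
            hi = min(int((h + stance) * fs) + 1, n)
            if hi <= lo:
                continue
            s = (t[lo:hi] - h) / stance
            fy[lo:hi] += sign * 0.08 * bw * 2.0 * np.sin(np.pi * np.clip(s, 0, 1)) * (1.0 - np.clip(s, 0, 1))

    rng = _rng(params, 1)
    if params.noise_force_N > 0 and n:
        fz = fz + rng.normal(0.0, params.noise_force_N, n)
        fy = fy + rng.normal(0.0, params.noise_force_N, n)
        fx = rng.normal(0.0, params.noise_force_N, n)
    else:
        fx = np.zeros(n)

    return ForcePlateRecording(
        t=t, fx=fx, fy=fy, fz=fz,
        body_weight=bw, sample_rate=fs,
        aux=_aux_channel(t, params.duration_s, params.sync_pulse),
    )


def earth_vertical_acceleration(truth: GroundTruth, params: GaitSimParams, t: np.ndarray) -> np.ndarray:
    """True earth-frame vertical acceleration (g) of the waist, noise-free."""
    av = np.zeros_like(t)
    steps = _steps(truth)
    for k in range(len(steps) - 1):
        h, h2 = steps[k], steps[k + 1]
        m = (t >= h) & (t < h2)
        av[m] += _WAIST_OSC_G * np.sin(2.0 * np.pi * (t[m] - h) / (h2 - h))
    sig = _WAIST_PEAK_SIGMA_S
    for h in steps:
        m = np.abs(t - h) < 5 * sig
        av[m] += _WAIST_PEAK_G * np.exp(-0.5 * ((t[m] - h) / sig) ** 2)
    return av


def _waist_tilt(params: GaitSimParams, t: np.ndarray, walking: bool) -> tuple[np.ndarray, np.ndarray]:
    """Tilt angle about x (rad) and its rate (rad/s); sway only during gait."""
    base = np.deg2rad(params.waist_tilt_deg)
    if not walking:
        return np.full_like(t, base), np.zeros_like(t)
    w = 2.0 * np.pi * _WAIST_SWAY_HZ
    amp = np.deg2rad(_WAIST_SWAY_DEG)
    return base + amp * np.sin(w * t), amp * w * np.cos(w * t)


def synthesize_waist_imu(truth: GroundTruth, params: GaitSimParams) -> ImuRecording:
    """Waist IMU: tilted, swaying sensor observing gait vertical acceleration."""
    fs = params.imu_rate_hz
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    walking = len(truth.right_hs) > 0

    av = earth_vertical_acceleration(truth, params, t)
    theta, theta_dot = _waist_tilt(params, t, walking)

    # specific force in earth frame (g): f_e = a_e + (0,0,1)
    f_e = np.zeros((n, 3))
    f_e[:, 2] = av + 1.0
    # sensor frame: rotate earth vector by R_x(θ)^T (sensor→earth is R_x(θ))
    c, s = np.cos(theta), np.sin(theta)
    acc = np.empty((n, 3))
    acc[:, 0] = f_e[:, 0]
    acc[:, 1] = s * f_e[:, 2]
    acc[:, 2] = c * f_e[:, 2]

    gyr = np.zeros((n, 3))
    gyr[:, 0] = np.rad2deg(theta_dot)

    rng = _rng(params, 2)
    if params.noise_acc_g > 0 and n:
        acc = acc + rng.normal(0.0, params.noise_acc_g, (n, 3))
        gyr = gyr + rng.normal(0.0, 0.2, (n, 3))

    return ImuRecording(
        t=t - params.imu_clock_offset_s,
        acc=acc, gyr=gyr, placement="waist", sample_rate=fs,
        aux=_aux_channel(t, params.duration_s, params.sync_pulse),
    )


def synthesize_ankle_imu(truth: GroundTruth, params: GaitSimParams) -> ImuRecording:
    """Right-ankle IMU: sagittal gyro with mid-swing lobe and event troughs."""
    fs = params.imu_rate_hz
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    gy = np.zeros(n)

    for k in range(len(truth.right_hs) - 1):
        hs0, hs1 = truth.right_hs[k], truth.right_hs[k + 1]
        to = hs0 + params.duty_factor * (hs1 - hs0)
        swing = hs1 - to
        gy += _ANKLE_SWING_DPS * _raised_cosine(t, to + 0.5 * swing, 0.8 * swing)
    sig = _ANKLE_TROUGH_SIGMA_S
    for e in np.concatenate([truth.right_hs, truth.right_to]):
        m = np.abs(t - e) < 5 * sig
        gy[m] -= _ANKLE_TROUGH_DPS * np.exp(-0.5 * ((t[m] - e) / sig) ** 2)

    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0
    gyr = np.zeros((n, 3))
    gyr[:, 1] = gy

    rng = _rng(params, 3)
    if params.noise_acc_g > 0 and n:
        acc = acc + rng.normal(0.0, params.noise_acc_g, (n, 3))
        gyr = gyr + rng.normal(0.0, 1.0, (n, 3))

    return ImuRecording(
        t=t - params.imu_clock_offset_s,
        acc=acc, gyr=gyr, placement="ankle", sample_rate=fs,
        aux=_aux_channel(t, params.duration_s, params.sync_pulse),
    )


def simulate_session(
    params: GaitSimParams,
) -> tuple[ForcePlateRecording, ImuRecording, ImuRecording, GroundTruth]:
    """One synchronized walk: (force plate, waist IMU, ankle IMU, truth)."""
    truth = generate_stride_plan(params)
    return (
        synthesize_forceplate(truth, params),
        synthesize_waist_imu(truth, params),
        synthesize_ankle_imu(truth, params),
        truth,
    )


def write_session(out_dir: str | Path, params: GaitSimParams) -> dict[str, Path]:
    """Simulate and write force.csv, waist.csv, ankle.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    force, waist, ankle, truth = simulate_session(params)
    paths = {
        "force": out / "force.csv",
        "waist": out / "waist.csv",
        "ankle": out / "ankle.csv",
        "truth": out / "truth.json",
    }
    write_forceplate(paths["force"], force)
    write_imu(paths["waist"], waist)
    write_imu(paths["ankle"], ankle)
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    return paths
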