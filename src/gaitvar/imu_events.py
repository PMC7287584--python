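"""Gait-event detection from IMU-derived signals.

Waist: the earth-frame vertical acceleration is convolved with a 16 Hz
Ricker (Mexican hat) wavelet — a matched filter for the heel-strike impact
transient — then low-pass filtered with a 4th-order zero-lag 6 Hz
Butterworth (2nd order run forward and backward).  Local maxima with a
prominence above 0.5 × the 80th percentile of all maxima prominences mark
heel-strikes of either foot.

Ankle: mid-swing positive peaks of the sagittal angular velocity anchor a
search for the deepest trough after the peak (heel-strike) and before it
(toe-off); each trough is refined by the vertex of a parabola fitted around
the minimum.  Heel-strikes and toe-offs are then merged, sorted, and reduced
so the labels strictly alternate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .events import HS, TO, EventSeries
from .kinematics import ScalarSeries

__all__ = [
    "WaveletKernel",
    "ricker_kernel",
    "detect_waist_heelstrikes",
    "detect_ankle_events",
    "pair_ankle_events",
]


@dataclass
class WaveletKernel:
    """Sampled Ricker wavelet: zero-sum, symmetric about its centre."""

    samples: np.ndarray
    peak_frequency: float
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) % 2 != 1:
            raise ValueError("kernel must have odd length (symmetric about centre)")


def ricker_kernel(peak_frequency: float = 16.0, sample_rate: float = 400.0) -> WaveletKernel:
    """Ricker wavelet ψ(t) = (1 − (t/σ)²)·exp(−t²/(2σ²)), σ = 1/(π f √2).

    ``peak_frequency`` is the spectral peak of the wavelet (|Ψ(f)| ∝
    f² exp(−(πσf)²·2) peaks at f = 1/(πσ√2)).  Sampled on ±4σ; the small
    truncation residual is removed so the kernel sums exactly to zero
    (admissibility).
    """
    if not 0 < peak_frequency < sample_rate / 2:
        raise ValueError("peak_frequency must lie in (0, sample_rate/2)")
    sigma = 1.0 / (np.pi * peak_frequency * np.sqrt(2.0))
    half = int(np.ceil(4.0 * sigma * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    u = t / sigma
    psi = (1.0 - u * u) * np.exp(-0.5 * u * u)
    psi = psi - psi.mean()
    return WaveletKernel(samples=psi, peak_frequency=peak_frequency, sample_rate=sample_rate)


def zero_lag_lowpass(x: np.ndarray, cutoff_hz: float, sample_rate: float, order: int = 2) -> np.ndarray:
    """Butterworth of ``order`` applied forward and backward (zero phase).

    Running a 2nd-order filter both ways yields the conventional
    "4th-order zero-lag" response.
    """
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_waist_heelstrikes(
    vacc: ScalarSeries,
    kernel: WaveletKernel | None = None,
    lp_cutoff: float = 6.0,
    prom_frac: float = 0.5,
    prom_pct: float = 80.0,
) -> EventSeries:
    """Heel-strikes (both feet, foot unknown) from waist vertical acceleration.

    The prominence threshold is relative (``prom_frac`` × the
    ``prom_pct``-th percentile of all local-maxima prominences), so the
    detector is invariant to amplitude scaling of the input.
    """
    if kernel is None:
        kernel = ricker_kernel(sample_rate=vacc.sample_rate)
    x = vacc.values
    if len(x) <= len(kernel.samples):
        raise ValueError("signal must be longer than the wavelet kernel")
    conv = np.convolve(x, kernel.samples, mode="same")
    filt = zero_lag_lowpass(conv, lp_cutoff, vacc.sample_rate)

    maxima, _ = sps.find_peaks(filt)
    if len(maxima) == 0:
        return EventSeries.from_times([], source="waist")
    prominences = sps.peak_prominences(filt, maxima)[0]
    threshold = prom_frac * float(np.percentile(prominences, prom_pct))
    keep = maxima[prominences > threshold]
    times = vacc.t0 + keep / vacc.sample_rate
    return EventSeries.from_times(times, label=HS, foot="unknown", source="waist")


def _parabolic_refine(y: np.ndarray, i: int, halfwidth: int, sample_rate: float) -> float:
    """Vertex (in samples, relative to index i) of a parabola fitted around i.

    The fit uses 2·halfwidth+1 samples; the returned shift is clamped to
    ±halfwidth so refinement never moves an event beyond its fit window.
    """
    lo = max(i - halfwidth, 0)
    hi = min(i + halfwidth + 1, len(y))
    xs = np.arange(lo, hi) - i
    if len(xs) < 3:
        return 0.0
    a, b, _ = np.polyfit(xs, y[lo:hi], 2)
    if a <= 0:
        return 0.0
    shift = -b / (2.0 * a)
    return float(np.clip(shift, -halfwidth, halfwidth))


def detect_ankle_events(
    gyro_sag: ScalarSeries,
    min_swing_dps: float = 100.0,
    parabola_halfwidth: int = 2,
    search_s: float = 0.4,
    min_separation_s: float = 0.5,
) -> EventSeries:
    """Heel-strikes and toe-offs from the sagittal angular velocity.

    Per mid-swing peak (above ``min_swing_dps``, separated by at least
    ``min_separation_s``): heel-strike = deepest minimum in
    (peak, peak + ``search_s``], toe-off = deepest minimum in
    [peak − ``search_s``, peak), each refined by a fitted parabola vertex.
    """
    y = gyro_sag.values
    fs = gyro_sag.sample_rate
    if len(y) == 0:
        return EventSeries.from_times([], source="ankle")
    dist = max(int(round(min_separation_s * fs)), 1)
    peaks, _ = sps.find_peaks(y, height=min_swing_dps, distance=dist)
    w = int(round(search_s * fs))
    times, labels = [], []
    for p in peaks:
        for label, lo, hi in ((TO, max(p - w, 0), p), (HS, p + 1, min(p + w + 1, len(y)))):
            if hi <= lo:
                continue
            i = lo + int(np.argmin(y[lo:hi]))
            shift = _parabolic_refine(y, i, parabola_halfwidth, fs)
            times.append(gyro_sag.t0 + (i + shift) / fs)
            labels.append(label)
    order = np.argsort(times)
    times = np.asarray(times)[order]
    labels = np.asarray(labels, dtype=object)[order]
    return EventSeries(times, labels, np.full(len(times), "right", dtype=object), "ankle")


def pair_ankle_events(events: EventSeries) -> EventSeries:
    """Reduce a merged HS/TO sequence so labels strictly alternate.

    Within any run of same-labelled events the earliest is kept — the
    filtering rule that discards heel-strikes not followed by a toe-off and
    toe-offs not followed by a heel-strike.
    """
    if len(events) == 0:
        return events
    keep = [0]
    for i in range(1, len(events)):
        if events.labels[i] != events.labels[keep[-1]]:
            keep.append(i)
    idx = np.asarray(keep)
    return EventSeries(events.times[idx], events.labels[idx], events.foot[idx], events.source)
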