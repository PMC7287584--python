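"""Stride series, the median-ratio inclusion filter, cross-instrument event
matching at 0.2 s, and stride-duration outcomes (mean, SD, CV%)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import HS, EventSeries

__all__ = [
    "StrideSeries",
    "GaitOutcomes",
    "build_strides",
    "median_ratio_filter",
    "match_events",
    "gait_outcomes",
]


@dataclass
class StrideSeries:
    """Stride start times (s, sorted) and durations (ms) from one instrument."""

    start_times: np.ndarray
    durations_ms: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.start_times = np.asarray(self.start_times, dtype=float)
        self.durations_ms = np.asarray(self.durations_ms, dtype=float)
        if len(self.start_times) != len(self.durations_ms):
            raise ValueError("start_times and durations_ms must match in length")
        if np.any(self.durations_ms <= 0):
            raise ValueError("stride durations must be positive")

    def __len__(self) -> int:
        return len(self.start_times)


@dataclass(frozen=True)
class GaitOutcomes:
    """Stride-duration outcomes; cv_pct = sd_ms / mean_ms × 100."""

    n_strides: int
    mean_ms: float
    sd_ms: float
    cv_pct: float


def build_strides(hs, step: int = 1, source: str | None = None) -> StrideSeries:
    """Strides spanning heel-strike k → k+step.

    ``step=1`` for a single-foot series (force plate, ankle); ``step=2``
    when heel-strikes of both feet are present but unlabelled (waist), so a
    stride is the current to current + 2 heel-strike.
    """
    if step not in (1, 2):
        raise ValueError("step must be 1 or 2")
    if isinstance(hs, EventSeries):
        times = hs.select(label=HS).times
        source = source or hs.source
    else:
        times = np.sort(np.asarray(hs, dtype=float))
    source = source or "unknown"
    if len(times) < step + 1:
        return StrideSeries(np.empty(0), np.empty(0), source)
    starts = times[:-step]
    durations = (times[step:] - starts) * 1000.0
    return StrideSeries(starts, durations, source)


def median_ratio_filter(s: StrideSeries, ratio: float = 1.25) -> StrideSeries:
    """Keep strides with duration within a ``ratio`` band of the median.

    The band is two-sided multiplicative, median/ratio ≤ d ≤ median×ratio,
    with the median of all candidate durations computed once (not iterated).
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if len(s) == 0:
        return s
    med = float(np.median(s.durations_ms))
    keep = (s.durations_ms >= med / ratio) & (s.durations_ms <= med * ratio)
    return StrideSeries(s.start_times[keep], s.durations_ms[keep], s.source)


def match_events(
    reference: EventSeries | np.ndarray,
    candidate: EventSeries | np.ndarray,
    tol_s: float = 0.2,
) -> list[tuple[float, float]]:
    """Greedy one-to-one nearest-neighbour matching within ``tol_s``.

    Reference events are visited in time order; each takes the nearest
    still-unused candidate if within tolerance.  With events separated by
    more than twice the tolerance (the gait regime, tolerance 0.2 s against
    step times > 0.4 s) this equals the optimal assignment.
    """
    ref = reference.times if isinstance(reference, EventSeries) else np.asarray(reference, float)
    cand = candidate.times if isinstance(candidate, EventSeries) else np.asarray(candidate, float)
    used = np.zeros(len(cand), dtype=bool)
    pairs: list[tuple[float, float]] = []
    for r in ref:
        free = np.flatnonzero(~used)
        if len(free) == 0:
            break
        j = free[int(np.argmin(np.abs(cand[free] - r)))]
        if abs(cand[j] - r) <= tol_s:
            used[j] = True
            pairs.append((float(r), float(cand[j])))
    return pairs


def gait_outcomes(s: StrideSeries) -> GaitOutcomes:
    """Mean, sample SD (n−1) and CV% of the stride durations.

    With fewer than two strides the SD (and CV) are undefined and returned
    as NaN with a warning.
    """
    n = len(s)
    if n == 0:
        warnings.warn("no strides: outcomes undefined", stacklevel=2)
        return GaitOutcomes(0, float("nan"), float("nan"), float("nan"))
    mean = float(np.mean(s.durations_ms))
    if n < 2:
        warnings.warn("fewer than 2 strides: SD undefined", stacklevel=2)
        return GaitOutcomes(n, mean, float("nan"), float("nan"))
    sd = float(np.std(s.durations_ms, ddof=1))
    return GaitOutcomes(n, mean, sd, sd / mean * 100.0)
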