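"""Heel-strike detection from the summed vertical ground reaction force.

The chain: (1) find all continuous runs of at least 2.5 ms above 1.1 × body
weight in the vertical force; (2) within a 50 ms window backwards from each
run's force maximum, take the peak positive jerk (first time derivative of
force) as a heel-strike candidate; (3) drop candidates whose jerk falls below
0.3 × the mean of the 50 highest candidate jerks; (4) assign the foot from
the sign of the mediolateral force just after the candidate instant; (5)
right-foot heel-strike to next right-foot heel-strike defines a stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .events import HS, EventSeries
from .signal_io import ForcePlateRecording
from .strides import StrideSeries, build_strides

__all__ = [
    "HeelStrikeCandidate",
    "detect_force_peaks",
    "jerk_candidates",
    "filter_false_candidates",
    "assign_foot",
    "right_strides",
    "detect_force_heelstrikes",
]

logger = logging.getLogger(__name__)

#: candidates closer than this keep only the higher jerk — below any
#: plausible step time, so the two force humps of one stance cannot both
#: survive as heel-strikes.
DEDUP_GAP_S = 0.25


@dataclass(frozen=True)
class HeelStrikeCandidate:
    """Peak positive jerk within the search window of one force run."""

    time: float
    jerk: float
    source_peak_time: float

    def __post_init__(self) -> None:
        if self.time > self.source_peak_time:
            raise ValueError("candidate cannot postdate its source peak")


def detect_force_peaks(
    rec: ForcePlateRecording,
    min_above_ms: float = 2.5,
    bw_factor: float = 1.1,
) -> list[tuple[tuple[int, int], float]]:
    """Maximal runs of fz above ``bw_factor`` × BW lasting ≥ ``min_above_ms``.

    Returns ``((i_start, i_stop), peak_time)`` per run with i_stop exclusive
    and ``peak_time`` the time of the run's force maximum.
    """
    thr = bw_factor * rec.body_weight
    above = rec.fz > thr
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))
    min_samples = min_above_ms / 1000.0 * rec.sample_rate
    out = []
    for i0, i1 in zip(starts, stops):
        if i1 - i0 >= min_samples:
            peak = i0 + int(np.argmax(rec.fz[i0:i1]))
            out.append(((i0, i1), float(rec.t[peak])))
    return out


def _jerk(rec: ForcePlateRecording) -> np.ndarray:
    """First time derivative of fz, central difference (one-sided at edges)."""
    return np.gradient(rec.fz, rec.t)


def jerk_candidates(
    rec: ForcePlateRecording,
    peaks: list[tuple[tuple[int, int], float]],
    window_ms: float = 50.0,
) -> list[HeelStrikeCandidate]:
    """Heel-strike candidate per run: argmax jerk in [peak − window, peak].

    Windows reaching before the recording start are truncated.  Candidates
    within :data:`DEDUP_GAP_S` of a higher-jerk candidate are dropped, so the
    two force humps of one stance yield at most one heel-strike.
    """
    if not peaks:
        return []
    jerk = _jerk(rec)
    w = int(round(window_ms / 1000.0 * rec.sample_rate))
    cands: list[HeelStrikeCandidate] = []
    for (_, _), peak_time in peaks:
        ip = int(round((peak_time - rec.t[0]) * rec.sample_rate))
        lo = max(ip - w, 0)
        seg = jerk[lo : ip + 1]
        if len(seg) == 0:
            continue
        i = lo + int(np.argmax(seg))
        cands.append(HeelStrikeCandidate(float(rec.t[i]), float(jerk[i]), peak_time))

    # de-duplicate: exact-time duplicates, then the 250 ms higher-jerk rule
    cands = list({c.time: c for c in sorted(cands, key=lambda c: c.jerk)}.values())
    kept: list[HeelStrikeCandidate] = []
    for c in sorted(cands, key=lambda c: -c.jerk):
        if all(abs(c.time - k.time) >= DEDUP_GAP_S for k in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: c.time)


def filter_false_candidates(
    cands: list[HeelStrikeCandidate],
    frac: float = 0.3,
    top_n: int = 50,
) -> list[HeelStrikeCandidate]:
    """Drop candidates with jerk below ``frac`` × mean of the ``top_n`` highest."""
    if not cands:
        return []
    jerks = np.sort([c.jerk for c in cands])[::-1]
    threshold = frac * float(np.mean(jerks[:top_n]))
    return [c for c in cands if c.jerk >= threshold]


def assign_foot(
    rec: ForcePlateRecording,
    cands: list[HeelStrikeCandidate],
    window_ms: float = 150.0,
    right_fy_positive: bool = True,
) -> EventSeries:
    """Label each candidate right/left from mean fy after the instant.

    Convention: positive mean mediolateral force over [t, t + window] marks a
    right-foot strike (configurable).  Zero mean falls back to 'left'.  A
    warning is logged when successive labels fail to alternate.
    """
    w = int(round(window_ms / 1000.0 * rec.sample_rate))
    times, feet = [], []
    for c in sorted(cands, key=lambda c: c.time):
        i = int(round((c.time - rec.t[0]) * rec.sample_rate))
        seg = rec.fy[i : i + w + 1]
        mean_fy = float(np.mean(seg)) if len(seg) else 0.0
        if not right_fy_positive:
            mean_fy = -mean_fy
        times.append(c.time)
        feet.append("right" if mean_fy > 0 else "left")
    violations = sum(1 for a, b in zip(feet, feet[1:]) if a == b)
    if violations:
        logger.warning("foot assignment: %d alternation violation(s) in %d events",
                       violations, len(feet))
    return EventSeries(
        times=np.asarray(times),
        labels=np.full(len(times), HS, dtype=object),
        foot=np.asarray(feet, dtype=object),
        source="force",
    )


def right_strides(events: EventSeries) -> StrideSeries:
    """Right heel-strike to next right heel-strike; empty if fewer than two.

    The result is a raw candidate series: apply the median-ratio filter
    before reporting outcomes.
    """
    rhs = events.select(label=HS, foot="right")
    return build_strides(rhs, step=1, source="force")


def detect_force_heelstrikes(
    rec: ForcePlateRecording,
    min_above_ms: float = 2.5,
    bw_factor: float = 1.1,
    window_ms: float = 50.0,
    frac: float = 0.3,
    top_n: int = 50,
    right_fy_positive: bool = True,
) -> EventSeries:
    """Full force-plate chain: runs → jerk candidates → jerk filter → feet."""
    peaks = detect_force_peaks(rec, min_above_ms=min_above_ms, bw_factor=bw_factor)
    cands = jerk_candidates(rec, peaks, window_ms=window_ms)
    cands = filter_false_candidates(cands, frac=frac, top_n=top_n)
    return assign_foot(rec, cands, right_fy_positive=right_fy_positive)
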