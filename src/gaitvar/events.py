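"""Sorted, labelled gait-event series shared by all detectors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HS", "TO", "EventSeries"]

HS = "HS"
TO = "TO"

_FEET = ("right", "left", "unknown")


@dataclass
class EventSeries:
    """Gait events: heel-strikes / toe-offs with foot side and origin.

    times are strictly increasing seconds; ``labels`` and ``foot`` are
    parallel arrays; ``source`` records the detecting instrument
    (``force``, ``waist`` or ``ankle``).
    """

    times: np.ndarray
    labels: np.ndarray
    foot: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.foot = np.asarray(self.foot, dtype=object)
        if not (len(self.times) == len(self.labels) == len(self.foot)):
            raise ValueError("times, labels and foot must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        bad = set(self.foot) - set(_FEET)
        if bad:
            raise ValueError(f"unknown foot value(s): {bad}")
        bad = set(self.labels) - {HS, TO}
        if bad:
            raise ValueError(f"unknown label(s): {bad}")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_times(
        cls,
        times,
        label: str = HS,
        foot: str = "unknown",
        source: str = "unknown",
    ) -> "EventSeries":
        times = np.asarray(times, dtype=float)
        return cls(
            times=times,
            labels=np.full(len(times), label, dtype=object),
            foot=np.full(len(times), foot, dtype=object),
            source=source,
        )

    def select(self, label: str | None = None, foot: str | None = None) -> "EventSeries":
        mask = np.ones(len(self), dtype=bool)
        if label is not None:
            mask &= self.labels == label
        if foot is not None:
            mask &= self.foot == foot
        return EventSeries(self.times[mask], self.labels[mask], self.foot[mask], self.source)

    def shifted(self, dt: float) -> "EventSeries":
        return EventSeries(self.times + dt, self.labels.copy(), self.foot.copy(), self.source)
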