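"""Recording containers, CSV round-trip I/O, and sync-pulse alignment.

Force-plate and IMU streams recorded concurrently are stored in a plain CSV
layout (one row per sample) and synchronised through the square pulse applied
to each device's auxiliary channel at the end of a recording.

CSV layouts
-----------
force plate : ``t,fx,fy,fz[,aux]`` — time in s, forces in N, aux in V
IMU         : ``t,ax,ay,az,gx,gy,gz[,mx,my,mz][,aux]`` — accelerometer in g,
              gyroscope in °/s, magnetometer in μT, aux in V
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_GRAVITY",
    "ForcePlateRecording",
    "ImuRecording",
    "SyncAlignment",
    "FormatError",
    "DataError",
    "SyncError",
    "read_forceplate",
    "write_forceplate",
    "read_imu",
    "write_imu",
    "align_by_sync_pulse",
]

STANDARD_GRAVITY = 9.81  # N per kg


class FormatError(ValueError):
    """File does not follow the documented CSV layout."""


class DataError(ValueError):
    """File parsed but the data violate a recording invariant."""


class SyncError(ValueError):
    """Auxiliary channel does not contain exactly one usable sync edge."""


def _as_1d(x) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=float))


@dataclass
class ForcePlateRecording:
    """Summed 3-D ground reaction force of the whole plate array.

    Parameters
    ----------
    t : array of float
        Sample times, seconds, uniformly spaced.
    fx, fy, fz : array of float
        Horizontal (fx anteroposterior, fy mediolateral) and vertical force
        in newtons, summed over all plates.
    body_weight : float
        Participant body weight in newtons (> 0).
    sample_rate : float
        Sampling rate in Hz.
    aux : array of float, optional
        Auxiliary sync channel in volts.
    """

    t: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    body_weight: float
    sample_rate: float = 1000.0
    aux: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = _as_1d(self.t)
        self.fx = _as_1d(self.fx)
        self.fy = _as_1d(self.fy)
        self.fz = _as_1d(self.fz)
        if self.aux is not None:
            self.aux = _as_1d(self.aux)
        n = len(self.t)
        for name in ("fx", "fy", "fz", "aux"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise DataError(f"channel {name!r} length {len(ch)} != {n}")
        if self.sample_rate <= 0:
            raise DataError("sample_rate must be positive")
        if not self.body_weight > 0:
            raise DataError("body_weight must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ImuRecording:
    """Inertial measurement unit streams (waist- or ankle-worn).

    acc is specific force in g (±16 g range device), gyr angular velocity in
    °/s (±2000 °/s), both shaped (n, 3); the magnetometer, when present, is
    stored on the same time grid in μT.
    """

    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    placement: str
    sample_rate: float = 400.0
    mag: np.ndarray | None = None
    aux: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = _as_1d(self.t)
        self.acc = np.ascontiguousarray(np.asarray(self.acc, dtype=float))
        self.gyr = np.ascontiguousarray(np.asarray(self.gyr, dtype=float))
        if self.mag is not None:
            self.mag = np.ascontiguousarray(np.asarray(self.mag, dtype=float))
        if self.aux is not None:
            self.aux = _as_1d(self.aux)
        if self.placement not in ("waist", "ankle"):
            raise DataError(f"placement must be 'waist' or 'ankle', got {self.placement!r}")
        n = len(self.t)
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise DataError("acc and gyr must both be shaped (n, 3) and match t")
        if self.aux is not None and len(self.aux) != n:
            raise DataError("aux length mismatch")
        if self.sample_rate <= 0:
            raise DataError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SyncAlignment:
    """Offset (s) to add to device B's time base so sync edges coincide."""

    offset: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.offset):
            raise SyncError("alignment offset is not finite")


def _check_uniform_time(t: np.ndarray, context: str) -> float:
    """Validate monotonicity/uniformity; return the sampling rate inferred from t."""
    if len(t) < 2:
        return float("nan")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{context}: time stamps are not strictly increasing")
    period = float(np.median(dt))
    jitter = float(np.max(np.abs(dt - period)))
    if jitter >= 0.5 * period:
        raise DataError(f"{context}: timestamp jitter {jitter:.2e}s exceeds half a sample period")
    return 1.0 / period


def read_forceplate(path: str | Path, body_mass: float) -> ForcePlateRecording:
    """Read a force-plate CSV; body weight is body_mass (kg) × 9.81 N/kg."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    df = pd.read_csv(path)
    required = ["t", "fx", "fy", "fz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["t"].to_numpy(float)
    rate = _check_uniform_time(t, str(path))
    aux = df["aux"].to_numpy(float) if "aux" in df.columns else None
    return ForcePlateRecording(
        t=t,
        fx=df["fx"].to_numpy(float),
        fy=df["fy"].to_numpy(float),
        fz=df["fz"].to_numpy(float),
        body_weight=body_mass * STANDARD_GRAVITY,
        sample_rate=rate if np.isfinite(rate) else 1000.0,
        aux=aux,
    )


def write_forceplate(path: str | Path, rec: ForcePlateRecording) -> None:
    cols = {"t": rec.t, "fx": rec.fx, "fy": rec.fy, "fz": rec.fz}
    if rec.aux is not None:
        cols["aux"] = rec.aux
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


_IMU_COLS = ["ax", "ay", "az", "gx", "gy", "gz"]
_MAG_COLS = ["mx", "my", "mz"]


def read_imu(path: str | Path, placement: str) -> ImuRecording:
    """Read an IMU CSV (units preserved: g, °/s, μT)."""
    df = pd.read_csv(path)
    missing = [c for c in ["t"] + _IMU_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["t"].to_numpy(float)
    rate = _check_uniform_time(t, str(path))
    mag = None
    if all(c in df.columns for c in _MAG_COLS):
        mag = df[_MAG_COLS].to_numpy(float)
    aux = df["aux"].to_numpy(float) if "aux" in df.columns else None
    return ImuRecording(
        t=t,
        acc=df[["ax", "ay", "az"]].to_numpy(float),
        gyr=df[["gx", "gy", "gz"]].to_numpy(float),
        placement=placement,
        sample_rate=rate if np.isfinite(rate) else 400.0,
        mag=mag,
        aux=aux,
    )


def write_imu(path: str | Path, rec: ImuRecording) -> None:
    cols = {"t": rec.t}
    for i, c in enumerate(["ax", "ay", "az"]):
        cols[c] = rec.acc[:, i]
    for i, c in enumerate(["gx", "gy", "gz"]):
        cols[c] = rec.gyr[:, i]
    if rec.mag is not None:
        for i, c in enumerate(_MAG_COLS):
            cols[c] = rec.mag[:, i]
    if rec.aux is not None:
        cols["aux"] = rec.aux
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def _single_rising_edge(t: np.ndarray, aux: np.ndarray, threshold: float, name: str) -> float:
    """Time of the unique upward threshold crossing of the aux channel."""
    below = aux[:-1] <= threshold
    above = aux[1:] > threshold
    idx = np.flatnonzero(below & above) + 1
    if len(idx) == 0:
        raise SyncError(f"{name}: no rising sync edge crosses {threshold} V")
    if len(idx) > 1:
        raise SyncError(f"{name}: {len(idx)} rising sync edges found, expected exactly one")
    return float(t[idx[0]])


def align_by_sync_pulse(
    a: ForcePlateRecording | ImuRecording,
    b: ForcePlateRecording | ImuRecording,
    threshold: float = 0.75,
) -> SyncAlignment:
    """Offset to add to b's time base so the 1.5 V sync edges coincide.

    The edge is the first sample above ``threshold`` (no sub-sample
    interpolation: the pulse sits at the end of the recording and only the
    relative offset matters, so the error is bounded by one sample period of
    the coarser device).
    """
    if a.aux is None or b.aux is None:
        raise SyncError("both recordings need an aux channel for sync alignment")
    ta = _single_rising_edge(a.t, a.aux, threshold, "a")
    tb = _single_rising_edge(b.t, b.aux, threshold, "b")
    return SyncAlignment(offset=ta - tb)
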