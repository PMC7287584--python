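"""Refined composite multiscale entropy (RCME) and refined multiscale
permutation entropy (RMPE) of the resultant waist acceleration.

The resultant-acceleration stream of a walking bout is divided into
non-overlapping 1-minute epochs (the remainder is discarded) and each epoch
is analysed over coarseness scales τ = 1…80 — non-overlapping means of τ
samples as a pre-processing step.  "Refined composite" means the
template-match counts (RCME) or the ordinal-pattern frequencies (RMPE) are
pooled across all τ coarse-graining offsets of a scale before the final
logarithm, which stabilises the estimate at large τ where each coarse
series becomes short.

RCME uses sample entropy with template length m = 4, Chebyshev distance,
self-matches excluded, and a tolerance R = 0.3 × the SD of the un-coarsened
epoch — held fixed across scales, so the profile is invariant to affine
rescaling of the signal.  RMPE uses ordinal patterns of m = 4 consecutive
coarse-grained samples (delay 1, ties broken by index order) and reports the
Shannon entropy of the pooled pattern distribution in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
from numba import njit

from .kinematics import ScalarSeries

__all__ = [
    "EpochSet",
    "EntropyProfile",
    "split_epochs",
    "coarse_grain",
    "sample_entropy_counts",
    "rcme",
    "rmpe",
    "session_entropy",
]

DEFAULT_SCALES = tuple(range(1, 81))


@dataclass
class EpochSet:
    """Equal-length, non-overlapping epochs of one scalar stream."""

    epochs: list[ScalarSeries]
    sample_rate: float

    def __len__(self) -> int:
        return len(self.epochs)


@dataclass
class EntropyProfile:
    """Per-scale entropy values (nats); undefined scales are NaN."""

    scales: np.ndarray
    values: np.ndarray
    kind: str
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.scales) != len(self.values):
            raise ValueError("scales and values must have equal length")


def split_epochs(x: ScalarSeries, epoch_s: float = 60.0) -> EpochSet:
    """Non-overlapping epochs of ``epoch_s`` seconds; the tail is discarded."""
    n_per = int(round(epoch_s * x.sample_rate))
    n_epochs = len(x) // n_per if n_per > 0 else 0
    if n_epochs == 0:
        warnings.warn(
            f"stream of {len(x)} samples yields no full {epoch_s:g} s epoch",
            stacklevel=2,
        )
    epochs = [
        ScalarSeries(
            x.values[k * n_per : (k + 1) * n_per],
            x.sample_rate,
            x.kind,
            x.t0 + k * n_per / x.sample_rate,
        )
        for k in range(n_epochs)
    ]
    return EpochSet(epochs=epochs, sample_rate=x.sample_rate)


def coarse_grain(x: np.ndarray, tau: int, offset: int = 1) -> np.ndarray:
    """Non-overlapping means of ``tau`` samples starting at ``offset`` (1-based).

    y_j = mean(x[offset+(j−1)τ … offset+jτ−1]); length floor((N−offset+1)/τ).
    """
    x = np.asarray(x, dtype=float)
    if not 1 <= offset <= tau:
        raise ValueError("offset must lie in 1…tau")
    if len(x) < tau:
        raise ValueError("series shorter than tau")
    start = offset - 1
    n = (len(x) - start) // tau
    return x[start : start + n * tau].reshape(n, tau).mean(axis=1)


@njit(cache=True)
def _match_counts(y: np.ndarray, m: int, r: float) -> tuple[int, int]:  # pragma: no cover
    """(A, B): template-match counts for lengths m+1 and m.

    Unordered pairs i<j over the common template range of L−m start points,
    Chebyshev distance, self-matches excluded.
    """
    n = y.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            ok = True
            for u in range(m):
                if abs(y[i + u] - y[j + u]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(y[i + m] - y[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy_counts(y: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Match counts (A, B) of one series; SampEn = −ln(A/B)."""
    y = np.ascontiguousarray(y, dtype=float)
    if len(y) <= m + 1:
        return 0, 0
    return _match_counts(y, m, r)


def rcme(
    x: ScalarSeries | np.ndarray,
    m: int = 4,
    r_frac: float = 0.3,
    scales=DEFAULT_SCALES,
) -> EntropyProfile:
    """Refined composite multiscale sample entropy of one epoch.

    The tolerance R = ``r_frac`` × SD(x) is computed once from the
    un-coarsened epoch and reused at every scale; per scale the match counts
    are summed over all τ coarse-graining offsets before taking
    −ln(ΣA/ΣB).  Scales where either pooled count is zero are NaN.
    """
    values = x.values if isinstance(x, ScalarSeries) else np.asarray(x, dtype=float)
    scales = np.asarray(list(scales), dtype=int)
    if len(values) < (m + 1) * int(scales.max()):
        raise ValueError("epoch too short for the requested scales")
    r = r_frac * float(np.std(values))
    out = np.empty(len(scales))
    for si, tau in enumerate(scales):
        a_tot = 0
        b_tot = 0
        for offset in range(1, tau + 1):
            y = coarse_grain(values, int(tau), offset)
            a, b = sample_entropy_counts(y, m, r)
            a_tot += a
            b_tot += b
        out[si] = -np.log(a_tot / b_tot) if a_tot > 0 and b_tot > 0 else np.nan
    return EntropyProfile(scales=scales, values=out, kind="RCME")


def _ordinal_histogram(y: np.ndarray, m: int) -> np.ndarray:
    """Counts of the m! ordinal patterns of m consecutive samples (delay 1).

    Ties are broken by index order (the earlier sample ranks lower), via the
    Lehmer code c_i = #{j > i : y[j] < y[i]}.
    """
    k = len(y) - m + 1
    if k <= 0:
        return np.zeros(factorial(m), dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(y, m)
    code = np.zeros(k, dtype=np.int64)
    radix = 1
    for i in range(m - 2, -1, -1):
        c = (win[:, i + 1 :] < win[:, i : i + 1]).sum(axis=1)
        code += c * radix
        radix *= m - i
    return np.bincount(code, minlength=factorial(m))


def rmpe(
    x: ScalarSeries | np.ndarray,
    m: int = 4,
    scales=DEFAULT_SCALES,
    normalize: bool = False,
) -> EntropyProfile:
    """Refined multiscale permutation entropy of one epoch (nats).

    Per scale the relative ordinal-pattern frequencies are averaged over the
    τ coarse-graining offsets and the Shannon entropy of the averaged
    distribution is reported; ``normalize`` divides by ln(m!).
    """
    values = x.values if isinstance(x, ScalarSeries) else np.asarray(x, dtype=float)
    scales = np.asarray(list(scales), dtype=int)
    if len(values) < m * int(scales.max()):
        raise ValueError("epoch too short for the requested scales")
    out = np.empty(len(scales))
    n_patterns = factorial(m)
    for si, tau in enumerate(scales):
        p_bar = np.zeros(n_patterns)
        n_offsets = 0
        for offset in range(1, tau + 1):
            y = coarse_grain(values, int(tau), offset)
            counts = _ordinal_histogram(y, m)
            total = counts.sum()
            if total > 0:
                p_bar += counts / total
                n_offsets += 1
        if n_offsets == 0:
            out[si] = np.nan
            continue
        p_bar /= n_offsets
        nz = p_bar[p_bar > 0]
        h = float(-(nz * np.log(nz)).sum())
        out[si] = h / np.log(n_patterns) if normalize else h
    return EntropyProfile(scales=scales, values=out, kind="RMPE")


def session_entropy(epochs: EpochSet, kind: str, **kwargs) -> EntropyProfile:
    """Arithmetic mean of per-epoch profiles; NaN scales excluded pairwise."""
    if kind not in ("RCME", "RMPE"):
        raise ValueError("kind must be 'RCME' or 'RMPE'")
    if len(epochs) == 0:
        scales = np.asarray(list(kwargs.get("scales", DEFAULT_SCALES)), dtype=int)
        return EntropyProfile(scales, np.full(len(scales), np.nan), kind, 0)
    fn = rcme if kind == "RCME" else rmpe
    profiles = [fn(ep, **kwargs) for ep in epochs.epochs]
    stacked = np.vstack([p.values for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN scales stay NaN
        mean = np.nanmean(stacked, axis=0)
    return EntropyProfile(profiles[0].scales, mean, kind, len(profiles))
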