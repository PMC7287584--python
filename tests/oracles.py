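"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain-Python enumeration or
closed-form arithmetic, sharing no code path with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sampen_counts_bruteforce(y, m: int, r: float) -> tuple[int, int]:
    """O(n²) sample-entropy match counts: unordered template pairs i<j over
    the common range of n−m start points, Chebyshev distance."""
    y = list(map(float, y))
    n = len(y)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(y[i + u] - y[j + u]) for u in range(m)) <= r:
                b += 1
                if max(abs(y[i + u] - y[j + u]) for u in range(m + 1)) <= r:
                    a += 1
    return a, b


def sampen_bruteforce(y, m: int, r: float) -> float:
    a, b = sampen_counts_bruteforce(y, m, r)
    return -math.log(a / b)


def rcme_scale_bruteforce(x, m: int, r: float, tau: int) -> float:
    """Composite sample entropy at one scale: counts pooled over all tau
    coarse-graining offsets (coarse series built by explicit slicing)."""
    x = list(map(float, x))
    a_tot = b_tot = 0
    for k in range(tau):
        n = (len(x) - k) // tau
        y = [sum(x[k + j * tau : k + (j + 1) * tau]) / tau for j in range(n)]
        a, b = sampen_counts_bruteforce(y, m, r)
        a_tot += a
        b_tot += b
    return -math.log(a_tot / b_tot)


def permutation_entropy_bruteforce(y, m: int) -> float:
    """Ordinal-pattern Shannon entropy (nats), ties broken by index order,
    patterns identified by their stable argsort tuple."""
    y = list(map(float, y))
    counts: dict[tuple, int] = {}
    for i in range(len(y) - m + 1):
        w = y[i : i + m]
        pattern = tuple(sorted(range(m), key=lambda j: (w[j], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum(c / total * math.log(c / total) for c in counts.values())


def optimal_match_count(ref, cand, tol: float) -> int:
    """Maximum one-to-one matching within tolerance, by exhaustive search
    over injective assignments (small instances only)."""
    ref = list(ref)
    cand = list(cand)

    def recurse(i: int, used: frozenset) -> int:
        if i == len(ref):
            return 0
        best = recurse(i + 1, used)  # leave ref[i] unmatched
        for j, c in enumerate(cand):
            if j not in used and abs(ref[i] - c) <= tol:
                best = max(best, 1 + recurse(i + 1, used | {j}))
        return best

    return recurse(0, frozenset())


def median_band_keepset(durations, ratio: float) -> list[bool]:
    """Direct re-statement of the median-ratio inclusion predicate."""
    d = sorted(durations)
    n = len(d)
    med = d[n // 2] if n % 2 else (d[n // 2 - 1] + d[n // 2]) / 2.0
    return [med / ratio <= x <= med * ratio for x in durations]


def icc_a1_pingouin(a, b) -> tuple[float, tuple[float, float]]:
    """Absolute-agreement single-measures ICC via pingouin (library route)."""
    import pandas as pd
    import pingouin as pg

    n = len(a)
    df = pd.DataFrame({
        "subject": list(range(n)) * 2,
        "rater": ["a"] * n + ["b"] * n,
        "score": list(a) + list(b),
    })
    res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci = row[[c for c in res.columns if c.startswith("CI95")][0]]
    return float(row["ICC"]), (float(ci[0]), float(ci[1]))
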