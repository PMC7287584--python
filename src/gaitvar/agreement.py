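"""Reliability and concurrent-validity statistics for paired measurements.

Absolute-agreement intra-class correlation ICC(A,1) from the two-way
random-effects ANOVA decomposition (single measures), with the F-based 95%
confidence interval; Bland–Altman bias and 95% limits of agreement with a
paired t-test; Pearson r and r²; the root-mean-square between-method
coefficient of variation (CV%RMS); and per-scale correlations between an
entropy profile matrix and a reference gait-variability outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "AgreementResult",
    "BlandAltman",
    "icc_absolute",
    "icc_category",
    "bland_altman",
    "pearson",
    "cv_rms",
    "scale_correlations",
    "agreement_battery",
    "plot_bland_altman",
]


@dataclass
class PairedSample:
    """One measurement per subject from each of two methods/sessions."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class BlandAltman:
    """Bias, 95% limits of agreement, paired-t p, and the plot coordinates."""

    bias: float
    loa_low: float
    loa_high: float
    t_p: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class AgreementResult:
    """The full agreement battery between two measurement columns."""

    bias: float
    loa_low: float
    loa_high: float
    t_p: float
    r: float
    r2: float
    icc: float
    icc_ci: tuple[float, float]
    icc_category: str
    cv_rms_pct: float


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way crossed layout, subjects × methods."""
    n, k = x.shape
    grand = x.mean()
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = x - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute(
    p: PairedSample,
    alpha: float = 0.05,
    variant: str = "A1",
) -> tuple[float, tuple[float, float]]:
    """ICC with its F-based confidence interval.

    ``variant='A1'`` is the two-way random-effects, absolute-agreement,
    single-measures ICC(A,1) (= ICC(2,1)); ``variant='C1'`` gives the
    two-way mixed consistency ICC(3,1) for sensitivity analyses.
    """
    if p.n < 3:
        raise ValueError("ICC confidence intervals need at least 3 subjects")
    x = np.column_stack([p.a, p.b])
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    if msr == 0 and msc == 0 and mse == 0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return float("nan"), (float("nan"), float("nan"))

    if variant == "C1":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse if mse > 0 else np.inf
        fl = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = f_obs * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(icc), (float(lo), float(hi))
    if variant != "A1":
        raise ValueError("variant must be 'A1' or 'C1'")

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if (mse == 0 and msc == 0) or 1.0 - icc < 1e-12:
        # agreement exact to machine precision
        return 1.0, (1.0, 1.0)
    # Satterthwaite df for the absolute-agreement interval
    with np.errstate(divide="ignore", invalid="ignore"):
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    if not np.isfinite(v):
        return float(icc), (float("nan"), float("nan"))
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    denom_lb = f_u * (k * msc + (k * n - k - n) * mse) + n * msr
    lo = n * (msr - f_u * mse) / denom_lb
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return float(icc), (float(lo), float(hi))


def icc_category(icc: float) -> str:
    """Agreement category: poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def bland_altman(p: PairedSample) -> BlandAltman:
    """Bias = mean(a−b), LoA = bias ± 1.96 × sample SD of the differences."""
    if p.n < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    d = p.a - p.b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        t_p = 1.0 if bias == 0 else 0.0
    else:
        t_p = float(stats.ttest_rel(p.a, p.b).pvalue)
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        t_p=t_p,
        means=(p.a + p.b) / 2.0,
        diffs=d,
    )


def pearson(p: PairedSample) -> tuple[float, float]:
    """Product-moment correlation r and r²."""
    if p.n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.std(p.a) == 0 or np.std(p.b) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(p.a, p.b).statistic)
    return r, r * r


def cv_rms(p: PairedSample) -> float:
    """Root-mean-square of the per-subject between-method CV (%).

    Per subject, the two-value sample SD is |a−b|/√2 and the CV is that SD
    over the pair mean × 100; subjects with a zero pair mean are excluded
    with a warning.
    """
    means = (p.a + p.b) / 2.0
    ok = means != 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-mean pair(s) from CV%RMS",
                      stacklevel=2)
    if not ok.any():
        return float("nan")
    cv = np.abs(p.a[ok] - p.b[ok]) / np.sqrt(2.0) / np.abs(means[ok]) * 100.0
    return float(np.sqrt(np.mean(cv**2)))


def scale_correlations(
    entropy_by_subject: pd.DataFrame | np.ndarray,
    ref: np.ndarray,
) -> pd.DataFrame:
    """Pearson r (and p) per coarseness scale against a reference outcome.

    ``entropy_by_subject`` is subjects × scales (DataFrame columns name the
    scales); subjects with NaN at a scale are excluded pairwise and scales
    with fewer than 3 complete subjects are reported as NaN.
    """
    if isinstance(entropy_by_subject, pd.DataFrame):
        scales = list(entropy_by_subject.columns)
        mat = entropy_by_subject.to_numpy(dtype=float)
    else:
        mat = np.asarray(entropy_by_subject, dtype=float)
        scales = list(range(1, mat.shape[1] + 1))
    ref = np.asarray(ref, dtype=float)
    if mat.shape[0] != len(ref):
        raise ValueError("subject dimension mismatch")
    rows = []
    for j, scale in enumerate(scales):
        col = mat[:, j]
        ok = np.isfinite(col) & np.isfinite(ref)
        if ok.sum() < 3 or np.std(col[ok]) == 0 or np.std(ref[ok]) == 0:
            rows.append((scale, float("nan"), float("nan")))
            continue
        res = stats.pearsonr(col[ok], ref[ok])
        rows.append((scale, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["scale", "r", "p"])


def agreement_battery(p: PairedSample) -> AgreementResult:
    """Bias/LoA/t, Pearson, ICC(A,1) with CI and category, and CV%RMS."""
    ba = bland_altman(p)
    r, r2 = pearson(p)
    icc, ci = icc_absolute(p)
    return AgreementResult(
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        t_p=ba.t_p,
        r=r,
        r2=r2,
        icc=icc,
        icc_ci=ci,
        icc_category=icc_category(icc) if np.isfinite(icc) else "undefined",
        cv_rms_pct=cv_rms(p),
    )


def plot_bland_altman(ba: BlandAltman, ax=None, title: str | None = None):
    """Mean–difference plot with bias and 95% limit-of-agreement lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.diffs, s=18, color="0.2")
    ax.axhline(ba.bias, color="k", lw=1.2)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a − b)")
    if title:
        ax.set_title(title)
    return ax
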