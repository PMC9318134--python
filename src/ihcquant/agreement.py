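"""Method- and observer-agreement statistics.

Implements the three tools of the reliability analysis: the one-way
random-effects single-measure intraclass correlation coefficient with the
Fleiss reliability labels, Bland–Altman bias and 95% limits of agreement
with empirical coverage, and the Pearson correlation (plain, or between
paired differences and pair means as a proportional-bias check).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import PairedMeasurementSet

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "icc_oneway",
    "classify_icc",
    "bland_altman",
    "pearson_r",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class ICCResult:
    """One-way random-effects single-measure ICC with its ANOVA components.

    ``variance_between`` = (MSB - MSW)/k and ``variance_error`` = MSW are the
    method-of-moments variance components (percent squared); ``p_value`` is
    the one-way ANOVA F test of zero between-subject variance; ``label`` is
    the Fleiss reliability class.
    """

    icc: float
    ms_between: float
    ms_within: float
    variance_between: float
    variance_error: float
    p_value: float
    label: str
    n_subjects: int
    k: int = 2


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman agreement summary for paired differences B - A.

    ``bias`` is the mean difference, ``loa_low/loa_high`` the limits of
    agreement bias -/+ multiplier * SD(differences), and ``coverage`` the
    percentage of differences inside the limits (boundary counted inside).
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    coverage: float
    multiplier: float = 1.96
    n: int = 0


PairsLike = "PairedMeasurementSet | tuple[np.ndarray, np.ndarray]"


def _pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, PairedMeasurementSet):
        return pairs.value_a, pairs.value_b
    a, b = pairs
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired input must be two equal-length 1-D arrays")
    return a, b


def icc_oneway(pairs) -> ICCResult:
    """One-way random-effects, single-measure ICC for k = 2 repeated measures.

    With n subjects each measured twice, the one-way ANOVA decomposition
    gives MSB (between subjects) and MSW (within subjects), and

        ICC = (MSB - MSW) / (MSB + (k - 1) * MSW).

    Raises if fewer than 2 subjects or if the data carry no variance at all
    (the coefficient is undefined there, and silently returning 0 would
    misreport perfect agreement on constant data).
    """
    a, b = _pair_arrays(pairs)
    n = a.size
    k = 2
    if n < 2:
        raise ValueError("ICC needs at least 2 subjects")
    x = np.column_stack([a, b]).astype(float)
    grand = x.mean()
    subj_means = x.mean(axis=1)
    ss_between = k * ((subj_means - grand) ** 2).sum()
    ss_within = ((x - subj_means[:, None]) ** 2).sum()
    if ss_between + ss_within == 0.0:
        raise ValueError("zero total variance: ICC undefined on constant data")
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if msw == 0.0:
        p = 0.0
    else:
        f = msb / msw
        p = float(stats.f.sf(f, n - 1, n * (k - 1)))
    return ICCResult(
        icc=float(icc),
        ms_between=float(msb),
        ms_within=float(msw),
        variance_between=float((msb - msw) / k),
        variance_error=float(msw),
        p_value=p,
        label=classify_icc(float(icc)),
        n_subjects=n,
        k=k,
    )


def classify_icc(icc: float) -> str:
    """Fleiss reliability label: > 0.75 excellent, 0.40–0.75 good, < 0.40 poor."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc > 0.75:
        return "excellent"
    if icc >= 0.40:
        return "good"
    return "poor"


def bland_altman(pairs, multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman analysis of differences d_i = B_i - A_i.

    Limits of agreement are bias +/- multiplier * SD (sample SD, n-1
    denominator); coverage is the percentage of differences in
    [loa_low, loa_high], boundaries inclusive. Under normal differences the
    default 1.96 multiplier gives ~95% expected coverage.
    """
    a, b = _pair_arrays(pairs)
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = bias - multiplier * sd
    hi = bias + multiplier * sd
    coverage = 100.0 * float(((d >= lo) & (d <= hi)).mean())
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
        coverage=coverage, multiplier=multiplier, n=int(d.size),
    )


def pearson_r(x, y, mode: str = "plain") -> float:
    """Pearson product-moment correlation.

    mode="plain" correlates x with y. mode="diff_vs_mean" correlates the
    paired differences (y - x) with the pair means (x + y)/2 — the
    proportional-bias companion to a Bland–Altman plot, near zero when the
    disagreement between methods does not grow with the measured magnitude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D arrays with at least 3 values")
    if mode == "diff_vs_mean":
        x, y = (x + y) / 2.0, y - x
    elif mode != "plain":
        raise ValueError(f"unknown mode {mode!r}")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman_plot(pairs, result: BlandAltmanResult | None = None, ax=None, path=None):
    """Difference-vs-mean scatter with bias and limit-of-agreement lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    a, b = _pair_arrays(pairs)
    if result is None:
        result = bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, b - a, s=12, alpha=0.6, edgecolor="none")
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias {result.bias:.2f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean of methods (%)")
    ax.set_ylabel("difference (%)")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
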