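"""Lesion-cohort comparison statistics.

Per-marker comparison of peri-implantitis (PI) versus periodontitis (PD)
area fractions with the Mann–Whitney U test, per-marker comparison of the
two measurement methods (MC vs DC) with the Wilcoxon signed-rank test, and
the D'Agostino–Pearson omnibus normality check, all at a configurable
significance level (default 0.05, no multiplicity correction by default).

The test engines are scipy.stats; this module owns the method-selection
policy (exact enumeration for small tie-free samples, tie/continuity-
corrected normal approximation otherwise), the validity preconditions, and
the cohort orchestration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import MARKERS, CohortDataset

__all__ = [
    "TestOutcome",
    "MarkerComparisonResult",
    "dagostino_pearson",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "compare_cohort",
    "results_to_frame",
]


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"

    def __iter__(self):  # allows `stat, p = outcome`
        yield self.statistic
        yield self.p_value


@dataclass(frozen=True)
class MarkerComparisonResult:
    """One hypothesis test in the cohort table; ``significant`` iff p < alpha."""

    marker: str
    comparison: str      # "PI_vs_PD" or "MC_vs_DC" or "normality"
    method: str          # measurement method the test ran on ("MC", "DC", "both")
    test_name: str
    statistic: float
    p_value: float
    significant: bool | None
    alpha: float = 0.05
    note: str = ""


def dagostino_pearson(values) -> TestOutcome:
    """D'Agostino–Pearson omnibus normality test.

    K2 combines the transformed-moment Z statistics for skewness and
    kurtosis; the p-value is chi-square with 2 df. Requires n >= 8 (the
    kurtosis Z transform is not defined below that) and non-constant data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(
            f"D'Agostino-Pearson needs n >= 8 (got {x.size}); "
            "collect more values or use a small-sample normality test"
        )
    if x.std() == 0.0:
        raise ValueError("normality test undefined for zero-variance data")
    k2, p = stats.normaltest(x)
    return TestOutcome(statistic=float(k2), p_value=float(p), method="asymptotic")


def mann_whitney(group_a, group_b) -> TestOutcome:
    """Two-sided Mann–Whitney U test of two independent samples.

    The p-value is exact (full enumeration of rank assignments) when
    n_a + n_b <= 12 and there are no ties across the pooled sample; otherwise
    the normal approximation with tie and continuity corrections is used.
    The statistic reported is U for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = tie_free and (a.size + b.size) <= 12
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return TestOutcome(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "asymptotic",
    )


def _wsr_exact(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments.

    Tied absolute differences get midranks; the T+ null distribution is the
    convolution over points {0, rank_i}, which enumerates the 2^n signings in
    polynomial time. Doubled ranks keep midranks (.5) integral.
    """
    ranks2 = np.rint(2 * stats.rankdata(np.abs(d))).astype(int)
    t_plus2 = int(ranks2[d > 0].sum())
    dist = np.zeros(ranks2.sum() + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:-r] if r else dist
        dist = dist + shifted
    dist /= dist.sum()
    cdf = np.cumsum(dist)
    p_le = cdf[t_plus2]
    p_ge = dist[t_plus2:].sum()
    p = min(1.0, 2.0 * min(p_le, p_ge))
    t_plus = t_plus2 / 2.0
    return min(t_plus, ranks2.sum() / 2.0 - t_plus), p


def wilcoxon_signed_rank(paired_a, paired_b) -> TestOutcome:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are excluded (the classical convention). The p-value is
    exact — full enumeration of the 2^n sign assignments, midranks for tied
    absolute differences — when n <= 15 after exclusion; otherwise the
    continuity-corrected normal approximation is used. All-zero differences
    are an error: the test carries no information there.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = b - a
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: signed-rank test undefined")
    if d.size <= 15:
        w, p = _wsr_exact(d)
        return TestOutcome(statistic=float(w), p_value=p, method="exact")
    res = stats.wilcoxon(
        d, alternative="two-sided", zero_method="wilcox", correction=True, method="approx"
    )
    return TestOutcome(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="asymptotic",
    )


def _patient_means(data: pd.DataFrame) -> pd.DataFrame:
    return (
        data.groupby(["patient_id", "group", "marker", "method"], as_index=False)["value"]
        .mean()
    )


def _adjust_pvalues(pvals: np.ndarray, how: str) -> np.ndarray:
    if how == "bonferroni":
        return np.minimum(1.0, pvals * pvals.size)
    if how == "fdr_bh":
        return stats.false_discovery_control(pvals, method="bh")
    raise ValueError(f"unknown correction {how!r}")


def compare_cohort(
    cohort: CohortDataset,
    alpha: float = 0.05,
    unit: str = "patient",
    include_normality: bool = True,
    correction: str | None = None,
) -> list[MarkerComparisonResult]:
    """Run the full per-marker comparison table on a two-group cohort.

    For every marker and measurement method, PI vs PD is tested with the
    Mann–Whitney U test; for every marker, MC vs DC (same patients, paired)
    with the Wilcoxon signed-rank test; optionally the D'Agostino–Pearson
    normality statistic is reported per marker/method (informational — the
    nonparametric tests are used regardless). ``unit="patient"`` (default)
    first averages each patient's fields to one value per patient, marker
    and method; ``unit="field"`` tests field-level values, a deliberately
    anticonservative alternative that ignores within-patient correlation.
    ``correction`` ("bonferroni" or "fdr_bh", default none) adjusts p-values
    across the markers within each test family before flagging.
    """
    if unit not in ("patient", "field"):
        raise ValueError(f"unknown unit {unit!r}")
    if correction is not None:
        _adjust_pvalues(np.array([0.5]), correction)  # validate the name early
    data = _patient_means(cohort.data) if unit == "patient" else cohort.data
    groups = set(data["group"].unique())
    if groups != {"PI", "PD"}:
        raise ValueError(f"cohort must contain exactly groups PI and PD, found {sorted(groups)}")
    markers = [m for m in MARKERS if m in set(data["marker"])]
    missing = set(data["marker"]) - set(MARKERS)
    if missing:
        markers += sorted(missing)

    results: list[MarkerComparisonResult] = []
    for marker in markers:
        sub = data[data["marker"] == marker]
        for method in sorted(sub["method"].unique()):
            mm = sub[sub["method"] == method]
            pi = mm.loc[mm["group"] == "PI", "value"].to_numpy()
            pd_ = mm.loc[mm["group"] == "PD", "value"].to_numpy()
            out = mann_whitney(pi, pd_)
            results.append(
                MarkerComparisonResult(
                    marker=marker, comparison="PI_vs_PD", method=method,
                    test_name=f"mann_whitney_{out.method}",
                    statistic=out.statistic, p_value=out.p_value,
                    significant=bool(out.p_value < alpha), alpha=alpha,
                )
            )
            if include_normality:
                try:
                    norm = dagostino_pearson(mm["value"].to_numpy())
                    results.append(
                        MarkerComparisonResult(
                            marker=marker, comparison="normality", method=method,
                            test_name="dagostino_pearson",
                            statistic=norm.statistic, p_value=norm.p_value,
                            significant=bool(norm.p_value < alpha), alpha=alpha,
                        )
                    )
                except ValueError as exc:
                    results.append(
                        MarkerComparisonResult(
                            marker=marker, comparison="normality", method=method,
                            test_name="dagostino_pearson",
                            statistic=float("nan"), p_value=float("nan"),
                            significant=None, alpha=alpha, note=str(exc),
                        )
                    )

        # MC vs DC, paired on subject (patient or patient-field) within marker
        key = ["patient_id"] if unit == "patient" else ["patient_id", "field_id"]
        wide = sub.pivot_table(index=key, columns="method", values="value", aggfunc="mean")
        if {"MC", "DC"} <= set(wide.columns):
            mc = wide["MC"].to_numpy()
            dc = wide["DC"].to_numpy()
            try:
                out = wilcoxon_signed_rank(mc, dc)
                results.append(
                    MarkerComparisonResult(
                        marker=marker, comparison="MC_vs_DC", method="both",
                        test_name=f"wilcoxon_{out.method}",
                        statistic=out.statistic, p_value=out.p_value,
                        significant=bool(out.p_value < alpha), alpha=alpha,
                    )
                )
            except ValueError as exc:
                results.append(
                    MarkerComparisonResult(
                        marker=marker, comparison="MC_vs_DC", method="both",
                        test_name="wilcoxon", statistic=float("nan"),
                        p_value=float("nan"), significant=None, alpha=alpha,
                        note=str(exc),
                    )
                )

    if correction is not None:
        # adjust across markers within each (comparison, method) family
        by_family: dict[tuple[str, str], list[int]] = {}
        for i, r in enumerate(results):
            if r.comparison in ("PI_vs_PD", "MC_vs_DC") and np.isfinite(r.p_value):
                by_family.setdefault((r.comparison, r.method), []).append(i)
        for idx in by_family.values():
            adj = _adjust_pvalues(np.array([results[i].p_value for i in idx]), correction)
            for i, p_adj in zip(idx, adj):
                r = results[i]
                results[i] = dataclasses.replace(
                    r, p_value=float(p_adj), significant=bool(p_adj < alpha),
                    note=(r.note + f" p adjusted ({correction})").strip(),
                )
    return results


def results_to_frame(results: list[MarkerComparisonResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a comparison table."""
    return pd.DataFrame([r.__dict__ for r in results])
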