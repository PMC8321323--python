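"""Cohort statistics for the morphometric quantities.

Mirrors the statistical treatment commonly applied to this kind of
morphometric cohort: per-metric summary (mean/std/min/max), the
D'Agostino-Pearson omnibus normality test, an unpaired two-sample
t-test between sexes (pooled-variance Student form by default, Welch as
an option), and Pearson correlation of volume and membrane area with
age.  Also provides the exact pooling arithmetic that reconstructs
whole-cohort summaries from per-group means, standard deviations and
sizes via the total sum of squares.

Standard tests are delegated to scipy.stats; the sample standard
deviation uses the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    std: float
    min: float
    max: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    p: float


@dataclass(frozen=True)
class NormalityResult:
    k2: float
    p: float
    zskew: float
    zkurt: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Sample summary with n-1 std (0 for a single value)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    std = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return SummaryStats(n=int(x.size), mean=float(x.mean()), std=std,
                        min=float(x.min()), max=float(x.max()))


def combine_group_stats(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Pooled mean and combined std of the union of two groups.

    The combined std is reconstructed from the total sum of squares::

        M = (n1 m1 + n2 m2) / (n1 + n2)
        s = sqrt([ (n1-1) s1^2 + n1 (m1-M)^2
                 + (n2-1) s2^2 + n2 (m2-M)^2 ] / (n1 + n2 - 1))

    which agrees exactly with ``summarize`` applied to the concatenated
    raw samples.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    n = n1 + n2
    mean = (n1 * m1 + n2 * m2) / n
    ss = (
        (n1 - 1) * s1**2
        + n1 * (m1 - mean) ** 2
        + (n2 - 1) * s2**2
        + n2 * (m2 - mean) ** 2
    )
    return float(mean), float(np.sqrt(ss / (n - 1)))


def unpaired_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-sample t-test (Student pooled-variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2 if equal_var else float("nan")
            return TTestResult(t=0.0, df=float(df), p=1.0)
        raise ValueError("zero pooled variance with unequal means: t is infinite")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def unpaired_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    equal_var: bool = True,
) -> TTestResult:
    """Two-sample t-test from per-group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return TTestResult(t=0.0, df=float(n1 + n2 - 2), p=1.0)
        raise ValueError("zero pooled variance with unequal means: t is infinite")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, p=float(res.pvalue))


def dagostino_pearson(x: Sequence[float], floor: int = 20) -> NormalityResult:
    """D'Agostino-Pearson omnibus normality test.

    Combines the skewness and kurtosis z-transforms into
    k2 = zskew^2 + zkurt^2, referred to chi-square with 2 df.  The
    transforms are asymptotic, hence the configurable sample-size floor.
    """
    x = np.asarray(x, dtype=float)
    if x.size < floor:
        raise ValueError(f"need at least {floor} observations, got {x.size}")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance sample")
    zskew = float(stats.skewtest(x).statistic)
    zkurt = float(stats.kurtosistest(x).statistic)
    k2 = zskew**2 + zkurt**2
    p = float(stats.chi2.sf(k2, df=2))
    return NormalityResult(k2=float(k2), p=p, zskew=zskew, zkurt=zkurt)


# ---------------------------------------------------------------------------
# cohort report

METRICS = ("vol_mm3", "area_mm2", "oh_mm", "d_mm")
_METRIC_LABELS = {
    "vol_mm3": "Vol (mm^3)",
    "area_mm2": "A (mm^2)",
    "oh_mm": "oh (mm)",
    "d_mm": "d (mm)",
}


def cohort_report(
    table: pd.DataFrame,
    t_test: str = "student",
    normality_floor: int = 20,
) -> dict[str, Any]:
    """Cohort-level statistics from a per-case metrics table.

    ``table`` needs the metric columns plus ``sex`` and ``age``.
    Returns a deterministic, JSON-serializable report: per-metric
    summary and normality p, sex-grouped comparison (volume and area)
    and Pearson correlation with age (volume and area).  Sections whose
    preconditions fail (too few cases per group) are omitted with a
    warning entry.
    """
    report: dict[str, Any] = {"n_cases": int(len(table)), "warnings": []}
    summary = {}
    for metric in METRICS:
        values = table[metric].to_numpy(dtype=float)
        s = summarize(values)
        entry = {
            "label": _METRIC_LABELS[metric],
            "n": s.n, "mean": s.mean, "std": s.std, "min": s.min, "max": s.max,
        }
        if len(values) >= normality_floor and np.std(values) > 0:
            norm = dagostino_pearson(values, floor=normality_floor)
            entry["normality_k2"] = norm.k2
            entry["normality_p"] = norm.p
        else:
            report["warnings"].append(
                f"normality test skipped for {metric} (n < {normality_floor} or constant)"
            )
        summary[metric] = entry
    report["summary"] = summary

    if "sex" in table.columns:
        males = table[table["sex"] == "male"]
        females = table[table["sex"] == "female"]
        if len(males) >= 2 and len(females) >= 2:
            by_sex = {}
            for metric in ("vol_mm3", "area_mm2"):
                xm = males[metric].to_numpy(dtype=float)
                xf = females[metric].to_numpy(dtype=float)
                res = unpaired_t(xm, xf, equal_var=(t_test == "student"))
                by_sex[metric] = {
                    "male_mean": float(xm.mean()), "male_std": float(xm.std(ddof=1)),
                    "male_n": int(len(xm)),
                    "female_mean": float(xf.mean()), "female_std": float(xf.std(ddof=1)),
                    "female_n": int(len(xf)),
                    "t": res.t, "df": res.df, "p": res.p,
                }
            report["sex_comparison"] = by_sex
        else:
            report["warnings"].append("sex comparison skipped: fewer than 2 cases per sex")

    if "age" in table.columns and len(table) >= 3:
        ages = table["age"].to_numpy(dtype=float)
        if np.std(ages) > 0:
            by_age = {}
            for metric in ("vol_mm3", "area_mm2"):
                values = table[metric].to_numpy(dtype=float)
                if np.std(values) == 0:
                    continue
                res = pearson_corr(ages, values)
                by_age[metric] = {"r": res.r, "r2": res.r2, "p": res.p}
            report["age_correlation"] = by_age
        else:
            report["warnings"].append("age correlation skipped: constant ages")
    elif len(table) < 3:
        report["warnings"].append("age correlation skipped: fewer than 3 cases")
    return report


def report_markdown(report: dict[str, Any]) -> str:
    """Render a cohort report as deterministic Markdown."""
    lines = [f"# Cohort report (n = {report['n_cases']})", ""]
    lines.append("| metric | n | mean | std | min | max | normality p |")
    lines.append("|---|---|---|---|---|---|---|")
    for metric, entry in report["summary"].items():
        normp = entry.get("normality_p")
        lines.append(
            f"| {entry['label']} | {entry['n']} | {entry['mean']:.3f} | {entry['std']:.3f} "
            f"| {entry['min']:.3f} | {entry['max']:.3f} "
            f"| {'' if normp is None else format(normp, '.3f')} |"
        )
    if "sex_comparison" in report:
        lines += ["", "## Sex comparison", "",
                  "| metric | male (mean ± std, n) | female (mean ± std, n) | t | p |",
                  "|---|---|---|---|---|"]
        for metric, e in report["sex_comparison"].items():
            lines.append(
                f"| {_METRIC_LABELS[metric]} "
                f"| {e['male_mean']:.2f} ± {e['male_std']:.2f} (n={e['male_n']}) "
                f"| {e['female_mean']:.2f} ± {e['female_std']:.2f} (n={e['female_n']}) "
                f"| {e['t']:.3f} | {e['p']:.3f} |"
            )
    if "age_correlation" in report:
        lines += ["", "## Correlation with age", "",
                  "| metric | r | R^2 | p |", "|---|---|---|---|"]
        for metric, e in report["age_correlation"].items():
            lines.append(
                f"| {_METRIC_LABELS[metric]} | {e['r']:.3f} | {e['r2']:.3f} | {e['p']:.3f} |"
            )
    for warning in report.get("warnings", []):
        lines += ["", f"_Note: {warning}_"]
    return "\n".join(lines) + "\n"
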