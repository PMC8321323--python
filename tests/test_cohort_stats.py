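"""Summary statistics, pooling arithmetic, tests and report assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from rwniche.cohort_stats import (
    cohort_report,
    combine_group_stats,
    dagostino_pearson,
    pearson_corr,
    report_markdown,
    summarize,
    unpaired_t,
    unpaired_t_from_summary,
)


def test_summarize_basics():
    s = summarize([1.0, 2.0, 3.0])
    assert (s.n, s.mean, s.std, s.min, s.max) == (3, 2.0, 1.0, 1.0, 3.0)
    single = summarize([4.2])
    assert single.mean == single.min == single.max == 4.2
    assert single.std == 0.0
    with pytest.raises(ValueError):
        summarize([])


def test_summarize_matches_direct_resummation():
    rng = np.random.default_rng(0)
    x = rng.normal(4.5, 1.0, size=50)
    s = summarize(x)
    assert s.mean == pytest.approx(x.sum() / 50, rel=1e-14)
    assert s.std == pytest.approx(np.sqrt(((x - x.mean()) ** 2).sum() / 49), rel=1e-12)


def test_identical_groups_combine_to_known_closed_form():
    """Merging (m, s, n) with itself: mean m, std s * sqrt((2n-2)/(2n-1))."""
    m, s, n = 3.7, 0.9, 25
    mean, std = combine_group_stats(m, s, n, m, s, n)
    assert mean == pytest.approx(m, rel=1e-14)
    assert std == pytest.approx(s * np.sqrt((2 * n - 2) / (2 * n - 1)), rel=1e-12)


def test_combine_equals_summarize_of_concatenation():
    """Exact algebraic identity, checked over random splits."""
    rng = np.random.default_rng(1)
    for _ in range(100):
        n1, n2 = rng.integers(2, 40, size=2)
        x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), size=n1)
        y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), size=n2)
        sx, sy, s_all = summarize(x), summarize(y), summarize(np.concatenate([x, y]))
        mean, std = combine_group_stats(sx.mean, sx.std, sx.n, sy.mean, sy.std, sy.n)
        assert mean == pytest.approx(s_all.mean, abs=1e-12)
        assert std == pytest.approx(s_all.std, abs=1e-12)


def test_unpaired_t_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    res = unpaired_t(x, x)
    assert res.t == 0.0
    assert res.p == pytest.approx(1.0)


def test_t_from_summary_closed_form_arithmetic():
    """Pooled-variance t for two summarized groups, against by-hand algebra."""
    m1, s1, n1, m2, s2, n2 = 4.50, 0.82, 22, 4.57, 1.21, 28
    res = unpaired_t_from_summary(m1, s1, n1, m2, s2, n2)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t_hand = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    assert res.t == pytest.approx(t_hand, rel=1e-12)
    assert abs(res.t) == pytest.approx(0.232, abs=0.001)
    assert res.df == n1 + n2 - 2
    assert res.p == pytest.approx(0.82, abs=0.005)


def test_p_value_matches_incomplete_beta():
    """Two-sided p from t and df via the regularized incomplete beta."""
    for (m1, s1, n1, m2, s2, n2) in [
        (4.50, 0.82, 22, 4.57, 1.21, 28),
        (3.13, 0.71, 22, 2.77, 0.69, 28),
        (1.0, 1.0, 10, 2.0, 1.5, 15),
    ]:
        res = unpaired_t_from_summary(m1, s1, n1, m2, s2, n2)
        df = res.df
        p_beta = special.betainc(df / 2, 0.5, df / (df + res.t**2))
        assert res.p == pytest.approx(p_beta, abs=1e-10)


def test_raw_equals_summary_route():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 20)
    y = rng.normal(0.3, 1.2, 25)
    raw = unpaired_t(x, y)
    summ = unpaired_t_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )
    assert raw.t == pytest.approx(summ.t, abs=1e-12)
    assert raw.p == pytest.approx(summ.p, abs=1e-12)


def test_welch_option_differs_with_unequal_variances():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 0.5, 12)
    y = rng.normal(0, 3.0, 40)
    student = unpaired_t(x, y, equal_var=True)
    welch = unpaired_t(x, y, equal_var=False)
    assert student.p != pytest.approx(welch.p, abs=1e-6)


def test_degenerate_variance_handling():
    with pytest.raises(ValueError, match="infinite"):
        unpaired_t([1.0, 1.0], [2.0, 2.0])
    res = unpaired_t_from_summary(5.0, 0.0, 10, 5.0, 0.0, 12)
    assert (res.t, res.p) == (0.0, 1.0)


def test_pearson_perfect_linear_relation():
    x = np.arange(10.0)
    res = pearson_corr(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    assert res.r2 == res.r**2


def test_r_squared_bookkeeping_at_printed_precision():
    r = -0.22
    assert round(r * r, 2) == 0.05


def test_pearson_p_matches_permutation_null():
    """Analytic two-sided p within Monte-Carlo error of a permutation null."""
    rng = np.random.default_rng(4)
    n = 20
    x = rng.normal(size=n)
    y = 0.3 * x + rng.normal(size=n)
    res = pearson_corr(x, y)
    n_perm = 100_000
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    xc = x - x.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_null = (pc @ xc) / (np.sqrt((pc**2).sum(axis=1)) * np.linalg.norm(xc))
    p_perm = float((np.abs(r_null) >= abs(res.r) - 1e-12).mean())
    mc_sigma = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert res.p == pytest.approx(p_perm, abs=max(5 * mc_sigma, 0.003))


def test_correlation_invariant_under_affine_rescaling():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    base = pearson_corr(x, y)
    scaled = pearson_corr(3.2 * x - 7, -0.5 * y + 2)
    assert abs(scaled.r) == pytest.approx(abs(base.r), abs=1e-12)
    assert scaled.p == pytest.approx(base.p, abs=1e-12)


def test_dagostino_floor_and_components():
    rng = np.random.default_rng(6)
    with pytest.raises(ValueError):
        dagostino_pearson(rng.normal(size=10), floor=20)
    x = rng.normal(size=80)
    res = dagostino_pearson(x)
    assert res.k2 == pytest.approx(res.zskew**2 + res.zkurt**2, rel=1e-12)
    # agrees with the omnibus implementation in scipy
    k2_ref, p_ref = stats.normaltest(x)
    assert res.k2 == pytest.approx(float(k2_ref), rel=1e-12)
    assert res.p == pytest.approx(float(p_ref), rel=1e-12)


def test_dagostino_type_one_error_calibration():
    """Rejection rate at alpha = 0.05 on normal samples of n = 50."""
    rng = np.random.default_rng(7)
    samples = rng.normal(size=(5000, 50))
    zs = stats.skewtest(samples, axis=1).statistic
    zk = stats.kurtosistest(samples, axis=1).statistic
    p = stats.chi2.sf(zs**2 + zk**2, df=2)
    rate = float((p < 0.05).mean())
    assert 0.04 <= rate <= 0.06


def test_dagostino_power_against_exponential():
    rng = np.random.default_rng(8)
    rejections = sum(
        dagostino_pearson(rng.exponential(size=50)).p < 0.05 for _ in range(200)
    )
    assert rejections / 200 > 0.5


# ---------------------------------------------------------------------------
# report


def _toy_table(n=30, seed=9):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "vol_mm3": rng.normal(4.5, 1.0, n),
            "area_mm2": rng.normal(2.9, 0.7, n),
            "oh_mm": rng.normal(0.56, 0.2, n).clip(0),
            "d_mm": rng.normal(1.35, 0.2, n),
            "sex": ["male", "female"] * (n // 2),
            "age": rng.integers(13, 93, n),
        }
    )


def test_report_sections_and_determinism():
    table = _toy_table()
    report = cohort_report(table)
    assert set(report["summary"]) == {"vol_mm3", "area_mm2", "oh_mm", "d_mm"}
    assert "sex_comparison" in report and "age_correlation" in report
    assert report["summary"]["vol_mm3"]["normality_p"] > 0
    md1 = report_markdown(cohort_report(table))
    md2 = report_markdown(cohort_report(table.copy()))
    assert md1 == md2  # byte-identical on identical input


def test_report_single_case_omits_statistics():
    report = cohort_report(_toy_table(n=2).iloc[:1])
    assert "sex_comparison" not in report
    assert "age_correlation" not in report
    assert any("skipped" in w for w in report["warnings"])


def test_report_small_groups_warn():
    table = _toy_table(n=6)
    table["sex"] = ["male"] + ["female"] * 5
    report = cohort_report(table)
    assert "sex_comparison" not in report
    assert any("sex comparison skipped" in w for w in report["warnings"])
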