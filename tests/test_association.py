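"""Tests of the statistical battery: Hedge's g, Spearman, exact tests and
covariate-adjusted standardized regressions, each against an independent
oracle where one exists."""

import math

import numpy as np
import pingouin
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mtdrive.association import (
    adjusted_group_difference,
    fit_adjusted_association,
    group_compare,
    hedges_g,
    hedges_g_from_summary,
    spearman,
    spearman_by_group,
)
from mtdrive.published import N_CU, N_IMPAIRED, TABLE1
from mtdrive.scoring import ValidationError


# ---------------------------------------------------------------------------
# Hedge's g


def test_hedges_g_hand_computation():
    es = hedges_g([1, 2, 3], [2, 3, 4])
    assert es.g == pytest.approx(0.8)
    assert es.ci_low < 0.8 < es.ci_high


def test_hedges_g_no_difference_symmetric_ci():
    es = hedges_g_from_summary(5.0, 1.0, 20, 5.0, 1.2, 25)
    assert es.g == 0.0
    assert es.ci_low == pytest.approx(-es.ci_high)


def test_hedges_g_reproduces_published_composite_effect():
    r = TABLE1["mtd_sbcr"]
    es = hedges_g_from_summary(r.cu_mean, r.cu_sd, N_CU, r.imp_mean, r.imp_sd, N_IMPAIRED)
    assert es.g == pytest.approx(-2.02, abs=0.01)
    assert es.ci_low == pytest.approx(-2.35, abs=0.01)
    assert es.ci_high == pytest.approx(-1.68, abs=0.01)


def test_hedges_g_degenerate_inputs():
    with pytest.raises(ValidationError):
        hedges_g([1.0], [2.0, 3.0])
    with pytest.raises(ValidationError, match="pooled SD"):
        hedges_g([1.0, 1.0], [1.0, 1.0])


def test_hedges_g_matches_pingouin_point_estimate():
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1.3, 25)
    ours = hedges_g(x, y)
    theirs = pingouin.compute_effsize(y, x, eftype="hedges")
    assert ours.g == pytest.approx(theirs, abs=1e-10)


@given(
    data=st.lists(st.floats(-50, 50), min_size=4, max_size=40),
    split=st.integers(2, 38),
)
@settings(max_examples=150, deadline=None)
def test_hedges_raw_path_equals_summary_path(data, split):
    x = np.asarray(data[: max(2, min(split, len(data) - 2))])
    y = np.asarray(data[len(x):])
    if len(y) < 2:
        return
    pooled_var = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
    if pooled_var <= 1e-12:
        return
    raw = hedges_g(x, y)
    summ = hedges_g_from_summary(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
    assert raw.g == pytest.approx(summ.g, abs=1e-12)
    assert raw.ci_low == pytest.approx(summ.ci_low, abs=1e-12)
    assert raw.ci_high == pytest.approx(summ.ci_high, abs=1e-12)


# ---------------------------------------------------------------------------
# Spearman


def _rank_average_ties(v):
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _spearman_bruteforce(x, y):
    rx, ry = _rank_average_ties(x), _rank_average_ties(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def test_spearman_monotone_cases():
    x = np.array([0.2, 1.5, -0.3, 2.2, 0.9])
    assert spearman(x, x)[0] == pytest.approx(1.0)
    assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [1, 3, 2, 4])[0] == pytest.approx(0.8)


def test_spearman_equals_bruteforce_rank_pearson_small_n():
    rng = np.random.default_rng(11)
    for _ in range(300):
        n = rng.integers(3, 9)
        x = rng.integers(0, 5, n).astype(float)  # integer values force ties
        y = rng.normal(size=n)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(_spearman_bruteforce(x, y), abs=1e-12)


def test_spearman_constant_input_is_missing():
    rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert math.isnan(rho) and math.isnan(p)


def test_spearman_by_group_splits_correctly():
    x = np.arange(10, dtype=float)
    y = np.concatenate([np.arange(5), 5 - np.arange(5)])
    g = ["a"] * 5 + ["b"] * 5
    table = spearman_by_group(x, y, g)
    assert table.set_index("group").loc["a", "rho"] == pytest.approx(1.0)
    assert table.set_index("group").loc["b", "rho"] == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# two-group tests


def _fisher_bruteforce(table):
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def p_of(a_):
        return (
            math.comb(r1, a_) * math.comb(r2, c1 - a_) / math.comb(n, c1)
        )

    p_obs = p_of(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = p_of(a_)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_fisher_matches_exhaustive_enumeration():
    rng = np.random.default_rng(5)
    tables = [np.array([[1, 9], [11, 3]])] + [rng.integers(0, 12, (2, 2)) for _ in range(50)]
    for t in tables:
        if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
            continue
        ours = group_compare(t, kind="fisher")
        assert ours.p == pytest.approx(_fisher_bruteforce(t), rel=1e-9)


def test_chi_square_homogeneous_table():
    res = group_compare(np.array([[10, 10], [10, 10]]), kind="chi-square")
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_t_test_symmetry_and_pooled_variance():
    v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    g = ["a", "a", "a", "b", "b", "b"]
    res = group_compare(v, g, kind="t")
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)
    # pooled (Student) vs Welch differ with unequal variances/sizes
    rng = np.random.default_rng(9)
    v2 = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 4, 30)])
    g2 = ["a"] * 10 + ["b"] * 30
    pooled = group_compare(v2, g2, kind="t")
    welch = group_compare(v2, g2, kind="t", welch=True)
    assert pooled.p != pytest.approx(welch.p)


def test_group_compare_error_paths():
    with pytest.raises(ValidationError):
        group_compare(np.array([1.0, 2.0]), ["a", "a"], kind="t")
    with pytest.raises(ValidationError):
        group_compare(np.array([[1, 2, 3], [3, 2, 1]]), kind="fisher")
    with pytest.raises(ValidationError):
        group_compare(np.array([1.0]), ["a"], kind="bogus")


# ---------------------------------------------------------------------------
# adjusted models


def _toy_cohort(n, rng, beta=0.0):
    age = rng.uniform(55, 90, n)
    sex = rng.integers(0, 2, n).astype(float)
    edu = rng.uniform(10, 20, n)
    x = -0.02 * (age - 70) + rng.normal(0, 1, n)
    y = beta * x - 0.03 * (age - 70) + 0.1 * sex + rng.normal(0, 1, n)
    ref = np.ones(n, bool)
    return y, x, age, sex, edu, ref


def test_identity_regression_recovers_unit_slope(rng):
    y, x, age, sex, edu, ref = _toy_cohort(500, rng)
    res = fit_adjusted_association(x, x, age, sex, edu, ref)
    assert res.estimate == pytest.approx(1.0, abs=1e-10)
    assert res.p < 1e-100


def test_affine_invariance_of_standardized_estimate(rng):
    y, x, age, sex, edu, ref = _toy_cohort(800, rng, beta=-0.3)
    base = fit_adjusted_association(y, x, age, sex, edu, ref)
    scaled = fit_adjusted_association(3.7 * y - 11.0, -0.002 * x + 5.0, age, sex, edu, ref)
    assert abs(abs(scaled.estimate) - abs(base.estimate)) < 1e-10
    assert scaled.p == pytest.approx(base.p, abs=1e-10)


def test_null_estimate_centered_at_zero(rng):
    ests = []
    for _ in range(40):
        y, x, age, sex, edu, ref = _toy_cohort(400, rng, beta=0.0)
        ests.append(fit_adjusted_association(y, x, age, sex, edu, ref).estimate)
    assert np.mean(ests) == pytest.approx(0.0, abs=0.03)


def test_adjusted_model_error_paths(rng):
    y, x, age, sex, edu, ref = _toy_cohort(50, rng)
    with pytest.raises(ValidationError, match="zero variance"):
        fit_adjusted_association(y, np.zeros(50), age, sex, edu, ref)
    with pytest.raises(ValidationError, match="complete cases"):
        fit_adjusted_association(y[:5], x[:5], age[:5], sex[:5], edu[:5], ref[:5])


def test_adjusted_group_difference_no_confounding_matches_raw(rng):
    n = 4000
    group = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    age = rng.uniform(55, 90, n)  # independent of group: no confounding
    sex = rng.integers(0, 2, n).astype(float)
    edu = rng.uniform(10, 20, n)
    score = 2.0 * (group == "b") + rng.normal(0, 1, n)
    adj = adjusted_group_difference(score, group, age, sex, edu)
    raw = score[group == "b"].mean() - score[group == "a"].mean()
    assert adj.estimate == pytest.approx(raw, abs=0.05)


def test_adjusted_group_difference_mediated_by_covariate(rng):
    n = 3000
    group = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    age = np.where(group == "b", 80.0, 65.0) + rng.normal(0, 5, n)
    score = -0.5 * age + rng.normal(0, 1, n)  # group difference is pure age
    adj = adjusted_group_difference(score, group, age, rng.integers(0, 2, n).astype(float), np.full(n, 14.0))
    assert adj.estimate == pytest.approx(0.0, abs=0.2)
    with pytest.raises(ValidationError):
        adjusted_group_difference(score, ["a"] * n, age, np.zeros(n), np.full(n, 14.0))


def test_permutation_null_p_values_are_uniform(rng):
    """Randomly permuted group labels give uniform p-values (KS check)."""
    n = 600
    age = rng.uniform(55, 90, n)
    sex = rng.integers(0, 2, n).astype(float)
    edu = rng.uniform(10, 20, n)
    score = -0.04 * age + rng.normal(0, 1, n)
    ps = []
    for _ in range(200):
        group = rng.permutation(np.array(["a"] * (n // 2) + ["b"] * (n // 2)))
        ps.append(adjusted_group_difference(score, group, age, sex, edu).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01
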