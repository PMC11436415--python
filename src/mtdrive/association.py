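"""Statistical battery for the biomarker-cognition analyses.

Covers: covariate-adjusted standardized linear models (outcome and predictor
z-scored to the reference subgroup before fitting), Hedge's g effect sizes
with normal-approximation confidence intervals (from raw data or from
printed summary statistics), Spearman rank correlations overall and by
diagnostic group, and unadjusted two-group tests (pooled-variance t,
chi-square without continuity correction, Fisher exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import ValidationError, reference_stats, zscore

__all__ = [
    "AssociationResult",
    "EffectSize",
    "GroupComparison",
    "fit_adjusted_association",
    "adjusted_group_difference",
    "hedges_g",
    "hedges_g_from_summary",
    "spearman",
    "spearman_by_group",
    "group_compare",
]


@dataclass(frozen=True)
class AssociationResult:
    """Standardized regression estimate with its 95% CI and p-value."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class EffectSize:
    """Hedge's g (bias-corrected standardized mean difference) with 95% CI."""

    g: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float | None
    p: float


# ---------------------------------------------------------------------------
# adjusted linear models


def _complete(*arrays):
    cols = [np.asarray(a, dtype=float) for a in arrays]
    ok = ~np.any([np.isnan(c) for c in cols], axis=0)
    return [c[ok] for c in cols], ok


def fit_adjusted_association(
    outcome, predictor, age, sex, education, reference_mask, min_n: int = 10
) -> AssociationResult:
    """OLS of the z-scored outcome on the z-scored predictor plus age, sex
    and education, complete-case per model.

    Outcome and predictor are z-scored against the reference subgroup (so the
    reported estimate is a standardized mean estimate, invariant to affine
    rescaling of either raw variable); the CI uses the t distribution with
    residual degrees of freedom.  ``sex`` may be a string array (F/M) or a
    numeric indicator.
    """
    sex_num = _sex_indicator(sex)
    (y, x, a, s, e), ok = _complete(outcome, predictor, age, sex_num, education)
    if y.size < min_n:
        raise ValidationError(f"need >= {min_n} complete cases, got {y.size}")
    mask = np.asarray(reference_mask, dtype=bool)[ok]
    if np.nanstd(x) == 0:
        raise ValidationError("predictor has zero variance")
    y = zscore(y, reference_stats(y, mask, name="outcome"))
    x = zscore(x, reference_stats(x, mask, name="predictor"))
    X = sm.add_constant(np.column_stack([x, a, s, e]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient design matrix (collinear covariates)")
    fit = sm.OLS(y, X).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return AssociationResult(float(fit.params[1]), float(lo), float(hi), float(fit.pvalues[1]), int(y.size))


def adjusted_group_difference(score, group, age, sex, education) -> AssociationResult:
    """OLS of the raw score on a two-level group indicator plus age, sex and
    education; returns the group coefficient (second level minus first, with
    levels in sorted order) with CI and p."""
    g = pd.Series(np.asarray(group, dtype=object))
    levels = sorted(g.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly two group levels, got {levels}")
    indicator = g.map({levels[0]: 0.0, levels[1]: 1.0}).to_numpy(dtype=float)
    (y, d, a, s, e), _ = _complete(score, indicator, age, _sex_indicator(sex), education)
    X = sm.add_constant(np.column_stack([d, a, s, e]), has_constant="add")
    fit = sm.OLS(y, X).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return AssociationResult(float(fit.params[1]), float(lo), float(hi), float(fit.pvalues[1]), int(y.size))


def _sex_indicator(sex):
    arr = np.asarray(sex)
    if arr.dtype.kind in "fiub":
        return arr.astype(float)
    return pd.Series(arr).map({"F": 1.0, "M": 0.0}).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# effect sizes


def hedges_g_from_summary(m1, sd1, n1, m2, sd2, n2) -> EffectSize:
    """Hedge's g from group summary statistics.

    Pooled SD uses (n1-1, n2-1) weights; the small-sample correction is
    J = 1 - 3/(4*df - 1) with df = n1 + n2 - 2, applied to Cohen's d of
    (m2 - m1); the 95% CI is g +/- 1.96*SE with
    SE = sqrt((n1+n2)/(n1*n2) + g^2/(2*df)).
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValidationError("both groups need n >= 2")
    df = n1 + n2 - 2
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    if pooled == 0:
        raise ValidationError("pooled SD is zero")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (m2 - m1) / pooled
    se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * df))
    return EffectSize(float(g), float(g - 1.96 * se), float(g + 1.96 * se), n1, n2)


def hedges_g(group1_values, group2_values) -> EffectSize:
    """Hedge's g from raw data; agrees exactly with the summary path."""
    x1 = np.asarray(group1_values, dtype=float)
    x2 = np.asarray(group2_values, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("both groups need n >= 2 non-missing values")
    return hedges_g_from_summary(
        x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
    )


# ---------------------------------------------------------------------------
# correlations and two-group tests


def spearman(x, y, min_pairs: int = 3):
    """Spearman rho (average ranks for ties) and two-sided p via the t
    approximation.  Returns (nan, nan) with a warning path for constant input."""
    (xv, yv), _ = _complete(x, y)
    if xv.size < min_pairs:
        raise ValidationError(f"need >= {min_pairs} complete pairs, got {xv.size}")
    if np.std(xv) == 0 or np.std(yv) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p)


def spearman_by_group(x, y, group) -> pd.DataFrame:
    """Spearman rho/p within each level of ``group`` (tidy table)."""
    g = pd.Series(np.asarray(group, dtype=object))
    rows = []
    for level in sorted(g.dropna().unique()):
        sel = (g == level).to_numpy()
        xv = np.asarray(x, dtype=float)[sel]
        yv = np.asarray(y, dtype=float)[sel]
        ok = ~np.isnan(xv) & ~np.isnan(yv)
        if ok.sum() >= 3:
            rho, p = spearman(xv[ok], yv[ok])
        else:
            rho, p = float("nan"), float("nan")
        rows.append({"group": level, "rho": rho, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def group_compare(values_or_counts, groups=None, kind: str = "t", welch: bool = False) -> GroupComparison:
    """Unadjusted two-group comparison.

    kind="t": pooled-variance two-sample t-test (Welch behind a flag) on
    ``values_or_counts`` split by the two levels of ``groups``.
    kind="chi-square": Pearson chi-square without continuity correction on a
    contingency table (rows x groups).
    kind="fisher": Fisher exact two-sided test on a 2x2 count table.
    """
    if kind == "t":
        v = np.asarray(values_or_counts, dtype=float)
        g = pd.Series(np.asarray(groups, dtype=object))
        levels = sorted(g.dropna().unique())
        if len(levels) != 2:
            raise ValidationError(f"t-test needs exactly two groups, got {levels}")
        x1 = v[(g == levels[0]).to_numpy()]
        x2 = v[(g == levels[1]).to_numpy()]
        x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
        if x1.size == 0 or x2.size == 0:
            raise ValidationError("empty group in t-test")
        t, p = stats.ttest_ind(x1, x2, equal_var=not welch)
        return GroupComparison("t", float(t), float(p))
    table = np.asarray(values_or_counts, dtype=float)
    if kind == "chi-square":
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValidationError("chi-square table has an empty margin")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison("chi-square", float(chi2), float(p))
    if kind == "fisher":
        if table.shape != (2, 2):
            raise ValidationError("fisher requires a 2x2 count table")
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison("fisher", None, float(p))
    raise ValidationError(f"unknown test kind {kind!r}")
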