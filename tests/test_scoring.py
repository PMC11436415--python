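"""Unit and property tests for session scoring and composite construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdrive.scoring import (
    MTD_SBCZ_CONSTITUENTS,
    ReferenceStats,
    SLSRawSession,
    SymbolsSession,
    ValidationError,
    accuracy_weight,
    compute_mtd_sbcr,
    reference_stats,
    score_cohort,
    score_sls,
    score_symbols,
    z_composite,
)


# ---------------------------------------------------------------------------
# SLS


@pytest.mark.parametrize(
    "spans, correct, delay_presented, delay_correct, t15, sot, maxspan",
    [
        ((8, 9, 10, 11, 12), (8, 9, 10, 11, 12), 24, 24, 50, 74, 12),
        ((8, 8, 8, 8, 8), (0, 0, 0, 0, 0), 8, 0, 0, 0, 8),
        ((8, 8, 8, 8, 8), (4, 4, 4, 4, 4), 8, 5, 20, 25, 8),
    ],
)
def test_score_sls_totals(spans, correct, delay_presented, delay_correct, t15, sot, maxspan):
    scores = score_sls(SLSRawSession(spans, correct, delay_presented, delay_correct))
    assert scores.trials_1_5_total == t15
    assert scores.sum_of_trials == sot
    assert scores.max_learning_span == maxspan
    assert scores.sum_of_trials == scores.trials_1_5_total + scores.delay


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(trial_spans=(7, 8, 8, 8, 8), trial_correct=(0,) * 5, delay_presented=8, delay_correct=0), "trial_spans"),
        (dict(trial_spans=(8, 24, 8, 8, 8), trial_correct=(0,) * 5, delay_presented=24, delay_correct=0), "trial_spans"),
        (dict(trial_spans=(8,) * 5, trial_correct=(9, 0, 0, 0, 0), delay_presented=8, delay_correct=0), "trial_correct"),
        (dict(trial_spans=(8,) * 5, trial_correct=(0,) * 5, delay_presented=8, delay_correct=9), "delay_correct"),
        (dict(trial_spans=(8,) * 5, trial_correct=(0,) * 5, delay_presented=5, delay_correct=0), "delay_presented"),
    ],
)
def test_sls_session_invariants_rejected(kwargs, match):
    with pytest.raises(ValidationError, match=match):
        SLSRawSession(**kwargs)


# ---------------------------------------------------------------------------
# accuracy weighting and Symbols


def test_accuracy_weight_step_boundaries():
    for n, expected in [(34, 1), (35, 2), (41, 2), (42, 3), (43, 4), (44, 4.25), (45, 4.5), (46, 4.75), (47, 5), (48, 5), (20, 1), (0, 1)]:
        assert accuracy_weight(n) == expected


def test_accuracy_weight_rejects_out_of_range():
    with pytest.raises(ValidationError):
        accuracy_weight(49)
    with pytest.raises(ValidationError):
        accuracy_weight(-1)


def _symbols_session(n_correct, rt_correct=3.0, rt_wrong=5.0):
    correct = [True] * n_correct + [False] * (48 - n_correct)
    rts = [rt_correct] * n_correct + [rt_wrong] * (48 - n_correct)
    return SymbolsSession(tuple(correct), tuple(rts))


def test_score_symbols_all_correct():
    s = score_symbols(_symbols_session(48, rt_correct=3.0))
    assert s.sym == pytest.approx(3.0)
    assert s.accuracy_weight == 5
    assert s.symaw == pytest.approx(35.0)


def test_score_symbols_floor_at_ten_seconds():
    s = score_symbols(_symbols_session(48, rt_correct=10.0))
    assert s.symaw == 0.0
    slow = score_symbols(_symbols_session(48, rt_correct=12.5))
    assert slow.symaw == 0.0


def test_score_symbols_partial_accuracy():
    s = score_symbols(_symbols_session(40, rt_correct=4.0))
    assert s.sym == pytest.approx(4.0)
    assert s.accuracy_weight == 2
    assert s.symaw == pytest.approx(12.0)


def test_score_symbols_zero_correct_is_missing_not_zero():
    s = score_symbols(_symbols_session(0))
    assert s.n_correct == 0
    assert np.isnan(s.sym) and np.isnan(s.symaw)
    assert not s.valid


def test_symbols_session_requires_48_positive_rts():
    with pytest.raises(ValidationError):
        SymbolsSession((True,) * 47, (1.0,) * 47)
    with pytest.raises(ValidationError):
        SymbolsSession((True,) * 48, (1.0,) * 47 + (-0.5,))


@given(
    sym1=st.floats(0.5, 15.0),
    delta=st.floats(0.0, 5.0),
    n_correct=st.integers(1, 48),
)
@settings(max_examples=200, deadline=None)
def test_symaw_non_increasing_in_sym(sym1, delta, n_correct):
    """Holding accuracy fixed, a slower mean response time never raises SYMaw."""
    w = accuracy_weight(n_correct)
    fast = max(0.0, 10.0 - sym1) * w
    slow = max(0.0, 10.0 - (sym1 + delta)) * w
    assert slow <= fast + 1e-12


@given(n1=st.integers(1, 48), n2=st.integers(1, 48), sym=st.floats(0.5, 9.99))
@settings(max_examples=200, deadline=None)
def test_symaw_non_decreasing_in_accuracy(n1, n2, sym):
    if n1 > n2:
        n1, n2 = n2, n1
    assert (10.0 - sym) * accuracy_weight(n1) <= (10.0 - sym) * accuracy_weight(n2) + 1e-12


# ---------------------------------------------------------------------------
# composites


def test_compute_mtd_sbcr_adds_constituents():
    sls = score_sls(SLSRawSession((8, 9, 10, 11, 12), (8, 9, 10, 11, 12), 24, 24))
    sym = score_symbols(_symbols_session(48, rt_correct=3.0))
    assert compute_mtd_sbcr(sls, sym) == pytest.approx(109.0)
    zero_sls = score_sls(SLSRawSession((8,) * 5, (0,) * 5, 8, 0))
    ten_s = score_symbols(_symbols_session(48, rt_correct=10.0))
    assert compute_mtd_sbcr(zero_sls, ten_s) == 0.0
    sls2 = score_sls(SLSRawSession((8, 8, 8, 8, 8), (4, 4, 4, 4, 4), 8, 5))
    sym2 = score_symbols(_symbols_session(40, rt_correct=4.0))
    assert compute_mtd_sbcr(sls2, sym2) == pytest.approx(37.0)


def test_compute_mtd_sbcr_missing_propagates():
    sls = score_sls(SLSRawSession((8,) * 5, (4,) * 5, 8, 5))
    assert np.isnan(compute_mtd_sbcr(sls, score_symbols(_symbols_session(0))))
    assert np.isnan(compute_mtd_sbcr(None, score_symbols(_symbols_session(48))))


def test_reference_stats_hand_values():
    mean, sd, n = reference_stats([1, 2, 3], [True, True, True])
    assert (mean, sd, n) == (2.0, 1.0, 3)
    mean, sd, n = reference_stats([1, 2, 3, 100], [True, True, True, False])
    assert (mean, sd, n) == (2.0, 1.0, 3)


def test_reference_stats_degenerate_inputs():
    with pytest.raises(ValidationError, match="memory_score"):
        reference_stats([5, 5, 5], [True] * 3, name="memory_score")
    with pytest.raises(ValidationError, match=">= 2"):
        reference_stats([1.0, np.nan, 2.0], [True, True, False])


def test_z_composite_zero_cases():
    frame = pd.DataFrame({"a": [1.0, 3.0, 2.0], "b": [10.0, 30.0, 20.0]})
    mask = np.array([True, True, True])
    comp = z_composite(frame, {"a": 1, "b": 1}, mask, restandardize=False)
    # participant exactly at both reference means scores 0
    assert comp.iloc[2] == pytest.approx(0.0, abs=1e-12)
    # symmetric constituents (z=+1, z=-1) cancel
    opposed = pd.DataFrame({"a": [1.0, 3.0, 3.0], "b": [30.0, 10.0, 10.0]})
    comp2 = z_composite(opposed, {"a": 1, "b": 1}, mask, restandardize=False)
    assert comp2.iloc[2] == pytest.approx(0.0, abs=1e-12)


def test_z_composite_signed_hand_value():
    refs = ReferenceStats({"a": (0.0, 1.0, 10), "b": (0.0, 1.0, 10), "c": (0.0, 1.0, 10), "d": (0.0, 1.0, 10)})
    frame = pd.DataFrame({"a": [0.5], "b": [0.5], "c": [0.5], "d": [-0.5]})
    comp = z_composite(frame, {"a": 1, "b": 1, "c": 1, "d": -1}, np.array([True]), refs=refs, restandardize=False)
    assert comp.iloc[0] == pytest.approx(0.5)


def test_z_composite_missing_constituent_propagates():
    frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan], "b": [1.0, 2.0, 3.0, 2.0]})
    mask = np.array([True, True, True, False])
    comp = z_composite(frame, {"a": 1, "b": 1}, mask, restandardize=False)
    assert np.isnan(comp.iloc[3]) and not comp.iloc[:3].isna().any()


def test_reference_normalization_on_cohort(cohort_small):
    """Each z-composite constituent has reference mean 0 and sample SD 1."""
    cu = (cohort_small["diagnosis"] == "CU").to_numpy()
    for col, sign in MTD_SBCZ_CONSTITUENTS.items():
        mean, sd, _ = reference_stats(cohort_small[col].to_numpy(float), cu, name=col)
        z = sign * (cohort_small.loc[cu, col].to_numpy(float) - mean) / sd
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12


def test_sum_identity_holds_cohort_wide(cohort_small):
    sot = cohort_small["sls_t15_total"] + cohort_small["sls_delay"]
    assert (sot == cohort_small["sls_sum_of_trials"]).all()


def test_summary_and_item_ingestion_paths_agree(cohort_small):
    """Scoring pre-computed summary columns reproduces the item-path scores."""
    summary_cols = cohort_small[
        ["diagnosis", "sls_t15_total", "sls_delay", "sls_max_span", "sym", "sym_n_correct"]
    ].copy()
    cu = (summary_cols["diagnosis"] == "CU").to_numpy()
    rescored = score_cohort(summary_cols, reference_mask=cu)
    for col in ["sls_sum_of_trials", "symaw", "mtd_sbcr", "mtd_sbcz"]:
        pd.testing.assert_series_equal(rescored[col], cohort_small[col], check_names=False)
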