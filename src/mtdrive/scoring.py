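"""Scoring of remote cognitive test sessions and composite construction.

The remote screening battery consists of two self-administered tests:

* the Stricker Learning Span (SLS), a computer-adaptive word-list learning
  task with five learning trials (four-choice recognition after each list)
  plus a delayed recognition trial over every word previously presented; and
* the Symbols Test, a processing-speed task of four 12-item trials (48 items)
  in which the primary score SYM is the mean response time in seconds over
  correctly answered items.

From these, two screening battery composites are computed:

* ``MTD-SBCr`` (raw scale): SLS Sum of Trials + SYMaw, where
  ``SYMaw = max(0, (10 - SYM)) * accuracy_weight(n_correct)`` and the
  accuracy weight is a step function of the number of correct Symbols items;
* ``MTD-SBCz`` (z scale): the average of CU-referenced z-scores of SLS
  Maximum Learning Span, SLS Trials 1-5 Total, SLS Delay and SYM (SYM
  sign-flipped so that higher is better), re-standardized to the reference
  (CU) subgroup.

All z-scoring in this package is reference-group z-scoring: the mean and
sample SD are computed on a designated reference subgroup (cognitively
unimpaired participants by default) and applied to the entire sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SLSRawSession",
    "SLSScores",
    "SymbolsSession",
    "SymbolsScores",
    "ReferenceStats",
    "ValidationError",
    "SLS_SPAN_MIN",
    "SLS_SPAN_MAX",
    "SLS_FIRST_SPAN",
    "SYMBOLS_N_ITEMS",
    "SYM_TIME_CEILING",
    "score_sls",
    "accuracy_weight",
    "score_symbols",
    "compute_mtd_sbcr",
    "reference_stats",
    "zscore",
    "z_composite",
    "score_cohort",
    "MTD_SBCZ_CONSTITUENTS",
    "MAYO_PACC_CONSTITUENTS",
    "GLOBAL_Z_CONSTITUENTS",
]

SLS_SPAN_MIN = 2
SLS_SPAN_MAX = 23
SLS_FIRST_SPAN = 8
SYMBOLS_N_ITEMS = 48
#: time in seconds that SYM is subtracted from when forming SYMaw
SYM_TIME_CEILING = 10.0


class ValidationError(ValueError):
    """Raised when a session or table violates a structural invariant."""


# ---------------------------------------------------------------------------
# session records


@dataclass(frozen=True)
class SLSRawSession:
    """Item-count record of one adaptive list-learning session.

    Parameters
    ----------
    trial_spans:
        Number of words presented on each of learning trials 1-5. The first
        trial always presents 8 words; adaptive spans stay within [2, 23].
    trial_correct:
        Words correctly recognized on each learning trial.
    delay_presented:
        Number of unique words presented across trials 1-5 (all are shown
        again on the delay trial); at least ``max(trial_spans)``.
    delay_correct:
        Words correctly recognized on the delay trial.
    """

    trial_spans: tuple[int, ...]
    trial_correct: tuple[int, ...]
    delay_presented: int
    delay_correct: int

    def __post_init__(self) -> None:
        spans = tuple(int(s) for s in self.trial_spans)
        correct = tuple(int(c) for c in self.trial_correct)
        object.__setattr__(self, "trial_spans", spans)
        object.__setattr__(self, "trial_correct", correct)
        if len(spans) != 5 or len(correct) != 5:
            raise ValidationError("trial_spans and trial_correct must have 5 entries")
        if spans[0] != SLS_FIRST_SPAN:
            raise ValidationError(f"trial_spans[0] must be {SLS_FIRST_SPAN}, got {spans[0]}")
        for i, s in enumerate(spans):
            if not (SLS_SPAN_MIN <= s <= SLS_SPAN_MAX):
                raise ValidationError(f"trial_spans[{i}]={s} outside [{SLS_SPAN_MIN}, {SLS_SPAN_MAX}]")
        for i, (c, s) in enumerate(zip(correct, spans)):
            if not (0 <= c <= s):
                raise ValidationError(f"trial_correct[{i}]={c} outside [0, span={s}]")
        if not (0 <= self.delay_correct <= self.delay_presented):
            raise ValidationError(
                f"delay_correct={self.delay_correct} outside [0, delay_presented={self.delay_presented}]"
            )
        if self.delay_presented < max(spans):
            raise ValidationError("delay_presented must be >= max(trial_spans)")


@dataclass(frozen=True)
class SLSScores:
    trials_1_5_total: int
    delay: int
    sum_of_trials: int
    max_learning_span: int


@dataclass(frozen=True)
class SymbolsSession:
    """48-item symbol-matching speed test record (four 12-item trials)."""

    correct: tuple[bool, ...]
    rt_seconds: tuple[float, ...]

    def __post_init__(self) -> None:
        correct = tuple(bool(c) for c in self.correct)
        rt = tuple(float(t) for t in self.rt_seconds)
        object.__setattr__(self, "correct", correct)
        object.__setattr__(self, "rt_seconds", rt)
        if len(correct) != SYMBOLS_N_ITEMS or len(rt) != SYMBOLS_N_ITEMS:
            raise ValidationError(f"Symbols session must have exactly {SYMBOLS_N_ITEMS} items")
        if any(t <= 0 for t in rt):
            raise ValidationError("rt_seconds must be strictly positive")


@dataclass(frozen=True)
class SymbolsScores:
    """Derived Symbols Test scores; ``sym``/``symaw`` are NaN when no item
    was answered correctly (mean RT over an empty set is undefined)."""

    n_correct: int
    sym: float
    accuracy_weight: float
    symaw: float

    @property
    def valid(self) -> bool:
        return not np.isnan(self.sym)


# ---------------------------------------------------------------------------
# scoring operations


def score_sls(session: SLSRawSession) -> SLSScores:
    """Score one SLS session.

    Sum of Trials (the primary outcome) is the number of words correctly
    recognized across learning trials 1-5 plus the delay trial.  Maximum
    learning span is the largest span attained through adaptation on trials
    1-5 (the spans are part of the raw record; this function does not model
    the adaptation itself).
    """
    t15 = int(sum(session.trial_correct))
    delay = int(session.delay_correct)
    return SLSScores(
        trials_1_5_total=t15,
        delay=delay,
        sum_of_trials=t15 + delay,
        max_learning_span=int(max(session.trial_spans)),
    )


# accuracy-weight step function: number of correct Symbols items -> weight
_WEIGHT_EDGES = np.array([35, 42, 43, 44, 45, 46, 47])
_WEIGHT_VALUES = np.array([1.0, 2.0, 3.0, 4.0, 4.25, 4.5, 4.75, 5.0])


def accuracy_weight(n_correct):
    """Accuracy weighting score (1-5) for the Symbols Test.

    Step function of the number of correct items out of 48:
    <35 -> 1; 35-41 -> 2; 42 -> 3; 43 -> 4; 44 -> 4.25; 45 -> 4.5;
    46 -> 4.75; 47-48 -> 5.  Accepts scalars or arrays.
    """
    n = np.asarray(n_correct)
    if np.any((n < 0) | (n > SYMBOLS_N_ITEMS)):
        raise ValidationError(f"n_correct must be in [0, {SYMBOLS_N_ITEMS}]")
    w = _WEIGHT_VALUES[np.searchsorted(_WEIGHT_EDGES, n, side="right")]
    if np.isscalar(n_correct) or np.ndim(n_correct) == 0:
        return float(w)
    return w


def _symaw(sym, weight):
    return np.maximum(0.0, SYM_TIME_CEILING - sym) * weight


def score_symbols(session: SymbolsSession) -> SymbolsScores:
    """Score one Symbols session.

    SYM is the arithmetic mean response time over correct items only.
    SYMaw = (10 - SYM) * accuracy_weight, floored at 0 for SYM >= 10 s.
    With zero correct items SYM is undefined and both SYM and SYMaw are NaN.
    """
    correct = np.asarray(session.correct, dtype=bool)
    rt = np.asarray(session.rt_seconds, dtype=float)
    n_correct = int(correct.sum())
    if n_correct == 0:
        return SymbolsScores(0, float("nan"), accuracy_weight(0), float("nan"))
    sym = float(rt[correct].mean())
    w = accuracy_weight(n_correct)
    return SymbolsScores(n_correct, sym, w, float(_symaw(sym, w)))


def compute_mtd_sbcr(sls: SLSScores | None, symbols: SymbolsScores | None) -> float:
    """Raw-scale screening battery composite: SLS Sum of Trials + SYMaw.

    Missing (None or NaN) constituents yield NaN, never a fabricated 0.
    """
    if sls is None or symbols is None or np.isnan(symbols.symaw):
        return float("nan")
    return float(sls.sum_of_trials + symbols.symaw)


# ---------------------------------------------------------------------------
# reference-group z-scoring


@dataclass(frozen=True)
class ReferenceStats:
    """Per-variable mean / sample SD / n from a designated reference subgroup."""

    stats: Mapping[str, tuple[float, float, int]] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return self.stats[name][0]

    def sd(self, name: str) -> float:
        return self.stats[name][1]

    def n(self, name: str) -> int:
        return self.stats[name][2]

    def __contains__(self, name: str) -> bool:
        return name in self.stats


def reference_stats(values, reference_mask, name: str = "variable") -> tuple[float, float, int]:
    """Mean and sample SD (n-1 denominator) over the reference subgroup only.

    NaNs within the reference subgroup are dropped.  Raises on fewer than two
    usable reference values or zero variance, naming the variable.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(reference_mask, dtype=bool)
    if v.shape != m.shape:
        raise ValidationError(f"{name}: values and reference_mask shapes differ")
    ref = v[m & ~np.isnan(v)]
    if ref.size < 2:
        raise ValidationError(f"{name}: need >= 2 non-missing reference values, got {ref.size}")
    sd = float(ref.std(ddof=1))
    if sd == 0.0:
        raise ValidationError(f"{name}: zero variance in reference subgroup")
    return float(ref.mean()), sd, int(ref.size)


def reference_stats_table(frame: pd.DataFrame, columns: Sequence[str], reference_mask) -> ReferenceStats:
    """ReferenceStats for several columns of a participant table."""
    return ReferenceStats(
        {c: reference_stats(frame[c].to_numpy(dtype=float), reference_mask, name=c) for c in columns}
    )


def zscore(values, ref: tuple[float, float, int] | Sequence[float]):
    """Apply a reference (mean, sd[, n]) z-transform to values."""
    mean, sd = ref[0], ref[1]
    return (np.asarray(values, dtype=float) - mean) / sd


# Composite definitions: constituent column -> sign applied to the raw z.
# SYM and Trail Making Test B are timed (higher = worse) and enter negated.
MTD_SBCZ_CONSTITUENTS: dict[str, int] = {
    "sls_max_span": 1,
    "sls_t15_total": 1,
    "sls_delay": 1,
    "sym": -1,
}
MAYO_PACC_CONSTITUENTS: dict[str, int] = {
    "avlt_sum_of_trials": 1,
    "animal_fluency": 1,
    "trail_making_b": -1,
}
GLOBAL_Z_CONSTITUENTS: dict[str, int] = {
    "avlt_delayed_recall": 1,
    "logical_memory_ii": 1,
    "visual_reproduction_ii": 1,
    "boston_naming": 1,
    "animal_fluency": 1,
    "trail_making_b": -1,
    "digit_symbol_coding": 1,
    "picture_completion": 1,
    "block_design": 1,
}


def z_composite(
    frame: pd.DataFrame,
    signs: Mapping[str, int],
    reference_mask,
    refs: ReferenceStats | None = None,
    restandardize: bool = True,
) -> pd.Series:
    """Average of signed reference-group z-scores over the named columns.

    Each constituent ``x`` contributes ``sign * (x - ref.mean) / ref.sd`` with
    the mean/SD taken on the reference subgroup; the composite is the mean of
    the constituents and is missing whenever any constituent is missing
    (complete-case per composite).  With ``restandardize=True`` (default) the
    averaged composite is itself z-scored to the reference subgroup, so its
    reference-subgroup mean is 0 and sample SD is 1.
    """
    mask = np.asarray(reference_mask, dtype=bool)
    if refs is None:
        refs = reference_stats_table(frame, list(signs), mask)
    zs = []
    for col, sign in signs.items():
        if col not in refs:
            raise ValidationError(f"no reference stats for composite constituent {col!r}")
        zs.append(sign * zscore(frame[col].to_numpy(dtype=float), refs.stats[col]))
    comp = np.vstack(zs).mean(axis=0)  # NaN propagates: missing constituent -> missing composite
    if restandardize:
        comp = zscore(comp, reference_stats(comp, mask, name="composite"))
    return pd.Series(comp, index=frame.index)


# ---------------------------------------------------------------------------
# cohort-level (vectorized) scoring


def score_cohort(frame: pd.DataFrame, reference_mask=None) -> pd.DataFrame:
    """Score a participant table and attach composites.

    Accepts either item-level summary columns produced by the simulator /
    long-format ingestion (``sls_correct_1`` .. ``sls_correct_5``,
    ``sls_span_1`` .. ``sls_span_5``, ``sls_delay_presented``,
    ``sls_delay_correct``, ``sym_n_correct``, ``sym_rt_mean_correct``) or
    pre-computed summary columns (``sls_t15_total``, ``sls_delay``,
    ``sls_max_span``, ``sym``, ``sym_n_correct``); both paths produce
    identical derived variables.

    Returns a copy of ``frame`` with columns ``sls_t15_total``, ``sls_delay``,
    ``sls_sum_of_trials``, ``sls_max_span``, ``sym``, ``sym_n_correct``,
    ``sym_accuracy_weight``, ``symaw``, ``mtd_sbcr`` and, when
    ``reference_mask`` is given, ``mtd_sbcz``.
    """
    out = frame.copy()
    if "sls_correct_1" in out.columns:
        corr = out[[f"sls_correct_{i}" for i in range(1, 6)]].to_numpy(dtype=float)
        spans = out[[f"sls_span_{i}" for i in range(1, 6)]].to_numpy(dtype=float)
        out["sls_t15_total"] = corr.sum(axis=1)
        out["sls_delay"] = out["sls_delay_correct"].astype(float)
        out["sls_max_span"] = spans.max(axis=1)
    elif "sls_t15_total" not in out.columns:
        raise ValidationError("no SLS columns found (need sls_correct_1..5 or sls_t15_total)")
    out["sls_sum_of_trials"] = out["sls_t15_total"] + out["sls_delay"]

    if "sym" not in out.columns:
        if "sym_rt_mean_correct" not in out.columns:
            raise ValidationError("no Symbols columns found (need sym or sym_rt_mean_correct)")
        out["sym"] = out["sym_rt_mean_correct"]
    n_correct = out["sym_n_correct"].to_numpy()
    out["sym_accuracy_weight"] = accuracy_weight(n_correct)
    out.loc[n_correct == 0, "sym"] = np.nan
    out["symaw"] = _symaw(out["sym"].to_numpy(dtype=float), out["sym_accuracy_weight"].to_numpy())
    out["mtd_sbcr"] = out["sls_sum_of_trials"] + out["symaw"]

    if reference_mask is not None:
        out["mtd_sbcz"] = z_composite(out, MTD_SBCZ_CONSTITUENTS, reference_mask)
    return out
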