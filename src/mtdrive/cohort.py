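"""Synthetic cohort generation for the remote-screening validation analyses.

Generates participant cohorts with the statistical structure the downstream
analyses assume: a predominantly cognitively-unimpaired (CU) case mix with
small MCI and dementia fractions, demographics, correlated latent memory and
processing-speed abilities that decline with age, item-level adaptive
list-learning (SLS) and symbol-matching (Symbols Test) sessions, in-person
neuropsychological scores, and imaging biomarkers (amyloid / tau PET SUVRs,
hippocampal and intracranial volume, white-matter hyperintensity volume).

Two properties are engineered rather than emergent:

* CU-subgroup means/SDs of the scored cognitive variables and of the
  biomarkers are calibrated to the validation study's published CU column;
* each biomarker's standardized, covariate-adjusted association with the
  anchor cognitive outcome (the raw screening battery composite, MTD-SBCr)
  equals a configured target in expectation.  The biomarker's log-scale
  signal is built as ``u = rho * y_resid / s + sqrt(1-rho^2) * noise`` where
  ``y_resid`` is the anchor z-outcome residualized on age/sex/education, and
  ``rho`` is solved so that OLS of the z-outcome on the z-biomarker plus
  covariates has the target coefficient.

All randomness flows from one explicitly passed numpy Generator; no global
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .scoring import (
    SLS_FIRST_SPAN,
    SLS_SPAN_MAX,
    SLS_SPAN_MIN,
    SYMBOLS_N_ITEMS,
    SLSRawSession,
    SymbolsSession,
    ValidationError,
    score_cohort,
)

__all__ = [
    "CohortConfig",
    "BiomarkerSpec",
    "generate_cohort",
    "simulate_sls_session",
    "simulate_symbols_session",
    "simulate_biomarkers",
    "DIAGNOSES",
]

DIAGNOSES = ("CU", "MCI", "DEM")

#: chance success rate of four-choice recognition
GUESS_FLOOR = 0.25


@dataclass(frozen=True)
class BiomarkerSpec:
    """Log-scale calibration of one biomarker.

    ``cu_mean``/``cu_sd`` are the natural-scale CU-subgroup targets;
    ``age_slope`` is the per-year slope on the log scale; ``target_beta`` is
    the standardized covariate-adjusted association with the anchor outcome.
    """

    cu_mean: float
    cu_sd: float
    age_slope: float
    target_beta: float

    @property
    def log_sd_total(self) -> float:
        # total log-scale SD implied by the CU coefficient of variation
        return float(np.sqrt(np.log1p((self.cu_sd / self.cu_mean) ** 2)))


def _tri(cu, mci, dem):
    return (float(cu), float(mci), float(dem))


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for cohort generation.

    Per-diagnosis tuples are ordered (CU, MCI, DEM).  Demographic and
    CU-calibration defaults follow the validation study's published cohort
    characteristics (N=684; 94% CU / 5% MCI / 1% dementia).
    """

    n: int = 684
    diagnosis_proportions: tuple[float, float, float] = (0.94, 0.05, 0.01)

    age_mean: tuple[float, float, float] = _tri(69.890, 77.786, 77.786)
    age_sd: tuple[float, float, float] = _tri(11.111, 10.097, 10.097)
    age_range: tuple[float, float] = (45.0, 95.0)
    female_prop: tuple[float, float, float] = _tri(0.495, 0.537, 0.537)
    education_mean: tuple[float, float, float] = _tri(15.719, 14.512, 14.512)
    education_sd: tuple[float, float, float] = _tri(2.335, 2.812, 2.812)
    education_range: tuple[float, float] = (8.0, 20.0)

    # latent memory ability (logit scale of item recognition)
    memory_mean: tuple[float, float, float] = _tri(2.27, 0.66, -0.12)
    memory_sd: tuple[float, float, float] = _tri(0.97, 0.85, 0.85)
    memory_age_slope_per_decade: float = -0.45

    # latent speed: theta is the person's log mean response time (seconds)
    theta_mean: tuple[float, float, float] = _tri(1.095, 1.52, 1.83)
    theta_sd: tuple[float, float, float] = _tri(0.30, 0.38, 0.38)
    theta_age_slope_per_decade: float = 0.08
    memory_speed_corr: float = -0.5  # memory vs theta residual correlation

    # SLS item model
    sls_difficulty_base: float = 0.0
    sls_difficulty_slope: float = 0.02  # per serial position
    sls_delay_shift: float = 0.5  # extra difficulty on the delay trial

    # Symbols item model
    symbols_rt_item_sd: float = 0.35  # within-person log-RT dispersion
    symbols_acc_intercept: float = 3.9  # logit accuracy at CU-average speed
    symbols_acc_slope: float = 0.9  # logit decrease per theta z-unit

    # imaging biomarkers (log-normal SUVRs; HV/WMH handled separately)
    amyloid: BiomarkerSpec = field(
        default_factory=lambda: BiomarkerSpec(1.527, 0.341, 0.008, -0.15)
    )
    tau_meta: BiomarkerSpec = field(
        default_factory=lambda: BiomarkerSpec(1.197, 0.098, 0.002, -0.19)
    )
    tau_ec: BiomarkerSpec = field(
        default_factory=lambda: BiomarkerSpec(1.120, 0.130, 0.003, -0.24)
    )

    icv_mean_male: float = 1.55e6  # mm^3
    icv_mean_female: float = 1.38e6
    icv_sd: float = 1.15e5
    hv_icv_slope: float = 0.003
    hv_intercept_male: float = 2650.0
    hv_intercept_female: float = 2860.0
    hv_age_slope: float = -30.0  # mm^3 per year
    hv_resid_sd: float = 550.0
    hv_target_beta: float = 0.24

    wmh_lnpct_cu_mean: float = -0.680  # ln of percent-of-ICV WMH volume
    wmh_lnpct_cu_sd: float = 0.884
    wmh_age_slope: float = 0.05  # per year, ln-percent scale
    wmh_target_beta: float = -0.19

    def __post_init__(self) -> None:
        p = self.diagnosis_proportions
        if len(p) != 3 or any(x < 0 or x > 1 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValidationError("diagnosis_proportions must be in [0,1] and sum to 1")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for name in ("age_sd", "education_sd", "memory_sd", "theta_sd"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValidationError(f"{name} entries must be > 0")

    def with_targets(self, **targets: float) -> "CohortConfig":
        """Copy of the config with replaced standardized effect targets.

        Keys: ``amyloid``, ``tau_meta``, ``tau_ec``, ``hv``, ``wmh``.
        """
        changes: dict = {}
        for key, beta in targets.items():
            if key in ("amyloid", "tau_meta", "tau_ec"):
                changes[key] = replace(getattr(self, key), target_beta=float(beta))
            elif key == "hv":
                changes["hv_target_beta"] = float(beta)
            elif key == "wmh":
                changes["wmh_target_beta"] = float(beta)
            else:
                raise ValidationError(f"unknown biomarker target {key!r}")
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# item-level test simulation (vectorized over participants)


def _sls_item_probs(memory: np.ndarray, difficulty: np.ndarray) -> np.ndarray:
    """Four-choice recognition: floor 0.25 plus 0.75 x logistic(ability - difficulty)."""
    return GUESS_FLOOR + (1.0 - GUESS_FLOOR) * expit(memory[:, None] - difficulty[None, :])


def _simulate_sls_batch(memory: np.ndarray, rng: np.random.Generator, cfg: CohortConfig):
    """Simulate SLS sessions for all participants at once.

    Adaptive rule per trial (isolated here so alternatives are pluggable):
    all items correct -> span +4; >=75% correct -> +2; >=50% -> unchanged;
    otherwise -2; clamped to [2, 23].  Trial 1 presents 8 words.  Word lists
    are nested (a span-k trial presents the first k words of a fixed pool),
    so the delay trial presents max(trial_spans) unique words.
    """
    n = memory.size
    pos_difficulty = cfg.sls_difficulty_base + cfg.sls_difficulty_slope * np.arange(SLS_SPAN_MAX)
    spans = np.empty((n, 5), dtype=np.int64)
    correct = np.empty((n, 5), dtype=np.int64)
    span = np.full(n, SLS_FIRST_SPAN, dtype=np.int64)
    p = _sls_item_probs(memory, pos_difficulty)
    for t in range(5):
        draws = rng.random((n, SLS_SPAN_MAX))
        mask = np.arange(SLS_SPAN_MAX)[None, :] < span[:, None]
        hits = ((draws < p) & mask).sum(axis=1)
        spans[:, t] = span
        correct[:, t] = hits
        frac = hits / span
        step = np.where(frac >= 1.0, 4, np.where(frac >= 0.75, 2, np.where(frac >= 0.5, 0, -2)))
        if t < 4:
            span = np.clip(span + step, SLS_SPAN_MIN, SLS_SPAN_MAX)
    delay_presented = spans.max(axis=1)
    p_delay = _sls_item_probs(memory, pos_difficulty + cfg.sls_delay_shift)
    draws = rng.random((n, SLS_SPAN_MAX))
    mask = np.arange(SLS_SPAN_MAX)[None, :] < delay_presented[:, None]
    delay_correct = ((draws < p_delay) & mask).sum(axis=1)
    return spans, correct, delay_presented, delay_correct


def _simulate_symbols_batch(theta: np.ndarray, rng: np.random.Generator, cfg: CohortConfig):
    """Simulate Symbols sessions; returns (correct (n,48) bool, rt (n,48))."""
    n = theta.size
    rt = np.exp(theta[:, None] + cfg.symbols_rt_item_sd * rng.standard_normal((n, SYMBOLS_N_ITEMS)))
    theta_z = (theta - cfg.theta_mean[0]) / cfg.theta_sd[0]
    p = expit(cfg.symbols_acc_intercept - cfg.symbols_acc_slope * theta_z)
    correct = rng.random((n, SYMBOLS_N_ITEMS)) < p[:, None]
    return correct, rt


def simulate_sls_session(
    latent_memory: float, rng: np.random.Generator, config: CohortConfig | None = None
) -> SLSRawSession:
    """Simulate one adaptive list-learning session (record-level API)."""
    cfg = config or CohortConfig()
    spans, correct, dp, dc = _simulate_sls_batch(np.array([float(latent_memory)]), rng, cfg)
    return SLSRawSession(
        trial_spans=tuple(spans[0]),
        trial_correct=tuple(correct[0]),
        delay_presented=int(dp[0]),
        delay_correct=int(dc[0]),
    )


def simulate_symbols_session(
    latent_speed: float, rng: np.random.Generator, config: CohortConfig | None = None
) -> SymbolsSession:
    """Simulate one Symbols session.

    ``latent_speed`` is on a CU z-scale with higher = faster/better; it maps
    to the person's log mean response time as
    ``theta = theta_mean_CU - theta_sd_CU * latent_speed``.
    """
    cfg = config or CohortConfig()
    theta = cfg.theta_mean[0] - cfg.theta_sd[0] * float(latent_speed)
    correct, rt = _simulate_symbols_batch(np.array([theta]), rng, cfg)
    return SymbolsSession(correct=tuple(correct[0]), rt_seconds=tuple(rt[0]))


# ---------------------------------------------------------------------------
# biomarker construction


def _solve_rho(target: float, s_c: float, s_f: float, g: float, v_a: float, c_ya: float) -> float:
    """Solve for the mixing weight giving the target standardized coefficient.

    The predictor's linear-scale signal is ``g*u + agepart`` with
    ``u = rho*(y~/s_c) + sqrt(1-rho^2)*w``; both outcome and predictor are
    CU-z-scored before fitting.  Taking expectations over the fresh noise w,
    the partial regression coefficient of the z-outcome on the z-predictor
    given the covariates is

        beta(rho) = rho*(s_f^2/s_c) * s(rho)/g / (rho^2*(s_f/s_c)^2 + 1 - rho^2)
        s(rho)^2  = g^2 + v_a + 2*g*rho*c_ya

    where s_c/s_f are the CU / full-sample SDs of the residualized z-outcome,
    v_a is the CU variance of the predictor's age part and c_ya the CU
    covariance of y~/s_c with the age part (nonzero because residualization
    is full-sample while z-scoring is CU-referenced).
    """
    if target == 0.0:
        return 0.0
    A2 = (s_f / s_c) ** 2

    def f(rho):
        s2 = g * g + v_a + 2.0 * g * rho * c_ya
        beta = (rho * s_f * s_f / s_c) * np.sqrt(s2) / g / (rho * rho * A2 + 1.0 - rho * rho)
        return beta - target

    lo, hi = -0.995, 0.995
    if f(lo) * f(hi) > 0:
        raise ValidationError(f"target standardized effect {target} is unattainable")
    return float(brentq(f, lo, hi, xtol=1e-12))


def _effect_signal(
    target: float,
    y_resid: np.ndarray,
    cu_mask: np.ndarray,
    g: float,
    age_part: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-CU-variance latent signal carrying the target adjusted effect.

    ``age_part`` is the deterministic age contribution to the predictor on
    the same linear scale as ``g * u`` (e.g. slope*(age-70) on the log scale).
    """
    s_c = float(y_resid[cu_mask].std(ddof=1))
    s_f = float(y_resid.std(ddof=1))
    v_a = float(np.var(age_part[cu_mask], ddof=1)) if np.ndim(age_part) else 0.0
    yc = y_resid[cu_mask] / s_c
    ac = age_part[cu_mask] if np.ndim(age_part) else np.zeros_like(yc)
    c_ya = float(np.cov(yc, ac, ddof=1)[0, 1]) if yc.size > 1 else 0.0
    rho = _solve_rho(target, s_c, s_f, g, v_a, c_ya)
    w = rng.standard_normal(y_resid.size)
    return rho * y_resid / s_c + np.sqrt(max(0.0, 1.0 - rho * rho)) * w


def _suvr_g(spec: BiomarkerSpec, cu_age_var: float) -> float:
    """Log-scale noise SD leaving CU total log-SD at the spec target after
    the age slope's contribution."""
    return float(np.sqrt(max(1e-12, spec.log_sd_total**2 - spec.age_slope**2 * cu_age_var)))


def _lognormal_biomarker(
    spec: BiomarkerSpec,
    u: np.ndarray,
    age: np.ndarray,
    cu_age_mean: float,
    g: float,
) -> np.ndarray:
    """Natural-scale biomarker with CU mean/SD matching the spec targets."""
    a = (
        np.log(spec.cu_mean)
        - spec.log_sd_total**2 / 2.0
        - spec.age_slope * (cu_age_mean - 70.0)
    )
    return np.exp(a + spec.age_slope * (age - 70.0) + g * u)


def simulate_biomarkers(
    latent_memory: float,
    latent_speed: float,
    age: float,
    sex: str,
    diagnosis: str,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
    memory_loading: float = 0.3,
    speed_loading: float = 0.2,
    noise_sd: float = 1.0,
) -> dict[str, float]:
    """Record-level biomarker draw (simplified path).

    Uses per-diagnosis locations and direct loadings of the latent abilities
    on the shared pathology signal; the cohort-level generator instead
    calibrates the signal to exact standardized-effect targets.  With all
    loadings, noise and age slopes at zero each SUVR equals its CU median,
    cu_mean * exp(-log_sd_total^2 / 2), since the log-normal mean is matched
    in expectation over the noise rather than per record.
    """
    cfg = config or CohortConfig()
    d = DIAGNOSES.index(diagnosis)
    mem_z = (latent_memory - cfg.memory_mean[0]) / cfg.memory_sd[0]
    u = -memory_loading * mem_z - speed_loading * latent_speed + noise_sd * rng.standard_normal()
    cu_age_var = cfg.age_sd[0] ** 2
    out: dict[str, float] = {}
    dx_shift = {"amyloid": (0.0, 0.15, 0.25), "tau_meta": (0.0, 0.10, 0.20), "tau_ec": (0.0, 0.12, 0.25)}
    for name, spec in (("amyloid", cfg.amyloid), ("tau_meta", cfg.tau_meta), ("tau_ec", cfg.tau_ec)):
        g = _suvr_g(spec, cu_age_var)
        v = _lognormal_biomarker(spec, np.array([u]), np.array([float(age)]), cfg.age_mean[0], g)[0]
        out[f"{name}_suvr"] = float(v * np.exp(dx_shift[name][d]) if (noise_sd or memory_loading or speed_loading) else v)
    female = sex.upper().startswith("F")
    icv = (cfg.icv_mean_female if female else cfg.icv_mean_male) + cfg.icv_sd * rng.standard_normal()
    hv = (
        (cfg.hv_intercept_female if female else cfg.hv_intercept_male)
        + cfg.hv_icv_slope * icv
        + cfg.hv_age_slope * (age - 70.0)
        + cfg.hv_resid_sd * (0.4 * mem_z + noise_sd * rng.standard_normal() * 0.9)
    )
    lnpct = (
        cfg.wmh_lnpct_cu_mean
        + cfg.wmh_age_slope * (age - cfg.age_mean[0])
        + cfg.wmh_lnpct_cu_sd * rng.standard_normal()
    )
    out.update(icv=float(icv), hv=float(hv), wmh=float(np.exp(lnpct) / 100.0 * icv))
    return out


# ---------------------------------------------------------------------------
# cohort generation


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal draw re-sampled into [lo, hi] (simple rejection, then clip)."""
    x = rng.normal(mean, sd, size)
    for _ in range(8):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(np.broadcast_to(mean, x.shape)[bad], np.broadcast_to(sd, x.shape)[bad])
    return np.clip(x, lo, hi)


# in-person neuropsychological tests: (cu_mean, cu_sd, memory loading,
# speed loading, both as correlations; speed loading is on -theta_z so a
# positive entry means faster people score higher)
_INPERSON_TESTS: Mapping[str, tuple[float, float, float, float]] = {
    "avlt_sum_of_trials": (66.979, 17.568, 0.80, 0.10),
    "avlt_delayed_recall": (9.8, 3.4, 0.78, 0.05),
    "logical_memory_ii": (30.0, 6.5, 0.65, 0.10),
    "visual_reproduction_ii": (28.0, 8.0, 0.55, 0.20),
    "boston_naming": (56.5, 2.8, 0.35, 0.15),
    "animal_fluency": (21.0, 5.2, 0.45, 0.30),
    "trail_making_b": (72.472, 34.875, -0.20, -0.62),  # seconds, higher = worse
    "digit_symbol_coding": (52.060, 12.222, 0.15, 0.68),
    "picture_completion": (14.0, 3.2, 0.25, 0.25),
    "block_design": (25.0, 7.5, 0.20, 0.40),
    "stms_total": (35.962, 1.905, 0.55, 0.25),
}


def _inperson_scores(mem_z, fast_z, rng):
    cols = {}
    for name, (mu, sd, rm, rs) in _INPERSON_TESTS.items():
        resid = np.sqrt(max(0.05, 1.0 - rm * rm - rs * rs))
        z = rm * mem_z + rs * fast_z + resid * rng.standard_normal(mem_z.size)
        if name == "trail_making_b":
            # right-skewed completion time; moments preserved on the log scale
            sigma = np.sqrt(np.log1p((sd / mu) ** 2))
            vals = np.exp(np.log(mu) - sigma**2 / 2 - sigma * z)  # worse (low z) -> slower
            vals = np.clip(vals, 15.0, 300.0)
        elif name == "stms_total":
            vals = np.minimum(38.0, np.round(36.6 + 2.2 * z))
            vals = np.maximum(vals, 0.0)
        else:
            vals = mu + sd * z
            vals = np.maximum(vals, 0.0)
        cols[name] = vals
    return cols


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Generate a scored synthetic cohort as one row per participant.

    Returns a DataFrame with identifiers, demographics, diagnosis, latent
    abilities, SLS/Symbols session summaries plus all derived cognitive
    scores (via :func:`mtdrive.scoring.score_cohort`), in-person test scores,
    and imaging biomarker columns (``amyloid_suvr``, ``tau_meta_suvr``,
    ``tau_ec_suvr``, ``hv``, ``icv``, ``wmh`` in mm^3).  Fully reproducible
    for a given config and seed.
    """
    cfg = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.n

    d_idx = rng.choice(3, size=n, p=cfg.diagnosis_proportions)
    pick = lambda tup: np.asarray(tup, dtype=float)[d_idx]  # noqa: E731

    age = _truncated_normal(rng, pick(cfg.age_mean), pick(cfg.age_sd), *cfg.age_range, n)
    female = rng.random(n) < pick(cfg.female_prop)
    education = _truncated_normal(
        rng, pick(cfg.education_mean), pick(cfg.education_sd), *cfg.education_range, n
    )
    education = np.round(education)

    # correlated latent abilities with age decline (age centered per diagnosis
    # so group means stay at their configured values)
    age_c = (age - pick(cfg.age_mean)) / 10.0
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    r = cfg.memory_speed_corr
    memory = pick(cfg.memory_mean) + cfg.memory_age_slope_per_decade * age_c + pick(cfg.memory_sd) * e1
    theta = (
        pick(cfg.theta_mean)
        + cfg.theta_age_slope_per_decade * age_c
        + pick(cfg.theta_sd) * (-r * e1 + np.sqrt(1 - r * r) * e2)
    )

    spans, correct, delay_presented, delay_correct = _simulate_sls_batch(memory, rng, cfg)
    sym_correct, sym_rt = _simulate_symbols_batch(theta, rng, cfg)
    n_correct = sym_correct.sum(axis=1)
    with np.errstate(invalid="ignore"):
        rt_mean_correct = np.where(
            n_correct > 0, (sym_rt * sym_correct).sum(axis=1) / np.maximum(n_correct, 1), np.nan
        )

    frame = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "diagnosis": np.asarray(DIAGNOSES)[d_idx],
            "age": age,
            "sex": np.where(female, "F", "M"),
            "education_years": education,
            "latent_memory": memory,
            "latent_speed": -(theta - cfg.theta_mean[0]) / cfg.theta_sd[0],
            **{f"sls_span_{t+1}": spans[:, t] for t in range(5)},
            **{f"sls_correct_{t+1}": correct[:, t] for t in range(5)},
            "sls_delay_presented": delay_presented,
            "sls_delay_correct": delay_correct,
            "sym_n_correct": n_correct,
            "sym_rt_mean_correct": rt_mean_correct,
        }
    )

    cu = frame["diagnosis"].to_numpy() == "CU"
    frame = score_cohort(frame, reference_mask=cu)

    mem_z = (memory - cfg.memory_mean[0]) / cfg.memory_sd[0]
    fast_z = -(theta - cfg.theta_mean[0]) / cfg.theta_sd[0]
    for col, vals in _inperson_scores(mem_z, fast_z, rng).items():
        frame[col] = vals

    # ---- biomarkers carrying configured standardized adjusted effects ----
    y = frame["mtd_sbcr"].to_numpy(dtype=float)
    ok = ~np.isnan(y)  # zero-correct Symbols sessions have no composite
    mu_cu, sd_cu = y[cu & ok].mean(), y[cu & ok].std(ddof=1)
    y_z = (y - mu_cu) / sd_cu
    C = np.column_stack([np.ones(n), age, female.astype(float), education])
    coef, *_ = np.linalg.lstsq(C[ok], y_z[ok], rcond=None)
    y_resid = np.where(ok, y_z - C @ coef, 0.0)

    cu_age_mean = float(age[cu].mean())
    cu_age_var = float(age[cu].var(ddof=1))

    for name, spec in (("amyloid", cfg.amyloid), ("tau_meta", cfg.tau_meta), ("tau_ec", cfg.tau_ec)):
        g = _suvr_g(spec, cu_age_var)
        u = _effect_signal(spec.target_beta, y_resid, cu, g, spec.age_slope * (age - 70.0), rng)
        frame[f"{name}_suvr"] = _lognormal_biomarker(spec, u, age, cu_age_mean, g)

    icv = np.where(female, cfg.icv_mean_female, cfg.icv_mean_male) + cfg.icv_sd * rng.standard_normal(n)
    hv_age_part = cfg.hv_age_slope * (age - 70.0)
    u_hv = _effect_signal(cfg.hv_target_beta, y_resid, cu, cfg.hv_resid_sd, hv_age_part, rng)
    frame["icv"] = icv
    frame["hv"] = (
        np.where(female, cfg.hv_intercept_female, cfg.hv_intercept_male)
        + cfg.hv_icv_slope * icv
        + hv_age_part
        + cfg.hv_resid_sd * u_hv
    )

    g_w = float(np.sqrt(max(1e-12, cfg.wmh_lnpct_cu_sd**2 - cfg.wmh_age_slope**2 * cu_age_var)))
    wmh_age_part = cfg.wmh_age_slope * (age - cu_age_mean)
    u_w = _effect_signal(cfg.wmh_target_beta, y_resid, cu, g_w, wmh_age_part, rng)
    lnpct = cfg.wmh_lnpct_cu_mean + wmh_age_part + g_w * u_w
    frame["wmh"] = np.exp(lnpct) / 100.0 * icv

    return frame


def export_items_long(frame_or_config, seed: int = 0, n: int | None = None) -> pd.DataFrame:
    """Long-format item-level export (participant_id, test, trial, item,
    correct, rt_seconds) for a freshly simulated small cohort.

    Session simulation is re-run with the given seed; intended for producing
    small ingestion fixtures, not for large cohorts.
    """
    cfg = frame_or_config if isinstance(frame_or_config, CohortConfig) else CohortConfig(n=n or 25)
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(replace(cfg, n=n or cfg.n), rng)
    rng2 = np.random.default_rng(seed + 1)
    rows = []
    for _, row in cohort.iterrows():
        sess = simulate_symbols_session(row["latent_speed"], rng2, cfg)
        for i in range(SYMBOLS_N_ITEMS):
            rows.append(
                (row["participant_id"], "symbols", i // 12 + 1, i % 12 + 1, int(sess.correct[i]), sess.rt_seconds[i])
            )
    return pd.DataFrame(rows, columns=["participant_id", "test", "trial", "item", "correct", "rt_seconds"])
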