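"""Orchestration: simulate -> score -> prepare -> analyze -> report.

Produces table-shaped report bundles mirroring a validation-study layout:

* ``table1``  — per-group descriptives with unadjusted tests and Hedge's g;
* ``table2``  — standardized adjusted associations, composite outcomes x
  biomarkers;
* ``table3``  — the same for cognitive subtest outcomes;
* ``table4``  — Spearman correlations by diagnostic group;
* ``manifest`` — machine-readable provenance (config, seed, versions, row
  counts, exclusions) from which every report cell is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    adjusted_group_difference,
    fit_adjusted_association,
    group_compare,
    hedges_g,
    hedges_g_from_summary,
    spearman,
)
from .biomarkers import PREPARED_COLUMNS, prepare_biomarkers
from .cohort import CohortConfig, generate_cohort
from .published import GroupSummaryRow
from .scoring import (
    GLOBAL_Z_CONSTITUENTS,
    MAYO_PACC_CONSTITUENTS,
    SYMBOLS_N_ITEMS,
    ValidationError,
    score_cohort,
    z_composite,
)

log = logging.getLogger("mtdrive")

COMPOSITE_OUTCOMES = ["mtd_sbcr", "mtd_sbcz", "mayo_pacc", "global_z", "stms_total"]
SUBTEST_OUTCOMES = [
    "sls_sum_of_trials",
    "sls_max_span",
    "sls_t15_total",
    "sls_delay",
    "avlt_sum_of_trials",
    "sym",
    "symaw",
    "trail_making_b",
    "digit_symbol_coding",
]
BIOMARKER_PREDICTORS = ["amyloid_z", "tau_meta_z", "tau_ec_z", "hv_adj_z", "wmh_pct_ln_z"]
TABLE1_CONTINUOUS = [
    "age",
    "education_years",
    "mtd_sbcr",
    "mtd_sbcz",
    "sls_sum_of_trials",
    "sym",
    "symaw",
    "mayo_pacc",
    "global_z",
    "avlt_sum_of_trials",
    "trail_making_b",
    "digit_symbol_coding",
    "stms_total",
    "amyloid_suvr",
    "tau_meta_suvr",
    "tau_ec_suvr",
    "hv_adj_z",
    "wmh_pct_ln",
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_csv: str | None = None  # when set, read participants instead of simulating
    reference_diagnosis: str = "CU"
    outcomes: Sequence[str] = tuple(COMPOSITE_OUTCOMES)
    subtests: Sequence[str] = tuple(SUBTEST_OUTCOMES)
    biomarkers: Sequence[str] = tuple(BIOMARKER_PREDICTORS)
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], Mapping):
            d["cohort"] = CohortConfig(**d["cohort"])
        return cls(**d)


# ---------------------------------------------------------------------------
# input validation

# column -> (min, max) permissible range; None disables a bound
_DATA_DICTIONARY: dict[str, tuple[float | None, float | None]] = {
    "age": (18, 110),
    "education_years": (0, 30),
    "sym_n_correct": (0, SYMBOLS_N_ITEMS),
    "sym_rt_mean_correct": (0, None),
    "rt_seconds": (0, None),
    "sls_delay_correct": (0, None),
    "sls_delay_presented": (2, None),
    **{f"sls_span_{i}": (2, 23) for i in range(1, 6)},
    **{f"sls_correct_{i}": (0, 23) for i in range(1, 6)},
}
_EXCLUSIVE_MIN = {"sym_rt_mean_correct", "rt_seconds"}


def validate_input(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column range checks against the data dictionary.

    Returns a tidy violation table (row, column, value, message); never
    mutates the input.  Cross-column checks: trial correct counts cannot
    exceed the trial span; delay correct cannot exceed delay presented.
    """
    rows = []

    def flag(idx, col, val, msg):
        rows.append({"row": int(idx), "column": col, "value": val, "message": msg})

    for col, (lo, hi) in _DATA_DICTIONARY.items():
        if col not in table.columns:
            continue
        v = pd.to_numeric(table[col], errors="coerce")
        bad_lo = (v < lo) | ((v <= lo) if col in _EXCLUSIVE_MIN else False) if lo is not None else False
        bad_hi = (v > hi) if hi is not None else False
        for idx in table.index[(bad_lo | bad_hi).fillna(False)]:
            flag(idx, col, table.loc[idx, col], f"outside permissible range [{lo}, {hi}]")
    for i in range(1, 6):
        s, c = f"sls_span_{i}", f"sls_correct_{i}"
        if s in table.columns and c in table.columns:
            bad = pd.to_numeric(table[c], errors="coerce") > pd.to_numeric(table[s], errors="coerce")
            for idx in table.index[bad.fillna(False)]:
                flag(idx, c, table.loc[idx, c], f"exceeds {s}={table.loc[idx, s]}")
    if {"sls_delay_correct", "sls_delay_presented"} <= set(table.columns):
        bad = pd.to_numeric(table["sls_delay_correct"], errors="coerce") > pd.to_numeric(
            table["sls_delay_presented"], errors="coerce"
        )
        for idx in table.index[bad.fillna(False)]:
            flag(idx, "sls_delay_correct", table.loc[idx, "sls_delay_correct"], "exceeds sls_delay_presented")
    return pd.DataFrame(rows, columns=["row", "column", "value", "message"])


# ---------------------------------------------------------------------------
# report tables


def _impairment_groups(frame: pd.DataFrame, reference_diagnosis: str) -> pd.Series:
    dx = frame["diagnosis"].astype(str)
    return pd.Series(np.where(dx == reference_diagnosis, "CU", "MCI/DEM"), index=frame.index)


def table1_descriptives(frame: pd.DataFrame, variables: Sequence[str], group: pd.Series) -> pd.DataFrame:
    """Per-group mean (SD) with t-test p, covariate-adjusted p and Hedge's g."""
    rows = []
    g1 = group == "CU"
    g2 = group == "MCI/DEM"
    for var in variables:
        if var not in frame.columns:
            log.warning("table1: column %s absent, skipped", var)
            continue
        v = frame[var].to_numpy(dtype=float)
        x1, x2 = v[g1.to_numpy()], v[g2.to_numpy()]
        x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
        cmp_t = group_compare(v, group, kind="t")
        es = hedges_g(x1, x2)
        try:
            adj = adjusted_group_difference(
                v, group, frame["age"], frame["sex"], frame["education_years"]
            )
            adj_p = adj.p
        except ValidationError:
            adj_p = np.nan
        rows.append(
            {
                "variable": var,
                "cu_n": x1.size,
                "cu_mean": x1.mean(),
                "cu_sd": x1.std(ddof=1),
                "imp_n": x2.size,
                "imp_mean": x2.mean(),
                "imp_sd": x2.std(ddof=1),
                "test": cmp_t.test_name,
                "p": cmp_t.p,
                "adj_p": adj_p,
                "g": es.g,
                "g_ci_low": es.ci_low,
                "g_ci_high": es.ci_high,
            }
        )
    # categorical row: sex by group (chi-square)
    counts = pd.crosstab(frame["sex"], group).reindex(columns=["CU", "MCI/DEM"]).fillna(0)
    if counts.shape[0] == 2:
        chi = group_compare(counts.to_numpy(), kind="chi-square")
        rows.append({"variable": "sex_female", "test": chi.test_name, "p": chi.p})
    return pd.DataFrame(rows)


def association_table(
    frame: pd.DataFrame, outcomes: Sequence[str], predictors: Sequence[str], reference_mask
) -> pd.DataFrame:
    """Tidy standardized adjusted estimates for each outcome x biomarker."""
    rows = []
    for outcome in outcomes:
        if outcome not in frame.columns:
            log.warning("association table: outcome %s absent, skipped", outcome)
            continue
        for pred in predictors:
            if pred not in frame.columns:
                log.warning("association table: predictor %s absent, skipped", pred)
                continue
            try:
                res = fit_adjusted_association(
                    frame[outcome], frame[pred], frame["age"], frame["sex"],
                    frame["education_years"], reference_mask,
                )
            except ValidationError as exc:
                log.warning("association %s ~ %s skipped: %s", outcome, pred, exc)
                continue
            rows.append(
                {
                    "outcome": outcome,
                    "biomarker": pred,
                    "estimate": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def spearman_table(
    frame: pd.DataFrame, outcomes: Sequence[str], predictors: Sequence[str], group: pd.Series
) -> pd.DataFrame:
    """Spearman rho within each diagnostic group for outcome x biomarker."""
    rows = []
    for outcome in outcomes:
        for pred in predictors:
            if outcome not in frame.columns or pred not in frame.columns:
                continue
            for level in ["CU", "MCI/DEM"]:
                sel = (group == level).to_numpy()
                x = frame.loc[sel, pred].to_numpy(dtype=float)
                y = frame.loc[sel, outcome].to_numpy(dtype=float)
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3:
                    continue
                rho, p = spearman(x[ok], y[ok])
                rows.append(
                    {"outcome": outcome, "biomarker": pred, "group": level, "rho": rho, "p": p, "n": int(ok.sum())}
                )
    return pd.DataFrame(rows)


def effect_sizes_from_summary_table(
    rows: Mapping[str, GroupSummaryRow], n1: int, n2: int
) -> pd.DataFrame:
    """Summary-mode report: Hedge's g (CI) recomputed from printed per-group
    means/SDs for every variable in ``rows``."""
    out = []
    for name, r in rows.items():
        es = hedges_g_from_summary(r.cu_mean, r.cu_sd, n1, r.imp_mean, r.imp_sd, n2)
        out.append(
            {
                "variable": name,
                "g": es.g,
                "ci_low": es.ci_low,
                "ci_high": es.ci_high,
                "published_g": r.g,
                "published_ci_low": r.ci[0],
                "published_ci_high": r.ci[1],
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# end-to-end run


def attach_composites(frame: pd.DataFrame, reference_mask) -> pd.DataFrame:
    """Attach the in-person z-composites where their constituents exist."""
    out = frame.copy()
    for name, signs in (("mayo_pacc", MAYO_PACC_CONSTITUENTS), ("global_z", GLOBAL_Z_CONSTITUENTS)):
        if set(signs) <= set(out.columns):
            out[name] = z_composite(out, signs, reference_mask)
        else:
            missing = sorted(set(signs) - set(out.columns))
            log.warning("%s not computed; missing constituents: %s", name, missing)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full pipeline and return (and optionally write) the report
    bundle: table1..table4 DataFrames plus the JSON-able manifest."""
    if config.input_csv is not None:
        frame = pd.read_csv(config.input_csv)
        violations = validate_input(frame)
        n_excluded = violations["row"].nunique() if len(violations) else 0
        if n_excluded:
            log.warning("excluding %d row(s) failing validation", n_excluded)
            frame = frame.drop(index=violations["row"].unique())
        cu = (frame["diagnosis"].astype(str) == config.reference_diagnosis).to_numpy()
        frame = score_cohort(frame, reference_mask=cu)
    else:
        frame = generate_cohort(config.cohort, seed=config.seed)
        violations = validate_input(frame)
        n_excluded = 0
        cu = (frame["diagnosis"].astype(str) == config.reference_diagnosis).to_numpy()
    if cu.sum() == 0:
        raise ValidationError("reference group is empty")

    frame = attach_composites(frame, cu)
    frame = prepare_biomarkers(frame, cu)
    group = _impairment_groups(frame, config.reference_diagnosis)

    t1_vars = [v for v in TABLE1_CONTINUOUS if v in frame.columns]
    bundle: dict[str, Any] = {
        "participants": frame,
        "table1": table1_descriptives(frame, t1_vars, group),
        "table2": association_table(frame, config.outcomes, config.biomarkers, cu),
        "table3": association_table(frame, config.subtests, config.biomarkers, cu),
        "table4": spearman_table(
            frame, list(config.outcomes) + list(config.subtests), config.biomarkers, group
        ),
    }
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "n_rows": int(len(frame)),
        "n_reference": int(cu.sum()),
        "n_excluded": int(n_excluded),
        "group_counts": group.value_counts().to_dict(),
        "config": _config_to_dict(config),
        "prepared_columns": [c for c in PREPARED_COLUMNS if c in frame.columns],
    }
    bundle["manifest"] = manifest

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("table1", "table2", "table3", "table4"):
            bundle[name].to_csv(outdir / f"{name}.csv", index=False)
        frame.to_csv(outdir / "participants.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return bundle


def _config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
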