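"""Imaging-biomarker transformations applied before analysis.

PET SUVRs (amyloid meta-ROI, tau meta-ROI, tau entorhinal-cortex ROI) are
natural-log transformed and z-scored against the reference (CU) subgroup.
Hippocampal volume is adjusted for head size by residualizing on intracranial
volume with sex-specific regression lines fit on the reference subgroup, and
the residuals are z-scored (residuals are signed, so no log step applies).
White-matter hyperintensity volume is expressed as a percentage of
intracranial volume, natural-log transformed, and z-scored.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .scoring import ValidationError, reference_stats, zscore

__all__ = ["ln_z", "adjust_hv_icv", "wmh_percent_ln", "prepare_biomarkers"]


def ln_z(values, reference_mask, name: str = "biomarker") -> np.ndarray:
    """Natural log, then reference-group z-score of the logged values.

    Non-positive values are set to missing with a warning (per record); they
    never enter the reference statistics.
    """
    v = np.asarray(values, dtype=float).copy()
    bad = ~np.isnan(v) & (v <= 0)
    if bad.any():
        warnings.warn(f"{name}: {int(bad.sum())} non-positive value(s) set to missing")
        v[bad] = np.nan
    logged = np.log(v)
    return zscore(logged, reference_stats(logged, reference_mask, name=f"ln({name})"))


def adjust_hv_icv(hv, icv, sex, reference_mask, min_reference: int = 3):
    """Head-size-adjusted hippocampal volume z-score.

    Within each sex, a least-squares line HV ~ ICV is fit on the reference
    subgroup and applied to all records of that sex; the residual
    (observed - predicted) is then z-scored against the reference subgroup.
    Records with unknown sex are missing.  Returns (residuals, z).
    """
    hv = np.asarray(hv, dtype=float)
    icv = np.asarray(icv, dtype=float)
    sex = np.asarray(sex, dtype=object)
    mask = np.asarray(reference_mask, dtype=bool)
    resid = np.full(hv.shape, np.nan)
    known = pd.Series(sex).isin(["F", "M"]).to_numpy()
    if (~known).any():
        warnings.warn(f"hippocampal volume: {int((~known).sum())} record(s) with unknown sex set to missing")
    for s in ("F", "M"):
        in_sex = known & (sex == s)
        if not in_sex.any():
            continue
        ref = in_sex & mask & ~np.isnan(hv) & ~np.isnan(icv)
        if ref.sum() < min_reference:
            raise ValidationError(f"adjust_hv_icv: fewer than {min_reference} reference records for sex={s}")
        X = np.column_stack([np.ones(ref.sum()), icv[ref]])
        coef, *_ = np.linalg.lstsq(X, hv[ref], rcond=None)
        resid[in_sex] = hv[in_sex] - (coef[0] + coef[1] * icv[in_sex])
    z = zscore(resid, reference_stats(resid, mask, name="hv_adjusted"))
    return resid, z


def wmh_percent_ln(wmh, icv, reference_mask, floor: float = 1e-6):
    """ln of WMH volume as a percentage of intracranial volume, plus its
    reference-group z-score.  Returns (ln_percent, z).

    Records with WMH >= ICV or WMH <= 0 are missing with a warning; percent
    values below ``floor`` are flagged (set missing) as numerically degenerate.
    """
    wmh = np.asarray(wmh, dtype=float)
    icv = np.asarray(icv, dtype=float)
    pct = 100.0 * wmh / icv
    bad = ~np.isnan(pct) & ((wmh <= 0) | (wmh >= icv))
    tiny = ~np.isnan(pct) & ~bad & (pct < floor)
    if bad.any():
        warnings.warn(f"WMH: {int(bad.sum())} record(s) with WMH outside (0, ICV) set to missing")
    if tiny.any():
        warnings.warn(f"WMH: {int(tiny.sum())} record(s) below the percent floor set to missing")
    pct[bad | tiny] = np.nan
    ln_pct = np.log(pct)
    z = zscore(ln_pct, reference_stats(ln_pct, reference_mask, name="wmh_pct_ln"))
    return ln_pct, z


#: raw column -> prepared z column for the three log-normal SUVRs
SUVR_COLUMNS = {
    "amyloid_suvr": "amyloid_z",
    "tau_meta_suvr": "tau_meta_z",
    "tau_ec_suvr": "tau_ec_z",
}

PREPARED_COLUMNS = ["amyloid_z", "tau_meta_z", "tau_ec_z", "hv_adj_z", "wmh_pct_ln", "wmh_pct_ln_z"]


def prepare_biomarkers(frame: pd.DataFrame, reference_mask) -> pd.DataFrame:
    """Attach prepared biomarker columns to a participant table.

    Requires raw columns ``amyloid_suvr``, ``tau_meta_suvr``, ``tau_ec_suvr``,
    ``hv``, ``icv``, ``wmh`` and a ``sex`` column with values F/M.
    """
    out = frame.copy()
    mask = np.asarray(reference_mask, dtype=bool)
    for raw, prepared in SUVR_COLUMNS.items():
        out[prepared] = ln_z(out[raw].to_numpy(dtype=float), mask, name=raw)
    _, out["hv_adj_z"] = adjust_hv_icv(
        out["hv"].to_numpy(dtype=float), out["icv"].to_numpy(dtype=float), out["sex"].to_numpy(), mask
    )
    out["wmh_pct_ln"], out["wmh_pct_ln_z"] = wmh_percent_ln(
        out["wmh"].to_numpy(dtype=float), out["icv"].to_numpy(dtype=float), mask
    )
    return out
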