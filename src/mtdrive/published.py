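"""Published summary statistics of the remote-screening validation cohort.

These are the printed per-group descriptive statistics (mean, SD) of the
validation study cohort (N=684: 643 cognitively unimpaired, 41 MCI/dementia),
used as inputs for summary-statistic effect-size reproduction and as
calibration targets for the synthetic cohort generator.  ``g``/``ci`` are the
printed Hedge's g effect sizes (MCI/dementia minus CU) with 95% CIs.

``n_var`` is the printed per-variable analysis n; the CU/impaired split of
the per-variable missingness is not published, so recomputed effect sizes
use the full group sizes (643/41).
"""

from __future__ import annotations

from dataclasses import dataclass

N_CU = 643
N_IMPAIRED = 41
N_TOTAL = 684

FULL_SAMPLE_AGE_MEAN = 70.363


@dataclass(frozen=True)
class GroupSummaryRow:
    full_mean: float
    full_sd: float
    cu_mean: float
    cu_sd: float
    imp_mean: float
    imp_sd: float
    g: float
    ci: tuple[float, float]
    n_var: int = N_TOTAL


TABLE1: dict[str, GroupSummaryRow] = {
    # demographics
    "age": GroupSummaryRow(70.363, 11.204, 69.890, 11.111, 77.786, 10.097, 0.71, (0.40, 1.03)),
    "education_years": GroupSummaryRow(15.646, 2.381, 15.719, 2.335, 14.512, 2.812, -0.51, (-0.83, -0.19)),
    # remote screening battery
    "mtd_sbcr": GroupSummaryRow(105.221, 22.675, 107.653, 20.171, 66.314, 25.200, -2.02, (-2.35, -1.68), 680),
    "mtd_sbcz": GroupSummaryRow(-0.121, 1.124, 0.000, 1.000, -1.830, 1.057, -2.10, (-2.44, -1.76), 680),
    "sls_sum_of_trials": GroupSummaryRow(74.023, 18.747, 75.833, 17.174, 45.025, 19.265, -1.78, (-2.11, -1.45), 681),
    "sym": GroupSummaryRow(3.472, 1.313, 3.337, 1.067, 5.623, 2.513, 1.91, (1.57, 2.24), 681),
    "symaw": GroupSummaryRow(31.219, 6.849, 31.839, 6.065, 21.289, 10.338, -1.65, (-1.98, -1.32), 681),
    # in-person cognition
    "mayo_pacc": GroupSummaryRow(-0.123, 1.144, 0.000, 1.000, -2.356, 1.368, -2.28, (-2.64, -1.92), 661),
    "global_z": GroupSummaryRow(-0.111, 1.132, 0.000, 1.000, -2.694, 0.923, -2.70, (-3.12, -2.28), 629),
    "avlt_sum_of_trials": GroupSummaryRow(65.177, 18.759, 66.979, 17.568, 35.289, 11.130, -1.83, (-2.18, -1.49), 668),
    "trail_making_b": GroupSummaryRow(77.166, 43.657, 72.472, 34.875, 157.351, 83.977, 2.17, (1.82, 2.52), 669),
    "digit_symbol_coding": GroupSummaryRow(51.299, 12.650, 52.060, 12.222, 34.179, 9.843, -1.47, (-1.86, -1.09), 658),
    "stms_total": GroupSummaryRow(35.581, 2.624, 35.962, 1.905, 29.500, 4.449, -3.02, (-3.38, -2.67), 677),
    # imaging
    "amyloid_suvr": GroupSummaryRow(1.549, 0.375, 1.527, 0.341, 1.890, 0.637, 0.99, (0.67, 1.32), 670),
    "tau_meta_suvr": GroupSummaryRow(1.209, 0.140, 1.197, 0.098, 1.389, 0.374, 1.45, (1.13, 1.78), 667),
    "tau_ec_suvr": GroupSummaryRow(1.134, 0.159, 1.120, 0.130, 1.360, 0.322, 1.62, (1.29, 1.95), 667),
    "hv_external_z": GroupSummaryRow(-0.343, 0.686, -0.283, 0.611, -1.292, 1.023, -1.57, (-1.90, -1.24), 680),
    "wmh_pct_ln": GroupSummaryRow(-0.645, 0.904, -0.680, 0.884, -0.111, 1.047, 0.64, (0.32, 0.95), 665),
}

#: published standardized adjusted associations (composite-outcome table),
#: anchor (raw screening composite) row: biomarker -> mean estimate
COMPOSITE_EFFECTS_MTD_SBCR: dict[str, float] = {
    "amyloid": -0.15,
    "tau_meta": -0.19,
    "tau_ec": -0.24,
    "hv": 0.24,
    "wmh": -0.19,
}
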