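# Methods note

## Composite scoring

**SLS.** Each session records five learning trials (list length a.k.a. span,
and items correctly recognized) plus a delayed recognition trial that
re-presents the longest list reached. Derived scores: Trials 1–5 Total,
Delay, Sum of Trials (= Trials 1–5 Total + Delay), Max Learning Span.
Session records are validated on construction: spans within [2, 23], trial 1
span = 8, correct counts bounded by spans, delay presented ≥ max span.

**Symbols.** 48 items; SYM is the mean response time in seconds over
correctly answered items (missing if no item is correct, rather than 0 —
a participant with no correct responses has no defined speed). The accuracy
weight is a step function of items correct: <35 → 1, 35–41 → 2, 42 → 3,
43 → 4, 44 → 4.25, 45 → 4.5, 46 → 4.75, 47–48 → 5.
SYMaw = max(0, 10 − SYM) × weight, so responses at or beyond the 10 s
ceiling floor at 0.

**Composites.** MTD-SBCr = SLS Sum of Trials + SYMaw (raw units).
MTD-SBCz = mean of CU-referenced z-scores of SLS Max Span, SLS Trials 1–5
Total, SLS Delay and SYM with its sign flipped, then re-standardized so the
CU subgroup has mean 0 and SD 1 (the published descriptive table prints
CU 0.000 (1.000) for this composite, which identifies the re-standardized
variant). The reference SD is the sample SD (ddof = 1). The in-person
Mayo-PACC and global-cognition composites are generic z-composites over
their constituent columns with the same convention.

## Synthetic cohort

Diagnoses are drawn at configured proportions (default 0.94 / 0.05 / 0.01
CU / MCI / dementia); age, education and sex come from per-diagnosis
distributions matched to the published demographic table.

**SLS simulation.** Each participant has a latent memory ability. Item-level
recognition follows a four-alternative guessing-floor model,
P(correct) = 0.25 + 0.75·logistic(ability − item difficulty), with
difficulty increasing in list position and an extra shift for the delay
trial. The adaptive rule, applied to the fraction correct on the previous
trial: all correct → span +4; ≥ 0.75 → +2; ≥ 0.5 → unchanged; else −2;
clamped to [2, 23]. *This departs from a literal ±1 adaptation rule: with
trial 1 fixed at 8 and only four adaptation steps, ±1 cannot reach the
documented span ceiling of 23 by trial 5, nor produce the published CU mean
Sum of Trials (≈ 76, above the ±1 rule's attainable maximum). The larger
steps reproduce both the documented span range and the published CU score
distribution.* Word lists are nested, so the delay trial presents exactly
the longest list reached.

**Symbols simulation.** Per-item response times are log-normal around a
per-person speed parameter drawn from per-diagnosis distributions; item
accuracy is Bernoulli with logit linear in standardized slowness
(calibrated intercept 3.9, slope −0.9), which reproduces the published CU
means of SYM (≈ 3.34 s) and SYMaw.

**Biomarkers with known effect sizes.** For each biomarker the generator
builds a pathology signal u = ρ·ỹ/s + √(1−ρ²)·w, where ỹ is the
covariate-residualized (age, sex, education; full sample) CU-z-scored
MTD-SBCr and w is independent noise. ρ is solved numerically (Brent's
method) so that the covariate-adjusted standardized regression of MTD-SBCr
on the biomarker equals the configured target β exactly in expectation; the
solution accounts for the CU-subgroup covariance between the residualized
anchor and the biomarker's age component (residualization is full-sample
while z-scoring is CU-referenced, so this cross-term does not vanish).
PET SUVRs are log-normal with CU mean/SD matched to the published table in
expectation plus a per-decade age slope; hippocampal volume is linear in
ICV, age and u with a sex-specific intercept; WMH is generated on the
ln(percent-of-ICV) scale. The MTD-SBCr composite is the single anchor for
the configured effects — one scalar biomarker cannot carry exact configured
effects on several correlated outcomes simultaneously; other outcomes'
associations emerge through their correlation with the anchor.

## Neuroimaging variable preparation

- PET SUVRs: natural log, then CU-referenced z (`ln_z`). Non-positive
  values become missing with a warning.
- Hippocampal volume: within each sex, OLS of HV on ICV fit in the CU
  subgroup, applied to all records of that sex; the residual is CU-z-scored.
  Strata absent from the data are skipped; a present stratum with fewer than
  3 CU records is an error; unknown sex is missing with a warning.
- WMH: 100·WMH/ICV, natural log, CU-referenced z. WMH outside (0, ICV) or
  percent values below 1e-6 become missing with a warning.

## Statistical battery

- **Hedge's g**: pooled SD with (n₁−1, n₂−1) weights, small-sample
  correction J = 1 − 3/(4·df − 1), df = n₁+n₂−2;
  SE = √((n₁+n₂)/(n₁n₂) + g²/(2·df)); 95% CI = g ± 1.96·SE. Computable from
  raw data or from printed per-group summary statistics; the raw path calls
  the summary path so the two agree exactly.
- **Adjusted associations**: OLS of the CU-z-scored outcome on the
  CU-z-scored biomarker plus age, sex (F = 1) and education; complete-case
  per model; t-based CI. Group differences use the same design with a group
  indicator in place of the z-scored predictor.
- **Spearman** (scipy, average ranks for ties) overall and within
  diagnostic group; **t / chi-square (no continuity correction) / Fisher
  exact** for unadjusted group comparisons.

## Verification strategy

Expected values in the test suite were derived before implementation; no
expected value was invented to match observed output. Each oracle is either
an independent brute-force implementation (rank-Pearson Spearman, exhaustive hypergeometric Fisher),
an external library (pingouin for Hedge's g), published printed values fed
through the summary-statistic path, or an exact structural identity
(reference-group mean 0 / SD 1; sum identities; affine invariance).
Monte-Carlo tests (CI coverage ≥ 93/100 at β = −0.20, type-I error within
[0.03, 0.07] over 1000 replicates) run against cohorts whose true effect is
known by construction.
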