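# mtdrive

Scoring, synthetic-cohort simulation and biomarker-association analysis for
the **Mayo Test Drive (MTD)** remote cognitive screening battery.

MTD is a brief, self-administered web-based battery comprising the
**Stricker Learning Span (SLS)**, a computer-adaptive word-list learning test
(five learning trials plus a delayed recognition trial), and the
**Symbols Test**, a 48-item speeded symbol-matching test. This package
implements the battery's composite scores, a calibrated synthetic cohort that
stands in for the restricted clinical study data, the neuroimaging variable
derivations (amyloid and tau PET SUVRs, hippocampal volume, white-matter
hyperintensities), and the statistical battery used to relate the cognitive
scores to those biomarkers.

## Scores implemented

| Score | Definition |
|---|---|
| SLS Sum of Trials | correct items on trials 1–5 plus the delay trial |
| SLS Max Span | largest list length presented across learning trials |
| SYM | mean response time (s) over correctly answered Symbols items |
| SYMaw | `max(0, 10 − SYM) ×` accuracy weight (step function of items correct, 1–5) |
| MTD-SBCr | raw screening composite: SLS Sum of Trials + SYMaw |
| MTD-SBCz | z composite: mean of CU-referenced z-scores of SLS Max Span, SLS Trials 1–5, SLS Delay and −SYM, re-standardized to the CU subgroup |

All z-scoring is **reference-group z-scoring**: means and SDs are computed in
a designated reference subgroup (cognitively unimpaired, CU) and applied to
everyone, so impairment shows up as negative z even though the reference
group itself is centered at 0 with SD 1.

The accuracy weight is a step function of the number of Symbols items
correct (0–48): `<35 → 1`, `35–41 → 2`, `42 → 3`, `43 → 4`, `44 → 4.25`,
`45 → 4.5`, `46 → 4.75`, `47–48 → 5`.

## Worked example

Scoring one participant's session:

```python
from mtdrive.scoring import SLSRawSession, SymbolsSession, score_sls, score_symbols, compute_mtd_sbcr

sls = score_sls(SLSRawSession(
    trial_spans=(8, 9, 10, 11, 12),     # adaptive list lengths, trial 1 always 8
    trial_correct=(7, 9, 9, 11, 12),
    delay_presented=12,                 # delay presents the longest list reached
    delay_correct=11,
))
print("SLS  trials 1-5 =", sls.trials_1_5_total,
      "| delay =", sls.delay,
      "| sum of trials =", sls.sum_of_trials,
      "| max span =", sls.max_learning_span)

sym = score_symbols(SymbolsSession(
    correct=(True,) * 44 + (False,) * 4,
    rt_seconds=(2.8,) * 44 + (6.0,) * 4,
))
print("SYM  =", round(sym.sym, 2), "s | n correct =", sym.n_correct,
      "| weight =", sym.accuracy_weight, "| SYMaw =", round(sym.symaw, 2))

print("MTD-SBCr =", compute_mtd_sbcr(sls, sym))
```

Output:

```
SLS  trials 1-5 = 48 | delay = 11 | sum of trials = 59 | max span = 12
SYM  = 2.8 s | n correct = 44 | weight = 4.25 | SYMaw = 30.6
MTD-SBCr = 89.6
```

Cohort-level use goes through the CLI:

```bash
mtdrive simulate --n 684 --seed 0 --out cohort.csv   # synthetic participants
mtdrive validate cohort.csv                          # data-dictionary checks
mtdrive score cohort.csv --out scored.csv            # composites, CU-referenced
mtdrive report --out report/                         # all four report tables + manifest
```

or the numbered drivers in `analysis/` (`01_simulate_cohort.py` …
`06_full_report.py`), which write to `results/`.

## Synthetic cohort

The real study cohort (Mayo Clinic Study of Aging / Alzheimer's Disease
Research Center participants) is not distributable, so `mtdrive.cohort`
simulates one: a case mix of ~94% CU, ~5% MCI, ~1% dementia with demographics,
item-level SLS sessions from a latent-ability adaptive-testing model,
log-normal Symbols response times, correlated in-person neuropsychological
scores, and imaging biomarkers constructed so that (a) CU-subgroup means and
SDs match the published descriptive table in expectation and (b) the
covariate-adjusted standardized association between each biomarker and the
MTD-SBCr composite equals a configured target exactly in expectation —
so parameter-recovery tests have a known truth.

## Statistics

`mtdrive.association` provides Hedge's g (bias-corrected standardized mean
difference) with a normal-approximation CI, computable from raw data or
directly from printed per-group summary statistics (both paths agree to
1e-12); covariate-adjusted standardized linear models (outcome and predictor
CU-z-scored, adjusted for age, sex, education); Spearman correlations by
diagnostic group; and unadjusted t / chi-square / Fisher exact group tests.

As a check against the published study, feeding its printed per-group
means/SDs (n = 643 CU, 41 MCI/dementia) back through the summary-statistic
path reproduces the printed effect sizes, e.g. MTD-SBCr g = −2.01
(−2.35, −1.68) against the printed −2.02 (−2.35, −1.68).

## Reproduction

Everything is seeded; the same seed gives byte-identical outputs.

```bash
pip install --no-build-isolation -e ".[test]"
python -m pytest -q tests/                    # full suite, ~1 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
python analysis/01_simulate_cohort.py         # then 02..06 in order
```

`scripts/acceptance.py` writes the CU-subgroup mean of MTD-SBCz on a freshly
simulated cohort; it is zero to machine precision by construction for any
seed. The test suite covers scoring exactness (all 49 accuracy-weight
inputs), brute-force oracles for Spearman/Fisher, reproduction of the
published effect sizes within ±0.03, CI coverage and type-I error of the
adjusted models on cohorts with known effects, and end-to-end pipeline
determinism.

See `docs/methods.md` for the methods note, including where the simulator
deliberately departs from the real task's adaptation rule.
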