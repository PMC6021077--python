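# iciss

Derivation and temporal validation of ICD-based injury severity scores
(ICISS) from trauma-registry data, with a synthetic registry generator
that makes the whole pipeline testable without access to patient data.

## The problem and the method

Trauma registries in low- and middle-income settings record each
patient's injuries as ICD-10 codes plus binary outcomes (death within
24 hours and within 30 days). The ICISS turns these codes into a
survival probability. For each ICD-10 code the **survival risk ratio**
is the survival fraction among patients carrying it,

```
SRR = A / (A + B)
```

with `A` survivors and `B` deaths, derived separately for each outcome
(SRRm30d, SRRm24h). The conventional multiplicative ICISS of a patient
is the product of the SRRs of all their injury codes,

```
ICISS = ∏ SRR(code_i)   ∈ [0, 1],
```

read as the patient's probability of survival; a patient with no
recorded injury scores 1, and codes carried by fewer than 10 derivation
patients contribute no factor. The predictor handed to evaluation is
`1 − ICISS` (predicted mortality).

The pipeline follows the standard prognostic-model workflow:

1. **complete-case filter** — drop records missing any outcome or
   covariate (arrival, age, sex, mechanism, transfer status);
2. **temporal split** — the validation sample is the smallest
   most-recent time window holding 200 deaths within 24 hours plus all
   non-events arriving in it; everything earlier is derivation;
3. **SRR derivation** on the derivation sample only, per outcome;
4. **scoring** of both samples with both tables;
5. **evaluation** — discrimination by AUROCC (the Mann–Whitney
   concordance probability, ties counting ½) and calibration by an OLS
   line of observed on predicted mortality (patient-level and
   decile-level), each with a percentile-bootstrap 95% CI
   (1000 pair resamples);
6. **sensitivity analyses** — four one-switch variants of the main
   plan: keep missing-covariate patients, exclude uninjured patients,
   use every SRR regardless of carrier count, count duplicate codes
   once. Overlapping 95% CIs are read as no significant difference.

The synthetic generator draws injury codes from a skewed rank-frequency
law and produces 30-day death from the multiplicative
independent-survival model itself, so derived SRRs must recover the
generator's per-code survival probabilities and a score built from the
true probabilities must be perfectly calibrated — the properties the
test suite checks.

## Worked example

`examples/03_temporal_validation.py` generates a 16,000-patient cohort,
splits it at the most recent 200 events, derives SRRm30d on the
derivation sample and evaluates the score out of time:

```
split at 2015-07-05: 12812 derivation, 3024 validation patients (200 events in validation)
validation AUROCC:       0.821 (95% CI 0.804-0.838)
calibration slope:       0.935 (95% CI 0.876-0.994)
calibration intercept:   -0.186 (95% CI -0.209--0.163)
decile-scale slope:      0.945
```

The AUROCC of 0.82 says a randomly chosen death outranks a randomly
chosen survivor 82% of the time. The calibration line is fitted to
observed on predicted mortality, so slope 1 / intercept 0 would be
perfect; here the negative intercept at slope < 1 means the score
predicts substantially more deaths than occur. That overestimation is
structural: each SRR is the *marginal* death rate among carriers of a
code, which already absorbs the mortality of co-occurring injuries, so
the product double-counts risk. Scoring the same cohort with the
generator's true per-code survival probabilities instead gives a decile
slope of 1.01 and intercept −0.004 (`examples/05_correct_specification.py`),
confirming that the miscalibration comes from the score, not the
evaluator.

The other examples show cohort simulation (`01`), SRR tables and
scoring variants (`02`) and the sensitivity-analysis comparison (`04`).

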