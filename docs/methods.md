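# Methods

## Model

The ICISS treats each ICD-10 injury code as an independent
survival factor. For a code with `A` surviving and `B` non-surviving
carriers the survival risk ratio is `SRR = A/(A+B)` — the raw ratio,
deliberately unsmoothed and unshrunk. A patient's score is the product
of the SRRs of their injury codes and is read as a survival
probability; the complement `1 − ICISS` is the predicted mortality used
in evaluation. Two outcome definitions are carried through in
parallel (death within 30 days, `m30d`, and within 24 hours, `m24h`),
giving two SRR tables, two scores, and a 2×2 score-by-outcome
evaluation grid in each sample.

Assumptions the model makes, and that its known failure mode follows
from: injuries contribute independently and multiplicatively to the
risk of death, and a code's marginal carrier survival identifies its
per-injury factor. In real registries carriers of one code tend to
carry others, so the marginal SRR absorbs co-occurring injuries'
mortality and the product double-counts risk, overestimating mortality.
The package reproduces this structurally (see *Synthetic cohorts*).

## Pipeline conventions

* **Registry format.** Flat CSV, one row per patient, columns
  `patient_id, arrival, age, sex, mechanism, transferred, injuries,
  died_24h, died_30d`; the injury list is semicolon-packed in one cell.
  Missing values are empty cells. Unparseable cells are read as
  missing, never defaulted; a 24-hour death recorded as a 30-day
  survivor is rejected at load.
* **ICD granularity.** Codes are uppercased and dot-stripped. Default
  truncation is 0 (codes used as given); 3- or 4-character truncation is
  configurable because registry practice varies and neither choice is
  canonical.
* **Counting unit.** When tallying A and B, the default counts each
  patient at most once per distinct code (`per_patient_presence`);
  "number of surviving patients" is a patient-level notion.
  `per_occurrence` is available because the multiplicative score itself
  multiplies duplicate occurrences.
* **min_count.** SRRs are published only for codes with `A + B >= 10`
  carriers in the derivation sample — a precision compromise; the
  threshold applies to carriers, not deaths. Codes below it (or unseen
  in derivation) contribute no factor when scoring — skipped, not
  imputed — and are tallied in a diagnostic count.
* **Temporal split.** Patients are ordered by arrival; the validation
  sample is the smallest time suffix containing the target number of
  events (deaths within 24 hours by default, 200 events) plus every
  non-event arriving in the same window. Ties on the cutoff timestamp
  all go to validation, so achieved events can exceed the target;
  this is the deterministic, audit-friendly resolution. Records with
  missing arrival cannot be "most recent" and are excluded by the main
  complete-case rule anyway; when the missing-covariate sensitivity
  plan retains them they are assigned to derivation, and that plan
  reuses the main analysis' cutoff so the two samples stay comparable.
* **Scoring order.** SRR factors are multiplied in sorted order so the
  score is exactly invariant to injury-list permutations in floating
  point.

## Evaluation

* **Discrimination.** AUROCC, computed by rank statistics
  (`sklearn.metrics.roc_auc_score`); by construction it equals the
  Mann–Whitney concordance probability with ties counting ½, and the
  test suite verifies exact agreement with an O(n²) pair count.
* **Calibration.** OLS of observed on predicted mortality on two
  scales: patient-level (each 0/1 outcome on its prediction — the
  headline slope/intercept) and decile-level (observed decile mortality
  on mean predicted decile mortality, the quantity a calibration plot
  shows). Slope 1 / intercept 0 is perfect; both scales are reported
  because neither is canonical in the literature. A
  logistic-recalibration (logit-scale) slope is available as a labelled
  extra but is not part of the default report.
* **Deciles.** Equal-count bins by predicted mortality with tied
  predictions kept together; when ties straddle an ideal boundary the
  bin extends past the tie run and per-bin n is reported. Fewer than
  two non-degenerate bins is an error.
* **Bootstrap.** Percentile bootstrap, 1000 draws by default:
  (prediction, outcome) pairs resampled jointly with replacement at the
  original sample size; the 95% interval is the 2.5th–97.5th percentile
  of the draw distribution. Draws on which a metric is undefined
  (single-class resamples) are redrawn so every interval rests on
  exactly the requested number of valid statistics; if more than half
  of all attempts are undefined the bootstrap aborts with a diagnostic.
  The three report metrics share one resampling stream, and every
  report records its seed and draw count.

## Synthetic cohorts

The generator emulates the shape of a large urban multicentre trauma
registry and uses the score's own generative assumption:

* code usage follows a Zipf-like rank-frequency law (exponent 1.0 by
  default) over 150 ICD-10-like codes, drawn with replacement so
  duplicate codes occur (needed by the unique-code sensitivity
  variant); the code count per patient is 1 + Poisson(mean − 1), with a
  2% chance of an empty injury list;
* 30-day death is Bernoulli with probability `1 − ∏ survival(code)`
  over the drawn list; 24-hour death is a Bernoulli thinning of 30-day
  death (conditional probability 0.296 ≈ 6.4/21.6), the simplest
  mechanism that guarantees nesting;
* per-code death probabilities rise with rarity,
  `d(rank) = (0.02 + 0.665·(rank/n)^1.2) · LogNormal(0, 0.2)` — common
  codes are mild, rare codes severe — calibrated once by simulation so
  a 16,000-patient cohort shows ≈21–22% 30-day and ≈6.4% 24-hour
  mortality with low seed-to-seed variance;
* covariate marginals: 76.8% male; mechanism mix 41% road traffic,
  33% falls, 8.4% burns, remainder assault/railway/other; 70.4%
  transferred; right-skewed age (gamma, mean ≈32 y); arrivals uniform
  over a 2013–2015 window; per-field MCAR missingness ≤1%, never on
  the patient id.

Everything is reproducible from a single integer seed; the per-code
severity curve is seeded separately (seed + 104729) so cohort draws and
code parameters are decoupled.

What the generator does *not* emulate: dependence between a patient's
codes and their covariates, diagnostic under-ascertainment, site
effects, or the real registry's joint code-outcome distribution. It
claims marginal fidelity only. Consequently, passing tests show the
pipeline's arithmetic and statistical machinery are correct under the
model's own assumptions — they do not certify performance numbers on
any real registry. Notably, even under this generator the
estimated-SRR score overestimates mortality (codes co-occur within
patients), mirroring the direction of miscalibration registry studies
report, while scoring with the true per-code survival probabilities
yields decile calibration slope ≈1 — the dual check the acceptance
suite runs.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 2,000–16,000 patients for
pipeline checks, 20,000 single-code patients for SRR parameter recovery
(3 binomial-SE tolerance at exposure ≥500), and 50,000 patients for the
correct-specification calibration check (decile slope within
[0.9, 1.1], intercept within [−0.02, 0.02]); bootstrap intervals use
1000 draws in headline runs and fewer in unit tests. Degenerate inputs
fail loudly: single-class outcomes, constant predictions and
empty-after-exclusion cohorts raise typed errors rather than returning
NaN.

## Known limitations

Worst-injury and max-k-injury ICISS variants are out of scope, as are
SRR shrinkage or pooling across registries, formal calibration tests
(e.g. Hosmer–Lemeshow) and significance tests between AUROCCs beyond
CI overlap. ICD-9/ICD-11 and validation of codes against the official
ICD-10 tabulation are not supported.
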