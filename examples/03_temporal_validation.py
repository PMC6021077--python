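"""Temporal split and out-of-time evaluation of the ICISS.

The validation sample is the smallest most-recent time window holding
200 24-hour deaths (plus every non-event arriving in it); SRRs are
derived on the earlier derivation sample only and evaluated on both.
"""

from iciss import (
    complete_case_filter,
    derive_srr_table,
    evaluate_performance,
    generate_cohort,
    score_cohort,
    split_by_recent_events,
    titco_like_spec,
)

cohort = complete_case_filter(generate_cohort(titco_like_spec(1))).cohort
split = split_by_recent_events(cohort, target_events=200, event="m24h")
print(
    f"split at {split.cutoff:%Y-%m-%d}: {split.n_derivation} derivation, "
    f"{split.n_validation} validation patients "
    f"({split.achieved_events} events in validation)"
)

derivation = cohort.subset(split.derivation_ids)
validation = cohort.subset(split.validation_ids)
table = derive_srr_table(derivation, "m30d", min_count=10)
scored = score_cohort(validation, table)
outcomes = [int(r.died_30d) for r in validation]
report = evaluate_performance(
    scored.predicted_mortality(), outcomes, n_bootstrap=1000, seed=1
)

a, s, i = report.auroc, report.cal_slope, report.cal_intercept
print(f"validation AUROCC:       {a.point:.3f} (95% CI {a.lower:.3f}-{a.upper:.3f})")
print(f"calibration slope:       {s.point:.3f} (95% CI {s.lower:.3f}-{s.upper:.3f})")
print(f"calibration intercept:   {i.point:.3f} (95% CI {i.lower:.3f}-{i.upper:.3f})")
print(f"decile-scale slope:      {report.decile_slope:.3f}")
print("AUROCC is the probability a random death outranks a random "
      "survivor; slope 1 / intercept 0 would be perfect calibration — "
      "a slope below 1 with observed < predicted means the score "
      "overestimates mortality.")
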