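"""Analysis plans: the main analysis and its four sensitivity variants.

Each plan is a declarative configuration over the other modules; the
runner executes the same pipeline for all of them:

    complete-case filter → temporal split → SRR derivation (derivation
    sample only, per outcome) → ICISS scoring of both samples with both
    tables → 2×2 score-by-outcome evaluation in both samples.

The variants each flip exactly one switch relative to the main plan:

* ``s1_missing_covariates`` — keep patients with missing covariates
  (outcomes still required).  The temporal cutoff from the main
  complete-case split is reused so the samples stay comparable;
  patients whose arrival is unknown cannot be placed "most recent" and
  go to derivation.
* ``s2_exclude_uninjured`` — drop patients with no recorded injuries
  instead of scoring them 1.
* ``s3_all_srrs`` — score against every derived SRR regardless of how
  many patients it was based on (scoring table built at min_count 1).
* ``s4_unique_codes`` — each distinct code contributes at most one SRR
  factor per patient.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, replace

import pandas as pd

from .cohort import Cohort, complete_case_filter, write_cohort
from .errors import ValidationError
from .evaluate import PerformanceReport, evaluate_matrix
from .scoring import ScoreConfig, score_cohort
from .split import SplitResult, split_by_recent_events
from .srr import SRRTable, derive_srr_table

PLAN_NAMES = (
    "main",
    "s1_missing_covariates",
    "s2_exclude_uninjured",
    "s3_all_srrs",
    "s4_unique_codes",
)


@dataclass(frozen=True)
class AnalysisPlan:
    """One pipeline configuration."""

    name: str
    require_covariates: bool = True
    min_count: int = 10
    score_config: ScoreConfig = ScoreConfig()
    target_events: int = 200
    split_event: str = "m24h"

    def switches(self) -> dict:
        """The flat switch dict used for plan-difference audits."""
        return {
            "require_covariates": self.require_covariates,
            "unique_codes_only": self.score_config.unique_codes_only,
            "use_all_srrs": self.score_config.use_all_srrs,
            "exclude_uninjured": self.score_config.exclude_uninjured,
        }


def standard_plans(target_events: int = 200) -> dict[str, AnalysisPlan]:
    """The main analysis plus the four one-switch sensitivity plans."""
    base = AnalysisPlan(name="main", target_events=target_events)
    return {
        "main": base,
        "s1_missing_covariates": replace(
            base, name="s1_missing_covariates", require_covariates=False
        ),
        "s2_exclude_uninjured": replace(
            base,
            name="s2_exclude_uninjured",
            score_config=ScoreConfig(exclude_uninjured=True),
        ),
        "s3_all_srrs": replace(
            base, name="s3_all_srrs", score_config=ScoreConfig(use_all_srrs=True)
        ),
        "s4_unique_codes": replace(
            base,
            name="s4_unique_codes",
            score_config=ScoreConfig(unique_codes_only=True),
        ),
    }


def plan_diff(a: AnalysisPlan, b: AnalysisPlan) -> list[str]:
    """Names of switches on which two plans differ."""
    sa, sb = a.switches(), b.switches()
    return [k for k in sa if sa[k] != sb[k]]


@dataclass
class ResultBundle:
    """Everything one plan run produces."""

    plan: AnalysisPlan
    split: SplitResult
    srr_tables: dict[str, SRRTable]  # outcome -> table used for scoring
    reports: dict[str, dict[tuple[str, str], PerformanceReport]]  # sample -> grid
    manifest: dict

    def report(self, sample: str, outcome: str, score_label: str) -> PerformanceReport:
        return self.reports[sample][(outcome, score_label)]


def cohort_hash(cohort: Cohort) -> str:
    """Content hash of the serialised cohort (the reproducibility anchor)."""
    buf = io.StringIO()
    write_cohort(cohort, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


_OUTCOME_ATTR = {"m30d": "died_30d", "m24h": "died_24h"}


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_plan(
    cohort: Cohort,
    plan: AnalysisPlan,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ResultBundle:
    """Execute one analysis plan end to end on a raw cohort."""
    chash = cohort_hash(cohort)

    with _stage("complete_case_filter"):
        filtered = complete_case_filter(cohort, plan.require_covariates)

    with _stage("temporal_split"):
        if plan.require_covariates:
            split = split_by_recent_events(
                filtered.cohort, plan.target_events, plan.split_event
            )
            analysis = filtered.cohort
        else:
            # Reuse the main analysis' cutoff so derivation/validation
            # windows stay comparable; missing arrivals go to derivation.
            main_cc = complete_case_filter(cohort, require_covariates=True)
            main_split = split_by_recent_events(
                main_cc.cohort, plan.target_events, plan.split_event
            )
            cutoff = main_split.cutoff
            analysis = filtered.cohort
            attr = _OUTCOME_ATTR[plan.split_event]
            val_ids, der_ids = [], []
            for r in analysis:
                if r.arrival is not None and r.arrival >= cutoff:
                    val_ids.append(r.patient_id)
                else:
                    der_ids.append(r.patient_id)
            achieved = sum(
                1
                for r in analysis
                if r.patient_id in set(val_ids) and getattr(r, attr)
            )
            split = SplitResult(
                derivation_ids=der_ids,
                validation_ids=val_ids,
                cutoff=cutoff,
                target_events=plan.target_events,
                achieved_events=achieved,
            )

    derivation = analysis.subset(split.derivation_ids, provenance="derivation")
    validation = analysis.subset(split.validation_ids, provenance="validation")

    with _stage("srr_derivation"):
        table_min_count = 1 if plan.score_config.use_all_srrs else plan.min_count
        srr_tables = {
            outcome: derive_srr_table(
                derivation,
                outcome,
                min_count=table_min_count,
                truncation=plan.score_config.truncation,
            )
            for outcome in ("m30d", "m24h")
        }

    with _stage("scoring_and_evaluation"):
        reports: dict[str, dict] = {}
        sample_sizes = {}
        dropped_uninjured = {}
        for sample_name, sample in (
            ("derivation", derivation),
            ("validation", validation),
        ):
            scores = {}
            ids = None
            for outcome, label in (("m30d", "ICISSm30d"), ("m24h", "ICISSm24h")):
                result = score_cohort(sample, srr_tables[outcome], plan.score_config)
                scores[label] = result.predicted_mortality()
                scored_ids = [s.patient_id for s in result]
                if ids is None:
                    ids = scored_ids
                elif ids != scored_ids:
                    raise ValidationError("score alignment mismatch across tables")
                dropped_uninjured[sample_name] = result.n_dropped_uninjured
            by_id = {r.patient_id: r for r in sample}
            outcomes = {
                outcome: [
                    int(getattr(by_id[i], _OUTCOME_ATTR[outcome])) for i in ids
                ]
                for outcome in ("m30d", "m24h")
            }
            sample_sizes[sample_name] = len(ids)
            reports[sample_name] = evaluate_matrix(
                scores,
                outcomes,
                n_bootstrap=n_bootstrap,
                seed=(seed + (1 if sample_name == "validation" else 0)),
            )

    manifest = {
        "plan": plan.name,
        "switches": plan.switches(),
        "cohort_hash": chash,
        "seed": seed,
        "n_bootstrap": n_bootstrap,
        "n_input": len(cohort),
        "n_after_filter": len(filtered.cohort),
        "n_excluded": filtered.n_excluded,
        "exclusions_by_field": filtered.exclusions_by_field,
        "split": {
            "cutoff": split.cutoff.isoformat(),
            "target_events": split.target_events,
            "achieved_events": split.achieved_events,
            "n_derivation": split.n_derivation,
            "n_validation": split.n_validation,
        },
        "srr_table_sizes": {o: len(t) for o, t in srr_tables.items()},
        "scoring_min_count": table_min_count,
        "n_evaluated": sample_sizes,
        "n_dropped_uninjured": dropped_uninjured,
    }
    return ResultBundle(
        plan=plan,
        split=split,
        srr_tables=srr_tables,
        reports=reports,
        manifest=manifest,
    )


_METRICS = ("auroc", "cal_slope", "cal_intercept")


def compare_plans(bundles: dict[str, ResultBundle]) -> pd.DataFrame:
    """Side-by-side metric table across plans with CI-overlap flags.

    Overlapping 95% CIs are read as no significant difference; each
    non-reference plan is compared cell-by-cell against the first
    (reference) bundle and flagged where the intervals are disjoint.
    """
    if len(bundles) < 2:
        raise ValidationError("need at least two bundles to compare")
    names = list(bundles)
    ref_hash = bundles[names[0]].manifest["cohort_hash"]
    for name in names[1:]:
        if bundles[name].manifest["cohort_hash"] != ref_hash:
            raise ValidationError(
                f"bundle {name!r} was run on a different cohort"
            )
    ref = bundles[names[0]]
    rows = []
    for sample in ("derivation", "validation"):
        for key in sorted(ref.reports[sample]):
            outcome, label = key
            for metric in _METRICS:
                row = {
                    "sample": sample,
                    "outcome": outcome,
                    "score": label,
                    "metric": metric,
                }
                ref_ci = getattr(ref.reports[sample][key], metric)
                for name in names:
                    ci = getattr(bundles[name].reports[sample][key], metric)
                    row[f"{name}_point"] = ci.point
                    row[f"{name}_lower"] = ci.lower
                    row[f"{name}_upper"] = ci.upper
                    if name != names[0]:
                        row[f"{name}_disjoint_ci"] = not ci.overlaps(ref_ci)
                rows.append(row)
    return pd.DataFrame(rows)


def save_bundle(bundle: ResultBundle, path) -> None:
    """Write a bundle's manifest and report grid to a JSON file."""
    payload = {
        "manifest": bundle.manifest,
        "reports": {
            sample: {
                f"{outcome}+{label}": rep.as_dict()
                for (outcome, label), rep in grid.items()
            }
            for sample, grid in bundle.reports.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
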