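"""Multiplicative ICISS scoring.

The conventional (multiplicative) ICISS of a patient is the product of
the SRRs of all their tabulated injury codes and is interpreted as the
patient's survival probability.  A patient with no recorded injuries
scores 1 (certain survival under the model); injury codes absent from
the SRR table (too rare in derivation, or never seen there) contribute
no factor.  The predictor handed to evaluation is
``predicted_mortality = 1 - ICISS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort, PatientRecord, normalize_icd
from .errors import ValidationError
from .srr import SRRTable


@dataclass(frozen=True)
class ScoreConfig:
    """Variant switches for ICISS computation.

    unique_codes_only
        Each distinct code contributes at most one SRR factor even when
        it occurs several times in the same patient (sensitivity IV).
    use_all_srrs
        Score against a table derived with ``min_count=1`` so every SRR
        is used regardless of how many patients it was based on
        (sensitivity III).  The switch itself only *declares* the
        intent; pair it with a table derived at min_count 1.
    exclude_uninjured
        Drop patients with an empty injury list before scoring instead
        of assigning them ICISS 1 (sensitivity II).
    truncation
        ICD-code granularity passed to normalisation (0 = full code).
    """

    unique_codes_only: bool = False
    use_all_srrs: bool = False
    exclude_uninjured: bool = False
    truncation: int = 0


@dataclass(frozen=True)
class ScoredPatient:
    """One patient's ICISS on the survival-probability scale."""

    patient_id: str
    iciss: float
    n_codes_matched: int

    @property
    def predicted_mortality(self) -> float:
        return 1.0 - self.iciss


@dataclass
class ScoringResult:
    """Scores for a cohort plus the uninjured-exclusion audit count."""

    scored: list[ScoredPatient]
    n_dropped_uninjured: int = 0

    def __len__(self) -> int:
        return len(self.scored)

    def __iter__(self):
        return iter(self.scored)

    def predicted_mortality(self) -> list[float]:
        return [s.predicted_mortality for s in self.scored]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in self.scored],
                "iciss": [s.iciss for s in self.scored],
                "predicted_mortality": [s.predicted_mortality for s in self.scored],
                "n_codes_matched": [s.n_codes_matched for s in self.scored],
            }
        )


def score_patient(
    record: PatientRecord, table: SRRTable, config: ScoreConfig = ScoreConfig()
) -> ScoredPatient:
    """Multiply the SRRs of the patient's tabulated injury codes.

    Codes below the table's count threshold or unseen in derivation are
    skipped (multiply by 1), never imputed; an empty injury list yields
    ICISS 1 exactly.
    """
    codes = [normalize_icd(c, config.truncation) for c in record.injuries]
    if config.unique_codes_only:
        codes = list(dict.fromkeys(codes))
    factors = []
    for code in codes:
        entry = table.entries.get(code)
        if entry is not None:
            factors.append(entry.srr)
    # multiply in sorted order so the score is exactly invariant to the
    # ordering of the injury list
    iciss = 1.0
    for f in sorted(factors):
        iciss *= f
    return ScoredPatient(record.patient_id, iciss, len(factors))


def score_cohort(
    cohort: Cohort, table: SRRTable, config: ScoreConfig = ScoreConfig()
) -> ScoringResult:
    """Score every patient; optionally drop uninjured patients first."""
    records = list(cohort)
    dropped = 0
    if config.exclude_uninjured:
        n0 = len(records)
        records = [r for r in records if r.injuries]
        dropped = n0 - len(records)
        if not records:
            raise ValidationError(
                "no patients left to score after excluding the uninjured"
            )
    return ScoringResult(
        scored=[score_patient(r, table, config) for r in records],
        n_dropped_uninjured=dropped,
    )
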