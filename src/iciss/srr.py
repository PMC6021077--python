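"""Survival risk ratio (SRR) derivation.

For each ICD-10 code the SRR is the observed survival fraction among
patients carrying the code::

    SRR = A / (A + B)

where ``A`` counts survivors and ``B`` deaths under a chosen outcome
definition (death within 30 days, ``m30d``, or within 24 hours,
``m24h``).  Codes carried by fewer than ``min_count`` patients are
dropped from the published table; the registry analysis this package
implements uses ``min_count=10`` as a precision compromise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

from .cohort import Cohort, normalize_icd
from .errors import ValidationError

Outcome = Literal["m30d", "m24h"]
CountMode = Literal["per_patient_presence", "per_occurrence"]

_OUTCOME_ATTR = {"m30d": "died_30d", "m24h": "died_24h"}


def _died(record, outcome: Outcome) -> bool:
    value = getattr(record, _OUTCOME_ATTR[outcome])
    if value is None:
        raise ValidationError(
            f"patient {record.patient_id} has missing outcome {outcome}; "
            "apply the complete-case filter before deriving SRRs"
        )
    return value


@dataclass(frozen=True)
class SRREntry:
    """Counts and ratio for one code: srr = A/(A+B)."""

    A: int  # survivors carrying the code
    B: int  # deaths carrying the code

    @property
    def n(self) -> int:
        return self.A + self.B

    @property
    def srr(self) -> float:
        return self.A / (self.A + self.B)


@dataclass
class SRRTable:
    """Per-code survival risk ratios for one outcome definition."""

    outcome: Outcome
    entries: dict[str, SRREntry]
    min_count: int
    derivation_n: int
    truncation: int = 0
    provenance: str = ""

    def srr(self, code: str) -> float | None:
        """SRR of a (raw) code, or None when the code is not tabulated."""
        e = self.entries.get(normalize_icd(code, self.truncation))
        return None if e is None else e.srr

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return normalize_icd(code, self.truncation) in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "code": c,
                "A": e.A,
                "B": e.B,
                "n": e.n,
                "srr": e.srr,
                "outcome": self.outcome,
                "min_count": self.min_count,
            }
            for c, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["code", "A", "B", "n", "srr", "outcome", "min_count"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SRRTable":
        df = pd.read_csv(path, dtype={"code": str})
        if df.empty:
            raise ValidationError("empty SRR table file")
        outcome = df["outcome"].iloc[0]
        min_count = int(df["min_count"].iloc[0])
        entries = {
            str(r.code): SRREntry(int(r.A), int(r.B)) for r in df.itertuples()
        }
        return cls(
            outcome=outcome,
            entries=entries,
            min_count=min_count,
            derivation_n=int(df["n"].sum()),  # lower bound; true n not stored
            provenance=str(path),
        )


def count_code_outcomes(
    cohort: Cohort,
    outcome: Outcome,
    count_mode: CountMode = "per_patient_presence",
    truncation: int = 0,
) -> dict[str, SRREntry]:
    """Tally survivor (A) and death (B) contributions per code.

    Under ``per_patient_presence`` each patient contributes at most one
    count to each distinct code it carries; under ``per_occurrence``
    duplicate codes within a patient contribute multiply.
    """
    if count_mode not in ("per_patient_presence", "per_occurrence"):
        raise ValidationError(f"unknown count_mode {count_mode!r}")
    counts: dict[str, list[int]] = {}
    for record in cohort:
        died = _died(record, outcome)
        codes = [normalize_icd(c, truncation) for c in record.injuries]
        if count_mode == "per_patient_presence":
            codes = list(dict.fromkeys(codes))  # de-duplicate, keep order
        for code in codes:
            ab = counts.setdefault(code, [0, 0])
            ab[1 if died else 0] += 1
    return {c: SRREntry(A=ab[0], B=ab[1]) for c, ab in counts.items()}


def derive_srr_table(
    cohort: Cohort,
    outcome: Outcome,
    min_count: int = 10,
    count_mode: CountMode = "per_patient_presence",
    truncation: int = 0,
) -> SRRTable:
    """Derive the SRR table for one outcome from a derivation cohort.

    Only codes with ``A + B >= min_count`` are retained; the threshold
    applies to all patients carrying the code, not to deaths alone.
    The ratio is the raw A/(A+B) with no smoothing or shrinkage.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot derive SRRs from an empty cohort")
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    raw = count_code_outcomes(cohort, outcome, count_mode, truncation)
    entries = {c: e for c, e in raw.items() if e.n >= min_count}
    return SRRTable(
        outcome=outcome,
        entries=entries,
        min_count=min_count,
        derivation_n=len(cohort),
        truncation=truncation,
        provenance=cohort.provenance,
    )
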