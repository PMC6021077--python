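"""Patient-level data model and registry table IO.

A trauma registry is represented as a :class:`Cohort` of
:class:`PatientRecord` objects.  On disk a cohort is a flat CSV with one
row per patient and the injury list packed into a single
semicolon-separated column — the layout used by flat hospital registries
whose free-text injuries have already been coded to ICD-10.

Fixed column names: ``patient_id, arrival, age, sex, mechanism,
transferred, injuries, died_24h, died_30d``.  Missing values are empty
cells; there are no numeric sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterator, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

COLUMNS = [
    "patient_id",
    "arrival",
    "age",
    "sex",
    "mechanism",
    "transferred",
    "injuries",
    "died_24h",
    "died_30d",
]

SEXES = frozenset({"male", "female"})
MECHANISMS = frozenset({"assault", "burn", "fall", "railway", "rti", "other"})

#: Separator for the packed injury-list column.
INJURY_SEP = ";"

#: Fields treated as covariates by the complete-case rule (outcomes are
#: always required).
COVARIATE_FIELDS = ("arrival", "age", "sex", "mechanism", "transferred")
OUTCOME_FIELDS = ("died_24h", "died_30d")


@dataclass(frozen=True)
class PatientRecord:
    """One trauma patient: covariates, ICD-10 injury codes and outcomes.

    ``injuries`` is an ordered list of ICD-10 code strings; it may be
    empty (a patient with no recorded injury — valid, not missing) and
    may contain duplicates.  Any field except ``patient_id`` and
    ``injuries`` may be ``None`` (missing).
    """

    patient_id: str
    arrival: datetime | None = None
    age: float | None = None
    sex: str | None = None
    mechanism: str | None = None
    transferred: bool | None = None
    injuries: tuple[str, ...] = ()
    died_24h: bool | None = None
    died_30d: bool | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be a non-empty string")
        object.__setattr__(self, "injuries", tuple(self.injuries))
        if self.age is not None and self.age < 0:
            raise ValidationError(
                f"age must be non-negative, got {self.age} for {self.patient_id}"
            )
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.mechanism is not None and self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
        # A death within 24 hours is by definition a death within 30 days.
        if self.died_24h is True and self.died_30d is False:
            raise IntegrityError(
                f"patient {self.patient_id}: died_24h=True but died_30d=False"
            )

    def is_complete(self, require_covariates: bool = True) -> bool:
        """True when the record passes the complete-case rule."""
        if self.died_24h is None or self.died_30d is None:
            return False
        if not require_covariates:
            return True
        return not any(
            getattr(self, f) is None for f in COVARIATE_FIELDS
        )

    def missing_fields(self, require_covariates: bool = True) -> tuple[str, ...]:
        fields = OUTCOME_FIELDS + (COVARIATE_FIELDS if require_covariates else ())
        return tuple(f for f in fields if getattr(self, f) is None)


@dataclass
class Cohort:
    """An ordered collection of patient records with unique ids."""

    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.patient_id in seen:
                raise IntegrityError(f"duplicate patient_id {r.patient_id!r}")
            seen.add(r.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def subset(self, ids: Sequence[str], provenance: str | None = None) -> "Cohort":
        """Order-preserving subset by patient id."""
        wanted = set(ids)
        return Cohort(
            [r for r in self.records if r.patient_id in wanted],
            provenance if provenance is not None else self.provenance,
        )


@dataclass(frozen=True)
class CompleteCaseResult:
    """Filtered cohort plus an audit count of exclusions per field."""

    cohort: Cohort
    n_excluded: int
    exclusions_by_field: dict[str, int]


def complete_case_filter(
    cohort: Cohort, require_covariates: bool = True
) -> CompleteCaseResult:
    """Apply the complete-case rule.

    With ``require_covariates=True`` (the main analysis) a record must
    have non-missing outcomes *and* non-missing arrival, age, sex,
    mechanism and transfer status.  With ``require_covariates=False``
    (sensitivity analysis on missing covariates) only the two outcomes
    are required.  An empty result is allowed; downstream stages raise
    their own errors on empty input.

    The filter is order-preserving and idempotent.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot filter an empty cohort")
    kept: list[PatientRecord] = []
    by_field: dict[str, int] = {}
    for r in cohort:
        missing = r.missing_fields(require_covariates)
        if missing:
            for f in missing:
                by_field[f] = by_field.get(f, 0) + 1
        else:
            kept.append(r)
    return CompleteCaseResult(
        cohort=Cohort(kept, provenance=cohort.provenance),
        n_excluded=len(cohort) - len(kept),
        exclusions_by_field=by_field,
    )


def normalize_icd(code: str, truncation: int = 0) -> str:
    """Canonicalise an ICD-10 code string.

    Uppercases, strips whitespace and removes dots; ``truncation`` of 3
    or 4 keeps that many leading characters (3- or 4-character code
    granularity), 0 keeps the full code.  Idempotent.
    """
    if truncation not in (0, 3, 4):
        raise ValidationError(f"truncation must be 0, 3 or 4, got {truncation}")
    out = code.strip().upper().replace(".", "")
    if not out:
        raise ValidationError("empty ICD code")
    if truncation:
        out = out[:truncation]
    return out


# ---------------------------------------------------------------------------
# CSV serialisation

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


def _parse_bool(cell: str, column: str, row: str) -> bool:
    if cell in _TRUE:
        return True
    if cell in _FALSE:
        return False
    raise FormatError(f"row {row}: cannot parse {column}={cell!r} as boolean")


def _cell(value) -> str | None:
    """Normalise a pandas cell to a stripped string, None when blank."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_cohort(path, *, injury_sep: str = INJURY_SEP) -> Cohort:
    """Read a registry CSV into a :class:`Cohort`.

    Unparseable timestamps, ages, sexes and mechanisms become missing
    values rather than silent defaults; an unparseable *outcome* cell is
    also treated as missing (the complete-case filter will drop it).
    A missing required column raises :class:`FormatError` naming the
    column; a duplicate patient id raises :class:`IntegrityError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    for col in COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        pid = _cell(row["patient_id"])
        if pid is None:
            raise FormatError("blank patient_id cell")
        arrival_s = _cell(row["arrival"])
        arrival = None
        if arrival_s is not None:
            try:
                arrival = datetime.fromisoformat(arrival_s)
            except ValueError:
                arrival = None
        age_s = _cell(row["age"])
        age = None
        if age_s is not None:
            try:
                age = float(age_s)
            except ValueError:
                age = None
            else:
                if age < 0:
                    age = None
        sex = _cell(row["sex"])
        if sex is not None and sex not in SEXES:
            sex = None
        mechanism = _cell(row["mechanism"])
        if mechanism is not None and mechanism not in MECHANISMS:
            mechanism = None

        def opt_bool(col: str):
            s = _cell(row[col])
            if s is None:
                return None
            if s in _TRUE:
                return True
            if s in _FALSE:
                return False
            return None

        inj_s = _cell(row["injuries"])
        injuries: tuple[str, ...] = ()
        if inj_s is not None:
            injuries = tuple(
                c.strip() for c in inj_s.split(injury_sep) if c.strip()
            )
        records.append(
            PatientRecord(
                patient_id=pid,
                arrival=arrival,
                age=age,
                sex=sex,
                mechanism=mechanism,
                transferred=opt_bool("transferred"),
                injuries=injuries,
                died_24h=opt_bool("died_24h"),
                died_30d=opt_bool("died_30d"),
            )
        )
    return Cohort(records, provenance=str(path))


def write_cohort(cohort: Cohort, path, *, injury_sep: str = INJURY_SEP) -> None:
    """Write a cohort to CSV; round-trips through :func:`read_cohort`."""

    def fmt_bool(b: bool | None) -> str:
        return "" if b is None else ("1" if b else "0")

    rows = []
    for r in cohort:
        rows.append(
            {
                "patient_id": r.patient_id,
                "arrival": r.arrival.isoformat() if r.arrival else "",
                "age": "" if r.age is None else repr(r.age),
                "sex": r.sex or "",
                "mechanism": r.mechanism or "",
                "transferred": fmt_bool(r.transferred),
                "injuries": injury_sep.join(r.injuries),
                "died_24h": fmt_bool(r.died_24h),
                "died_30d": fmt_bool(r.died_30d),
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def with_normalized_codes(cohort: Cohort, truncation: int = 0) -> Cohort:
    """Return a cohort whose injury codes have been canonicalised."""
    return Cohort(
        [
            replace(r, injuries=tuple(normalize_icd(c, truncation) for c in r.injuries))
            for r in cohort
        ],
        provenance=cohort.provenance,
    )
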