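"""Temporal derivation/validation split by the most-recent-events rule.

The validation sample is sized by walking backwards in arrival time
until it contains a target number of events (deaths by a chosen
definition, 24-hour deaths in the design this package implements) and
taking every patient — event or not — who arrived at or after that
point.  Everything earlier is the derivation sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Literal

from .cohort import Cohort
from .errors import ValidationError

Event = Literal["m24h", "m30d"]
_EVENT_ATTR = {"m24h": "died_24h", "m30d": "died_30d"}


@dataclass
class SplitResult:
    """Assignment of every split-eligible patient to derivation or validation."""

    derivation_ids: list[str]
    validation_ids: list[str]
    cutoff: datetime
    target_events: int
    achieved_events: int

    @property
    def n_derivation(self) -> int:
        return len(self.derivation_ids)

    @property
    def n_validation(self) -> int:
        return len(self.validation_ids)


def split_by_recent_events(
    cohort: Cohort, target_events: int, event: Event = "m24h"
) -> SplitResult:
    """Find the smallest time suffix holding ``target_events`` deaths.

    All records must carry a non-missing arrival and a non-missing value
    for the chosen event outcome.  The cutoff is the arrival of the
    earliest patient in the suffix; every patient arriving at or after
    the cutoff goes to validation (so patients tied on the cutoff
    timestamp are all validation, and tied events can push
    ``achieved_events`` above the target).  Everything earlier is
    derivation.
    """
    if target_events < 1:
        raise ValidationError(f"target_events must be >= 1, got {target_events}")
    attr = _EVENT_ATTR[event]
    for r in cohort:
        if r.arrival is None:
            raise ValidationError(
                f"patient {r.patient_id} has no arrival time; "
                "temporal split requires complete arrival data"
            )
        if getattr(r, attr) is None:
            raise ValidationError(
                f"patient {r.patient_id} has missing outcome {event}"
            )
    total_events = sum(1 for r in cohort if getattr(r, attr))
    if total_events < target_events:
        raise ValidationError(
            f"cohort holds only {total_events} {event} events, "
            f"short of the {target_events} required"
        )
    # Walk backwards in arrival time until the target is met, then pull
    # in every record sharing the cutoff timestamp.
    ordered = sorted(cohort, key=lambda r: r.arrival, reverse=True)
    seen = 0
    cutoff: datetime | None = None
    for r in ordered:
        if getattr(r, attr):
            seen += 1
            if seen == target_events:
                cutoff = r.arrival
                break
    assert cutoff is not None
    validation = [r for r in cohort if r.arrival >= cutoff]
    derivation = [r for r in cohort if r.arrival < cutoff]
    achieved = sum(1 for r in validation if getattr(r, attr))
    return SplitResult(
        derivation_ids=[r.patient_id for r in derivation],
        validation_ids=[r.patient_id for r in validation],
        cutoff=cutoff,
        target_events=target_events,
        achieved_events=achieved,
    )
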