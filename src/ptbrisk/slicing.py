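"""Delivery-anchored timeline slicing into prediction tasks.

A prediction point is an offset of 1, 3, 6 or 9 months (P1-P4) before the
delivery date: the model may only see visits up to that cutoff.  Two data
windows exist: ``long_term`` keeps the full pre-cutoff history, while
``short_term`` further discards everything before the start of the
pregnancy.  Months default to 30 days (calendar-month subtraction is
available), and a visit exactly on the cutoff day is retained.  The
delivery visit itself is always excluded from model input -- its codes
define the outcome label.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .cohort import CohortValidationError, PatientRecord

__all__ = ["SliceSpec", "SlicedCohort", "slice_record", "build_task_datasets"]

LONG_TERM = "long_term"
SHORT_TERM = "short_term"


def _subtract_calendar_months(date: datetime.date, months: int) -> datetime.date:
    month = date.month - 1 - months
    year = date.year + month // 12
    month = month % 12 + 1
    # clamp to the last day of the target month (e.g. Mar 31 - 1mo -> Feb 28)
    day = date.day
    while True:
        try:
            return datetime.date(year, month, day)
        except ValueError:
            day -= 1


@dataclass(frozen=True)
class SliceSpec:
    """One prediction task: months-before-delivery offset plus data window."""

    prediction_offset_months: int = 1
    window: str = LONG_TERM
    days_per_month: int = 30
    calendar_months: bool = False

    def __post_init__(self) -> None:
        if self.prediction_offset_months < 0:
            raise CohortValidationError("prediction offset must be >= 0 months")
        if not self.calendar_months and self.days_per_month < 28:
            raise CohortValidationError("days_per_month must be >= 28")
        if self.window not in (LONG_TERM, SHORT_TERM):
            raise CohortValidationError(f"unknown window {self.window!r}")

    def cutoff(self, delivery_date: datetime.date) -> datetime.date:
        if self.calendar_months:
            return _subtract_calendar_months(delivery_date, self.prediction_offset_months)
        return delivery_date - datetime.timedelta(
            days=self.prediction_offset_months * self.days_per_month
        )

    def name(self) -> str:
        return f"P{self.prediction_offset_months}m-{self.window}"


@dataclass
class SlicedCohort:
    """Records surviving a slice, with provenance counts."""

    spec: SliceSpec
    records: tuple[PatientRecord, ...]
    n_input: int = 0
    n_excluded: int = 0
    exclusion_reasons: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def patient_ids(self) -> set[str]:
        return {r.patient_id for r in self.records}

    def provenance(self) -> dict:
        return {
            "prediction_offset_months": self.spec.prediction_offset_months,
            "window": self.spec.window,
            "days_per_month": self.spec.days_per_month,
            "n_input": self.n_input,
            "n_retained": len(self.records),
            "n_excluded": self.n_excluded,
            "exclusion_reasons": dict(self.exclusion_reasons),
        }


def slice_record(
    record: PatientRecord, spec: SliceSpec, min_visits: int = 2
) -> Optional[PatientRecord]:
    """Cut one timeline at the prediction point.

    Retains visits with ``date <= cutoff`` (inclusive) and, for the
    short-term window, ``date >= pregnancy_start_date``.  Visits on or
    after the delivery date are always dropped (label leakage).  Returns
    ``None`` when fewer than ``min_visits`` visits survive.
    """
    if record.label is None:
        raise CohortValidationError(
            f"patient {record.patient_id}: cannot slice an unlabeled record"
        )
    if spec.window == SHORT_TERM and record.pregnancy_start_date is None:
        raise CohortValidationError(
            f"patient {record.patient_id}: short-term window requires pregnancy_start_date"
        )
    cutoff = spec.cutoff(record.delivery_date)
    kept = [
        v
        for v in record.visits
        if v.date <= cutoff
        and v.date < record.delivery_date
        and (spec.window == LONG_TERM or v.date >= record.pregnancy_start_date)
    ]
    if len(kept) < min_visits:
        return None
    return replace(record, visits=tuple(kept))


def build_task_datasets(
    records: Sequence[PatientRecord],
    specs: Iterable[SliceSpec],
    min_visits: int = 2,
) -> dict[SliceSpec, SlicedCohort]:
    """One sliced cohort per spec.

    For a fixed window, retained patient sets are nested: a longer offset
    can only lose patients (cutoff monotonicity).
    """
    out: dict[SliceSpec, SlicedCohort] = {}
    for spec in specs:
        kept: list[PatientRecord] = []
        reasons: dict[str, int] = {}
        for rec in records:
            sliced = slice_record(rec, spec, min_visits=min_visits)
            if sliced is None:
                reasons["too_few_visits_after_slicing"] = (
                    reasons.get("too_few_visits_after_slicing", 0) + 1
                )
            else:
                kept.append(sliced)
        out[spec] = SlicedCohort(
            spec=spec,
            records=tuple(kept),
            n_input=len(records),
            n_excluded=len(records) - len(kept),
            exclusion_reasons=reasons,
        )
    return out
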