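"""Longitudinal EHR data model: coded visits, delivery labeling, and cohort I/O.

A patient timeline is an ordered sequence of dated visits, each visit a set
of medical codes drawn from four modalities (diagnosis, medication,
procedure, lab order).  The delivery outcome is labeled from ICD-9
diagnosis codes on the delivery visit: codes under 644.2x mark a preterm
delivery, codes 645.xx, 649.8, 650 and 652.5 mark a full-term delivery.

Cohorts are serialized as JSON Lines, one patient object per line -- the
"list of lists of lists" layout (patients > visits > codes) that temporal
EHR models consume.  Vocabularies map codes to contiguous integer indices
and round-trip through a TSV file.
"""

from __future__ import annotations

import csv
import datetime
import json
from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "CodingSystem",
    "Modality",
    "MedicalCode",
    "Visit",
    "PatientRecord",
    "Vocabulary",
    "CohortValidationError",
    "normalize_code",
    "label_from_diagnoses",
    "find_delivery_visit",
    "encode_visit",
    "apply_inclusion_rules",
    "read_cohort",
    "write_cohort",
]


class CohortValidationError(ValueError):
    """Raised when a record, file line, or code fails validation."""


class CodingSystem(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"
    NDC = "NDC"
    CPT = "CPT"
    LOINC = "LOINC"
    OTHER = "OTHER"


class Modality(str, Enum):
    DIAGNOSIS = "diagnosis"
    MEDICATION = "medication"
    PROCEDURE = "procedure"
    LAB = "lab"


#: Default modality when the caller does not state one. ICD systems carry
#: both diagnoses and procedures; diagnosis is the common case.
_DEFAULT_MODALITY = {
    CodingSystem.ICD9: Modality.DIAGNOSIS,
    CodingSystem.ICD10: Modality.DIAGNOSIS,
    CodingSystem.NDC: Modality.MEDICATION,
    CodingSystem.CPT: Modality.PROCEDURE,
    CodingSystem.LOINC: Modality.LAB,
    CodingSystem.OTHER: Modality.DIAGNOSIS,
}

_ICD_SYSTEMS = (CodingSystem.ICD9, CodingSystem.ICD10)


@dataclass(frozen=True, order=True)
class MedicalCode:
    """One standardized clinical concept (e.g. an ICD-9 diagnosis)."""

    system: CodingSystem
    value: str
    modality: Modality

    def __post_init__(self) -> None:
        if not self.value:
            raise CohortValidationError("medical code value must be non-empty")

    def key(self) -> tuple[str, str]:
        return (self.system.value, self.value)


def normalize_code(
    raw: str,
    system: CodingSystem,
    modality: Optional[Modality] = None,
) -> MedicalCode:
    """Normalize a raw code string into a :class:`MedicalCode`.

    ICD codes are uppercased and dot-stripped (source systems disagree on
    dotted vs flat forms; all downstream prefix matching assumes the flat
    form).  Other systems are whitespace-trimmed only -- LOINC codes keep
    their hyphen.  Normalization is idempotent.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise CohortValidationError("cannot normalize an empty code string")
    system = CodingSystem(system)
    value = raw.strip()
    if system in _ICD_SYSTEMS:
        value = value.upper().replace(".", "")
    if modality is None:
        modality = _DEFAULT_MODALITY[system]
    return MedicalCode(system=system, value=value, modality=Modality(modality))


# Delivery-outcome labeling on normalized (dot-stripped) ICD-9 codes.
_PRETERM_PREFIX = "6442"          # 644.2x
_FULLTERM_PREFIX = "645"          # 645.xx
_FULLTERM_EXACT = frozenset({"6498", "650", "6525"})  # 649.8, 650, 652.5


def label_from_diagnoses(codes: Iterable[MedicalCode]) -> Optional[int]:
    """Outcome label from the ICD-9 codes of a delivery visit.

    Returns 1 (preterm) if any ICD-9 code falls under 644.2x, 0 (full term)
    if any matches 645.xx / 649.8 / 650 / 652.5, and ``None`` when no
    labeling code is present.  Preterm takes precedence when both families
    appear: the positive class is the rarer, clinically critical one.
    """
    found_fullterm = False
    for code in codes:
        if code.system is not CodingSystem.ICD9:
            continue
        if code.value.startswith(_PRETERM_PREFIX):
            return 1
        if code.value.startswith(_FULLTERM_PREFIX) or code.value in _FULLTERM_EXACT:
            found_fullterm = True
    return 0 if found_fullterm else None


@dataclass(frozen=True)
class Visit:
    """One dated encounter: a non-empty set of distinct medical codes."""

    date: datetime.date
    codes: frozenset[MedicalCode]

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))
        if not self.codes:
            raise CohortValidationError(f"visit on {self.date} has no codes")
        keys = [c.key() for c in self.codes]
        if len(set(keys)) != len(keys):
            raise CohortValidationError(
                f"visit on {self.date} has duplicate (system, value) pairs"
            )

    def sorted_codes(self) -> list[MedicalCode]:
        return sorted(self.codes)


@dataclass(frozen=True)
class PatientRecord:
    """A delivery-anchored patient timeline.

    ``visits`` are in nondecreasing date order; ``delivery_date`` anchors
    the prediction points.  ``label`` is 1 for preterm, 0 for full term,
    ``None`` while unlabeled.
    """

    patient_id: str
    visits: tuple[Visit, ...]
    delivery_date: datetime.date
    pregnancy_start_date: Optional[datetime.date] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "visits", tuple(self.visits))
        dates = [v.date for v in self.visits]
        if any(a > b for a, b in zip(dates, dates[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: visits not in date order"
            )
        if dates and self.delivery_date < dates[0]:
            raise CohortValidationError(
                f"patient {self.patient_id}: delivery precedes first visit"
            )
        if (
            self.pregnancy_start_date is not None
            and self.pregnancy_start_date >= self.delivery_date
        ):
            raise CohortValidationError(
                f"patient {self.patient_id}: pregnancy start not before delivery"
            )
        if self.label is not None and self.label not in (0, 1):
            raise CohortValidationError(
                f"patient {self.patient_id}: label must be 0, 1 or unset"
            )

    def n_visits(self) -> int:
        return len(self.visits)


def find_delivery_visit(
    visits: Sequence[Visit],
) -> Optional[tuple[int, datetime.date, int]]:
    """Locate the delivery visit in a raw timeline.

    The delivery visit is the *last* visit containing any labeling code;
    its date defines the delivery date.  Returns ``(index, date, label)``
    or ``None`` when no visit carries a labeling code.
    """
    for idx in range(len(visits) - 1, -1, -1):
        label = label_from_diagnoses(visits[idx].codes)
        if label is not None:
            return idx, visits[idx].date, label
    return None


class Vocabulary:
    """Bijective code <-> index mapping, partitioned by modality.

    Entry order is the index order and is stable across save/load.
    Out-of-vocabulary codes seen by :func:`encode_visit` are dropped and
    tallied on :attr:`oov_count` (vocabularies are built on training data
    only, so unseen codes at inference are expected).
    """

    def __init__(
        self,
        entries: Sequence[MedicalCode],
        frequencies: Optional[Sequence[int]] = None,
    ) -> None:
        self.entries: list[MedicalCode] = list(entries)
        if frequencies is None:
            frequencies = [0] * len(self.entries)
        self.frequencies: list[int] = list(frequencies)
        if len(self.frequencies) != len(self.entries):
            raise CohortValidationError("frequencies must align with entries")
        self.index_of: dict[tuple[str, str], int] = {
            c.key(): i for i, c in enumerate(self.entries)
        }
        if len(self.index_of) != len(self.entries):
            raise CohortValidationError("vocabulary entries must be unique")
        self.oov_count: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: MedicalCode) -> bool:
        return code.key() in self.index_of

    def index(self, code: MedicalCode) -> int:
        return self.index_of[code.key()]

    def modality_indices(self, modalities: Iterable[Modality]) -> np.ndarray:
        wanted = {Modality(m) for m in modalities}
        return np.array(
            [i for i, c in enumerate(self.entries) if c.modality in wanted],
            dtype=np.int64,
        )

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], min_count: int = 1
    ) -> "Vocabulary":
        """Build a vocabulary from observed codes, most frequent first."""
        counts: Counter[MedicalCode] = Counter()
        for rec in records:
            for visit in rec.visits:
                counts.update(visit.codes)
        items = [(c, n) for c, n in counts.items() if n >= min_count]
        items.sort(key=lambda it: (-it[1], it[0]))
        return cls([c for c, _ in items], [n for _, n in items])

    def save(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["index", "system", "value", "modality", "train_frequency"])
            for i, (code, freq) in enumerate(zip(self.entries, self.frequencies)):
                writer.writerow([i, code.system.value, code.value, code.modality.value, freq])

    @classmethod
    def load(cls, path) -> "Vocabulary":
        entries: list[MedicalCode] = []
        freqs: list[int] = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None or header[:4] != ["index", "system", "value", "modality"]:
                raise CohortValidationError(f"{path}: not a vocabulary TSV")
            for row in reader:
                idx, system, value, modality = row[0], row[1], row[2], row[3]
                if int(idx) != len(entries):
                    raise CohortValidationError(f"{path}: non-contiguous index {idx}")
                entries.append(
                    MedicalCode(CodingSystem(system), value, Modality(modality))
                )
                freqs.append(int(row[4]) if len(row) > 4 else 0)
        return cls(entries, freqs)


def encode_visit(visit: Visit, vocab: Vocabulary) -> np.ndarray:
    """Multi-hot indicator vector of length ``|C|`` for one visit.

    Codes absent from the vocabulary are dropped and counted on
    ``vocab.oov_count``.
    """
    vec = np.zeros(len(vocab), dtype=np.float32)
    for code in visit.codes:
        idx = vocab.index_of.get(code.key())
        if idx is None:
            vocab.oov_count += 1
        else:
            vec[idx] = 1.0
    return vec


def apply_inclusion_rules(
    records: Iterable[PatientRecord],
    min_visits: int = 2,
    max_visits: int = 200,
) -> list[PatientRecord]:
    """Enforce the cohort inclusion rules.

    Patients with fewer than ``min_visits`` visits are excluded; patients
    with more than ``max_visits`` keep only their most recent
    ``max_visits`` visits (order preserved).  Idempotent.
    """
    kept: list[PatientRecord] = []
    for rec in records:
        n = rec.n_visits()
        if n < min_visits:
            continue
        if n > max_visits:
            rec = replace(rec, visits=rec.visits[-max_visits:])
        kept.append(rec)
    return kept


# ----------------------------------------------------------------------
# JSON Lines serialization
# ----------------------------------------------------------------------

def _code_to_json(code: MedicalCode) -> dict:
    return {"system": code.system.value, "value": code.value, "modality": code.modality.value}


def _record_to_json(rec: PatientRecord) -> dict:
    return {
        "patient_id": rec.patient_id,
        "visits": [
            {"date": v.date.isoformat(), "codes": [_code_to_json(c) for c in v.sorted_codes()]}
            for v in rec.visits
        ],
        "delivery_date": rec.delivery_date.isoformat(),
        "pregnancy_start_date": (
            rec.pregnancy_start_date.isoformat() if rec.pregnancy_start_date else None
        ),
        "label": rec.label,
    }


def _record_from_json(obj: dict) -> PatientRecord:
    visits = tuple(
        Visit(
            date=datetime.date.fromisoformat(v["date"]),
            codes=frozenset(
                MedicalCode(CodingSystem(c["system"]), c["value"], Modality(c["modality"]))
                for c in v["codes"]
            ),
        )
        for v in obj["visits"]
    )
    start = obj.get("pregnancy_start_date")
    return PatientRecord(
        patient_id=obj["patient_id"],
        visits=visits,
        delivery_date=datetime.date.fromisoformat(obj["delivery_date"]),
        pregnancy_start_date=datetime.date.fromisoformat(start) if start else None,
        label=obj.get("label"),
    )


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write a cohort as JSON Lines (one patient per line, sorted codes)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_json(rec), separators=(",", ":")))
            fh.write("\n")


def read_cohort(path) -> list[PatientRecord]:
    """Read a JSON Lines cohort; errors name the offending line number."""
    records: list[PatientRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortValidationError(f"{path}: line {lineno}: malformed JSON ({exc})")
            try:
                records.append(_record_from_json(obj))
            except (KeyError, ValueError, TypeError) as exc:
                raise CohortValidationError(f"{path}: line {lineno}: {exc}")
    return records
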