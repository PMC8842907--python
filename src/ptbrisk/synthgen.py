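"""Synthetic delivery-anchored EHR cohorts with planted, time-localized risk codes.

The study-scale data behind preterm-birth EHR models is proprietary, so
this generator emulates its structure at desk scale: four code modalities
with Zipf-distributed background usage, ~8% preterm prevalence, Poisson
visit counts, timelines spanning three years before delivery, and a small
set of *risk codes* whose presence inside an active window shortly before
delivery raises the preterm probability through a logistic model.

Generation per patient:

1. draw a delivery date and a Poisson number of visits (>= 2) on distinct
   days uniform over the history span before delivery;
2. fill visits with background codes drawn Zipf-per-modality;
3. for each risk code, draw an exposure indicator; exposed patients get
   the code placed in a visit inside its active window (an existing
   in-window visit is reused; otherwise a new visit is created there, so
   the timeline outside the window carries no trace of the exposure);
4. draw the label from P(preterm) = logistic(intercept + sum of exposed
   effects), the intercept solved numerically so the expected prevalence
   matches the configured one;
5. append a delivery visit carrying the appropriate ICD-9 labeling code.

The exposure indicators and per-patient linear predictors are returned as
ground truth for parameter-recovery experiments.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (
    CodingSystem,
    CohortValidationError,
    MedicalCode,
    Modality,
    PatientRecord,
    Visit,
    Vocabulary,
)

__all__ = [
    "RiskCode",
    "GeneratorConfig",
    "GroundTruth",
    "build_synthetic_vocabulary",
    "generate_cohort",
    "summarize_cohort",
]

# Scaled-down echo of the study vocabulary (diagnosis-dominated).
DEFAULT_VOCAB_SIZES = {
    Modality.DIAGNOSIS: 500,
    Modality.MEDICATION: 100,
    Modality.PROCEDURE: 150,
    Modality.LAB: 120,
}

_MODALITY_SYSTEM = {
    Modality.DIAGNOSIS: CodingSystem.ICD9,
    Modality.MEDICATION: CodingSystem.NDC,
    Modality.PROCEDURE: CodingSystem.CPT,
    Modality.LAB: CodingSystem.LOINC,
}
_MODALITY_PREFIX = {
    Modality.DIAGNOSIS: "D",
    Modality.MEDICATION: "M",
    Modality.PROCEDURE: "P",
    Modality.LAB: "L",
}
_MODALITY_ORDER = (
    Modality.DIAGNOSIS,
    Modality.MEDICATION,
    Modality.PROCEDURE,
    Modality.LAB,
)

PRETERM_DELIVERY_CODE = MedicalCode(CodingSystem.ICD9, "64421", Modality.DIAGNOSIS)
FULLTERM_DELIVERY_CODE = MedicalCode(CodingSystem.ICD9, "650", Modality.DIAGNOSIS)

#: Gestation length assumed for every synthetic pregnancy (days).
PREGNANCY_LENGTH_DAYS = 270


@dataclass(frozen=True)
class RiskCode:
    """A planted risk factor: a vocabulary index with a log-odds effect,
    active only within a window of days before delivery."""

    vocab_index: int
    effect: float
    active_window_days: int = 90
    exposure_prob: float = 0.25

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise CohortValidationError("risk-code effect must be finite")
        if not 0.0 <= self.exposure_prob <= 1.0:
            raise CohortValidationError("exposure_prob must lie in [0, 1]")
        if self.active_window_days < 1:
            raise CohortValidationError("active_window_days must be >= 1")


def default_risk_codes(
    effect: float = 2.5,
    active_window_days: int = 90,
    exposure_prob: float = 0.25,
) -> list[RiskCode]:
    """Three diagnosis risk codes at mid-frequency Zipf ranks (50/130/210):
    rare enough that background draws add little noise, common enough to
    appear in every training split."""
    return [
        RiskCode(rank - 1, effect, active_window_days, exposure_prob)
        for rank in (50, 130, 210)
    ]


@dataclass
class GeneratorConfig:
    n_patients: int = 1000
    vocab_sizes: dict = field(default_factory=lambda: dict(DEFAULT_VOCAB_SIZES))
    preterm_prevalence: float = 0.08
    visits_mean: float = 11.0
    codes_per_visit_mean: float = 4.0
    zipf_exponent: float = 1.2
    risk_codes: Optional[Sequence[RiskCode]] = None
    history_span_days: int = 1095
    seed: int = 0
    base_date: datetime.date = datetime.date(2019, 1, 1)
    emit_delivery_visit: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise CohortValidationError("n_patients must be positive")
        if not 0.0 < self.preterm_prevalence < 1.0:
            raise CohortValidationError("preterm_prevalence must lie in (0, 1)")
        if self.visits_mean <= 0 or self.codes_per_visit_mean <= 0:
            raise CohortValidationError("visit and code means must be positive")
        if self.zipf_exponent <= 0:
            raise CohortValidationError("zipf_exponent must be positive")
        self.vocab_sizes = {Modality(k): int(v) for k, v in self.vocab_sizes.items()}
        for mod, size in self.vocab_sizes.items():
            if size < 10:
                raise CohortValidationError(f"vocabulary for {mod.value} must be >= 10")
        if self.history_span_days < 30:
            raise CohortValidationError("history_span_days must be >= 30")
        if self.risk_codes is None:
            self.risk_codes = default_risk_codes()
        self.risk_codes = [
            rc if isinstance(rc, RiskCode) else RiskCode(*rc) for rc in self.risk_codes
        ]
        n_codes = sum(self.vocab_sizes.values())
        for rc in self.risk_codes:
            if not 0 <= rc.vocab_index < n_codes:
                raise CohortValidationError(
                    f"risk code index {rc.vocab_index} outside vocabulary of {n_codes}"
                )


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery experiments."""

    risk_codes: list[RiskCode]
    intercept: float
    exposures: np.ndarray        # (n_patients, n_risk_codes) 0/1
    linear_predictors: np.ndarray  # intercept + exposures @ effects
    labels: np.ndarray

    def to_json(self) -> dict:
        return {
            "risk_codes": [asdict(rc) for rc in self.risk_codes],
            "intercept": self.intercept,
            "exposures": self.exposures.astype(int).tolist(),
            "linear_predictors": self.linear_predictors.tolist(),
            "labels": self.labels.astype(int).tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)


def build_synthetic_vocabulary(vocab_sizes: Optional[dict] = None) -> Vocabulary:
    """Symbolic codes per modality: D0000.., M0000.., P0000.., L0000..

    Index order is diagnosis block, then medication, procedure, lab; within
    a block, ascending Zipf rank (index 0 = most frequent diagnosis code).
    """
    sizes = {Modality(k): int(v) for k, v in (vocab_sizes or DEFAULT_VOCAB_SIZES).items()}
    entries = []
    for mod in _MODALITY_ORDER:
        size = sizes.get(mod, 0)
        system = _MODALITY_SYSTEM[mod]
        prefix = _MODALITY_PREFIX[mod]
        for i in range(size):
            entries.append(MedicalCode(system, f"{prefix}{i:04d}", mod))
    return Vocabulary(entries)


def _background_probs(config: GeneratorConfig) -> np.ndarray:
    """Per-code draw probability: Zipf within modality, blocks weighted by size."""
    total = sum(config.vocab_sizes.get(m, 0) for m in _MODALITY_ORDER)
    chunks = []
    for mod in _MODALITY_ORDER:
        size = config.vocab_sizes.get(mod, 0)
        if size == 0:
            continue
        ranks = np.arange(1, size + 1, dtype=np.float64)
        w = ranks ** (-config.zipf_exponent)
        w *= (size / total) / w.sum()
        chunks.append(w)
    probs = np.concatenate(chunks)
    return probs / probs.sum()


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a labeled, delivery-anchored synthetic cohort.

    Deterministic for a fixed config (including seed).  Returns the
    records plus the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    vocab = build_synthetic_vocabulary(config.vocab_sizes)
    probs = _background_probs(config)
    n = config.n_patients
    risk = list(config.risk_codes)
    effects = np.array([rc.effect for rc in risk], dtype=np.float64)

    # --- exposures, intercept, labels -------------------------------------
    exposures = (
        rng.random((n, len(risk))) < np.array([rc.exposure_prob for rc in risk])
    ).astype(np.float64) if risk else np.zeros((n, 0))
    lin = exposures @ effects if risk else np.zeros(n)

    def mean_prev(b0: float) -> float:
        return float(np.mean(expit(b0 + lin))) - config.preterm_prevalence

    intercept = float(brentq(mean_prev, -30.0, 30.0))
    labels = (rng.random(n) < expit(intercept + lin)).astype(np.int64)

    # --- timelines ---------------------------------------------------------
    records: list[PatientRecord] = []
    span = config.history_span_days
    for i in range(n):
        delivery = config.base_date + datetime.timedelta(
            days=int(rng.integers(0, 365))
        )
        n_visits = max(2, int(rng.poisson(config.visits_mean)))
        n_visits = min(n_visits, span)
        # distinct days-before-delivery in [1, span]
        days = rng.choice(np.arange(1, span + 1), size=n_visits, replace=False)
        day_codes: dict[int, set[int]] = {}
        for d in days:
            k = 1 + int(rng.poisson(config.codes_per_visit_mean - 1.0))
            day_codes[int(d)] = set(rng.choice(len(vocab), size=k, p=probs).tolist())

        # plant exposed risk codes inside their active windows
        for r_idx, rc in enumerate(risk):
            if not exposures[i, r_idx]:
                continue
            window = min(rc.active_window_days, span)
            in_window = [d for d in day_codes if d <= window]
            if in_window:
                target = int(rng.choice(in_window))
            else:
                # no visit inside the window: add one (with background
                # codes) rather than moving an existing visit -- moving
                # would leave an exposure trace in the pre-window timeline
                target = int(rng.integers(1, window + 1))
                while target in day_codes:
                    target = int(rng.integers(1, window + 1))
                k = 1 + int(rng.poisson(config.codes_per_visit_mean - 1.0))
                day_codes[target] = set(
                    rng.choice(len(vocab), size=k, p=probs).tolist()
                )
            day_codes[target].add(rc.vocab_index)

        visits = [
            Visit(
                date=delivery - datetime.timedelta(days=d),
                codes=frozenset(vocab.entries[c] for c in code_idx),
            )
            for d, code_idx in sorted(day_codes.items(), reverse=True)
        ]
        if config.emit_delivery_visit:
            delivery_code = (
                PRETERM_DELIVERY_CODE if labels[i] else FULLTERM_DELIVERY_CODE
            )
            visits.append(Visit(date=delivery, codes=frozenset({delivery_code})))

        records.append(
            PatientRecord(
                patient_id=f"synth-{i:06d}",
                visits=tuple(visits),
                delivery_date=delivery,
                pregnancy_start_date=delivery
                - datetime.timedelta(days=PREGNANCY_LENGTH_DAYS),
                label=int(labels[i]),
            )
        )

    truth = GroundTruth(
        risk_codes=risk,
        intercept=intercept,
        exposures=exposures.astype(np.int64),
        linear_predictors=intercept + lin,
        labels=labels,
    )
    return records, truth


def summarize_cohort(records: Sequence[PatientRecord]) -> dict:
    """Deterministic cohort summary in the usual reporting shape.

    ``mean_visits`` counts pre-delivery visits (the delivery visit carries
    the label, not history).  Class counts sum to the cohort size.
    """
    if not records:
        raise CohortValidationError("cannot summarize an empty cohort")
    n = len(records)
    n_pre = sum(1 for r in records if r.label == 1)
    n_full = sum(1 for r in records if r.label == 0)
    visit_counts = []
    code_counts = []
    modality_usage = {m.value: 0 for m in Modality}
    for rec in records:
        pre_delivery = [v for v in rec.visits if v.date < rec.delivery_date]
        visit_counts.append(len(pre_delivery))
        for v in pre_delivery:
            code_counts.append(len(v.codes))
            for c in v.codes:
                modality_usage[c.modality.value] += 1
    return {
        "n_patients": n,
        "n_preterm": n_pre,
        "n_fullterm": n_full,
        "n_unlabeled": n - n_pre - n_full,
        "prevalence": n_pre / max(1, n_pre + n_full),
        "mean_visits": float(np.mean(visit_counts)),
        "mean_codes_per_visit": float(np.mean(code_counts)) if code_counts else 0.0,
        "modality_code_usage": modality_usage,
    }
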