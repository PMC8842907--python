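"""Stratified splitting, imbalance-aware metrics, and the experiment grid.

The evaluation protocol: patients split 70/10/20 into train/validation/
test with the preterm:full-term ratio preserved in each split; models
scored by ROC-AUC, PR-AUC, sensitivity and specificity (PR-AUC being the
imbalance-robust headline metric); and a grid runner crossing prediction
points x data windows x modality subsets x model kinds.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import CohortValidationError, Modality, PatientRecord, Visit
from .slicing import SliceSpec, slice_record

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "ExperimentGrid",
    "stratified_split",
    "compute_metrics",
    "youden_threshold",
    "modality_filter",
    "run_grid",
    "write_grid_results",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    val_fraction: float = 0.10
    test_fraction: float = 0.20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise CohortValidationError("split fractions must sum to 1")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.train_fraction, self.val_fraction, self.test_fraction)


def _quota(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items over the fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def stratified_split(
    records: Sequence[PatientRecord], spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index partition.

    Per class, split sizes follow largest-remainder quotas, so each
    split's class count is within one patient of its target.  Seeded and
    deterministic.
    """
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise CohortValidationError("cannot split unlabeled records")
    rng = np.random.default_rng(spec.seed)
    splits: list[list[int]] = [[], [], []]
    groups: Iterable[np.ndarray]
    if spec.stratified:
        labels_arr = np.asarray(labels)
        groups = [np.flatnonzero(labels_arr == cls) for cls in (0, 1)]
        for g in groups:
            if 0 < len(g) < 3:
                raise CohortValidationError(
                    "each outcome class needs >= 3 members to stratify"
                )
    else:
        groups = [np.arange(len(records))]
    for g in groups:
        g = rng.permutation(g)
        n_tr, n_va, n_te = _quota(len(g), spec.fractions)
        splits[0].extend(g[:n_tr])
        splits[1].extend(g[n_tr : n_tr + n_va])
        splits[2].extend(g[n_tr + n_va :])
    return tuple(np.sort(np.array(s, dtype=np.int64)) for s in splits)


@dataclass
class MetricsReport:
    roc_auc: float
    pr_auc: float
    sensitivity: float
    specificity: float
    threshold: float
    n: int
    n_pos: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """ROC-AUC (Mann-Whitney convention on ties), PR-AUC (precision-recall
    step curve), and sensitivity/specificity at ``threshold``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64)
    if scores.shape != labels.shape:
        raise CohortValidationError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise CohortValidationError("metrics need at least one of each class")
    roc = float(roc_auc_score(labels, scores))
    pr = float(average_precision_score(labels, scores))
    pred_pos = scores >= threshold
    sens = float(np.sum(pred_pos & (labels == 1)) / n_pos)
    spec = float(np.sum(~pred_pos & (labels == 0)) / n_neg)
    return MetricsReport(
        roc_auc=roc, pr_auc=pr, sensitivity=sens, specificity=spec,
        threshold=float(threshold), n=len(labels), n_pos=n_pos,
    )


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (ties: lowest)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64)
    candidates = np.unique(scores)
    best_t, best_j = candidates[0], -np.inf
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def modality_filter(
    records: Sequence[PatientRecord],
    modalities: Iterable[Modality | str],
    min_visits: int = 2,
) -> list[PatientRecord]:
    """Restrict every record to codes of the given modalities.

    Visits emptied of all codes are dropped; records left with fewer than
    ``min_visits`` visits are excluded.  Input records are not mutated.
    """
    wanted = {Modality(m) for m in modalities}
    if not wanted:
        raise CohortValidationError("modality subset must be non-empty")
    out: list[PatientRecord] = []
    for rec in records:
        visits = []
        for v in rec.visits:
            codes = frozenset(c for c in v.codes if c.modality in wanted)
            if codes:
                visits.append(Visit(date=v.date, codes=codes))
        if len(visits) >= min_visits:
            out.append(replace(rec, visits=tuple(visits)))
    return out


@dataclass
class ExperimentGrid:
    """The experiment cross: prediction offsets x windows x modality
    subsets x model kinds."""

    prediction_offsets: Sequence[int] = (1, 3, 6, 9)
    windows: Sequence[str] = ("long_term", "short_term")
    modality_subsets: Sequence[tuple] = (
        (Modality.DIAGNOSIS, Modality.MEDICATION, Modality.PROCEDURE, Modality.LAB),
    )
    model_kinds: Sequence[str] = ("code_attention",)
    days_per_month: int = 30

    def __post_init__(self) -> None:
        if not (self.prediction_offsets and self.windows
                and self.modality_subsets and self.model_kinds):
            raise CohortValidationError("grid axes must be non-empty")
        self.modality_subsets = [
            tuple(Modality(m) for m in subset) for subset in self.modality_subsets
        ]

    def cells(self):
        for offset in self.prediction_offsets:
            for window in self.windows:
                for subset in self.modality_subsets:
                    for kind in self.model_kinds:
                        yield offset, window, subset, kind


def _cell_seed(base_seed: int, offset: int, window: str, subset, kind: str) -> int:
    key = f"{base_seed}|{offset}|{window}|{','.join(m.value for m in subset)}|{kind}"
    return zlib.crc32(key.encode()) % (2**31)


def run_grid(
    grid: ExperimentGrid,
    records: Sequence[PatientRecord],
    model_config=None,
    split_spec: Optional[SplitSpec] = None,
    base_seed: int = 0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Slice, filter, train, and score one model per grid cell.

    Each cell gets a deterministic seed derived from its coordinates, so
    the table is invariant to the row order of the input cohort.
    Degenerate cells (too few patients or a single class after slicing)
    are marked skipped with a reason rather than raised.
    """
    from .models import ModelConfig, train  # deferred: avoids cycle

    model_config = model_config or ModelConfig()
    rows = []
    for offset, window, subset, kind in grid.cells():
        spec = SliceSpec(prediction_offset_months=offset, window=window,
                         days_per_month=grid.days_per_month)
        seed = _cell_seed(base_seed, offset, window, subset, kind)
        row = {
            "offset_months": offset,
            "window": window,
            "modalities": "+".join(m.value for m in subset),
            "model": kind,
            "seed": seed,
        }
        sliced = [r for r in (slice_record(rec, spec) for rec in records) if r]
        sliced = modality_filter(sliced, subset)
        labels = np.array([r.label for r in sliced])
        if len(sliced) < 30 or len(np.unique(labels)) < 2 or labels.sum() < 10:
            rows.append({**row, "status": "skipped",
                         "reason": "degenerate sliced cohort"})
            continue
        cfg = dataclasses.replace(model_config, seed=seed)
        cell_split = dataclasses.replace(split_spec or SplitSpec(), seed=seed)
        try:
            trained = train(kind, sliced, cfg, split_spec=cell_split)
        except CohortValidationError as exc:
            rows.append({**row, "status": "skipped", "reason": str(exc)})
            continue
        by_id = {r.patient_id: r for r in sliced}
        test_recs = [by_id[pid] for pid in trained.split_ids["test"]]
        y = np.array([r.label for r in test_recs])
        if len(np.unique(y)) < 2:
            rows.append({**row, "status": "skipped",
                         "reason": "single-class test split"})
            continue
        p = trained.predict_records(test_recs)
        rep = compute_metrics(p, y, threshold=threshold)
        rows.append({**row, "status": "ok", "reason": "",
                     "n_train": len(trained.split_ids["train"]),
                     **rep.to_dict()})
    return pd.DataFrame(rows)


def write_grid_results(df: pd.DataFrame, tsv_path, json_path=None,
                       provenance: Optional[dict] = None) -> None:
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {"provenance": provenance or {},
                   "rows": df.to_dict(orient="records")}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
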