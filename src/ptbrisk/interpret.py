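"""Exact additive attribution of the outcome logit to individual codes.

Because the context vector is c = sum_j beta_j * v_j with a linear
embedding (v_j = sum_k x_{j,k} W_emb[:,k]) and a single-logit head
(s = w.c + b), the logit decomposes exactly:

    s = b + sum_j sum_k omega(j, k),
    omega(j, k) = w . (beta_j * W_emb[:, k]) * x_{j,k}

so each code occurrence at each visit owns a signed share of the logit,
zero whenever the code is absent.  Visit-level contributions are the sums
of their member codes' omegas, and the identity carries over.  For the
RETAIN baseline the scalar visit weight enters as a factor:
omega = alpha_j * w.(beta_j * W_emb[:,k]) * x_{j,k}.

The identity requires the linear, bias-free embedding (the model
default); a relu/sigmoid embedding breaks additivity across codes and is
rejected rather than silently approximated.
"""

from __future__ import annotations

import csv
import datetime
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import MedicalCode, PatientRecord
from .models import TrainedModel

__all__ = [
    "CodeContribution",
    "AttributionReport",
    "UnsupportedModelError",
    "code_contributions",
    "visit_contributions",
    "top_codes",
    "export_timeline",
    "read_timeline",
]


class UnsupportedModelError(TypeError):
    """The model cannot produce an exact additive decomposition."""


@dataclass(frozen=True)
class CodeContribution:
    """The signed logit share of one code at one visit."""

    visit_index: int
    code_index: int
    code: MedicalCode
    visit_date: datetime.date
    omega: float


@dataclass
class AttributionReport:
    """All code contributions for one patient timeline, plus the model
    score they reconstruct: sum(omega) + bias = logit."""

    patient_id: str
    contributions: list[CodeContribution]
    visit_dates: list[datetime.date]
    logit: float
    probability: float
    bias: float

    def total_omega(self) -> float:
        return float(sum(c.omega for c in self.contributions))

    def reconstruction_error(self) -> float:
        """|logit - (bias + sum omega)|, relative to 1 + |logit|."""
        return abs(self.logit - (self.bias + self.total_omega())) / (
            1.0 + abs(self.logit)
        )

    def per_code_totals(self) -> dict[int, float]:
        totals: dict[int, float] = defaultdict(float)
        for c in self.contributions:
            totals[c.code_index] += c.omega
        return dict(totals)


def _check_supported(trained: TrainedModel) -> None:
    if trained.kind not in ("code_attention", "retain"):
        raise UnsupportedModelError(
            f"model kind {trained.kind!r} has no additive code decomposition"
        )
    cfg = trained.config
    if cfg.embedding_activation != "linear" or cfg.embedding_bias:
        raise UnsupportedModelError(
            "exact attribution requires a linear embedding without bias; "
            f"got activation={cfg.embedding_activation!r}, "
            f"bias={cfg.embedding_bias}"
        )


def code_contributions(
    record: PatientRecord, trained: TrainedModel
) -> AttributionReport:
    """Compute omega for every (visit, code) occurrence of a record.

    The report satisfies the additive identity against the model's own
    forward-pass logit; a reconstruction error above ~1e-10 indicates a
    model/attribution mismatch.
    """
    _check_supported(trained)
    if record.n_visits() < 1:
        raise UnsupportedModelError("record has no visits to attribute")
    fwd = trained.forward_record(record)
    P = trained.model.params
    beta = fwd["beta"][0]          # (T, m)
    index_lists = fwd["index_lists"]
    visits = record.visits[-trained.config.max_visits:]
    coef = P["w_out"] * beta       # (T, m); per-visit contribution coefficients
    if trained.kind == "retain":
        coef = coef * fwd["alpha"][0][:, None]
    contributions: list[CodeContribution] = []
    entries = trained.vocab.entries
    for j, idx in enumerate(index_lists):
        if len(idx) == 0:
            continue
        omegas = coef[j] @ P["W_emb"][:, idx]  # (len(idx),)
        for k, om in zip(idx, omegas):
            contributions.append(
                CodeContribution(
                    visit_index=j,
                    code_index=int(k),
                    code=entries[int(k)],
                    visit_date=visits[j].date,
                    omega=float(om),
                )
            )
    return AttributionReport(
        patient_id=record.patient_id,
        contributions=contributions,
        visit_dates=[v.date for v in visits],
        logit=float(fwd["s"][0]),
        probability=float(fwd["p"][0]),
        bias=float(P["b_out"][0]),
    )


def visit_contributions(report: AttributionReport) -> list[tuple[int, datetime.date, float]]:
    """Per-visit aggregates: (visit index, date, sum of member omegas).

    Conservation: the visit sums plus the bias reconstruct the logit.
    """
    totals: dict[int, float] = defaultdict(float)
    for c in report.contributions:
        totals[c.visit_index] += c.omega
    return [
        (j, report.visit_dates[j], totals.get(j, 0.0))
        for j in range(len(report.visit_dates))
    ]


def top_codes(
    reports: AttributionReport | Sequence[AttributionReport],
    k: int = 10,
    direction: str = "positive",
) -> list[tuple[MedicalCode, int, float]]:
    """Codes ranked by mean signed omega across the supplied reports.

    ``direction='positive'`` ranks by most risk-raising mean contribution,
    ``'negative'`` by most protective.  Ties break by ascending code
    index.  Returns (code, code_index, mean_omega) triples.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(reports, AttributionReport):
        reports = [reports]
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    sums: dict[int, float] = defaultdict(float)
    codes: dict[int, MedicalCode] = {}
    for rep in reports:
        for idx, total in rep.per_code_totals().items():
            sums[idx] += total
    for rep in reports:
        for c in rep.contributions:
            codes.setdefault(c.code_index, c.code)
    n = len(reports)
    means = [(idx, s / n) for idx, s in sums.items()]
    sign = -1.0 if direction == "positive" else 1.0
    means.sort(key=lambda it: (sign * it[1], it[0]))
    return [(codes[idx], idx, mean) for idx, mean in means[:k]]


def export_timeline(
    report: AttributionReport,
    path,
    plot_path: Optional[str] = None,
) -> None:
    """Write the attribution table as TSV (one row per code occurrence,
    with its visit aggregate), optionally plus a timeline figure."""
    visit_totals = {j: t for j, _, t in visit_contributions(report)}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["patient_id", "visit_index", "date", "system", "code", "modality",
             "omega", "visit_total", "logit", "probability", "bias"]
        )
        for c in sorted(report.contributions,
                        key=lambda c: (c.visit_index, c.code_index)):
            writer.writerow(
                [report.patient_id, c.visit_index, c.visit_date.isoformat(),
                 c.code.system.value, c.code.value, c.code.modality.value,
                 repr(c.omega), repr(visit_totals[c.visit_index]),
                 repr(report.logit), repr(report.probability),
                 repr(report.bias)]
            )
    if plot_path is not None:
        _plot_timeline(report, plot_path)


def read_timeline(path) -> list[dict]:
    """Re-read an exported attribution table (lossless for omega values)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            row["visit_index"] = int(row["visit_index"])
            for key in ("omega", "visit_total", "logit", "probability", "bias"):
                row[key] = float(row[key])
            rows.append(row)
    return rows


def _plot_timeline(report: AttributionReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_visit = visit_contributions(report)
    dates = [d for _, d, _ in per_visit]
    totals = [t for _, _, t in per_visit]
    fig, ax = plt.subplots(figsize=(9, 3.2))
    colors = ["#c0392b" if t > 0 else "#2980b9" for t in totals]
    ax.bar(dates, totals, width=6.0, color=colors)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("visit date")
    ax.set_ylabel("visit contribution (logit)")
    ax.set_title(
        f"patient {report.patient_id}: p(preterm)={report.probability:.3f}"
    )
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
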