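import datetime

import numpy as np
import pytest

from ptbrisk import cohort as co
from ptbrisk import models as md
from ptbrisk import synthgen as sg

D = datetime.date


def dx(value: str) -> co.MedicalCode:
    return co.normalize_code(value, co.CodingSystem.ICD9, co.Modality.DIAGNOSIS)


def visit(date, *codes):
    return co.Visit(date=date, codes=frozenset(codes))


@pytest.fixture
def toy_cohort():
    """Three hand-built patients with known dates, codes and labels."""
    a = co.PatientRecord(
        patient_id="a",
        visits=(
            visit(D(2019, 1, 10), dx("250.00")),
            visit(D(2019, 6, 1), dx("401.9"), dx("V22.1")),
            visit(D(2019, 9, 20), dx("644.21")),
        ),
        delivery_date=D(2019, 9, 20),
        pregnancy_start_date=D(2018, 12, 24),
        label=1,
    )
    b = co.PatientRecord(
        patient_id="b",
        visits=(
            visit(D(2018, 3, 5), dx("462")),
            visit(D(2020, 1, 2), dx("V22.0")),
            visit(D(2020, 5, 30), dx("650")),
        ),
        delivery_date=D(2020, 5, 30),
        pregnancy_start_date=D(2019, 9, 2),
        label=0,
    )
    c = co.PatientRecord(
        patient_id="c",
        visits=(
            visit(D(2020, 2, 1), dx("401.9")),
            visit(D(2020, 8, 15), dx("645.11")),
        ),
        delivery_date=D(2020, 8, 15),
        pregnancy_start_date=D(2019, 11, 19),
        label=0,
    )
    return [a, b, c]


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort shared across tests (deterministic)."""
    config = sg.GeneratorConfig(
        n_patients=200,
        vocab_sizes={"diagnosis": 30, "medication": 10, "procedure": 10, "lab": 10},
        visits_mean=6.0,
        seed=42,
        risk_codes=[sg.RiskCode(2, 2.5), sg.RiskCode(7, 2.0), sg.RiskCode(15, 2.0)],
    )
    records, truth = sg.generate_cohort(config)
    return records, truth, config


@pytest.fixture(scope="session")
def tiny_trained(small_cohort):
    """A quickly trained code-attention model for attribution tests."""
    records, _, _ = small_cohort
    records = co.apply_inclusion_rules(records)
    cfg = md.ModelConfig(
        embedding_size=8, rnn_hidden_size=6, epochs=4, patience=4,
        learning_rate=5e-3, seed=42,
    )
    return md.train("code_attention", records, cfg)


def random_params(model, rng, scale=0.5):
    """Overwrite a model's parameters with random values (the default
    init zeroes the attention head, which would trivialize identities)."""
    for k, v in model.params.items():
        model.params[k] = rng.normal(scale=scale, size=np.shape(v))
    for lstm in getattr(model, "lstms", []):
        lstm.params = model.params
    if hasattr(model, "lstm_a"):
        model.lstm_a.params = model.params
    return model
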