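import numpy as np
import pytest

from ptbrisk import cohort as co
from ptbrisk import interpret as it
from ptbrisk import models as md
from ptbrisk import synthgen as sg

from conftest import random_params


def make_trained(kind="code_attention", seed=0, act="linear", bias=False,
                 randomize=True, n_codes=12, m=5, q=4):
    """A TrainedModel wrapper around a (possibly random) small model."""
    cfg = md.ModelConfig(embedding_size=m, rnn_hidden_size=q,
                         embedding_activation=act, embedding_bias=bias, seed=seed)
    cls = {"code_attention": md.CodeAttentionModel, "retain": md.RetainModel,
           "mlp": md.MlpModel}[kind]
    model = cls(n_codes, cfg, np.random.default_rng(seed))
    if randomize:
        random_params(model, np.random.default_rng(seed + 100))
    vocab = sg.build_synthetic_vocabulary(
        {"diagnosis": 6, "medication": 2, "procedure": 2, "lab": 2}
    )
    return md.TrainedModel(kind=kind, model=model, vocab=vocab, config=cfg,
                           log={}, split_ids={"train": [], "val": [], "test": []})


def random_record(rng, vocab, T=4):
    import datetime

    delivery = datetime.date(2020, 6, 1)
    visits = []
    for t in range(T):
        k = int(rng.integers(1, 4))
        codes = frozenset(
            vocab.entries[i] for i in rng.choice(len(vocab), size=k, replace=False)
        )
        visits.append(co.Visit(date=delivery - datetime.timedelta(days=30 * (T - t)),
                               codes=codes))
    return co.PatientRecord("r", tuple(visits), delivery, label=1)


class TestDecomposition:
    def test_identity_random_models(self):
        for seed in range(10):
            trained = make_trained(seed=seed)
            rng = np.random.default_rng(seed)
            rec = random_record(rng, trained.vocab)
            report = it.code_contributions(rec, trained)
            assert report.reconstruction_error() < 1e-10

    def test_identity_retain(self):
        trained = make_trained("retain", seed=4)
        rec = random_record(np.random.default_rng(4), trained.vocab)
        report = it.code_contributions(rec, trained)
        assert report.reconstruction_error() < 1e-10

    def test_identity_trained_model(self, tiny_trained, small_cohort):
        records, _, _ = small_cohort
        for rec in records[:20]:
            report = it.code_contributions(rec, tiny_trained)
            assert report.reconstruction_error() < 1e-10

    def test_completeness_only_present_pairs(self):
        trained = make_trained(seed=1)
        rec = random_record(np.random.default_rng(1), trained.vocab)
        report = it.code_contributions(rec, trained)
        expected_pairs = {
            (j, trained.vocab.index(c))
            for j, v in enumerate(rec.visits)
            for c in v.codes
        }
        got_pairs = {(c.visit_index, c.code_index) for c in report.contributions}
        assert got_pairs == expected_pairs

    def test_zero_beta_visit_zero_omega(self):
        trained = make_trained(seed=2)
        trained.model.params["W_beta"][:] = 0.0
        trained.model.params["b_beta"][:] = 0.0
        rec = random_record(np.random.default_rng(2), trained.vocab)
        report = it.code_contributions(rec, trained)
        assert all(c.omega == 0.0 for c in report.contributions)

    def test_bias_shift_changes_logit_not_omegas(self):
        trained = make_trained(seed=3)
        rec = random_record(np.random.default_rng(3), trained.vocab)
        before = it.code_contributions(rec, trained)
        trained.model.params["b_out"] = trained.model.params["b_out"] + 5.0
        after = it.code_contributions(rec, trained)
        assert after.logit == pytest.approx(before.logit + 5.0)
        for a, b in zip(before.contributions, after.contributions):
            assert a.omega == pytest.approx(b.omega)

    @pytest.mark.parametrize("kwargs", [
        dict(kind="mlp"),
        dict(act="relu"),
        dict(act="sigmoid", bias=True),
        dict(bias=True),
    ])
    def test_unsupported_models_rejected(self, kwargs):
        trained = make_trained(**kwargs)
        rec = random_record(np.random.default_rng(0), trained.vocab)
        with pytest.raises(it.UnsupportedModelError):
            it.code_contributions(rec, trained)


class TestVisitContributions:
    def test_single_visit_equals_logit_minus_bias(self):
        trained = make_trained(seed=6)
        rec = random_record(np.random.default_rng(6), trained.vocab, T=1)
        report = it.code_contributions(rec, trained)
        (visit_row,) = it.visit_contributions(report)
        assert visit_row[2] == pytest.approx(report.logit - report.bias)

    def test_conservation(self):
        trained = make_trained(seed=7)
        rec = random_record(np.random.default_rng(7), trained.vocab, T=3)
        report = it.code_contributions(rec, trained)
        rows = it.visit_contributions(report)
        assert sum(t for _, _, t in rows) == pytest.approx(report.total_omega())

    def test_grouping_matches_brute_force(self):
        trained = make_trained(seed=8)
        rec = random_record(np.random.default_rng(8), trained.vocab, T=3)
        report = it.code_contributions(rec, trained)
        rows = {j: t for j, _, t in it.visit_contributions(report)}
        by_hand: dict[int, float] = {j: 0.0 for j in range(3)}
        for c in report.contributions:
            by_hand[c.visit_index] += c.omega
        for j in range(3):
            assert rows[j] == pytest.approx(by_hand[j])


class TestTopCodes:
    def test_k1_is_argmax(self):
        trained = make_trained(seed=9)
        rec = random_record(np.random.default_rng(9), trained.vocab)
        report = it.code_contributions(rec, trained)
        totals = report.per_code_totals()
        best_idx = max(totals, key=lambda i: (totals[i], -i))
        ((code, idx, value),) = it.top_codes(report, k=1, direction="positive")
        assert idx == best_idx

    def test_all_zero_model_index_order(self):
        trained = make_trained(seed=10)
        trained.model.params["w_out"][:] = 0.0
        rec = random_record(np.random.default_rng(10), trained.vocab)
        report = it.code_contributions(rec, trained)
        ranked = it.top_codes(report, k=5)
        indices = [idx for _, idx, _ in ranked]
        assert indices == sorted(indices)
        assert all(v == 0.0 for _, _, v in ranked)

    def test_negative_direction_flips(self):
        trained = make_trained(seed=11)
        rec = random_record(np.random.default_rng(11), trained.vocab)
        report = it.code_contributions(rec, trained)
        pos = it.top_codes(report, k=100, direction="positive")
        neg = it.top_codes(report, k=100, direction="negative")
        assert pos[0][2] == max(v for _, _, v in pos)
        assert neg[0][2] == min(v for _, _, v in neg)

    def test_invalid_args(self):
        trained = make_trained(seed=12)
        rec = random_record(np.random.default_rng(12), trained.vocab)
        report = it.code_contributions(rec, trained)
        with pytest.raises(ValueError):
            it.top_codes(report, k=0)
        with pytest.raises(ValueError):
            it.top_codes(report, k=1, direction="sideways")


class TestExportTimeline:
    def test_round_trip_lossless(self, tmp_path):
        trained = make_trained(seed=13)
        rec = random_record(np.random.default_rng(13), trained.vocab, T=3)
        report = it.code_contributions(rec, trained)
        path = tmp_path / "timeline.tsv"
        it.export_timeline(report, path)
        rows = it.read_timeline(path)
        assert len(rows) == len(report.contributions)
        by_key = {(c.visit_index, c.code.value): c for c in report.contributions}
        for row in rows:
            c = by_key[(row["visit_index"], row["code"])]
            assert row["omega"] == c.omega  # exact: repr round-trip
            assert row["logit"] == report.logit

    def test_rows_and_visit_aggregates(self, tmp_path):
        trained = make_trained(seed=14)
        rec = random_record(np.random.default_rng(14), trained.vocab, T=2)
        report = it.code_contributions(rec, trained)
        path = tmp_path / "t.tsv"
        it.export_timeline(report, path)
        rows = it.read_timeline(path)
        per_visit = {j: t for j, _, t in it.visit_contributions(report)}
        for j, visit in enumerate(rec.visits):
            visit_rows = [r for r in rows if r["visit_index"] == j]
            assert len(visit_rows) == len(visit.codes)
            for r in visit_rows:
                assert r["visit_total"] == pytest.approx(per_visit[j])

    def test_plot_file_written(self, tmp_path):
        trained = make_trained(seed=15)
        rec = random_record(np.random.default_rng(15), trained.vocab)
        report = it.code_contributions(rec, trained)
        png = tmp_path / "timeline.png"
        it.export_timeline(report, tmp_path / "t.tsv", plot_path=png)
        assert png.exists() and png.stat().st_size > 0
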