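import numpy as np
import pytest

from ptbrisk import cohort as co
from ptbrisk import models as md

from conftest import D, dx, random_params, visit
import _reference as ref


RNG = np.random.default_rng(1234)


def make_model(kind="code_attention", n_codes=6, m=4, q=3, act="linear",
               bias=False, direction="bidirectional", seed=0, randomize=True):
    cfg = md.ModelConfig(
        embedding_size=m, rnn_hidden_size=q, embedding_activation=act,
        embedding_bias=bias, direction=direction, seed=seed,
    )
    cls = {"code_attention": md.CodeAttentionModel, "retain": md.RetainModel,
           "mlp": md.MlpModel}[kind]
    model = cls(n_codes, cfg, np.random.default_rng(seed))
    if randomize:
        random_params(model, np.random.default_rng(seed + 1))
    return model


def random_instance(rng, n_codes=6, T=4, B=3):
    x = (rng.random((B, T, n_codes)) < 0.4).astype(float)
    mask = np.ones((B, T))
    if T > 1:
        mask[0, T - 1] = 0.0
    y = rng.integers(0, 2, size=B).astype(float)
    if y.sum() == 0:
        y[0] = 1.0
    return x, mask, y


class TestEmbedVisits:
    def test_zero_input_zero_output_linear(self):
        model = make_model()
        x = np.zeros((3, model.n_codes))
        np.testing.assert_allclose(md.embed_visits(x, model), 0.0)

    def test_relu_nonnegative(self):
        model = make_model(act="relu", bias=True)
        x = (RNG.random((5, 6)) < 0.5).astype(float)
        assert (md.embed_visits(x, model) >= 0).all()

    def test_one_hot_selects_column(self):
        model = make_model()
        x = np.zeros((1, 6))
        x[0, 4] = 1.0
        np.testing.assert_allclose(
            md.embed_visits(x, model)[0], model.params["W_emb"][:, 4]
        )

    def test_matches_scalar_loop(self):
        for act, bias in (("linear", False), ("relu", True), ("sigmoid", True)):
            model = make_model(act=act, bias=bias)
            x = (RNG.random((4, 6)) < 0.4).astype(float)
            got = md.embed_visits(x, model)
            want = ref.ref_embed(
                x.tolist(), model.params["W_emb"].tolist(),
                model.params.get("b_x", np.zeros(4)).tolist(), act,
            )
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        model = make_model()
        with pytest.raises(co.CohortValidationError):
            md.embed_visits(np.zeros((2, 9)), model)


class TestAttentionWeights:
    def test_range_open_interval(self):
        model = make_model()
        v = RNG.normal(size=(5, 4))
        beta = md.attention_weights(v, model)
        assert (np.abs(beta) < 1.0).all()

    def test_zero_head_zero_beta(self):
        model = make_model()
        model.params["W_beta"][:] = 0.0
        model.params["b_beta"][:] = 0.0
        v = RNG.normal(size=(5, 4))
        np.testing.assert_allclose(md.attention_weights(v, model), 0.0)

    def test_padding_leaves_real_steps_unchanged(self):
        model = make_model()
        v = RNG.normal(size=(1, 4, 4))
        mask = np.ones((1, 4))
        beta = md.attention_weights(v, model, mask)
        v_pad = np.concatenate([v, np.zeros((1, 3, 4))], axis=1)
        mask_pad = np.concatenate([mask, np.zeros((1, 3))], axis=1)
        beta_pad = md.attention_weights(v_pad, model, mask_pad)
        np.testing.assert_allclose(beta_pad[:, :4], beta, atol=1e-6)


class TestContextAndPredict:
    def test_identity_weighting(self):
        v = RNG.normal(size=(1, 4))
        beta = np.ones((1, 4))
        np.testing.assert_allclose(md.context_vector(beta, v), v[0])

    def test_zero_beta_zero_context(self):
        v = RNG.normal(size=(3, 4))
        np.testing.assert_allclose(md.context_vector(np.zeros((3, 4)), v), 0.0)

    def test_double_loop_oracle(self):
        beta = RNG.uniform(-1, 1, size=(3, 4))
        v = RNG.normal(size=(3, 4))
        mask = np.array([1.0, 1.0, 0.0])
        got = md.context_vector(beta, v, mask)
        want = ref.ref_context(beta.tolist(), v.tolist(), mask.tolist())
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_predict_degenerate_cases(self):
        model = make_model()
        model.params["b_out"][0] = 0.7
        assert md.predict(np.zeros(4), model) == pytest.approx(
            ref.sigmoid(0.7)
        )
        model.params["w_out"][:] = 0.0
        model.params["b_out"][0] = 0.0
        assert md.predict(RNG.normal(size=4), model) == pytest.approx(0.5)

    def test_predict_oracle(self):
        model = make_model()
        c = RNG.normal(size=4)
        p, s = ref.ref_predict(
            c.tolist(), model.params["w_out"].tolist(), model.params["b_out"][0]
        )
        assert md.predict(c, model) == pytest.approx(p, abs=1e-9)


class TestRetain:
    def test_single_visit_alpha_one(self):
        model = make_model("retain")
        x = (RNG.random((1, 1, 6)) < 0.6).astype(float)
        x[0, 0, 0] = 1.0
        fwd = model.forward(x, np.ones((1, 1)))
        assert fwd["alpha"][0, 0] == pytest.approx(1.0)

    def test_uniform_logits_uniform_alpha(self):
        model = make_model("retain", randomize=False)  # zero-init w_alpha
        x = (RNG.random((1, 4, 6)) < 0.5).astype(float)
        fwd = model.forward(x, np.ones((1, 4)))
        np.testing.assert_allclose(fwd["alpha"][0], 0.25)

    def test_alpha_sums_to_one_over_unmasked(self):
        model = make_model("retain")
        x, mask, _ = random_instance(np.random.default_rng(5))
        fwd = model.forward(x, mask)
        np.testing.assert_allclose((fwd["alpha"] * (mask > 0)).sum(axis=1), 1.0)
        assert (fwd["alpha"][mask == 0] == 0).all()

    def test_context_matches_double_loop_oracle(self):
        model = make_model("retain")
        x = (np.random.default_rng(6).random((1, 3, 6)) < 0.5).astype(float)
        mask = np.ones((1, 3))
        fwd = model.forward(x, mask)
        want = ref.ref_retain_context(
            fwd["alpha"][0].tolist(), fwd["beta"][0].tolist(), fwd["v"][0].tolist()
        )
        np.testing.assert_allclose(fwd["c"][0], want, atol=1e-6)

    def test_retain_forward_probability(self):
        model = make_model("retain")
        x = (RNG.random((2, 6)) < 0.5).astype(float)
        p = md.retain_forward(x, model)
        assert 0.0 < p < 1.0


class TestMlpFeatures:
    def test_counts_by_visit(self, toy_cohort):
        vocab = co.Vocabulary.from_records(toy_cohort)
        rec = toy_cohort[0]
        counts = md.mlp_features(rec, vocab)
        assert counts[vocab.index(dx("250.00"))] == 1
        assert counts.sum() == sum(len(v.codes) for v in rec.visits)

    def test_code_in_multiple_visits_counts_per_visit(self):
        rec = co.PatientRecord(
            "x",
            (
                visit(D(2020, 1, 1), dx("A"), dx("B")),
                visit(D(2020, 2, 1), dx("C")),
                visit(D(2020, 3, 1), dx("A")),
                visit(D(2020, 4, 1), dx("A"), dx("C")),
            ),
            D(2020, 4, 1),
            label=0,
        )
        vocab = co.Vocabulary([dx("A"), dx("B"), dx("C")])
        np.testing.assert_array_equal(md.mlp_features(rec, vocab), [3, 1, 2])

    def test_disjoint_vocab_zero_vector(self):
        rec = co.PatientRecord(
            "x", (visit(D(2020, 1, 1), dx("A")),), D(2020, 1, 1), label=0
        )
        vocab = co.Vocabulary([dx("Z")])
        np.testing.assert_array_equal(md.mlp_features(rec, vocab), [0])

    def test_visit_order_invariance(self):
        visits = [
            visit(D(2020, 1, 1), dx("A")),
            visit(D(2020, 2, 1), dx("B")),
            visit(D(2020, 3, 1), dx("A"), dx("C")),
        ]
        vocab = co.Vocabulary([dx("A"), dx("B"), dx("C")])
        base = co.PatientRecord("x", tuple(visits), D(2020, 3, 1), label=0)
        # same visits on permuted dates: the count features cannot change
        permuted_dates = [D(2020, 1, 1), D(2020, 2, 1), D(2020, 3, 1)]
        for order in ((2, 0, 1), (1, 2, 0)):
            reordered = tuple(
                co.Visit(date=d, codes=visits[i].codes)
                for d, i in zip(permuted_dates, order)
            )
            rec = co.PatientRecord("x", reordered, D(2020, 3, 1), label=0)
            np.testing.assert_array_equal(
                md.mlp_features(rec, vocab), md.mlp_features(base, vocab)
            )


class TestMaskInvariance:
    @pytest.mark.parametrize("kind,direction", [
        ("code_attention", "bidirectional"),
        ("code_attention", "reversed"),
        ("retain", "reversed"),
    ])
    def test_padding_changes_nothing(self, kind, direction):
        model = make_model(kind, direction=direction)
        rng = np.random.default_rng(9)
        x, mask, _ = random_instance(rng, T=5)
        mask[:] = 1.0
        out = model.forward(x, mask)
        x_pad = np.concatenate([x, np.zeros((3, 4, 6))], axis=1)
        mask_pad = np.concatenate([mask, np.zeros((3, 4))], axis=1)
        out_pad = model.forward(x_pad, mask_pad)
        np.testing.assert_allclose(out_pad["p"], out["p"], atol=1e-6)
        np.testing.assert_allclose(out_pad["s"], out["s"], atol=1e-6)


class TestGradients:
    """Analytic gradients vs central finite differences.

    Smooth activations only: relu's kink at exactly-zero pre-activations
    (empty visits with zero bias) makes the numerical probe invalid there.
    """

    def numeric_check(self, model, x, mask, y, eps=1e-6, tol=1e-6):
        _, grads = model.loss_and_grads(x, mask, y)
        worst = 0.0
        for k, g in grads.items():
            p = model.params[k]
            flat = np.random.default_rng(0).choice(
                p.size, size=min(p.size, 25), replace=False
            )
            for pos in flat:
                idx = np.unravel_index(pos, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = md._bce_loss_and_dlogit(
                    model.forward(x, mask)["s"], y, model.config.pos_weight
                )
                p[idx] = orig - eps
                lm, _ = md._bce_loss_and_dlogit(
                    model.forward(x, mask)["s"], y, model.config.pos_weight
                )
                p[idx] = orig
                worst = max(worst, abs((lp - lm) / (2 * eps) - np.asarray(g)[idx]))
        assert worst < tol

    @pytest.mark.parametrize("kind,act,bias,direction", [
        ("code_attention", "linear", False, "bidirectional"),
        ("code_attention", "sigmoid", True, "reversed"),
        ("retain", "linear", False, "reversed"),
        ("mlp", "linear", False, "bidirectional"),
    ])
    def test_models(self, kind, act, bias, direction):
        model = make_model(kind, act=act, bias=bias, direction=direction)
        x, mask, y = random_instance(np.random.default_rng(21))
        self.numeric_check(model, x, mask, y)


class TestBatching:
    def test_make_batch_shapes_and_mask(self):
        lists = [
            [np.array([0, 2]), np.array([1])],
            [np.array([3])],
        ]
        batch = md.make_batch(lists, n_codes=5, labels=np.array([1, 0]))
        assert batch.x.shape == (2, 2, 5)
        np.testing.assert_array_equal(batch.mask, [[1, 1], [1, 0]])
        assert batch.x[0, 0, 0] == 1 and batch.x[0, 0, 2] == 1
        assert batch.x[1, 1].sum() == 0

    def test_truncation_to_most_recent(self):
        lists = [[np.array([i]) for i in range(6)]]
        batch = md.make_batch(lists, n_codes=6, max_visits=4)
        assert batch.x.shape[1] == 4
        assert batch.x[0, 0, 2] == 1  # oldest two visits dropped


class TestTraining:
    def small_records(self):
        from ptbrisk import synthgen as sg

        config = sg.GeneratorConfig(
            n_patients=150,
            vocab_sizes={"diagnosis": 20, "medication": 10, "procedure": 10, "lab": 10},
            visits_mean=4.0,
            seed=3,
            risk_codes=[sg.RiskCode(1, 3.0, 365, 0.5)],
            history_span_days=365,
        )
        records, _ = sg.generate_cohort(config)
        return co.apply_inclusion_rules(records)

    def cfg(self, **over):
        base = dict(embedding_size=8, rnn_hidden_size=6, epochs=5, patience=5,
                    learning_rate=5e-3, seed=3)
        base.update(over)
        return md.ModelConfig(**base)

    @pytest.mark.parametrize("kind", ["code_attention", "retain", "mlp"])
    def test_loss_decreases(self, kind):
        trained = md.train(kind, self.small_records(), self.cfg())
        losses = trained.log["train_loss"]
        assert losses[-1] < losses[0]

    def test_seeded_determinism(self):
        records = self.small_records()
        a = md.train("code_attention", records, self.cfg())
        b = md.train("code_attention", records, self.cfg())
        assert a.log["val_loss"] == b.log["val_loss"]

    def test_single_class_rejected(self):
        records = [r for r in self.small_records() if r.label == 0][:40]
        with pytest.raises(co.CohortValidationError):
            md.train("mlp", records, self.cfg())

    def test_unknown_kind_rejected(self):
        with pytest.raises(co.CohortValidationError):
            md.train("transformer", self.small_records(), self.cfg())

    def test_save_load_round_trip(self, tmp_path, tiny_trained):
        tiny_trained.save(tmp_path / "model")
        loaded = md.load_model(tmp_path / "model")
        # predictions must be identical on arbitrary records
        from ptbrisk import synthgen as sg

        config = sg.GeneratorConfig(
            n_patients=20,
            vocab_sizes={"diagnosis": 30, "medication": 10, "procedure": 10, "lab": 10},
            visits_mean=6.0,
            seed=77,
            risk_codes=[sg.RiskCode(2, 2.5)],
        )
        recs, _ = sg.generate_cohort(config)
        np.testing.assert_allclose(
            loaded.predict_records(recs), tiny_trained.predict_records(recs),
            atol=1e-12,
        )
        assert loaded.n_parameters() == tiny_trained.n_parameters()

    def test_split_ids_partition(self, tiny_trained):
        ids = tiny_trained.split_ids
        all_ids = ids["train"] + ids["val"] + ids["test"]
        assert len(all_ids) == len(set(all_ids))
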