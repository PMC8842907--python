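"""Risk-prediction models over coded visit sequences.

Three models share one training harness:

* ``code_attention`` -- the primary architecture.  Each multi-hot visit
  x_i is embedded as v_i = sigma(W_emb x_i + b_x); a recurrent network
  (BiLSTM by default) over the embeddings produces hidden states h_j from
  which per-visit, per-dimension attention weights beta_j = tanh(W_beta
  h_j + b_beta) are computed; the patient context is the attention-gated
  sum c = sum_j beta_j * v_j; and the preterm probability is
  logistic(w.c + b).  The single-logit head keeps the per-code additive
  attribution exact (see :mod:`ptbrisk.interpret`).
* ``retain`` -- the two-level attention baseline: a second reversed-time
  RNN yields scalar visit weights alpha_j (softmax-normalized over
  unmasked visits), and the context becomes sum_j alpha_j beta_j * v_j.
* ``mlp`` -- a one-hidden-layer perceptron over per-patient code counts,
  discarding visit order.

All models are plain numpy with hand-written gradients (validated against
finite differences in the tests) and train by mini-batch Adam on binary
cross-entropy, with early stopping on validation PR-AUC.  Padded visit
positions are mask-gated out of every sum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import CohortValidationError, PatientRecord, Vocabulary
from .nn import LSTM, Adam, clip_grads, glorot, sigmoid

__all__ = [
    "ModelConfig",
    "PaddedBatch",
    "CodeAttentionModel",
    "RetainModel",
    "MlpModel",
    "TrainedModel",
    "MODEL_KINDS",
    "embed_visits",
    "attention_weights",
    "context_vector",
    "predict",
    "retain_forward",
    "mlp_features",
    "encode_record_indices",
    "make_batch",
    "train",
    "load_model",
]

MODEL_KINDS = ("code_attention", "retain", "mlp")

BIDIRECTIONAL = "bidirectional"
REVERSED = "reversed"


@dataclass
class ModelConfig:
    """Hyperparameters.  Defaults follow the reference setup (embedding
    200, hidden 200, batch 32, 200-visit cap); optimizer settings are this
    package's choices.  ``embedding_activation='linear'`` with
    ``embedding_bias=False`` keeps the code-level attribution exactly
    additive; relu/sigmoid are available where attribution exactness is
    not needed."""

    embedding_size: int = 200
    rnn_hidden_size: int = 200
    batch_size: int = 32
    embedding_activation: str = "linear"
    embedding_bias: bool = False
    direction: str = BIDIRECTIONAL
    max_visits: int = 200
    learning_rate: float = 1e-3
    epochs: int = 50
    patience: int = 5
    seed: int = 0
    pos_weight: float = 1.0
    mlp_hidden: int = 64
    grad_clip: float = 5.0
    #: coupled L2 penalty on weight matrices (never biases); with adaptive
    #: optimizers a coupled penalty regularizes far more effectively than
    #: decoupled decay on sparse high-dimensional code inputs
    l2_penalty: float = 0.0
    #: checkpoint-selection / early-stopping metric.  Validation loss is
    #: the default: with few positives in a small validation split,
    #: PR-AUC/ROC-AUC estimates are too noisy to pick checkpoints by.
    selection_metric: str = "val_loss"

    def __post_init__(self) -> None:
        for name in ("embedding_size", "rnn_hidden_size", "batch_size", "max_visits",
                     "epochs", "mlp_hidden"):
            if getattr(self, name) < 1:
                raise CohortValidationError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise CohortValidationError("learning_rate must be positive")
        if self.embedding_activation not in ("linear", "relu", "sigmoid"):
            raise CohortValidationError(
                f"unknown embedding activation {self.embedding_activation!r}"
            )
        if self.direction not in (BIDIRECTIONAL, REVERSED):
            raise CohortValidationError(f"unknown direction {self.direction!r}")
        if self.selection_metric not in ("val_loss", "pr_auc", "roc_auc"):
            raise CohortValidationError(
                f"unknown selection metric {self.selection_metric!r}"
            )


@dataclass
class PaddedBatch:
    """Dense multi-hot batch: (B, T, |C|) indicators, (B, T) mask, labels."""

    x: np.ndarray
    mask: np.ndarray
    labels: Optional[np.ndarray] = None


def _activate(pre: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return pre
    if kind == "relu":
        return np.maximum(pre, 0.0)
    return sigmoid(pre)


def _activate_grad(pre: np.ndarray, out: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return np.ones_like(pre)
    if kind == "relu":
        return (pre > 0).astype(pre.dtype)
    return out * (1.0 - out)


def _bce_loss_and_dlogit(s: np.ndarray, y: np.ndarray, pos_weight: float):
    """Mean binary cross-entropy on logits, numerically stable."""
    log_p = -np.logaddexp(0.0, -s)
    log_1mp = -np.logaddexp(0.0, s)
    w = np.where(y > 0.5, pos_weight, 1.0)
    loss = -np.mean(w * (y * log_p + (1.0 - y) * log_1mp))
    p = sigmoid(s)
    dlogit = w * (p - y) / s.shape[0]
    return float(loss), dlogit


# ----------------------------------------------------------------------
# model classes
# ----------------------------------------------------------------------

class CodeAttentionModel:
    """Code-level attention recurrent model (single-logit head)."""

    kind = "code_attention"

    def __init__(self, n_codes: int, config: ModelConfig, rng: np.random.Generator):
        m, q = config.embedding_size, config.rnn_hidden_size
        self.n_codes = n_codes
        self.config = config
        self.params: dict[str, np.ndarray] = {
            "W_emb": glorot(rng, n_codes, m, shape=(m, n_codes)),
            "W_beta": None,  # set below once H is known
            "b_beta": np.zeros(m),
            "w_out": glorot(rng, m, 1, shape=(m,)),
            "b_out": np.zeros(1),
        }
        if config.embedding_bias:
            self.params["b_x"] = np.zeros(m)
        if config.direction == BIDIRECTIONAL:
            self.lstm_f = LSTM(m, q, rng, "f_")
            self.lstm_b = LSTM(m, q, rng, "b_")
            self.lstms = [self.lstm_f, self.lstm_b]
            self.H = 2 * q
        else:
            self.lstm_r = LSTM(m, q, rng, "r_")
            self.lstms = [self.lstm_r]
            self.H = q
        # zero-init attention head: beta starts uniform (tanh(0.5) on every
        # dimension of every visit), so optimization starts from a plain
        # visit-summing linear classifier and attention grows on demand
        self.params["W_beta"] = np.zeros((m, self.H))
        self.params["b_beta"][:] = 0.5
        for lstm in self.lstms:
            self.params.update(lstm.params)
            lstm.params = self.params  # share storage

    def n_parameters(self) -> int:
        return sum(int(np.asarray(v).size) for v in self.params.values())

    def _hidden(self, v: np.ndarray, mask: np.ndarray):
        if self.config.direction == BIDIRECTIONAL:
            h_f, cache_f = self.lstm_f.forward(v, mask, reverse=False)
            h_b, cache_b = self.lstm_b.forward(v, mask, reverse=True)
            return np.concatenate([h_f, h_b], axis=2), (cache_f, cache_b)
        h_r, cache_r = self.lstm_r.forward(v, mask, reverse=True)
        return h_r, (cache_r,)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> dict:
        """Full forward pass; returns intermediates for backward/attribution."""
        P = self.params
        act = self.config.embedding_activation
        v_pre = np.tensordot(x, P["W_emb"].T, axes=([2], [0]))
        if "b_x" in P:
            v_pre = v_pre + P["b_x"]
        v_act = _activate(v_pre, act)
        v = v_act * mask[..., None]
        h, lstm_caches = self._hidden(v, mask)
        beta_pre = np.tensordot(h, P["W_beta"].T, axes=([2], [0])) + P["b_beta"]
        beta = np.tanh(beta_pre)
        c = np.sum(beta * v, axis=1)
        s = c @ P["w_out"] + P["b_out"][0]
        return {
            "x": x, "mask": mask, "v_pre": v_pre, "v_act": v_act, "v": v,
            "h": h, "lstm_caches": lstm_caches, "beta": beta, "c": c,
            "s": s, "p": sigmoid(s),
        }

    def backward(self, fwd: dict, dlogit: np.ndarray) -> dict:
        P = self.params
        x, mask = fwd["x"], fwd["mask"]
        v, beta, h, c = fwd["v"], fwd["beta"], fwd["h"], fwd["c"]
        grads: dict[str, np.ndarray] = {}
        grads["w_out"] = c.T @ dlogit
        grads["b_out"] = np.array([dlogit.sum()])
        dc = dlogit[:, None] * P["w_out"]
        dbeta = dc[:, None, :] * v
        dv = dc[:, None, :] * beta
        dbeta_pre = dbeta * (1.0 - beta**2)
        grads["W_beta"] = np.einsum("btm,bth->mh", dbeta_pre, h)
        grads["b_beta"] = dbeta_pre.sum(axis=(0, 1))
        dh = np.tensordot(dbeta_pre, P["W_beta"], axes=([2], [0]))
        if self.config.direction == BIDIRECTIONAL:
            q = self.config.rnn_hidden_size
            cache_f, cache_b = fwd["lstm_caches"]
            dv_f, g_f = self.lstm_f.backward(dh[..., :q], cache_f)
            dv_b, g_b = self.lstm_b.backward(dh[..., q:], cache_b)
            grads.update(g_f)
            grads.update(g_b)
            dv = dv + dv_f + dv_b
        else:
            (cache_r,) = fwd["lstm_caches"]
            dv_r, g_r = self.lstm_r.backward(dh, cache_r)
            grads.update(g_r)
            dv = dv + dv_r
        dv = dv * mask[..., None]
        dv_pre = dv * _activate_grad(fwd["v_pre"], fwd["v_act"],
                                     self.config.embedding_activation)
        grads["W_emb"] = np.einsum("btm,btc->mc", dv_pre, x)
        if "b_x" in P:
            grads["b_x"] = dv_pre.sum(axis=(0, 1))
        return grads

    def loss_and_grads(self, x, mask, y):
        fwd = self.forward(x, mask)
        loss, dlogit = _bce_loss_and_dlogit(fwd["s"], y, self.config.pos_weight)
        return loss, self.backward(fwd, dlogit)

    def scores(self, x, mask) -> np.ndarray:
        return self.forward(x, mask)["s"]


class RetainModel(CodeAttentionModel):
    """Two-level attention baseline: scalar visit weights alpha (softmax
    over unmasked visits, from a reversed-time RNN) on top of the code
    attention beta.  Context: c = sum_j alpha_j * beta_j * v_j."""

    kind = "retain"

    def __init__(self, n_codes: int, config: ModelConfig, rng: np.random.Generator):
        # RETAIN reads the record in reversed time in both branches
        config = dataclasses.replace(config, direction=REVERSED)
        super().__init__(n_codes, config, rng)
        q = config.rnn_hidden_size
        m = config.embedding_size
        self.lstm_a = LSTM(m, q, rng, "a_")
        self.params.update(self.lstm_a.params)
        self.lstm_a.params = self.params
        # zero-init: alpha starts exactly uniform over unmasked visits
        self.params["w_alpha"] = np.zeros(q)
        self.params["b_alpha"] = np.zeros(1)

    @staticmethod
    def _masked_softmax(e: np.ndarray, mask: np.ndarray) -> np.ndarray:
        e = np.where(mask > 0, e, -np.inf)
        e = e - e.max(axis=1, keepdims=True)
        w = np.exp(e) * (mask > 0)
        return w / w.sum(axis=1, keepdims=True)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> dict:
        P = self.params
        act = self.config.embedding_activation
        v_pre = np.tensordot(x, P["W_emb"].T, axes=([2], [0]))
        if "b_x" in P:
            v_pre = v_pre + P["b_x"]
        v_act = _activate(v_pre, act)
        v = v_act * mask[..., None]
        h, cache_b = self.lstm_r.forward(v, mask, reverse=True)
        g, cache_a = self.lstm_a.forward(v, mask, reverse=True)
        e = np.tensordot(g, P["w_alpha"], axes=([2], [0])) + P["b_alpha"][0]
        alpha = self._masked_softmax(e, mask)
        beta_pre = np.tensordot(h, P["W_beta"].T, axes=([2], [0])) + P["b_beta"]
        beta = np.tanh(beta_pre)
        c = np.sum(alpha[..., None] * beta * v, axis=1)
        s = c @ P["w_out"] + P["b_out"][0]
        return {
            "x": x, "mask": mask, "v_pre": v_pre, "v_act": v_act, "v": v,
            "h": h, "g": g, "cache_b": cache_b, "cache_a": cache_a,
            "alpha": alpha, "beta": beta, "c": c, "s": s, "p": sigmoid(s),
        }

    def backward(self, fwd: dict, dlogit: np.ndarray) -> dict:
        P = self.params
        x, mask = fwd["x"], fwd["mask"]
        v, beta, alpha, h, g, c = (
            fwd["v"], fwd["beta"], fwd["alpha"], fwd["h"], fwd["g"], fwd["c"]
        )
        grads: dict[str, np.ndarray] = {}
        grads["w_out"] = c.T @ dlogit
        grads["b_out"] = np.array([dlogit.sum()])
        dc = dlogit[:, None] * P["w_out"]
        dbeta = alpha[..., None] * dc[:, None, :] * v
        dv = alpha[..., None] * dc[:, None, :] * beta
        dalpha = np.einsum("bm,btm->bt", dc, beta * v)
        # softmax jacobian, gated by the mask
        inner = (alpha * dalpha).sum(axis=1, keepdims=True)
        de = alpha * (dalpha - inner)
        de = de * (mask > 0)
        grads["w_alpha"] = np.einsum("btq,bt->q", g, de)
        grads["b_alpha"] = np.array([de.sum()])
        dg = de[..., None] * P["w_alpha"]
        dbeta_pre = dbeta * (1.0 - beta**2)
        grads["W_beta"] = np.einsum("btm,bth->mh", dbeta_pre, h)
        grads["b_beta"] = dbeta_pre.sum(axis=(0, 1))
        dh = np.tensordot(dbeta_pre, P["W_beta"], axes=([2], [0]))
        dv_b, g_b = self.lstm_r.backward(dh, fwd["cache_b"])
        dv_a, g_a = self.lstm_a.backward(dg, fwd["cache_a"])
        grads.update(g_b)
        grads.update(g_a)
        dv = dv + dv_b + dv_a
        dv = dv * mask[..., None]
        dv_pre = dv * _activate_grad(fwd["v_pre"], fwd["v_act"],
                                     self.config.embedding_activation)
        grads["W_emb"] = np.einsum("btm,btc->mc", dv_pre, x)
        if "b_x" in P:
            grads["b_x"] = dv_pre.sum(axis=(0, 1))
        return grads


class MlpModel:
    """One-hidden-layer perceptron on per-patient code-count vectors."""

    kind = "mlp"

    def __init__(self, n_codes: int, config: ModelConfig, rng: np.random.Generator):
        self.n_codes = n_codes
        self.config = config
        h = config.mlp_hidden
        self.params = {
            "W1": glorot(rng, n_codes, h),
            "b1": np.zeros(h),
            "w2": glorot(rng, h, 1, shape=(h,)),
            "b2": np.zeros(1),
        }

    def n_parameters(self) -> int:
        return sum(int(np.asarray(v).size) for v in self.params.values())

    def forward(self, x: np.ndarray, mask: Optional[np.ndarray] = None) -> dict:
        # x may be a (B, T, C) batch (collapsed to counts) or (B, C) counts
        if x.ndim == 3:
            x = x.sum(axis=1)
        P = self.params
        z1 = x @ P["W1"] + P["b1"]
        a1 = np.maximum(z1, 0.0)
        s = a1 @ P["w2"] + P["b2"][0]
        return {"counts": x, "z1": z1, "a1": a1, "s": s, "p": sigmoid(s)}

    def backward(self, fwd: dict, dlogit: np.ndarray) -> dict:
        P = self.params
        grads = {
            "w2": fwd["a1"].T @ dlogit,
            "b2": np.array([dlogit.sum()]),
        }
        da1 = dlogit[:, None] * P["w2"]
        dz1 = da1 * (fwd["z1"] > 0)
        grads["W1"] = fwd["counts"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def loss_and_grads(self, x, mask, y):
        fwd = self.forward(x, mask)
        loss, dlogit = _bce_loss_and_dlogit(fwd["s"], y, self.config.pos_weight)
        return loss, self.backward(fwd, dlogit)

    def scores(self, x, mask=None) -> np.ndarray:
        return self.forward(x, mask)["s"]


_MODEL_CLASSES = {
    "code_attention": CodeAttentionModel,
    "retain": RetainModel,
    "mlp": MlpModel,
}


# ----------------------------------------------------------------------
# spec-level functional surface
# ----------------------------------------------------------------------

def embed_visits(x: np.ndarray, model: CodeAttentionModel) -> np.ndarray:
    """v_i = sigma(W_emb x_i + b_x) for a (T, |C|) or (B, T, |C|) input."""
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[-1] != model.n_codes:
        raise CohortValidationError(
            f"expected {model.n_codes} code columns, got {x.shape[-1]}"
        )
    pre = np.tensordot(x, model.params["W_emb"].T, axes=([2], [0]))
    if "b_x" in model.params:
        pre = pre + model.params["b_x"]
    v = _activate(pre, model.config.embedding_activation)
    return v[0] if squeeze else v


def attention_weights(
    v: np.ndarray, model: CodeAttentionModel, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-visit, per-dimension attention beta_j in (-1, 1)."""
    squeeze = v.ndim == 2
    if squeeze:
        v = v[None]
    if mask is None:
        mask = np.ones(v.shape[:2])
    v = v * mask[..., None]
    h, _ = model._hidden(v, mask)
    beta = np.tanh(
        np.tensordot(h, model.params["W_beta"].T, axes=([2], [0]))
        + model.params["b_beta"]
    )
    return beta[0] if squeeze else beta


def context_vector(
    beta: np.ndarray, v: np.ndarray, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """c = sum_j mask_j * (beta_j * v_j)."""
    squeeze = v.ndim == 2
    if squeeze:
        beta, v = beta[None], v[None]
    if mask is None:
        mask = np.ones(v.shape[:2])
    c = np.sum(beta * v * mask[..., None], axis=1)
    return c[0] if squeeze else c


def predict(c: np.ndarray, model) -> np.ndarray | float:
    """Preterm probability logistic(w.c + b) from a context vector."""
    squeeze = c.ndim == 1
    if squeeze:
        c = c[None]
    s = c @ model.params["w_out"] + model.params["b_out"][0]
    p = sigmoid(s)
    return float(p[0]) if squeeze else p


def retain_forward(x: np.ndarray, model: RetainModel):
    """RETAIN probability for a (T, |C|) record or (B, T, |C|) batch."""
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    fwd = model.forward(x, np.ones(x.shape[:2]))
    return float(fwd["p"][0]) if squeeze else fwd["p"]


def mlp_features(record: PatientRecord, vocab: Vocabulary) -> np.ndarray:
    """Per-code visit counts: entry k = number of visits containing code k."""
    counts = np.zeros(len(vocab), dtype=np.float64)
    for visit in record.visits:
        for code in visit.codes:
            idx = vocab.index_of.get(code.key())
            if idx is None:
                vocab.oov_count += 1
            else:
                counts[idx] += 1.0
    return counts


# ----------------------------------------------------------------------
# encoding and batching
# ----------------------------------------------------------------------

def encode_record_indices(
    record: PatientRecord, vocab: Vocabulary
) -> list[np.ndarray]:
    """Per-visit arrays of vocabulary indices (OOV codes dropped+counted)."""
    out = []
    for visit in record.visits:
        idx = []
        for code in visit.codes:
            j = vocab.index_of.get(code.key())
            if j is None:
                vocab.oov_count += 1
            else:
                idx.append(j)
        out.append(np.array(sorted(idx), dtype=np.int64))
    return out


def make_batch(
    index_lists: Sequence[Sequence[np.ndarray]],
    n_codes: int,
    labels: Optional[np.ndarray] = None,
    max_visits: int = 200,
) -> PaddedBatch:
    """Pad a set of visit-index sequences into a dense multi-hot batch,
    keeping each record's most recent ``max_visits`` visits."""
    seqs = [list(s)[-max_visits:] for s in index_lists]
    B = len(seqs)
    T = max(1, max(len(s) for s in seqs))
    x = np.zeros((B, T, n_codes), dtype=np.float64)
    mask = np.zeros((B, T), dtype=np.float64)
    for b, seq in enumerate(seqs):
        for t, idx in enumerate(seq):
            mask[b, t] = 1.0
            if len(idx):
                x[b, t, idx] = 1.0
    y = None if labels is None else np.asarray(labels, dtype=np.float64)
    return PaddedBatch(x=x, mask=mask, labels=y)


def _batched_scores(model, index_lists, n_codes, max_visits, chunk=256) -> np.ndarray:
    out = []
    for start in range(0, len(index_lists), chunk):
        batch = make_batch(index_lists[start : start + chunk], n_codes,
                           max_visits=max_visits)
        out.append(model.scores(batch.x, batch.mask))
    return np.concatenate(out) if out else np.zeros(0)


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted model plus everything needed to reuse it: vocabulary,
    config, training log, and the patient-id split it was fitted on."""

    kind: str
    model: object
    vocab: Vocabulary
    config: ModelConfig
    log: dict
    split_ids: dict

    def n_parameters(self) -> int:
        return self.model.n_parameters()

    def predict_records(self, records: Sequence[PatientRecord]) -> np.ndarray:
        lists = [encode_record_indices(r, self.vocab) for r in records]
        s = _batched_scores(self.model, lists, len(self.vocab),
                            self.config.max_visits)
        return sigmoid(s)

    def forward_record(self, record: PatientRecord) -> dict:
        """Single-record forward pass with intermediates (for attribution)."""
        lists = [encode_record_indices(record, self.vocab)]
        batch = make_batch(lists, len(self.vocab), max_visits=self.config.max_visits)
        fwd = self.model.forward(batch.x, batch.mask)
        fwd["index_lists"] = lists[0][-self.config.max_visits:]
        return fwd

    def save(self, dirpath) -> None:
        d = Path(dirpath)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "params.npz", **self.model.params)
        self.vocab.save(d / "vocabulary.tsv")
        vocab_hash = hashlib.sha256((d / "vocabulary.tsv").read_bytes()).hexdigest()
        sidecar = {
            "kind": self.kind,
            "config": dataclasses.asdict(self.config),
            "n_codes": len(self.vocab),
            "n_parameters": self.n_parameters(),
            "vocabulary_sha256": vocab_hash,
            "log": self.log,
            "split_ids": self.split_ids,
        }
        with open(d / "model.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def load_model(dirpath) -> TrainedModel:
    d = Path(dirpath)
    with open(d / "model.json") as fh:
        sidecar = json.load(fh)
    config = ModelConfig(**sidecar["config"])
    vocab = Vocabulary.load(d / "vocabulary.tsv")
    model = _MODEL_CLASSES[sidecar["kind"]](
        len(vocab), config, np.random.default_rng(0)
    )
    with np.load(d / "params.npz") as npz:
        for k in model.params:
            model.params[k] = npz[k]
    for lstm in getattr(model, "lstms", []):
        lstm.params = model.params
    if hasattr(model, "lstm_a"):
        model.lstm_a.params = model.params
    return TrainedModel(
        kind=sidecar["kind"], model=model, vocab=vocab, config=config,
        log=sidecar["log"], split_ids=sidecar["split_ids"],
    )


def train(
    model_kind: str,
    records: Sequence[PatientRecord],
    config: Optional[ModelConfig] = None,
    split_spec=None,
    vocab: Optional[Vocabulary] = None,
) -> TrainedModel:
    """Fit a model on a labeled, sliced cohort.

    Records are split 70/10/20 stratified by outcome (seeded); the
    vocabulary is built from the *training* records only unless one is
    supplied.  Mini-batch Adam minimizes binary cross-entropy; the
    checkpoint with the best validation PR-AUC is returned, with early
    stopping after ``config.patience`` stale epochs.
    """
    from .evaluate import SplitSpec, stratified_split  # deferred: avoids cycle

    if model_kind not in _MODEL_CLASSES:
        raise CohortValidationError(f"unknown model kind {model_kind!r}")
    config = config or ModelConfig()
    records = sorted(records, key=lambda r: r.patient_id)
    if any(r.label is None for r in records):
        raise CohortValidationError("all records must be labeled before training")
    split_spec = split_spec or SplitSpec(seed=config.seed)
    tr_idx, va_idx, te_idx = stratified_split(records, split_spec)
    train_recs = [records[i] for i in tr_idx]
    val_recs = [records[i] for i in va_idx]
    y_tr = np.array([r.label for r in train_recs], dtype=np.float64)
    y_va = np.array([r.label for r in val_recs], dtype=np.float64)
    if len(np.unique(y_tr)) < 2:
        raise CohortValidationError("training split contains a single class")

    if vocab is None:
        vocab = Vocabulary.from_records(train_recs)
    n_codes = len(vocab)
    tr_lists = [encode_record_indices(r, vocab) for r in train_recs]
    va_lists = [encode_record_indices(r, vocab) for r in val_recs]

    rng = np.random.default_rng(config.seed)
    model = _MODEL_CLASSES[model_kind](n_codes, config, rng)
    # start the output bias at the log-odds of the training base rate so
    # early epochs learn discrimination, not calibration
    base = float(np.clip(y_tr.mean(), 1e-3, 1 - 1e-3))
    bias_key = "b_out" if "b_out" in model.params else "b2"
    model.params[bias_key][0] = np.log(base / (1.0 - base))
    opt = Adam(model.params, lr=config.learning_rate)

    log: dict = {"train_loss": [], "val_loss": [], "val_pr_auc": [],
                 "n_parameters": model.n_parameters()}
    best_metric = -np.inf
    best_params = {k: np.copy(v) for k, v in model.params.items()}
    stale = 0
    val_single_class = len(np.unique(y_va)) < 2

    decay_epoch = max(1, int(0.6 * config.epochs))
    for epoch in range(config.epochs):
        if epoch == decay_epoch:
            opt.lr = config.learning_rate * 0.3
        order = rng.permutation(len(tr_lists))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            batch = make_batch([tr_lists[i] for i in sel], n_codes,
                               labels=y_tr[sel], max_visits=config.max_visits)
            loss, grads = model.loss_and_grads(batch.x, batch.mask, batch.labels)
            if config.l2_penalty:
                for k in grads:
                    if "W" in k or k.startswith("w"):
                        grads[k] = grads[k] + config.l2_penalty * model.params[k]
            clip_grads(grads, config.grad_clip)
            opt.step(model.params, grads)
            epoch_loss += loss * len(sel)
        epoch_loss /= len(order)

        s_va = _batched_scores(model, va_lists, n_codes, config.max_visits)
        val_loss, _ = _bce_loss_and_dlogit(s_va, y_va, config.pos_weight)
        if val_single_class:
            metric = -val_loss
            val_pr = float("nan")
        else:
            val_pr = float(average_precision_score(y_va, s_va))
            if config.selection_metric == "pr_auc":
                metric = val_pr
            elif config.selection_metric == "roc_auc":
                metric = float(roc_auc_score(y_va, s_va))
            else:
                metric = -val_loss
        log["train_loss"].append(float(epoch_loss))
        log["val_loss"].append(float(val_loss))
        log["val_pr_auc"].append(val_pr)

        if metric > best_metric + 1e-5:
            best_metric = metric
            best_params = {k: np.copy(v) for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    model.params.update(best_params)
    for lstm in getattr(model, "lstms", []):
        lstm.params = model.params
    if hasattr(model, "lstm_a"):
        model.lstm_a.params = model.params
    split_ids = {
        "train": [records[i].patient_id for i in tr_idx],
        "val": [records[i].patient_id for i in va_idx],
        "test": [records[i].patient_id for i in te_idx],
    }
    return TrainedModel(kind=model_kind, model=model, vocab=vocab,
                        config=config, log=log, split_ids=split_ids)
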