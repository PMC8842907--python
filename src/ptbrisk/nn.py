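"""Minimal numpy neural-network primitives for the sequence models.

Contains a masked LSTM with hand-written backpropagation-through-time and
an Adam optimizer.  Masked time steps carry the hidden and cell state
through unchanged, so trailing padding never influences real steps in
either direction; the backward pass mirrors that gating exactly.
Gradients are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

__all__ = ["LSTM", "Adam", "glorot", "sigmoid"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class LSTM:
    """Single-direction LSTM over (batch, time, features) with a (batch,
    time) mask.  ``reverse=True`` iterates from the last time step to the
    first (reversed-time reading of the record)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator, prefix: str):
        q = d_hidden
        self.d_in, self.q, self.prefix = d_in, q, prefix
        self.params = {
            f"{prefix}Wx": glorot(rng, d_in, 4 * q),
            f"{prefix}Wh": glorot(rng, q, 4 * q),
            f"{prefix}b": np.zeros(4 * q),
        }
        # forget-gate bias +1: standard stabilization for long sequences
        self.params[f"{prefix}b"][q : 2 * q] = 1.0

    def forward(self, x: np.ndarray, mask: np.ndarray, reverse: bool = False):
        """Return hidden states (B, T, q) and a cache for backward."""
        Wx = self.params[f"{self.prefix}Wx"]
        Wh = self.params[f"{self.prefix}Wh"]
        b = self.params[f"{self.prefix}b"]
        B, T, _ = x.shape
        q = self.q
        order = range(T - 1, -1, -1) if reverse else range(T)
        h_prev = np.zeros((B, q))
        c_prev = np.zeros((B, q))
        h_out = np.zeros((B, T, q))
        steps = {}
        for t in order:
            a = x[:, t] @ Wx + h_prev @ Wh + b
            i = sigmoid(a[:, :q])
            f = sigmoid(a[:, q : 2 * q])
            g = np.tanh(a[:, 2 * q : 3 * q])
            o = sigmoid(a[:, 3 * q :])
            c_tilde = f * c_prev + i * g
            tanh_c = np.tanh(c_tilde)
            h_tilde = o * tanh_c
            m = mask[:, t : t + 1]
            c = m * c_tilde + (1.0 - m) * c_prev
            h = m * h_tilde + (1.0 - m) * h_prev
            steps[t] = (h_prev, c_prev, i, f, g, o, tanh_c)
            h_out[:, t] = h
            h_prev, c_prev = h, c
        cache = (x, mask, reverse, steps)
        return h_out, cache

    def backward(self, dh_out: np.ndarray, cache):
        """Backprop dL/dh_out; returns dL/dx and parameter gradients."""
        x, mask, reverse, steps = cache
        Wx = self.params[f"{self.prefix}Wx"]
        Wh = self.params[f"{self.prefix}Wh"]
        B, T, _ = x.shape
        q = self.q
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * q)
        dx = np.zeros_like(x)
        order = range(T - 1, -1, -1) if reverse else range(T)
        dh_next = np.zeros((B, q))
        dc_next = np.zeros((B, q))
        for t in reversed(list(order)):
            h_prev, c_prev, i, f, g, o, tanh_c = steps[t]
            m = mask[:, t : t + 1]
            dh_t = dh_out[:, t] + dh_next
            dh_tilde = m * dh_t
            dh_carry = (1.0 - m) * dh_t
            dc_tilde = m * dc_next + dh_tilde * o * (1.0 - tanh_c**2)
            dc_carry = (1.0 - m) * dc_next
            do = dh_tilde * tanh_c
            di = dc_tilde * g
            df = dc_tilde * c_prev
            dg = dc_tilde * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dx[:, t] = da @ Wx.T
            dWx += x[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dh_next = da @ Wh.T + dh_carry
            dc_next = dc_tilde * f + dc_carry
        grads = {
            f"{self.prefix}Wx": dWx,
            f"{self.prefix}Wh": dWh,
            f"{self.prefix}b": db,
        }
        return dx, grads


class Adam:
    """Adam over a dict of named parameter arrays (scalars allowed)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = np.asarray(g, dtype=np.float64)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            update = self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            params[k] = params[k] - update


def clip_grads(grads: dict, max_norm: float) -> None:
    """In-place global-norm gradient clipping."""
    total = np.sqrt(sum(float(np.sum(np.asarray(g) ** 2)) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale
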