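"""Pure scalar-loop reference implementations of every forward equation.

Deliberately written with explicit Python loops over indices -- no
vectorized shortcuts -- so they form an independent oracle for the
vectorized model code.  Used by the unit and acceptance tests only.
"""

import math


def sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def ref_embed(x, W_emb, b_x, activation="linear"):
    """v_i = sigma(W_emb x_i + b_x), one visit at a time."""
    T = len(x)
    m = len(W_emb)
    C = len(W_emb[0])
    out = []
    for t in range(T):
        v = []
        for d in range(m):
            acc = b_x[d] if b_x is not None else 0.0
            for c in range(C):
                acc += W_emb[d][c] * x[t][c]
            if activation == "relu":
                acc = max(acc, 0.0)
            elif activation == "sigmoid":
                acc = sigmoid(acc)
            v.append(acc)
        out.append(v)
    return out


def ref_lstm(v, Wx, Wh, b, mask=None, reverse=False):
    """Scalar-loop LSTM with mask-gated state carry-through.

    Gate layout in Wx/Wh/b columns: [input, forget, cell, output] blocks
    of size q each.
    """
    T = len(v)
    d_in = len(v[0])
    q = len(Wh)
    if mask is None:
        mask = [1.0] * T
    h_prev = [0.0] * q
    c_prev = [0.0] * q
    h_out = [[0.0] * q for _ in range(T)]
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        a = [0.0] * (4 * q)
        for j in range(4 * q):
            acc = b[j]
            for i in range(d_in):
                acc += v[t][i] * Wx[i][j]
            for i in range(q):
                acc += h_prev[i] * Wh[i][j]
            a[j] = acc
        h_new = [0.0] * q
        c_new = [0.0] * q
        for j in range(q):
            i_g = sigmoid(a[j])
            f_g = sigmoid(a[q + j])
            g_g = math.tanh(a[2 * q + j])
            o_g = sigmoid(a[3 * q + j])
            c_t = f_g * c_prev[j] + i_g * g_g
            h_t = o_g * math.tanh(c_t)
            m_t = mask[t]
            c_new[j] = m_t * c_t + (1 - m_t) * c_prev[j]
            h_new[j] = m_t * h_t + (1 - m_t) * h_prev[j]
        h_out[t] = h_new
        h_prev, c_prev = h_new, c_new
    return h_out


def ref_beta(h, W_beta, b_beta):
    """beta_j = tanh(W_beta h_j + b_beta)."""
    out = []
    for t in range(len(h)):
        row = []
        for d in range(len(W_beta)):
            acc = b_beta[d]
            for i in range(len(h[t])):
                acc += W_beta[d][i] * h[t][i]
            row.append(math.tanh(acc))
        out.append(row)
    return out


def ref_context(beta, v, mask=None):
    """c = sum_j mask_j * (beta_j elementwise* v_j)."""
    T = len(v)
    m = len(v[0])
    if mask is None:
        mask = [1.0] * T
    c = [0.0] * m
    for t in range(T):
        for d in range(m):
            c[d] += mask[t] * beta[t][d] * v[t][d]
    return c


def ref_predict(c, w_out, b_out):
    """p = logistic(w . c + b)."""
    s = b_out
    for d in range(len(c)):
        s += w_out[d] * c[d]
    return sigmoid(s), s


def ref_softmax(e, mask=None):
    if mask is None:
        mask = [1.0] * len(e)
    vals = [e[t] for t in range(len(e)) if mask[t] > 0]
    mx = max(vals)
    exps = [math.exp(e[t] - mx) if mask[t] > 0 else 0.0 for t in range(len(e))]
    z = sum(exps)
    return [x / z for x in exps]


def ref_retain_context(alpha, beta, v, mask=None):
    """c = sum_j alpha_j * beta_j elementwise* v_j."""
    T = len(v)
    m = len(v[0])
    if mask is None:
        mask = [1.0] * T
    c = [0.0] * m
    for t in range(T):
        for d in range(m):
            c[d] += mask[t] * alpha[t] * beta[t][d] * v[t][d]
    return c


def ref_mw_auc(scores, labels):
    """Brute-force Mann-Whitney ROC-AUC: all positive-negative pairs,
    ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
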