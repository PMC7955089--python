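"""Independent scalar re-implementations used as oracles in the tests.

These deliberately avoid the package's autodiff layers: plain NumPy
expressions written step by step from the gate equations, against which the
package's recurrent cells and attention are compared.
"""

import numpy as np


def sigmoid(x):
    return np.exp(-np.logaddexp(0.0, -x))


def gru_step_oracle(cell, x_t, h_prev):
    """Scalar-form GRU update from the printed equations."""
    W = {g: getattr(cell, f"W_{g}").data for g in "zrh"}
    U = {g: getattr(cell, f"U_{g}").data for g in "zrh"}
    b = {g: getattr(cell, f"b_{g}").data for g in "zrh"}
    z = sigmoid(x_t @ W["z"] + h_prev @ U["z"] + b["z"])
    r = sigmoid(x_t @ W["r"] + h_prev @ U["r"] + b["r"])
    h_cand = np.tanh(x_t @ W["h"] + (r * h_prev) @ U["h"] + b["h"])
    return (1.0 - z) * h_prev + z * h_cand


def ctx_gru_step_oracle(cell, y_prev, s_prev, c_t):
    """Decoder GRU update with context projections C·c_t in every gate."""
    W = {g: getattr(cell, f"W_{g}").data for g in "zrs"}
    U = {g: getattr(cell, f"U_{g}").data for g in "zrs"}
    C = {g: getattr(cell, f"C_{g}").data for g in "zrs"}
    z = sigmoid(y_prev @ W["z"] + s_prev @ U["z"] + c_t @ C["z"])
    r = sigmoid(y_prev @ W["r"] + s_prev @ U["r"] + c_t @ C["r"])
    s_cand = np.tanh(y_prev @ W["s"] + (r * s_prev) @ U["s"] + c_t @ C["s"])
    return (1.0 - z) * s_prev + z * s_cand


def lstm_step_oracle(cell, x_t, h_prev, c_prev):
    W = {g: getattr(cell, f"W_{g}").data for g in "ifog"}
    U = {g: getattr(cell, f"U_{g}").data for g in "ifog"}
    b = {g: getattr(cell, f"b_{g}").data for g in "ifog"}
    i = sigmoid(x_t @ W["i"] + h_prev @ U["i"] + b["i"])
    f = sigmoid(x_t @ W["f"] + h_prev @ U["f"] + b["f"])
    o = sigmoid(x_t @ W["o"] + h_prev @ U["o"] + b["o"])
    g = np.tanh(x_t @ W["g"] + h_prev @ U["g"] + b["g"])
    c = f * c_prev + i * g
    return o * np.tanh(c), c


def attention_oracle(att, s_prev, annotations):
    """Additive-attention scores, normalised-exponential weights, context."""
    M = annotations.shape[0]
    e = np.zeros(M)
    for j in range(M):
        hidden = np.tanh(s_prev @ att.W.data + annotations[j] @ att.U.data)
        e[j] = float((hidden @ att.v.data)[0])
    ex = np.exp(e - e.max())
    alpha = ex / ex.sum()
    c = (alpha[:, None] * annotations).sum(axis=0)
    return c, alpha, e
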