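"""Layers for the recurrent and convolutional models.

The recurrent cells are written directly from their gate equations: the GRU
cell uses update gate ``z``, reset gate ``r`` and candidate activation
``h'``; the decoder variant adds context projections ``C·c_t`` to every
gate.  A bidirectional wrapper reverses each row within its true length so
padding never enters the backward-direction recursion.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat, conv1d_same, embedding, stack

__all__ = [
    "Module",
    "Dense",
    "Embedding",
    "GRUCell",
    "ContextGRUCell",
    "ContextLSTMCell",
    "LSTMCell",
    "Recurrent",
    "BiRecurrent",
    "AdditiveAttention",
    "glorot",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape or (fan_in, fan_out))


class Module:
    """Base class with recursive parameter discovery and state (de)serialisation."""

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.W = Parameter(glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W + self.b
        if self.activation == "relu":
            y = y.relu()
        elif self.activation == "tanh":
            y = y.tanh()
        elif self.activation == "sigmoid":
            y = y.sigmoid()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.table = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.table, ids)

    def load_pretrained(self, vectors: np.ndarray) -> None:
        """Hook for externally trained token vectors (rows aligned to ids)."""
        if vectors.shape != self.table.data.shape:
            raise ValueError("pretrained vector table has wrong shape")
        self.table.data = np.asarray(vectors, dtype=np.float64).copy()


class GRUCell(Module):
    """Gated recurrent unit: ``h_t = (1-z_t)⊙h_{t-1} + z_t⊙h'_t``."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        for gate in ("z", "r", "h"):
            setattr(self, f"W_{gate}", Parameter(glorot(rng, n_in, n_hidden)))
            setattr(self, f"U_{gate}", Parameter(glorot(rng, n_hidden, n_hidden)))
            setattr(self, f"b_{gate}", Parameter(np.zeros(n_hidden)))

    def __call__(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        z = (x_t @ self.W_z + h_prev @ self.U_z + self.b_z).sigmoid()
        r = (x_t @ self.W_r + h_prev @ self.U_r + self.b_r).sigmoid()
        h_cand = (x_t @ self.W_h + (r * h_prev) @ self.U_h + self.b_h).tanh()
        return (1.0 - z) * h_prev + z * h_cand


class ContextGRUCell(Module):
    """GRU cell whose gates also receive a context vector through ``C`` matrices.

    ``s_t = (1-z'_t)⊙s_{t-1} + z'_t⊙s'_t`` with every gate of the form
    ``σ(W·y_{t-1} + U·s_{t-1} + C·c_t)``; the candidate applies the reset
    gate to the recurrent term before its ``U`` projection.
    """

    def __init__(self, n_in: int, n_hidden: int, n_ctx: int,
                 rng: np.random.Generator):
        self.n_hidden = n_hidden
        for gate in ("z", "r", "s"):
            setattr(self, f"W_{gate}", Parameter(glorot(rng, n_in, n_hidden)))
            setattr(self, f"U_{gate}", Parameter(glorot(rng, n_hidden, n_hidden)))
            setattr(self, f"C_{gate}", Parameter(glorot(rng, n_ctx, n_hidden)))

    def __call__(self, y_prev: Tensor, s_prev: Tensor, c_t: Tensor) -> Tensor:
        z = (y_prev @ self.W_z + s_prev @ self.U_z + c_t @ self.C_z).sigmoid()
        r = (y_prev @ self.W_r + s_prev @ self.U_r + c_t @ self.C_r).sigmoid()
        s_cand = (y_prev @ self.W_s + (r * s_prev) @ self.U_s
                  + c_t @ self.C_s).tanh()
        return (1.0 - z) * s_prev + z * s_cand


class ContextLSTMCell(Module):
    """LSTM cell with context projections, for the LSTM infiller variant."""

    def __init__(self, n_in: int, n_hidden: int, n_ctx: int,
                 rng: np.random.Generator):
        self.n_hidden = n_hidden
        for gate in ("i", "f", "o", "g"):
            setattr(self, f"W_{gate}", Parameter(glorot(rng, n_in, n_hidden)))
            setattr(self, f"U_{gate}", Parameter(glorot(rng, n_hidden, n_hidden)))
            setattr(self, f"C_{gate}", Parameter(glorot(rng, n_ctx, n_hidden)))
            setattr(self, f"b_{gate}", Parameter(
                np.ones(n_hidden) if gate == "f" else np.zeros(n_hidden)))

    def __call__(self, y_prev: Tensor, state: tuple[Tensor, Tensor], c_t: Tensor):
        h_prev, c_prev = state
        i = (y_prev @ self.W_i + h_prev @ self.U_i + c_t @ self.C_i + self.b_i).sigmoid()
        f = (y_prev @ self.W_f + h_prev @ self.U_f + c_t @ self.C_f + self.b_f).sigmoid()
        o = (y_prev @ self.W_o + h_prev @ self.U_o + c_t @ self.C_o + self.b_o).sigmoid()
        g = (y_prev @ self.W_g + h_prev @ self.U_g + c_t @ self.C_g + self.b_g).tanh()
        c = f * c_prev + i * g
        return o * c.tanh(), c


class LSTMCell(Module):
    """Standard LSTM cell (forget-gate bias initialised to 1)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        for gate in ("i", "f", "o", "g"):
            setattr(self, f"W_{gate}", Parameter(glorot(rng, n_in, n_hidden)))
            setattr(self, f"U_{gate}", Parameter(glorot(rng, n_hidden, n_hidden)))
            setattr(self, f"b_{gate}", Parameter(
                np.ones(n_hidden) if gate == "f" else np.zeros(n_hidden)))

    def __call__(self, x_t: Tensor, state: tuple[Tensor, Tensor]):
        h_prev, c_prev = state
        i = (x_t @ self.W_i + h_prev @ self.U_i + self.b_i).sigmoid()
        f = (x_t @ self.W_f + h_prev @ self.U_f + self.b_f).sigmoid()
        o = (x_t @ self.W_o + h_prev @ self.U_o + self.b_o).sigmoid()
        g = (x_t @ self.W_g + h_prev @ self.U_g + self.b_g).tanh()
        c = f * c_prev + i * g
        h = o * c.tanh()
        return h, c


class Recurrent(Module):
    """Run a GRU or LSTM cell over the time axis of ``(B, L, E)`` input."""

    def __init__(self, cell_type: str, n_in: int, n_hidden: int,
                 rng: np.random.Generator):
        if cell_type not in ("gru", "lstm"):
            raise ValueError(f"unknown cell type {cell_type!r}")
        self.cell_type = cell_type
        self.n_hidden = n_hidden
        self.cell = (GRUCell if cell_type == "gru" else LSTMCell)(
            n_in, n_hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        h = Tensor(np.zeros((B, self.n_hidden)))
        c = Tensor(np.zeros((B, self.n_hidden)))
        outs = []
        for t in range(L):
            x_t = x[:, t]
            if self.cell_type == "gru":
                h = self.cell(x_t, h)
            else:
                h, c = self.cell(x_t, (h, c))
            outs.append(h)
        return stack(outs, axis=1)


class BiRecurrent(Module):
    """Bidirectional recurrent layer; output is the fwd/bwd concatenation.

    The backward direction runs over each row reversed within its true
    length, so trailing padding stays at the tail and never seeds the
    reverse recursion.
    """

    def __init__(self, cell_type: str, n_in: int, n_hidden: int,
                 rng: np.random.Generator):
        self.fwd = Recurrent(cell_type, n_in, n_hidden, rng)
        self.bwd = Recurrent(cell_type, n_in, n_hidden, rng)

    @staticmethod
    def _reversal_index(lengths: np.ndarray, L: int) -> np.ndarray:
        t = np.arange(L)[None, :]
        lens = np.asarray(lengths)[:, None]
        rev = lens - 1 - t
        return np.where(t < lens, rev, t)

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        B, L, _ = x.shape
        idx = self._reversal_index(lengths, L)
        rows = np.arange(B)[:, None]
        out_f = self.fwd(x)
        out_b = self.bwd(x[rows, idx])
        out_b = out_b[rows, idx]  # undo the reversal
        return concat([out_f, out_b], axis=-1)


class AdditiveAttention(Module):
    """Alignment network ``e_tj = v·tanh(W s_{t-1} + U h_j)`` with softmax weights."""

    def __init__(self, n_state: int, n_annot: int, n_hidden: int,
                 rng: np.random.Generator):
        self.W = Parameter(glorot(rng, n_state, n_hidden))
        self.U = Parameter(glorot(rng, n_annot, n_hidden))
        self.v = Parameter(glorot(rng, n_hidden, 1))

    def __call__(self, s_prev: Tensor, annotations: Tensor,
                 valid: np.ndarray | None = None):
        """Return (context, weights, scores) for one decoding step.

        s_prev: (B, S); annotations: (B, M, A); valid: (B, M) 0/1 mask.
        """
        proj = s_prev @ self.W  # (B, H)
        keys = annotations @ self.U  # (B, M, H)
        e = ((keys + proj.reshape(proj.shape[0], 1, -1)).tanh() @ self.v)
        e = e.reshape(e.shape[0], e.shape[1])  # (B, M)
        if valid is not None:
            # padding positions get a large negative score -> ~0 weight
            e = e + Tensor(np.where(valid > 0, 0.0, -1e9))
        alpha = e.log_softmax(axis=-1).exp()  # (B, M)
        ctx = (alpha.reshape(alpha.shape[0], alpha.shape[1], 1)
               * annotations).sum(axis=1)
        return ctx, alpha, e


def conv_block(x: Tensor, weight: Parameter, bias: Parameter) -> Tensor:
    return conv1d_same(x, weight, bias).relu()
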