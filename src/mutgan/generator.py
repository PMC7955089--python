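"""The layered generative model.

Two cooperating networks mutate a token sequence:

* the *position selector* (``G_where``) scores every position with a
  replacement probability ``p_i``;
* ``f(p) ∘ x`` binarises those scores under the ``N_replace`` budget and
  blanks the selected positions;
* the *infiller* (``G_replace``), a recurrent encoder–decoder with additive
  attention, fills each blank with a substitute token, copying every
  unselected position through unchanged.

Selection is stochastic during training (positions drawn without
replacement proportionally to ``p``, tokens sampled from the decoder
softmax) so the policy-gradient estimator has exploration; at inference the
selector takes a deterministic top-k (lowest index wins ties) and the
decoder is greedy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .alphabet import Alphabet, dna_alphabet
from .sequence import GeneratedSequence, MaskedSequence, TokenSequence

__all__ = [
    "PositionSelector", "SequenceInfiller", "SequenceMutator",
    "ReplacementPlan", "MutationBatch",
    "resolve_n_replace", "binarize_topk", "sample_positions", "mask_apply",
]

_EPS = 1e-8
_NEG = -1e9


# ---------------------------------------------------------------------------
# replacement-budget plumbing


def resolve_n_replace(n_replace, M: int) -> int:
    """Resolve the replacement budget to a count.

    Floats are fractions of the true length (round half up, at least 1);
    ints are absolute counts.  The resolved count must satisfy 1 <= k <= M.
    """
    if isinstance(n_replace, float):
        k = max(1, int(np.floor(n_replace * M + 0.5)))
    else:
        k = int(n_replace)
    if not 1 <= k <= M:
        raise ValueError(f"resolved replacement count {k} outside [1, {M}]")
    return k


def binarize_topk(p: np.ndarray, n_replace, M: int,
                  rng: np.random.Generator | None = None,
                  mode: str = "topk") -> np.ndarray:
    """Binarise position scores under the replacement budget.

    ``mode='topk'`` is deterministic (ties break to the lowest index);
    ``mode='sample'`` draws without replacement proportionally to ``p``.
    Only the first ``M`` positions are eligible; the returned mask has the
    same number of slots as ``p``.
    """
    p = np.asarray(p, dtype=float)
    k = resolve_n_replace(n_replace, M)
    mask = np.zeros(p.size, dtype=np.int64)
    if mode == "topk":
        order = np.argsort(-p[:M], kind="stable")
        mask[order[:k]] = 1
    elif mode == "sample":
        if rng is None:
            raise ValueError("sampling mode needs an rng")
        pos = sample_positions(p, k, M, rng)
        mask[pos] = 1
    else:
        raise ValueError(f"unknown binarisation mode {mode!r}")
    return mask


def sample_positions(p: np.ndarray, k: int, M: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``k`` positions among the first ``M`` without replacement, ∝ p.

    Implemented as Gumbel top-k on ``log(p + eps)``, which realises exactly
    the sequential renormalised draw; the returned order is the draw order.
    """
    q = np.full(p.size, -np.inf)
    q[:M] = np.log(p[:M] + _EPS)
    g = rng.gumbel(size=p.size)
    keys = q + g
    order = np.argsort(-keys, kind="stable")
    return order[:k]


def mask_apply(mask: np.ndarray, seq: TokenSequence,
               blank_id: int = 1) -> MaskedSequence:
    """Blank the positions where ``mask == 1``; everything else unchanged."""
    mask = np.asarray(mask, dtype=np.int64)
    if mask.shape != seq.token_ids.shape:
        raise ValueError("mask and sequence lengths differ")
    ids = seq.token_ids.copy()
    ids[mask == 1] = blank_id
    return MaskedSequence(token_ids=ids, mask=mask, source_id=seq.id)


@dataclass
class ReplacementPlan:
    """Per-position replacement probabilities, the binarised mask, the budget."""

    p: np.ndarray
    mask: np.ndarray
    n_replace: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.int64)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if int(self.mask.sum()) != self.n_replace:
            raise ValueError("mask cardinality disagrees with the budget")


# ---------------------------------------------------------------------------
# G_where


class PositionSelector(nn.Module):
    """Scores each sequence position with a probability of replacement.

    Embedding, two bidirectional recurrent layers, a dense layer and a
    per-position sigmoid output; padding positions are forced to zero.
    """

    def __init__(self, n_tokens: int, embed_dim: int = 50,
                 hidden: tuple[int, int] = (32, 32), dense: int = 16,
                 cell: str = "lstm", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.embed = nn.Embedding(n_tokens, embed_dim, rng)
        self.rnn1 = nn.BiRecurrent(cell, embed_dim, hidden[0], rng)
        self.rnn2 = nn.BiRecurrent(cell, 2 * hidden[0], hidden[1], rng)
        self.dense = nn.Dense(2 * hidden[1], dense, rng, activation="relu")
        self.out = nn.Dense(dense, 1, rng)
        self.arch = f"EM-{hidden[0]}-{hidden[1]}-{dense}-OUT"

    def forward(self, X: np.ndarray, lengths: np.ndarray) -> nn.Tensor:
        """Per-position replacement probabilities, shape ``(B, L)``."""
        B, L = X.shape
        h = self.embed(X)
        h = self.rnn1(h, lengths)
        h = self.rnn2(h, lengths)
        p = self.out(self.dense(h)).sigmoid().reshape(B, L)
        valid = (np.arange(L)[None, :] < np.asarray(lengths)[:, None])
        return p * nn.Tensor(valid.astype(float))

    def probabilities(self, X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return self.forward(X, lengths).data

    @staticmethod
    def action_log_prob(p: nn.Tensor, positions: np.ndarray,
                        active: np.ndarray,
                        lengths: np.ndarray) -> nn.Tensor:
        """Log-probability of an ordered without-replacement draw.

        ``positions``: (B, k_max) draw order, ``active``: (B, k_max) 0/1 for
        ragged budgets.  The draw distribution is the sequential
        renormalisation of ``q = p + eps`` over the first ``M`` positions,
        matching :func:`sample_positions` exactly.
        """
        B, k_max = positions.shape
        L = p.data.shape[1]
        rows = np.arange(B)[:, None]
        valid = (np.arange(L)[None, :]
                 < np.asarray(lengths)[:, None]).astype(float)
        q = p + _EPS * nn.Tensor(valid)
        q_sel = q[rows, positions]  # (B, k_max)
        z = q.sum(axis=1, keepdims=True)
        csum = [q_sel[:, :1] * 0.0]
        for i in range(1, k_max):
            csum.append(csum[-1] + q_sel[:, i - 1:i])
        denom = nn.concat([z - c for c in csum], axis=1)
        act = nn.Tensor(active.astype(float))
        # inactive slots contribute log(1) = 0
        one_minus = nn.Tensor(1.0 - active.astype(float))
        terms = ((q_sel * act + one_minus).log()
                 - (denom * act + one_minus).log())
        return terms.sum(axis=1)


# ---------------------------------------------------------------------------
# G_replace


class SequenceInfiller(nn.Module):
    """Recurrent encoder–decoder with additive attention that fills blanks.

    The encoder reads the blanked sequence through two recurrent layers; at
    every output step the decoder attends over the encoder annotations,
    updates two context-aware recurrent layers and projects onto the
    vocabulary.  Only blank positions take their token from the decoder —
    all other positions copy the source token through.
    """

    def __init__(self, n_tokens: int, embed_dim: int = 50,
                 hidden: tuple[int, int] = (64, 64), cell: str = "gru",
                 attn_hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cell_type = cell
        self.embed = nn.Embedding(n_tokens, embed_dim, rng)
        self.enc1 = nn.Recurrent(cell, embed_dim, hidden[0], rng)
        self.enc2 = nn.Recurrent(cell, hidden[0], hidden[1], rng)
        ctx_cell = nn.ContextGRUCell if cell == "gru" else nn.ContextLSTMCell
        self.dec1 = ctx_cell(embed_dim, hidden[0], hidden[1], rng)
        self.dec2 = ctx_cell(hidden[0], hidden[1], hidden[1], rng)
        self.attn = nn.AdditiveAttention(hidden[1], hidden[1], attn_hidden, rng)
        self.out = nn.Dense(hidden[1], n_tokens, rng)
        self.hidden = hidden
        self.n_tokens = n_tokens
        self.arch = (f"EM-{hidden[0]}-{hidden[1]}-EM-{hidden[0]}-{hidden[1]}-OUT")

    def encode(self, masked_ids: np.ndarray) -> nn.Tensor:
        h = self.embed(masked_ids)
        return self.enc2(self.enc1(h))

    def fill(self, source_ids: np.ndarray, masks: np.ndarray,
             lengths: np.ndarray, mode: str = "greedy",
             rng: np.random.Generator | None = None,
             exclude_source: bool = True,
             fill_ids: np.ndarray | None = None,
             forced: np.ndarray | None = None,
             want_logp: bool = False):
        """Fill the blanks of a batch; returns ``(filled, logp)``.

        ``fill_ids`` restricts the substitute vocabulary (defaults to all
        non-reserved ids).  With ``forced`` (a filled id matrix) the choices
        are taken from it and only their log-probabilities are computed —
        the teacher-forced path used to re-score stored actions.
        ``logp`` is a per-sequence Tensor of summed fill log-probabilities
        (``None`` unless requested).
        """
        B, L = source_ids.shape
        masks = np.asarray(masks, dtype=np.int64)
        masked_ids = np.where(masks == 1, 1, source_ids)  # blank id = 1
        annotations = self.encode(masked_ids)
        valid = (np.arange(L)[None, :] < np.asarray(lengths)[:, None])

        # vocabulary bias: never emit pad or blank; optionally not the source
        base_bias = np.zeros(self.n_tokens)
        base_bias[0] = base_bias[1] = _NEG
        if fill_ids is not None:
            allowed = np.full(self.n_tokens, _NEG)
            allowed[np.asarray(fill_ids)] = 0.0
            base_bias = np.minimum(base_bias, 0.0) + allowed

        h1 = nn.Tensor(np.zeros((B, self.hidden[0])))
        h2 = nn.Tensor(np.zeros((B, self.hidden[1])))
        c1 = nn.Tensor(np.zeros((B, self.hidden[0])))
        c2 = nn.Tensor(np.zeros((B, self.hidden[1])))
        filled = source_ids.copy()
        y_prev = np.zeros(B, dtype=np.int64)  # pad id plays start-of-sequence
        logp_total = nn.Tensor(np.zeros(B)) if want_logp else None

        for t in range(L):
            ctx, _, _ = self.attn(h2, annotations, valid=valid)
            y_emb = self.embed(y_prev)
            if self.cell_type == "gru":
                h1 = self.dec1(y_emb, h1, ctx)
                h2 = self.dec2(h1, h2, ctx)
            else:
                h1, c1 = self.dec1(y_emb, (h1, c1), ctx)
                h2, c2 = self.dec2(h1, (h2, c2), ctx)
            rows = np.flatnonzero(masks[:, t] == 1)
            if rows.size:
                logits = self.out(h2[rows])
                bias = np.tile(base_bias, (rows.size, 1))
                if exclude_source:
                    bias[np.arange(rows.size), source_ids[rows, t]] = _NEG
                logits = logits + nn.Tensor(bias)
                logp = logits.log_softmax(axis=-1)
                if forced is not None:
                    choice = forced[rows, t]
                elif mode == "greedy":
                    choice = np.argmax(logp.data, axis=1)
                elif mode == "sample":
                    if rng is None:
                        raise ValueError("sampling mode needs an rng")
                    probs = np.exp(logp.data)
                    probs /= probs.sum(axis=1, keepdims=True)
                    u = rng.random(rows.size)
                    choice = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
                else:
                    raise ValueError(f"unknown fill mode {mode!r}")
                filled[rows, t] = choice
                if want_logp:
                    lp = logp[np.arange(rows.size), choice]
                    logp_total = logp_total + nn.scatter_rows(lp, rows, B)
            y_prev = filled[:, t] * valid[:, t]
        return filled, logp_total


# ---------------------------------------------------------------------------
# the combined transformer


@dataclass
class MutationBatch:
    """One sampled mutation of a batch, with everything needed for learning."""

    source_X: np.ndarray
    lengths: np.ndarray
    masks: np.ndarray
    positions: np.ndarray          # (B, k_max) draw order, padded with 0
    active: np.ndarray             # (B, k_max) 0/1 validity of each draw slot
    filled_X: np.ndarray
    p: "nn.Tensor | None" = None
    where_logp: "nn.Tensor | None" = None
    replace_logp: "nn.Tensor | None" = None

    def __len__(self) -> int:
        return self.source_X.shape[0]


class SequenceMutator(BaseEstimator, TransformerMixin):
    """scikit-learn style transformer wrapping the layered generator.

    ``transform`` deterministically mutates each input row (top-k positions,
    greedy fills); ``sample`` draws stochastic mutants and keeps the
    log-probability graph alive for policy-gradient training.

    Parameters mirror the two sub-networks; ``n_replace`` may be a fraction
    of the true length (float), an absolute count (int), or a mapping from
    sequence length to count (the splice-site augmentation uses
    ``{90: 9, 15: 3}``).
    """

    def __init__(self, alphabet: Alphabet | None = None, embed_dim: int = 50,
                 where_hidden: tuple[int, int] = (32, 32),
                 where_dense: int = 16, where_cell: str = "lstm",
                 replace_hidden: tuple[int, int] = (64, 64),
                 replace_cell: str = "gru", attn_hidden: int = 32,
                 n_replace=0.1, exclude_source: bool = True,
                 include_extended: bool = True, random_state: int = 0):
        self.alphabet = alphabet
        self.embed_dim = embed_dim
        self.where_hidden = where_hidden
        self.where_dense = where_dense
        self.where_cell = where_cell
        self.replace_hidden = replace_hidden
        self.replace_cell = replace_cell
        self.attn_hidden = attn_hidden
        self.n_replace = n_replace
        self.exclude_source = exclude_source
        self.include_extended = include_extended
        self.random_state = random_state

    # -- construction --------------------------------------------------------

    def _ensure_built(self):
        if not hasattr(self, "selector_"):
            self.fit()
        return self

    def fit(self, X=None, y=None):
        """Initialise the two networks (weights seeded by ``random_state``)."""
        alphabet = self.alphabet or dna_alphabet()
        rng = np.random.default_rng(self.random_state)
        n_tokens = alphabet.size
        self.alphabet_ = alphabet
        self.selector_ = PositionSelector(
            n_tokens, self.embed_dim, self.where_hidden, self.where_dense,
            self.where_cell, rng)
        self.infiller_ = SequenceInfiller(
            n_tokens, self.embed_dim, self.replace_hidden, self.replace_cell,
            self.attn_hidden, rng)
        self.fill_ids_ = alphabet.fill_ids(self.include_extended)
        return self

    # -- planning ------------------------------------------------------------

    def _resolve_k(self, n_replace, M: int) -> int:
        n_replace = self.n_replace if n_replace is None else n_replace
        if isinstance(n_replace, dict):
            try:
                n_replace = n_replace[M]
            except KeyError:
                raise ValueError(f"no replacement count configured for "
                                 f"length {M}") from None
        return resolve_n_replace(n_replace, M)

    def plan(self, seq: TokenSequence, n_replace=None, mode: str = "topk",
             rng: np.random.Generator | None = None) -> ReplacementPlan:
        """Score one sequence and binarise under the budget."""
        self._ensure_built()
        X = seq.token_ids[None, :]
        lengths = np.asarray([seq.length])
        p = self.selector_.probabilities(X, lengths)[0]
        k = self._resolve_k(n_replace, seq.length)
        mask = binarize_topk(p, k, seq.length, rng=rng, mode=mode)
        return ReplacementPlan(p=p, mask=mask, n_replace=k)

    # -- batched mutation ----------------------------------------------------

    def sample(self, X: np.ndarray, lengths: np.ndarray, n_replace=None,
               rng: np.random.Generator | None = None,
               mode: str = "sample", want_logp: bool = False) -> MutationBatch:
        """Mutate a batch; stochastic by default, deterministic with topk/greedy.

        With ``want_logp`` the forward passes build the autodiff graph and
        the returned batch carries per-sequence log-probabilities of the
        selection and fill actions.
        """
        self._ensure_built()
        X = np.asarray(X, dtype=np.int64)
        lengths = np.asarray(lengths, dtype=np.int64)
        B, L = X.shape
        rng = rng or np.random.default_rng(self.random_state)
        ks = np.asarray([self._resolve_k(n_replace, int(m)) for m in lengths])
        if B == 0:
            empty = np.zeros((0, 0), dtype=np.int64)
            return MutationBatch(source_X=X, lengths=lengths,
                                 masks=np.zeros((0, L), dtype=np.int64),
                                 positions=empty, active=empty,
                                 filled_X=X.copy())
        k_max = int(ks.max())

        if want_logp:
            p_t = self.selector_.forward(X, lengths)
            p = p_t.data
        else:
            p_t = None
            p = self.selector_.probabilities(X, lengths)

        positions = np.zeros((B, k_max), dtype=np.int64)
        active = np.zeros((B, k_max), dtype=np.int64)
        masks = np.zeros((B, L), dtype=np.int64)
        for i in range(B):
            if mode == "sample":
                pos = sample_positions(p[i], int(ks[i]), int(lengths[i]), rng)
            else:
                order = np.argsort(-p[i, :lengths[i]], kind="stable")
                pos = order[:ks[i]]
            positions[i, :ks[i]] = pos
            active[i, :ks[i]] = 1
            masks[i, pos] = 1

        fill_mode = "sample" if mode == "sample" else "greedy"
        filled, replace_logp = self.infiller_.fill(
            X, masks, lengths, mode=fill_mode, rng=rng,
            exclude_source=self.exclude_source, fill_ids=self.fill_ids_,
            want_logp=want_logp)
        where_logp = (self.selector_.action_log_prob(p_t, positions, active,
                                                     lengths)
                      if want_logp else None)
        return MutationBatch(source_X=X, lengths=lengths, masks=masks,
                             positions=positions, active=active,
                             filled_X=filled, p=p_t,
                             where_logp=where_logp, replace_logp=replace_logp)

    def transform(self, X, lengths: np.ndarray | None = None) -> np.ndarray:
        """Deterministic mutation of an id matrix (top-k + greedy fills)."""
        X = np.asarray(X, dtype=np.int64)
        if lengths is None:
            lengths = (X != 0).sum(axis=1)
        batch = self.sample(X, lengths, mode="topk")
        return batch.filled_X

    def mutate_sequences(self, sequences: list[TokenSequence], n_replace=None,
                         mode: str = "sample",
                         rng: np.random.Generator | None = None,
                         label_fn=None) -> list[GeneratedSequence]:
        """Mutate container sequences one length-group at a time."""
        self._ensure_built()
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(sequences):
            by_len.setdefault(s.padded_length, []).append(i)
        out: list[GeneratedSequence | None] = [None] * len(sequences)
        for L, idxs in sorted(by_len.items()):
            X = np.stack([sequences[i].token_ids for i in idxs])
            lengths = np.asarray([sequences[i].length for i in idxs])
            batch = self.sample(X, lengths, n_replace=n_replace, mode=mode,
                                rng=rng)
            for row, i in enumerate(idxs):
                src = sequences[i]
                label = label_fn(src.label) if label_fn else src.label
                out[i] = GeneratedSequence(
                    id=f"{src.id}~mut", token_ids=batch.filled_X[row],
                    length=src.length, source_id=src.id,
                    truth_mask=batch.masks[row], label=label)
        return out
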