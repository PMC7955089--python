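"""The layered discriminative model.

``MutationExplainer`` emits, for every position, the probability that the
token there was adversarially replaced; ``SequenceClassifier`` emits
sequence-level class probabilities.  The two share no parameters and are
trained independently.

The classifier is a text-CNN: embedding, two convolutional layers (kernel
width 3, same-padding, ReLU), max-over-time pooling, a dense layer and a
softmax (or single-sigmoid for the binary head).  The explainer has the
same architecture family as the position selector: two bidirectional
recurrent layers and a per-position sigmoid; padded positions are excluded
from its loss and forced to zero probability.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import nn
from .alphabet import Alphabet, dna_alphabet

__all__ = ["MutationExplainer", "SequenceClassifier",
           "bce_loss", "render_annotated"]

_CLIP = 1e-7


def bce_loss(probs: nn.Tensor, targets: np.ndarray,
             weights: np.ndarray | None = None) -> nn.Tensor:
    """Mean binary cross-entropy of probabilities against 0/1 targets.

    ``weights`` (same shape) masks entries out of the mean — padding
    positions carry weight 0.
    """
    t = np.asarray(targets, dtype=float)
    p = probs.clip(_CLIP, 1.0 - _CLIP)
    ll = nn.Tensor(t) * p.log() + nn.Tensor(1.0 - t) * (1.0 - p).log()
    if weights is None:
        return -ll.mean()
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total == 0:
        return ll.sum() * 0.0
    return -(ll * nn.Tensor(w)).sum() * (1.0 / total)


def _lengths_or_infer(X: np.ndarray, lengths) -> np.ndarray:
    if lengths is not None:
        return np.asarray(lengths, dtype=np.int64)
    inferred = (np.asarray(X) != 0).sum(axis=1)
    return inferred.astype(np.int64)


class _ExplainNet(nn.Module):
    def __init__(self, n_tokens, embed_dim, hidden, dense, cell, rng):
        self.embed = nn.Embedding(n_tokens, embed_dim, rng)
        self.rnn1 = nn.BiRecurrent(cell, embed_dim, hidden[0], rng)
        self.rnn2 = nn.BiRecurrent(cell, 2 * hidden[0], hidden[1], rng)
        self.dense = nn.Dense(2 * hidden[1], dense, rng, activation="relu")
        self.out = nn.Dense(dense, 1, rng)

    def forward(self, X, lengths) -> nn.Tensor:
        B, L = X.shape
        h = self.embed(X)
        h = self.rnn1(h, lengths)
        h = self.rnn2(h, lengths)
        p = self.out(self.dense(h)).sigmoid().reshape(B, L)
        valid = (np.arange(L)[None, :] < np.asarray(lengths)[:, None])
        return p * nn.Tensor(valid.astype(float))


class MutationExplainer(BaseEstimator):
    """Per-position replacement-probability discriminator (``fit``/``predict_proba``).

    ``y`` in :meth:`fit` is the ``(n, L)`` matrix of ground-truth
    replacement masks (all-zero rows for clean sequences).
    """

    def __init__(self, alphabet: Alphabet | None = None, embed_dim: int = 50,
                 hidden: tuple[int, int] = (32, 32), dense: int = 16,
                 cell: str = "lstm", lr: float = 1e-3, batch_size: int = 32,
                 epochs: int = 10, random_state: int = 0):
        self.alphabet = alphabet
        self.embed_dim = embed_dim
        self.hidden = hidden
        self.dense = dense
        self.cell = cell
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    @property
    def architecture(self) -> str:
        return f"EM-{self.hidden[0]}-{self.hidden[1]}-{self.dense}-OUT"

    def _build(self):
        alphabet = self.alphabet or dna_alphabet()
        rng = np.random.default_rng(self.random_state)
        self.alphabet_ = alphabet
        self.net_ = _ExplainNet(alphabet.size, self.embed_dim, self.hidden,
                                self.dense, self.cell, rng)
        self.optimizer_ = nn.Adam(self.net_.parameters(), lr=self.lr)
        return self

    def initialize(self):
        if not hasattr(self, "net_"):
            self._build()
        return self

    def fit(self, X, y, lengths=None):
        self._build()
        self.partial_fit(X, y, lengths=lengths, epochs=self.epochs)
        return self

    def partial_fit(self, X, y, lengths=None, epochs: int = 1,
                    rng: np.random.Generator | None = None):
        """Run extra binary cross-entropy epochs (padding excluded)."""
        self.initialize()
        X = np.asarray(X, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        lengths = _lengths_or_infer(X, lengths)
        rng = rng or np.random.default_rng(self.random_state + 1)
        n = X.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                probs = self.net_.forward(X[idx], lengths[idx])
                valid = (np.arange(X.shape[1])[None, :]
                         < lengths[idx][:, None]).astype(float)
                loss = bce_loss(probs, y[idx], weights=valid)
                self.optimizer_.zero_grad()
                loss.backward()
                self.optimizer_.step()
        return self

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        """Per-position replacement probabilities, zero at padding."""
        if not hasattr(self, "net_"):
            raise NotFittedError("MutationExplainer is not fitted")
        X = np.asarray(X, dtype=np.int64)
        with nn.no_grad():
            return self.net_.forward(X, _lengths_or_infer(X, lengths)).data

    def predict(self, X, lengths=None, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X, lengths) >= threshold).astype(np.int64)


class _ClassifyNet(nn.Module):
    def __init__(self, n_tokens, embed_dim, filters, dense, n_out, rng,
                 kernel: int = 3):
        self.embed = nn.Embedding(n_tokens, embed_dim, rng)
        self.conv1_w = nn.Parameter(nn.glorot(
            rng, kernel * embed_dim, filters[0], (kernel, embed_dim, filters[0])))
        self.conv1_b = nn.Parameter(np.zeros(filters[0]))
        self.conv2_w = nn.Parameter(nn.glorot(
            rng, kernel * filters[0], filters[1], (kernel, filters[0], filters[1])))
        self.conv2_b = nn.Parameter(np.zeros(filters[1]))
        self.dense = nn.Dense(filters[1], dense, rng, activation="relu")
        self.out = nn.Dense(dense, n_out, rng)

    def forward(self, X, lengths) -> nn.Tensor:
        B, L = X.shape
        h = self.embed(X)
        h = nn.conv1d_same(h, self.conv1_w, self.conv1_b).relu()
        h = nn.conv1d_same(h, self.conv2_w, self.conv2_b).relu()
        # max-over-time pooling restricted to real positions
        valid = (np.arange(L)[None, :] < np.asarray(lengths)[:, None])
        h = h + nn.Tensor(np.where(valid, 0.0, -1e9)[:, :, None])
        h = h.max(axis=1)
        return self.out(self.dense(h))  # raw logits


class SequenceClassifier(BaseEstimator, ClassifierMixin):
    """Sequence-level CNN classifier.

    Binary problems use a single sigmoid output whose value is the
    probability of ``classes_[1]`` (by convention the clean pole: pass the
    clean label through ``positive_label``); multi-class heads emit a
    softmax over 4 or 8 classes.
    """

    def __init__(self, alphabet: Alphabet | None = None, embed_dim: int = 50,
                 filters: tuple[int, int] = (32, 64), dense: int = 16,
                 positive_label: str | None = None, lr: float = 1e-3,
                 batch_size: int = 32, epochs: int = 10,
                 random_state: int = 0):
        self.alphabet = alphabet
        self.embed_dim = embed_dim
        self.filters = filters
        self.dense = dense
        self.positive_label = positive_label
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    @property
    def architecture(self) -> str:
        return f"EM-{self.filters[0]}-{self.filters[1]}-{self.dense}-OUT"

    def _build(self, classes: np.ndarray):
        if len(classes) not in (2, 4, 8):
            raise ValueError(f"unsupported class count {len(classes)}; "
                             "expected 2, 4 or 8")
        alphabet = self.alphabet or dna_alphabet()
        if self.positive_label is not None and len(classes) == 2:
            if self.positive_label not in classes:
                raise ValueError(f"positive_label {self.positive_label!r} "
                                 "not among the classes")
            other = [c for c in classes if c != self.positive_label]
            classes = np.asarray(other + [self.positive_label], dtype=object)
        self.classes_ = np.asarray(classes, dtype=object)
        self.n_classes_ = len(classes)
        n_out = 1 if self.n_classes_ == 2 else self.n_classes_
        rng = np.random.default_rng(self.random_state)
        self.alphabet_ = alphabet
        self.net_ = _ClassifyNet(alphabet.size, self.embed_dim, self.filters,
                                 self.dense, n_out, rng)
        self.optimizer_ = nn.Adam(self.net_.parameters(), lr=self.lr)
        self.frozen_ = False
        return self

    def _encode_labels(self, y) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes_)}
        try:
            return np.asarray([index[label] for label in y])
        except KeyError as err:
            raise ValueError(f"unknown label {err.args[0]!r}") from None

    def fit(self, X, y, lengths=None):
        y = np.asarray(y, dtype=object)
        classes = np.unique(y.astype(str)).astype(object)
        if len(classes) < 2:
            raise ValueError("training data must contain at least 2 classes")
        self._build(classes)
        self.partial_fit(X, y, lengths=lengths, epochs=self.epochs)
        return self

    def partial_fit(self, X, y, lengths=None, epochs: int = 1,
                    rng: np.random.Generator | None = None):
        if not hasattr(self, "net_"):
            raise NotFittedError("call fit first (classes unknown)")
        if self.frozen_:
            return self
        X = np.asarray(X, dtype=np.int64)
        lengths = _lengths_or_infer(X, lengths)
        codes = self._encode_labels(y)
        rng = rng or np.random.default_rng(self.random_state + 1)
        n = X.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                loss = self.loss(X[idx], codes[idx], lengths[idx])
                self.optimizer_.zero_grad()
                loss.backward()
                self.optimizer_.step()
        return self

    def loss(self, X, codes, lengths) -> nn.Tensor:
        """Cross-entropy training loss on encoded labels."""
        logits = self.net_.forward(X, lengths)
        if self.n_classes_ == 2:
            probs = logits.reshape(logits.shape[0]).sigmoid()
            return bce_loss(probs, codes.astype(float))
        logp = logits.log_softmax(axis=-1)
        picked = logp[np.arange(len(codes)), codes]
        return -picked.mean()

    def freeze(self):
        """Stop all further weight updates (pretrain-then-freeze protocol)."""
        self.frozen_ = True
        return self

    def unfreeze(self):
        self.frozen_ = False
        return self

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise NotFittedError("SequenceClassifier is not fitted")
        X = np.asarray(X, dtype=np.int64)
        with nn.no_grad():
            logits = self.net_.forward(X, _lengths_or_infer(X, lengths))
            if self.n_classes_ == 2:
                p1 = 1.0 / (1.0 + np.exp(-logits.data[:, 0]))
                return np.column_stack([1.0 - p1, p1])
            return logits.log_softmax(axis=-1).exp().data

    def predict(self, X, lengths=None) -> np.ndarray:
        probs = self.predict_proba(X, lengths)
        return self.classes_[np.argmax(probs, axis=1)]

    def decision_score(self, X, lengths=None) -> np.ndarray:
        """Binary-head score in [0, 1]: 1 = clean pole (``classes_[1]``)."""
        if self.n_classes_ != 2:
            raise ValueError("decision_score is defined for binary heads")
        return self.predict_proba(X, lengths)[:, 1]


def render_annotated(tokens: list[str], flags: np.ndarray,
                     delimiter: str = "") -> str:
    """Render a sequence with flagged tokens bracketed, e.g. ``AC[G]T``."""
    out = [f"[{tok}]" if flag else tok for tok, flag in zip(tokens, flags)]
    return delimiter.join(out)
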