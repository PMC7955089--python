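"""Sequence containers: encoded sequences, masked sequences, mutants."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .alphabet import Alphabet

__all__ = [
    "TokenSequence",
    "MaskedSequence",
    "GeneratedSequence",
    "SequenceDataset",
    "pad_or_truncate",
    "encode_sequence",
]


@dataclass
class TokenSequence:
    """A fixed-alphabet token-id sequence with explicit true length.

    ``token_ids`` may carry trailing padding (id 0); ``length`` is the
    number of real tokens.  Padding is only ever legal after ``length``.
    """

    id: str
    token_ids: np.ndarray
    length: int
    label: str | None = None
    group: str | None = None

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)
        if self.length < 0 or self.length > self.token_ids.size:
            raise ValueError(f"invalid true length {self.length} for "
                             f"{self.token_ids.size}-slot sequence {self.id!r}")
        if np.any(self.token_ids[self.length:] != 0):
            raise ValueError(f"non-pad tokens after position {self.length} "
                             f"in sequence {self.id!r}")
        if self.length and np.any(self.token_ids[:self.length] == 0):
            raise ValueError(f"pad token before position {self.length} "
                             f"in sequence {self.id!r}")

    @property
    def padded_length(self) -> int:
        return int(self.token_ids.size)

    def decode(self, alphabet: Alphabet) -> str:
        return alphabet.decode(self.token_ids[:self.length], strip_pad=False)


@dataclass
class MaskedSequence:
    """A sequence with blanks at the positions selected for replacement."""

    token_ids: np.ndarray
    mask: np.ndarray
    source_id: str

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=np.int64)
        if self.token_ids.shape != self.mask.shape:
            raise ValueError("mask and sequence lengths differ")

    @property
    def n_blanks(self) -> int:
        return int(self.mask.sum())


@dataclass
class GeneratedSequence:
    """A mutant with provenance: source id, ground-truth replacement mask."""

    id: str
    token_ids: np.ndarray
    length: int
    source_id: str
    truth_mask: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)
        self.truth_mask = np.asarray(self.truth_mask, dtype=np.int64)

    def as_token_sequence(self) -> TokenSequence:
        return TokenSequence(id=self.id, token_ids=self.token_ids,
                             length=self.length, label=self.label)


def encode_sequence(seq_id: str, text: str, alphabet: Alphabet,
                    label: str | None = None, group: str | None = None,
                    allow_extended: bool = True) -> TokenSequence:
    ids = alphabet.encode(text, allow_extended=allow_extended)
    return TokenSequence(id=seq_id, token_ids=ids, length=ids.size,
                         label=label, group=group)


def pad_or_truncate(seq: TokenSequence, max_len: int) -> TokenSequence:
    """Fix a sequence to ``max_len`` slots: tail zero-padding or tail truncation.

    Short sequences keep their true length; truncated ones get
    ``length == max_len`` (the tail is dropped — post truncation).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = seq.token_ids.size
    if n == max_len:
        return seq
    if n < max_len:
        ids = np.zeros(max_len, dtype=np.int64)
        ids[:n] = seq.token_ids
        return replace(seq, token_ids=ids)
    return replace(seq, token_ids=seq.token_ids[:max_len].copy(),
                   length=min(seq.length, max_len))


class SequenceDataset:
    """A list of :class:`TokenSequence` plus the alphabet they live in.

    Provides the dense views the models consume: an ``(n, L)`` id matrix,
    a length vector and a label array.
    """

    def __init__(self, sequences: Iterable[TokenSequence], alphabet: Alphabet):
        self.sequences = list(sequences)
        self.alphabet = alphabet

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[TokenSequence]:
        return iter(self.sequences)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return SequenceDataset([self.sequences[int(i)] for i in idx],
                                   self.alphabet)
        return self.sequences[idx]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([s.label for s in self.sequences], dtype=object)

    @property
    def groups(self) -> np.ndarray:
        return np.asarray([s.group for s in self.sequences], dtype=object)

    def padded(self, max_len: int | None = None) -> "SequenceDataset":
        if max_len is None:
            max_len = max((s.padded_length for s in self.sequences), default=0)
        return SequenceDataset([pad_or_truncate(s, max_len)
                                for s in self.sequences], self.alphabet)

    def to_arrays(self, max_len: int | None = None):
        """Return ``(X, lengths, labels)`` with X an ``(n, L)`` int matrix."""
        ds = self.padded(max_len)
        if not ds.sequences:
            L = max_len or 0
            return (np.zeros((0, L), dtype=np.int64),
                    np.zeros(0, dtype=np.int64), np.zeros(0, dtype=object))
        X = np.stack([s.token_ids for s in ds.sequences])
        lengths = np.asarray([s.length for s in ds.sequences], dtype=np.int64)
        return X, lengths, ds.labels

    def subset(self, indices) -> "SequenceDataset":
        return self[np.asarray(indices)]

    def extend(self, other: "SequenceDataset") -> "SequenceDataset":
        return SequenceDataset(self.sequences + list(other.sequences),
                               self.alphabet)
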