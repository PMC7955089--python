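"""Seeded synthetic datasets: splice-site-like DNA windows and token corpora.

The DNA generator emulates the statistical shape of the NN269 splice-site
benchmark: fixed-length acceptor windows (90 nt) and donor windows (15 nt),
positives carrying a degenerate consensus motif at a fixed offset, negatives
drawn from background composition.  It makes no attempt at deeper splice
biology (branch points, polypyrimidine tract length variation); only the
learnability structure matters for exercising the models.

All sampling is driven by a single master seed; independent streams are
derived by fixed offsets so each class is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import Alphabet, dna_alphabet, word_alphabet
from .sequence import SequenceDataset, TokenSequence

__all__ = [
    "MotifModel", "CompositionSpec",
    "acceptor_motif", "donor_motif",
    "sample_sequences", "generate_nn269_mimic", "generate_text_corpus",
    "NN269_TOTAL",
]

# Published composition of the NN269 splice-site benchmark as used here:
# 13231 sequences total; 6985 acceptors of length 90 and 6246 donors of
# length 15.  The per-subclass acceptor counts circulating in the
# literature (5643 positive / 1324 negative) do not sum to the acceptor
# total; 1324 is a digit transposition of 1342 (5643 + 1342 = 6985), so the
# default uses 1342 and the transposed variant remains available.
NN269_TOTAL = 13231
ACCEPTOR_LENGTH = 90
DONOR_LENGTH = 15
_NN269_COUNTS = {"AP": 5643, "AN": 1342, "DP": 4922, "DN": 1324}
_NN269_COUNTS_PRINTED = {"AP": 5643, "AN": 1324, "DP": 4922, "DN": 1324}


def _stream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) + offset) % (2 ** 31))


@dataclass(frozen=True)
class MotifModel:
    """Positional emission model: a consensus core inside background sequence.

    Positives emit the consensus base with probability ``match_prob`` at each
    motif position (the remainder spread uniformly over the other bases);
    all other positions — and negatives everywhere — follow ``background``.
    """

    consensus: str
    offset: int
    length: int
    match_prob: float = 0.9
    background: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    alphabet: Alphabet = field(default_factory=dna_alphabet)

    def __post_init__(self):
        if self.offset < 0 or self.offset + len(self.consensus) > self.length:
            raise ValueError("motif does not fit: offset + motif length "
                             f"{self.offset + len(self.consensus)} > {self.length}")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")
        if not 0.0 < self.match_prob <= 1.0:
            raise ValueError("match_prob must be in (0, 1]")

    @property
    def n_bases(self) -> int:
        return len(self.alphabet.tokens)

    def emission_matrix(self, positive: bool) -> np.ndarray:
        """Per-position base probabilities, shape ``(length, n_bases)``."""
        probs = np.tile(np.asarray(self.background), (self.length, 1))
        if positive:
            for j, base in enumerate(self.consensus):
                row = np.full(self.n_bases,
                              (1.0 - self.match_prob) / (self.n_bases - 1))
                row[self.alphabet.index(base) - 2] = self.match_prob
                probs[self.offset + j] = row
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        return probs

    def log_odds(self) -> np.ndarray:
        """Position-weight-matrix log-odds (positive vs background)."""
        pos = self.emission_matrix(True)
        neg = self.emission_matrix(False)
        return np.log(pos) - np.log(neg)


def acceptor_motif(offset: int | None = None, match_prob: float = 0.9) -> MotifModel:
    """90-nt acceptor-like window: pyrimidine-rich consensus ending in AG."""
    consensus = "TTTTCTCCAG"
    if offset is None:
        offset = (ACCEPTOR_LENGTH - len(consensus)) // 2
    return MotifModel(consensus, offset, ACCEPTOR_LENGTH, match_prob)


def donor_motif(offset: int | None = None, match_prob: float = 0.9) -> MotifModel:
    """15-nt donor-like window: exonic CAG followed by the GT-led intron core."""
    consensus = "CAGGTAAGT"
    if offset is None:
        offset = (DONOR_LENGTH - len(consensus)) // 2
    return MotifModel(consensus, offset, DONOR_LENGTH, match_prob)


def sample_sequences(model: MotifModel, n: int, positive: bool, seed: int,
                     id_prefix: str = "seq", label: str | None = None
                     ) -> list[TokenSequence]:
    """Draw ``n`` sequences from the motif model; deterministic given seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = _stream(seed, 0)
    probs = model.emission_matrix(positive)
    cum = probs.cumsum(axis=1)
    u = rng.random((n, model.length))
    base_idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    ids = base_idx + 2  # skip pad/blank
    return [TokenSequence(id=f"{id_prefix}{i:05d}", token_ids=row,
                          length=model.length, label=label)
            for i, row in enumerate(ids)]


@dataclass(frozen=True)
class CompositionSpec:
    """Per-class counts and lengths for a splice-site-like dataset."""

    counts: dict[str, int]
    acceptor_length: int = ACCEPTOR_LENGTH
    donor_length: int = DONOR_LENGTH
    seed: int = 0
    match_prob: float = 0.9

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("class counts must be >= 0")

    @classmethod
    def nn269(cls, seed: int = 0, printed_subclass_counts: bool = False,
              **kwargs) -> "CompositionSpec":
        counts = (_NN269_COUNTS_PRINTED if printed_subclass_counts
                  else _NN269_COUNTS)
        return cls(counts=dict(counts), seed=seed, **kwargs)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def generate_nn269_mimic(spec: CompositionSpec) -> SequenceDataset:
    """Emit exactly the per-class counts at the stated lengths.

    Labels are ``AP``/``AN`` (acceptor positive/negative, 90 nt) and
    ``DP``/``DN`` (donor positive/negative, 15 nt).  Sequences come out at
    native length; pad per type before stacking mixed-length batches.
    """
    acceptor = acceptor_motif(match_prob=spec.match_prob)
    donor = donor_motif(match_prob=spec.match_prob)
    if spec.acceptor_length != acceptor.length:
        acceptor = MotifModel(acceptor.consensus,
                              (spec.acceptor_length - len(acceptor.consensus)) // 2,
                              spec.acceptor_length, spec.match_prob)
    if spec.donor_length != donor.length:
        donor = MotifModel(donor.consensus,
                           (spec.donor_length - len(donor.consensus)) // 2,
                           spec.donor_length, spec.match_prob)
    plan = {
        "AP": (acceptor, True, 1),
        "AN": (acceptor, False, 2),
        "DP": (donor, True, 3),
        "DN": (donor, False, 4),
    }
    seqs: list[TokenSequence] = []
    for cls_label, (model, positive, offset) in plan.items():
        n = spec.counts.get(cls_label, 0)
        seqs.extend(sample_sequences(model, n, positive,
                                     seed=spec.seed + offset,
                                     id_prefix=f"{cls_label}_", label=cls_label))
    return SequenceDataset(seqs, acceptor.alphabet)


def generate_text_corpus(vocab_size: int, n: int, max_len: int, seed: int,
                         min_len: int = 5, n_keywords: int | None = None):
    """Markov-chain word sequences with a planted-keyword binary label.

    Positives contain at least one keyword token, negatives none, so labels
    are recomputable by a keyword scan.  Returns ``(dataset, keywords)``.
    """
    if vocab_size < 2:
        raise ValueError("vocab_size must be >= 2")
    rng = _stream(seed, 7)
    vocab = tuple(f"w{i:03d}" for i in range(vocab_size))
    if n_keywords is None:
        n_keywords = max(1, vocab_size // 10)
    keywords = set(vocab[:n_keywords])
    alphabet = word_alphabet(vocab)
    trans = rng.dirichlet(np.ones(vocab_size), size=vocab_size)
    start = rng.dirichlet(np.ones(vocab_size))
    non_kw = np.asarray([i for i, w in enumerate(vocab) if w not in keywords])
    min_len = min(min_len, max_len)
    seqs = []
    for i in range(n):
        positive = i % 2 == 0
        length = int(rng.integers(min_len, max_len + 1))
        toks = [int(rng.choice(vocab_size, p=start))]
        for _ in range(length - 1):
            toks.append(int(rng.choice(vocab_size, p=trans[toks[-1]])))
        toks = np.asarray(toks)
        kw_mask = np.isin(toks, np.arange(n_keywords))
        if positive and not kw_mask.any():
            toks[rng.integers(length)] = int(rng.integers(n_keywords))
        elif not positive and kw_mask.any():
            toks[kw_mask] = rng.choice(non_kw, size=int(kw_mask.sum()))
        seqs.append(TokenSequence(id=f"txt{i:05d}", token_ids=toks + 2,
                                  length=length,
                                  label="pos" if positive else "neg"))
    return SequenceDataset(seqs, alphabet), tuple(sorted(keywords))
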