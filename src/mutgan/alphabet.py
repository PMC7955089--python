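"""Token alphabets with reserved padding and blank symbols.

Index 0 is always the padding symbol and index 1 the blank (mask) symbol;
ordinary tokens follow in the order given, then any extended symbols.  The
default DNA alphabet is A/C/G/T with extended symbols N and S, since the
generator is allowed to emit non-canonical residues when it mutates a
sequence.  Positions are 0-based everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Alphabet", "build_alphabet", "dna_alphabet", "word_alphabet"]

PAD = "<pad>"
BLANK = "_"

DNA_TOKENS = ("A", "C", "G", "T")
DNA_EXTENDED = ("N", "S")


@dataclass(frozen=True)
class Alphabet:
    """Bijective mapping between token strings and integer ids.

    Parameters
    ----------
    tokens : tuple of str
        Ordinary tokens (without the reserved pad/blank symbols).
    extended : tuple of str
        Extra symbols that are only legal when ``allow_extended`` encoding is
        requested, but that always have ids (the generator may emit them).
    delimiter : str or None
        ``None`` for character sequences (DNA), ``" "`` for word sequences.
    """

    tokens: tuple[str, ...]
    extended: tuple[str, ...] = ()
    delimiter: str | None = None
    pad_token: str = PAD
    blank_token: str = BLANK
    _index: dict[str, int] = field(init=False, repr=False, compare=False,
                                   default=None)

    def __post_init__(self):
        symbols = [self.pad_token, self.blank_token, *self.tokens,
                   *self.extended]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate symbols in alphabet: {dupes}")
        object.__setattr__(self, "_index",
                           {s: i for i, s in enumerate(symbols)})

    # -- basic queries -------------------------------------------------------

    @property
    def symbols(self) -> tuple[str, ...]:
        return (self.pad_token, self.blank_token, *self.tokens, *self.extended)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def blank_id(self) -> int:
        return 1

    @property
    def size(self) -> int:
        """Total number of ids, including pad/blank and extended symbols."""
        return len(self._index)

    def fill_ids(self, include_extended: bool = True) -> np.ndarray:
        """Ids the generator may emit as substitutes (never pad or blank)."""
        hi = self.size if include_extended else 2 + len(self.tokens)
        return np.arange(2, hi)

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"symbol {token!r} not in alphabet") from None

    def __contains__(self, token: str) -> bool:
        return token in self._index

    # -- encode / decode -----------------------------------------------------

    def split(self, text: str) -> list[str]:
        return list(text) if self.delimiter is None else text.split(self.delimiter)

    def join(self, tokens: list[str]) -> str:
        return ("" if self.delimiter is None else self.delimiter).join(tokens)

    def encode(self, text: str, allow_extended: bool = True) -> np.ndarray:
        core = set(self.tokens)
        ids = []
        for pos, tok in enumerate(self.split(text)):
            if tok not in self._index or (not allow_extended
                                          and tok not in core):
                raise ValueError(
                    f"symbol {tok!r} at position {pos} is not encodable "
                    f"(extended symbols {'dis' if not allow_extended else 'en'}abled)")
            ids.append(self._index[tok])
        return np.asarray(ids, dtype=np.int64)

    def decode(self, ids: np.ndarray, strip_pad: bool = True) -> str:
        syms = self.symbols
        toks = [syms[int(i)] for i in ids
                if not (strip_pad and int(i) == self.pad_id)]
        return self.join(toks)


def build_alphabet(tokens, extended=(), delimiter: str | None = None) -> Alphabet:
    """Build an :class:`Alphabet`, validating token uniqueness."""
    tokens = tuple(tokens)
    if not tokens:
        raise ValueError("alphabet needs at least one token")
    if len(set(tokens)) != len(tokens):
        dupes = sorted({t for t in tokens if tokens.count(t) > 1})
        raise ValueError(f"duplicate tokens: {dupes}")
    return Alphabet(tokens=tokens, extended=tuple(extended), delimiter=delimiter)


def dna_alphabet(extended: bool = True) -> Alphabet:
    """A/C/G/T alphabet; with ``extended`` the substitute set adds N and S."""
    return Alphabet(tokens=DNA_TOKENS,
                    extended=DNA_EXTENDED if extended else ())


def word_alphabet(vocabulary, delimiter: str = " ") -> Alphabet:
    """Word-level alphabet over an explicit vocabulary (e.g. a corpus)."""
    return build_alphabet(tuple(vocabulary), delimiter=delimiter)
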