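"""Readers and writers: FASTA and labelled delimited tables.

FASTA has no standard slot for labels, so metadata travels as ``key=value``
tokens in the description line, e.g. ``>seq1 label=AP group=chr1``.
Delimited tables use columns ``id``, ``sequence``, ``label`` and an optional
``mask`` column holding either a 0/1 string aligned to the sequence or a
comma-separated list of 0-based replaced positions.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import Alphabet
from .sequence import GeneratedSequence, SequenceDataset, TokenSequence, encode_sequence

__all__ = [
    "read_fasta", "write_fasta", "read_table", "write_table",
    "parse_mask", "format_mask",
]


def _parse_metadata(description: str) -> dict[str, str]:
    meta = {}
    for tok in description.split()[1:]:  # first token repeats the id
        if "=" in tok:
            key, _, value = tok.partition("=")
            meta[key] = value
    return meta


def read_fasta(path, alphabet: Alphabet,
               allow_extended: bool = True) -> SequenceDataset:
    seqs = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        text = str(rec.seq)
        if not text:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        meta = _parse_metadata(rec.description)
        try:
            seq = encode_sequence(rec.id, text, alphabet,
                                  label=meta.get("label"),
                                  group=meta.get("group"),
                                  allow_extended=allow_extended)
        except ValueError as err:
            raise ValueError(f"record {rec.id!r}: {err}") from None
        seqs.append(seq)
    return SequenceDataset(seqs, alphabet)


def write_fasta(dataset: SequenceDataset, path) -> None:
    records = []
    for s in dataset:
        parts = []
        if s.label is not None:
            parts.append(f"label={s.label}")
        if s.group is not None:
            parts.append(f"group={s.group}")
        rec = SeqRecord(Seq(s.decode(dataset.alphabet)), id=s.id,
                        description=" ".join(parts))
        records.append(rec)
    SeqIO.write(records, os.fspath(path), "fasta")


def parse_mask(text: str, length: int) -> np.ndarray:
    """Parse a mask column value: 0/1 string or comma-separated positions."""
    text = str(text).strip()
    mask = np.zeros(length, dtype=np.int64)
    if set(text) <= {"0", "1"}:
        if len(text) != length:
            raise ValueError(f"mask length {len(text)} != sequence length {length}")
        mask[:] = np.frombuffer(text.encode(), dtype=np.uint8) - ord("0")
        return mask
    for part in text.split(","):
        pos = int(part)
        if not 0 <= pos < length:
            raise ValueError(f"mask position {pos} outside [0, {length})")
        mask[pos] = 1
    return mask


def format_mask(mask: np.ndarray) -> str:
    return "".join("1" if m else "0" for m in np.asarray(mask))


def _sep_for(path) -> str:
    return "," if os.fspath(path).endswith(".csv") else "\t"


def read_table(path, alphabet: Alphabet, allow_extended: bool = True):
    """Read a labelled table; returns ``(SequenceDataset, masks)``.

    ``masks`` is ``None`` when the table has no mask column, otherwise a
    list aligned to the dataset (entries may be ``None`` for blank cells).
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = {"id", "sequence"}
    if not required <= set(df.columns):
        raise ValueError(f"table needs columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    seqs, masks = [], []
    has_mask = "mask" in df.columns
    for _, row in df.iterrows():
        label = row["label"] if "label" in df.columns and row["label"] else None
        group = row["group"] if "group" in df.columns and row["group"] else None
        seq = encode_sequence(str(row["id"]), row["sequence"], alphabet,
                              label=label, group=group,
                              allow_extended=allow_extended)
        seqs.append(seq)
        if has_mask:
            cell = row["mask"]
            masks.append(parse_mask(cell, seq.length) if cell else None)
    return SequenceDataset(seqs, alphabet), (masks if has_mask else None)


def write_table(dataset: SequenceDataset, path,
                masks: Iterable[np.ndarray | None] | None = None,
                source_ids: Iterable[str] | None = None) -> None:
    rows = {
        "id": [s.id for s in dataset],
        "sequence": [s.decode(dataset.alphabet) for s in dataset],
        "label": [s.label if s.label is not None else "" for s in dataset],
    }
    groups = [s.group for s in dataset]
    if any(g is not None for g in groups):
        rows["group"] = [g if g is not None else "" for g in groups]
    if masks is not None:
        rows["mask"] = [format_mask(m) if m is not None else "" for m in masks]
    if source_ids is not None:
        rows["source_id"] = list(source_ids)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def write_generated(mutants: list[GeneratedSequence], alphabet: Alphabet,
                    path) -> None:
    """Write mutants with their provenance and ground-truth masks."""
    ds = SequenceDataset([m.as_token_sequence() for m in mutants], alphabet)
    write_table(ds, path, masks=[m.truth_mask[:m.length] for m in mutants],
                source_ids=[m.source_id for m in mutants])
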