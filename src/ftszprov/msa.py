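"""Multiple alignments with column provenance.

A :class:`MultipleAlignment` is an ordered set of equal-length gapped rows
plus a *provenance* vector mapping each current column back to its column
index in the original (untrimmed) alignment. Trimming operations compose
provenance, so any surviving column can always be traced to its source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .alphabet import AA_INDEX, GAP_CHARS, X_INDEX
from .exceptions import InvalidArgumentError

GAP_CODE = -1


def _row_to_codes(row: str) -> np.ndarray:
    out = np.empty(len(row), dtype=np.int8)
    for i, ch in enumerate(row):
        c = ch.upper()
        if ch in GAP_CHARS:
            out[i] = GAP_CODE
        else:
            out[i] = AA_INDEX.get(c, X_INDEX)
    return out


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InvalidArgumentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidArgumentError("duplicate row ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InvalidArgumentError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if self.provenance is None:
            self.provenance = np.arange(self.length)
        else:
            self.provenance = np.asarray(self.provenance)
            if len(self.provenance) != self.length:
                raise InvalidArgumentError("provenance length != alignment length")
            if self.length > 1 and not np.all(np.diff(self.provenance) > 0):
                raise InvalidArgumentError("provenance must be strictly increasing")

    # -- basic geometry -------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.rows))

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            from .exceptions import MissingIdError

            raise MissingIdError(seq_id) from None

    def ungapped(self, seq_id: str) -> str:
        return "".join(c for c in self.row(seq_id) if c not in GAP_CHARS)

    # -- numeric views ---------------------------------------------------

    def codes(self) -> np.ndarray:
        """Integer matrix (nrows x length); gaps are -1, X is 20."""
        return np.vstack([_row_to_codes(r) for r in self.rows]) if self.rows else np.empty((0, 0), dtype=np.int8)

    def nongap_fraction_per_column(self) -> np.ndarray:
        codes = self.codes()
        return (codes != GAP_CODE).mean(axis=0)

    def nongap_count_per_row(self) -> np.ndarray:
        codes = self.codes()
        return (codes != GAP_CODE).sum(axis=1)

    # -- derived alignments ---------------------------------------------

    def take_columns(self, idx: Sequence[int]) -> "MultipleAlignment":
        """New alignment with the given columns (in order), provenance composed."""
        idx = np.asarray(idx, dtype=int)
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        return MultipleAlignment(list(self.ids), rows, self.provenance[idx])

    def take_rows(self, keep_ids: Iterable[str]) -> "MultipleAlignment":
        keep = list(keep_ids)
        missing = set(keep) - set(self.ids)
        if missing:
            from .exceptions import MissingIdError

            raise MissingIdError(sorted(missing)[0])
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in set(keep)]
        return MultipleAlignment([p[0] for p in pairs], [p[1] for p in pairs], self.provenance.copy())

    def drop_empty_columns(self) -> "MultipleAlignment":
        codes = self.codes()
        keep = np.where((codes != GAP_CODE).any(axis=0))[0]
        return self.take_columns(keep)

    # -- I/O --------------------------------------------------------------

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        write_fasta(zip(self.ids, self.rows), path, width=width)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultipleAlignment":
        ids, rows = [], []
        for name, seq in read_fasta(path):
            ids.append(name)
            rows.append(seq)
        return cls(ids, rows)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
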