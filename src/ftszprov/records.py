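"""Protein records: the atom flowing through every pipeline stage.

A record ties a sequence to its genome, four-rank taxonomy and (optionally)
its locus on a contig. Loci are stored 0-based half-open internally and
written 1-based inclusive in tables (GFF convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .exceptions import InvalidArgumentError

_VALID_SEQ = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$", re.IGNORECASE)

RANKS = ("domain", "phylum", "class", "order")


@dataclass(frozen=True)
class Taxonomy:
    domain: str
    phylum: str
    klass: str
    order: str

    def rank(self, name: str) -> str:
        return {"domain": self.domain, "phylum": self.phylum, "class": self.klass, "order": self.order}[name]


@dataclass(frozen=True)
class Locus:
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidArgumentError(f"bad locus interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise InvalidArgumentError(f"bad strand {self.strand!r}")


@dataclass
class ProteinRecord:
    seq_id: str
    sequence: str
    genome: str
    taxonomy: Optional[Taxonomy] = None
    locus: Optional[Locus] = None

    def __post_init__(self) -> None:
        if not self.sequence or not _VALID_SEQ.match(self.sequence):
            raise InvalidArgumentError(f"record {self.seq_id!r}: invalid or empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Tables


def taxonomy_frame(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    seen: dict[str, Taxonomy] = {}
    for r in records:
        if r.taxonomy is not None:
            seen.setdefault(r.genome, r.taxonomy)
    return pd.DataFrame(
        [(g, t.domain, t.phylum, t.klass, t.order) for g, t in sorted(seen.items())],
        columns=["genome", "domain", "phylum", "class", "order"],
    )


def write_taxonomy(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def gene_table_frame(records: Iterable[ProteinRecord], truth_domain: dict[str, str] | None = None) -> pd.DataFrame:
    """Gene coordinate table, 1-based inclusive as written to disk."""
    rows = []
    for r in records:
        if r.locus is None:
            continue
        rows.append(
            (
                r.genome,
                r.locus.contig,
                r.seq_id,
                r.locus.start + 1,
                r.locus.end,
                r.locus.strand,
                (truth_domain or {}).get(r.seq_id, "."),
            )
        )
    return pd.DataFrame(rows, columns=["genome", "contig", "gene_id", "start", "end", "strand", "truth_domain"])


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome": str, "contig": str, "gene_id": str, "strand": str})
    return df


def taxonomy_lookup(df: pd.DataFrame) -> dict[str, Taxonomy]:
    out: dict[str, Taxonomy] = {}
    for _, row in df.iterrows():
        out[row["genome"]] = Taxonomy(row["domain"], row["phylum"], row["class"], row["order"])
    return out
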