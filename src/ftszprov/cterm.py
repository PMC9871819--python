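"""C-terminus provenance: the workflow's signature test.

The family's members share an N-terminal domain; everything downstream of
that domain's alignment envelope is the lineage-diagnostic tail. For each
phylogenetic group of interest the tails are extracted (anchored at the end
of the N-terminal domain hit), aligned, softly gap-trimmed (-gt 0.1), turned
into a profile HMM, and cross-searched against the *whole* collection with
no E-value threshold. Mapping the resulting E-value strata onto the
reference tree reveals which family a group's tail derives from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curate import trim_gap_threshold
from .exceptions import (
    AnchorNotFoundError,
    GroupTooSmallError,
    InvalidArgumentError,
    MissingIdError,
)
from .phmm import ProfileHMM, build_from_alignment, calibrate, evalue, forward_bits_many, viterbi_hit
from .phylo import SupportTree
from .records import ProteinRecord

MIN_TAIL = 20  # residues; shorter tails make meaningless models
DEFAULT_BIN_EDGES = (1e-10, 1e-5, 1e-3, 1e-1)
FLAG_MEDIAN_E = 1e-2  # weakest stratum still reported as a provenance signal


def extract_cterm(
    record: ProteinRecord,
    nterm_model: ProfileHMM,
    min_tail: int = MIN_TAIL,
    anchor_evalue: float = 1e-3,
) -> Optional[str]:
    """Residues from the end of the N-terminal domain envelope to the end.

    Raises :class:`AnchorNotFoundError` when the N-terminal model does not
    hit the sequence at ``anchor_evalue`` (single-sequence E-value); returns
    ``None`` when the remaining tail is shorter than ``min_tail``.
    """
    bits = forward_bits_many(nterm_model, [record.sequence])[0]
    if evalue(nterm_model, float(bits), db_size=1) > anchor_evalue:
        raise AnchorNotFoundError(f"no N-terminal domain anchor in {record.seq_id!r}")
    hit = viterbi_hit(nterm_model, record.sequence, target_id=record.seq_id)
    tail = record.sequence[hit.env_end :]
    if len(tail) < min_tail:
        return None
    return tail


def extract_group_tails(
    records: Sequence[ProteinRecord],
    nterm_model: ProfileHMM,
    min_tail: int = MIN_TAIL,
) -> tuple[dict[str, str], list[str]]:
    """Tails per record id; ids whose anchor was not found are returned
    separately (recorded and skipped, not fatal)."""
    tails: dict[str, str] = {}
    skipped: list[str] = []
    for rec in records:
        try:
            tail = extract_cterm(rec, nterm_model, min_tail=min_tail)
        except AnchorNotFoundError:
            skipped.append(rec.seq_id)
            continue
        if tail is not None:
            tails[rec.seq_id] = tail
    return tails, skipped


def build_group_model(
    tails: Mapping[str, str],
    name: str,
    gt: float = 0.1,
    seed: int = 0,
    calibrate_n: int = 1000,
) -> ProfileHMM:
    """Align the group's tails, soft-trim (-gt), build and calibrate an HMM."""
    if len(tails) < 3:
        raise GroupTooSmallError(f"group {name!r} has {len(tails)} usable tails (< 3)")
    recs = [ProteinRecord(rid, seq, genome="-") for rid, seq in sorted(tails.items())]
    from .align import progressive_align

    msa = progressive_align(recs)
    trimmed = trim_gap_threshold(msa, gt)
    model = build_from_alignment(trimmed, occupancy=0.5, name=name)
    return calibrate(model, n_random=calibrate_n, seed=seed)


# ---------------------------------------------------------------------------
# Cross-search


@dataclass
class HitMatrix:
    """Query-model x target best E-values (dense; searches are thresholdless)."""

    models: list[str]
    targets: list[str]
    evalues: np.ndarray  # (n_models, n_targets)
    db_size: int

    def __post_init__(self) -> None:
        self.evalues = np.asarray(self.evalues, dtype=float)
        if self.evalues.shape != (len(self.models), len(self.targets)):
            raise InvalidArgumentError("hit matrix shape mismatch")
        if (self.evalues < 0).any():
            raise InvalidArgumentError("negative E-values")

    def evalue_of(self, model: str, target: str) -> float:
        return float(self.evalues[self.models.index(model), self.targets.index(target)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("model\t" + "\t".join(self.targets) + "\n")
            for i, m in enumerate(self.models):
                fh.write(m + "\t" + "\t".join(repr(float(v)) for v in self.evalues[i]) + "\n")
            fh.write(f"#db_size\t{self.db_size}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HitMatrix":
        lines = Path(path).read_text().splitlines()
        targets = lines[0].split("\t")[1:]
        models, rows = [], []
        db_size = 0
        for ln in lines[1:]:
            if ln.startswith("#db_size"):
                db_size = int(ln.split("\t")[1])
                continue
            parts = ln.split("\t")
            models.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        return cls(models, targets, np.array(rows), db_size)


def cross_search(models: Sequence[ProfileHMM], collection: Sequence[ProteinRecord]) -> HitMatrix:
    """Every model against every collection member, no E-value threshold."""
    targets = [r.seq_id for r in collection]
    seqs = [r.sequence for r in collection]
    ev = np.zeros((len(models), len(targets)))
    db_size = len(collection)
    for i, model in enumerate(models):
        if not model.calibrated:
            from .exceptions import StateError

            raise StateError(f"model {model.name!r} is not calibrated")
        if seqs:
            bits = forward_bits_many(model, seqs)
            ev[i] = [evalue(model, float(b), db_size) for b in bits]
    return HitMatrix([m.name for m in models], targets, ev, db_size)


# ---------------------------------------------------------------------------
# Tree mapping and reporting


def evalue_bin(e: float, edges: Sequence[float] = DEFAULT_BIN_EDGES) -> int:
    """Bin index for an E-value; the last bin (len(edges)) renders blank."""
    return int(np.searchsorted(np.asarray(edges), e, side="left"))


def map_hits_to_tree(
    tree: SupportTree,
    matrix: HitMatrix,
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    dataset_label: str = "cterm_hits",
) -> str:
    """iTOL heatmap dataset: per leaf, per query model, the E-value bin index.

    Bin 0 is the strongest stratum (E below the first edge); leaves without a
    recorded hit fall in the maximum ("blank") bin.
    """
    leaves = set(tree.leaf_ids)
    missing = [t for t in matrix.targets if t not in leaves]
    if missing:
        raise MissingIdError(missing[0])
    max_bin = len(edges)
    by_target = {t: i for i, t in enumerate(matrix.targets)}
    lines = [
        "DATASET_HEATMAP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#444444",
        "FIELD_LABELS\t" + "\t".join(matrix.models),
        "DATA",
    ]
    for leaf in tree.leaf_ids:
        if leaf in by_target:
            bins = [evalue_bin(float(matrix.evalues[m, by_target[leaf]]), edges) for m in range(len(matrix.models))]
        else:
            bins = [max_bin] * len(matrix.models)
        lines.append(leaf + "\t" + "\t".join(str(b) for b in bins))
    return "\n".join(lines) + "\n"


def provenance_report(
    matrix: HitMatrix,
    family_of: Mapping[str, str],
    domain_of: Mapping[str, str],
    strong_evalue: float = 1e-3,
    flag_median_evalue: float = FLAG_MEDIAN_E,
) -> pd.DataFrame:
    """Per (query model, family, taxonomic domain) stratum statistics.

    Reports the median and minimum E-value, the fraction of targets hit at
    E <= ``strong_evalue``, and a verdict flag raised when the stratum's
    median E-value is <= ``flag_median_evalue`` (the weakest stratum still
    read as a provenance signal).
    """
    strata: dict[tuple[str, str], list[int]] = {}
    for j, t in enumerate(matrix.targets):
        key = (family_of.get(t, "?"), domain_of.get(t, "?"))
        strata.setdefault(key, []).append(j)
    rows = []
    for i, model in enumerate(matrix.models):
        for (family, dom), idx in sorted(strata.items()):
            ev = matrix.evalues[i, idx]
            if len(ev) == 0:
                med, mn, frac = math.inf, math.inf, 0.0
            else:
                med = float(np.median(ev))
                mn = float(ev.min())
                frac = float((ev <= strong_evalue).mean())
            rows.append((model, family, dom, len(idx), med, mn, frac, bool(med <= flag_median_evalue)))
    return pd.DataFrame(
        rows,
        columns=["query_model", "family", "tax_domain", "n", "median_evalue", "min_evalue", "hit_frac", "flagged"],
    )


def read_group_file(path: str | Path) -> dict[str, list[str]]:
    """Group definition TSV: columns (group name, member id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["group", "member"], dtype=str)
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["group"], []).append(row["member"])
    return out


def write_group_file(groups: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for g in sorted(groups):
            for m in groups[g]:
                fh.write(f"{g}\t{m}\n")
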