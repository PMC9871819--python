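"""Dataset curation: coverage filtering, taxonomically balanced redundancy
removal, one-per-order subsampling, and alignment trimming.

The redundancy scheme removes similar sequences *within each taxonomic
class*, with an identity cutoff that relaxes as the class grows: 95% for
classes of up to 20 sequences down to 55% at 250 or more, linearly
interpolated in between. Pairwise identity is matches / global-alignment
length (gaps count in the denominator), which approximates CD-HIT's
behaviour without its word-filter heuristics.

Two trimmers are provided: plain gap-threshold trimming (trimAl ``-gt``
semantics) and an entropy-based trimmer inspired by BMGE (similarity-aware
column entropy, gap rule, smoothing window) that is deliberately not
bit-compatible with BMGE itself.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .align import pairwise_identity
from .alphabet import substitution_matrix
from .exceptions import (
    ConfigurationError,
    EmptyAlignmentError,
    InvalidArgumentError,
    MissingIdError,
)
from .msa import GAP_CODE, MultipleAlignment
from .records import ProteinRecord


# ---------------------------------------------------------------------------
# Row-level curation


def coverage_filter(msa: MultipleAlignment, min_cov: float = 0.6) -> list[str]:
    """Ids of rows whose non-gap fraction of the alignment length is >= min_cov.

    The denominator is the full alignment length ("alignment coverage");
    the boundary is inclusive.
    """
    if msa.nrows == 0:
        raise InvalidArgumentError("empty alignment")
    if not (0 < min_cov <= 1):
        raise InvalidArgumentError("min_cov must be in (0, 1]")
    counts = msa.nongap_count_per_row()
    return [sid for sid, c in zip(msa.ids, counts) if c / msa.length >= min_cov]


def identity_cutoff_for_class(n_class: int) -> float:
    """Redundancy cutoff for a taxonomic class of ``n_class`` sequences.

    <=20 sequences -> 0.95; >=250 -> 0.55; linear in between, rounded to
    two decimals. Monotonically non-increasing in n.
    """
    if n_class < 0:
        raise InvalidArgumentError("n_class must be >= 0")
    if n_class <= 20:
        return 0.95
    if n_class >= 250:
        return 0.55
    return round(0.95 + (n_class - 20) * (0.55 - 0.95) / (250 - 20), 2)


def cluster_by_identity(
    records: Sequence[ProteinRecord],
    cutoff: float,
    **align_kwargs,
) -> list[ProteinRecord]:
    """Greedy length-sorted clustering; returns the representatives.

    Sequences are visited longest first (ties by id); each joins the first
    existing cluster whose representative is >= cutoff identical, else founds
    a new cluster. Representatives may themselves be >= cutoff identical
    (greedy, as in CD-HIT).
    """
    if not (0 < cutoff <= 1):
        raise InvalidArgumentError("cutoff must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.seq_id))
    reps: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for rep in reps:
            if pairwise_identity(rep.sequence, rec.sequence, **align_kwargs) >= cutoff:
                placed = True
                break
        if not placed:
            reps.append(rec)
    return reps


def cluster_members(
    records: Sequence[ProteinRecord], cutoff: float, **align_kwargs
) -> dict[str, list[str]]:
    """Representative id -> member ids (including the representative)."""
    if not (0 < cutoff <= 1):
        raise InvalidArgumentError("cutoff must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.seq_id))
    reps: list[ProteinRecord] = []
    out: dict[str, list[str]] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            if pairwise_identity(rep.sequence, rec.sequence, **align_kwargs) >= cutoff:
                home = rep
                break
        if home is None:
            reps.append(rec)
            out[rec.seq_id] = [rec.seq_id]
        else:
            out[home.seq_id].append(rec.seq_id)
    return out


def reduce_redundancy_by_class(
    records: Sequence[ProteinRecord], **align_kwargs
) -> list[ProteinRecord]:
    """Apply class-size-dependent identity clustering within each taxonomic class."""
    by_class: dict[str, list[ProteinRecord]] = {}
    for r in records:
        if r.taxonomy is None:
            raise InvalidArgumentError(f"record {r.seq_id!r} lacks taxonomy")
        by_class.setdefault(r.taxonomy.klass, []).append(r)
    kept: list[ProteinRecord] = []
    for klass in sorted(by_class):
        group = by_class[klass]
        cutoff = identity_cutoff_for_class(len(group))
        kept.extend(cluster_by_identity(group, cutoff, **align_kwargs))
    kept.sort(key=lambda r: r.seq_id)
    return kept


def one_per_order(
    records: Sequence[ProteinRecord],
    seed: int = 0,
    include_ids: Optional[Iterable[str]] = None,
) -> list[ProteinRecord]:
    """One uniformly random record per taxonomic order (plus forced includes).

    ``include_ids`` names records that must be retained regardless of the
    draw (the taxa one wants represented more densely).
    """
    rng = np.random.default_rng(seed)
    by_id = {r.seq_id: r for r in records}
    include = list(include_ids or [])
    for sid in include:
        if sid not in by_id:
            raise MissingIdError(sid)
    by_order: dict[str, list[ProteinRecord]] = {}
    for r in records:
        if r.taxonomy is None:
            raise InvalidArgumentError(f"record {r.seq_id!r} lacks taxonomy")
        by_order.setdefault(r.taxonomy.order, []).append(r)
    picked: dict[str, ProteinRecord] = {}
    for order in sorted(by_order):
        group = sorted(by_order[order], key=lambda r: r.seq_id)
        picked_rec = group[int(rng.integers(len(group)))]
        picked[picked_rec.seq_id] = picked_rec
    for sid in include:
        picked[sid] = by_id[sid]
    return [picked[k] for k in sorted(picked)]


# ---------------------------------------------------------------------------
# Column trimming


def trim_gap_threshold(msa: MultipleAlignment, gt: float) -> MultipleAlignment:
    """Keep columns whose non-gap fraction is >= gt (trimAl -gt semantics)."""
    if not (0 <= gt <= 1):
        raise InvalidArgumentError("gt must be in [0, 1]")
    frac = msa.nongap_fraction_per_column()
    keep = np.where(frac >= gt)[0]
    if len(keep) == 0:
        raise EmptyAlignmentError(f"gap-threshold trimming at gt={gt} removed every column")
    return msa.take_columns(keep)


def _column_entropy_scores(msa: MultipleAlignment, sim: np.ndarray) -> np.ndarray:
    """Similarity-aware normalised column entropies in [0, 1].

    Within a column, each residue's count is absorbed into the most frequent
    residue it has a positive similarity score with (strictly more frequent;
    ties by alphabet), then the normalised Shannon entropy of the merged
    distribution is taken. A conserved column scores 0; a column uniform
    over all 20 residues scores 1 (no residue is strictly dominant, so
    nothing merges).
    """
    codes = msa.codes()
    positive = sim > 0
    scores = np.zeros(msa.length)
    for col in range(msa.length):
        vals = codes[:, col]
        vals = vals[(vals != GAP_CODE) & (vals < 20)]
        if len(vals) == 0:
            scores[col] = 0.0
            continue
        counts = np.bincount(vals, minlength=20).astype(float)
        merged = counts.copy()
        for a in range(20):
            if counts[a] == 0:
                continue
            best = -1
            for b in range(20):
                if b != a and positive[a, b] and counts[b] > counts[a]:
                    if best < 0 or counts[b] > counts[best]:
                        best = b
            if best >= 0:
                merged[best] += merged[a]
                merged[a] = 0.0
        p = merged[merged > 0] / merged.sum()
        scores[col] = float(-(p * np.log(p)).sum() / math.log(20))
    return scores


def trim_entropy(
    msa: MultipleAlignment,
    h_max: float = 0.55,
    sim_matrix: str = "BLOSUM45",
    max_gap_fraction: float = 0.2,
    window: int = 3,
) -> MultipleAlignment:
    """Entropy-based trimming in the spirit of BMGE.

    A column is removed when its similarity-aware entropy score exceeds
    ``h_max`` (either raw or after smoothing with a centered moving-average
    window) or when its gap fraction exceeds ``max_gap_fraction``.
    """
    if not (0 < h_max <= 1):
        raise InvalidArgumentError("h_max must be in (0, 1]")
    try:
        sim = substitution_matrix(sim_matrix)
    except KeyError as exc:
        raise ConfigurationError(str(exc)) from exc
    raw = _column_entropy_scores(msa, sim)
    if window > 1 and msa.length >= window:
        kernel = np.ones(window) / window
        smooth = np.convolve(raw, kernel, mode="same")
    else:
        smooth = raw
    gap_frac = 1.0 - msa.nongap_fraction_per_column()
    # fully conserved columns (raw score 0) are never removed by smoothing
    entropy_ok = (raw <= h_max) & ((smooth <= h_max) | (raw == 0))
    keep = np.where(entropy_ok & (gap_frac <= max_gap_fraction))[0]
    if len(keep) == 0:
        raise EmptyAlignmentError("entropy trimming removed every column")
    return msa.take_columns(keep)


def trim_report(msa: MultipleAlignment, trimmed: MultipleAlignment) -> pd.DataFrame:
    """Per-original-column report: kept flag plus non-gap fraction."""
    kept_src = set(trimmed.provenance.tolist())
    frac = msa.nongap_fraction_per_column()
    rows = [
        (int(msa.provenance[i]), int(msa.provenance[i] in kept_src), "%.6g" % frac[i])
        for i in range(msa.length)
    ]
    return pd.DataFrame(rows, columns=["original_column", "kept", "nongap_fraction"])


# ---------------------------------------------------------------------------
# Alignment merging


def merge_alignments(msa_a: MultipleAlignment, msa_b: MultipleAlignment) -> MultipleAlignment:
    """Profile-profile merge of two alignments over disjoint row ids.

    Rows of each input stay mutually aligned exactly as before; the merge
    only inserts shared all-gap columns (MAFFT --merge semantics).
    """
    if msa_b.nrows == 0:
        return msa_a
    if msa_a.nrows == 0:
        return msa_b
    overlap = set(msa_a.ids) & set(msa_b.ids)
    if overlap:
        raise InvalidArgumentError(f"overlapping row ids: {sorted(overlap)[:3]}")
    from .align import _extended_matrix, _merge_profiles

    mat = _extended_matrix("BLOSUM62")
    rows_a, rows_b, _ = _merge_profiles(list(msa_a.rows), list(msa_b.rows), mat, -11.0, -1.0)
    return MultipleAlignment(list(msa_a.ids) + list(msa_b.ids), rows_a + rows_b)
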