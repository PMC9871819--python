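"""Built-in progressive multiple aligner.

The pipeline must run with no external binaries, so alignment is done with a
classic progressive strategy: a k-mer (k=3) cosine-distance guide tree built
by UPGMA, then profile-profile global alignments (affine gaps, Gotoh) merged
up the tree. Once two residues are aligned inside a profile their relative
alignment never changes ("once a gap, always a gap").

An adapter hook (:func:`align_with_external`) lets users plug in an external
aligner executable; its FASTA output is subjected to the same invariants.

Gap costs follow the "first residue costs ``gap_open``" convention: a gap of
length k costs ``gap_open + (k-1) * gap_extend`` (both are negative numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage

from .alphabet import GAP_CHARS, encode, substitution_matrix
from .exceptions import InvalidArgumentError
from .msa import MultipleAlignment
from .records import ProteinRecord

NEG_INF = -1e30


def _extended_matrix(name: str) -> np.ndarray:
    """21x21 score matrix: 20 residues + X (scores 0 against everything)."""
    m20 = substitution_matrix(name)
    m = np.zeros((21, 21))
    m[:20, :20] = m20
    return m


# ---------------------------------------------------------------------------
# Affine-gap global DP on a precomputed position-score matrix.
#
# Rows are vectorised; the horizontal gap state E, whose recurrence runs along
# the row, is computed exactly with a running-maximum transform:
#   E[i][j] = go + ge*(j-1) + max_{k<j} (H[i][k] - ge*k)
# which is valid because a horizontal gap always opens from a non-E state
# (an E->E "reopen" is dominated by extension when go <= ge).


def _affine_global(S: np.ndarray, go: float, ge: float):
    """Return (score, H, E, F) for global alignment over score matrix S (La x Lb)."""
    if go > ge:
        raise InvalidArgumentError("gap_open must be <= gap_extend (more negative)")
    la, lb = S.shape
    H = np.full((la + 1, lb + 1), NEG_INF)
    E = np.full((la + 1, lb + 1), NEG_INF)  # gap in A (consumes B)
    F = np.full((la + 1, lb + 1), NEG_INF)  # gap in B (consumes A)
    H[0, 0] = 0.0
    if lb:
        E[0, 1:] = go + ge * np.arange(lb)
        H[0, 1:] = E[0, 1:]
    js = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        F[i, 0] = max(H[i - 1, 0] + go, F[i - 1, 0] + ge)
        H[i, 0] = F[i, 0]
        if not lb:
            continue
        D = H[i - 1, :-1] + S[i - 1]
        F[i, 1:] = np.maximum(H[i - 1, 1:] + go, F[i - 1, 1:] + ge)
        G = np.maximum(D, F[i, 1:])  # candidates a horizontal gap can open from
        m = np.empty(lb + 1)
        m[0] = H[i, 0]
        m[1:] = G - ge * js
        E[i, 1:] = go + ge * (js - 1) + np.maximum.accumulate(m)[:-1]
        H[i, 1:] = np.maximum(G, E[i, 1:])
    return H[la, lb], H, E, F


def _traceback(S, go, ge, H, E, F):
    """Recover one optimal path; ties prefer diagonal > up (gap in B) > left."""
    i, j = S.shape
    ops: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + S[i - 1, j - 1]):
                ops.append("D")
                i, j = i - 1, j - 1
            elif i > 0 and np.isclose(H[i, j], F[i, j]):
                state = "F"
            elif j > 0 and np.isclose(H[i, j], E[i, j]):
                state = "E"
            elif i > 0:  # border column
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("A")  # consume A, gap in B
            if i > 1 and np.isclose(F[i, j], F[i - 1, j] + ge):
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # E
            ops.append("B")  # consume B, gap in A
            if j > 1 and np.isclose(E[i, j], E[i, j - 1] + ge):
                j -= 1
            else:
                j -= 1
                state = "H"
    ops.reverse()
    return ops


# ---------------------------------------------------------------------------
# Pairwise


@dataclass
class AlignedPair:
    a: str
    b: str
    score: float


def pairwise_global(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> AlignedPair:
    """Needleman-Wunsch global alignment with affine gaps.

    Deterministic tie-break: diagonal > up > left.
    """
    if not a or not b:
        raise InvalidArgumentError("pairwise_global requires two non-empty sequences")
    ea, eb = encode(a), encode(b)
    mat = _extended_matrix(matrix)
    S = mat[np.asarray(ea, dtype=int)[:, None], np.asarray(eb, dtype=int)[None, :]]
    score, H, E, F = _affine_global(S, gap_open, gap_extend)
    ops = _traceback(S, gap_open, gap_extend, H, E, F)
    ai = bi = 0
    ra, rb = [], []
    for op in ops:
        if op == "D":
            ra.append(a[ai]); rb.append(b[bi]); ai += 1; bi += 1
        elif op == "A":
            ra.append(a[ai]); rb.append("-"); ai += 1
        else:
            ra.append("-"); rb.append(b[bi]); bi += 1
    return AlignedPair("".join(ra), "".join(rb), float(score))


def pairwise_identity(a: str, b: str, **kwargs) -> float:
    """Fraction of identical positions over the *global alignment length*.

    Gap columns count in the denominator; an X never counts as a match.
    """
    pair = pairwise_global(a, b, **kwargs)
    matches = sum(
        1 for x, y in zip(pair.a, pair.b) if x == y and x not in GAP_CHARS and x != "X"
    )
    return matches / len(pair.a)


# ---------------------------------------------------------------------------
# Profiles and progressive alignment


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(L x 21) residue-count matrix; gaps contribute nothing."""
    L = len(rows[0])
    counts = np.zeros((L, 21))
    for r in rows:
        for i, ch in enumerate(r):
            if ch in GAP_CHARS:
                continue
            counts[i, encode(ch)[0]] += 1
    return counts


def _merge_profiles(rows_a: list[str], rows_b: list[str], mat: np.ndarray, go: float, ge: float):
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na = np.maximum(ca.sum(axis=1), 1e-9)
    nb = np.maximum(cb.sum(axis=1), 1e-9)
    S = (ca @ mat @ cb.T) / np.outer(na, nb)
    score, H, E, F = _affine_global(S, go, ge)
    ops = _traceback(S, go, ge, H, E, F)
    out_a, out_b = [], []
    ai = bi = 0
    for op in ops:
        if op == "D":
            out_a.append(ai); out_b.append(bi); ai += 1; bi += 1
        elif op == "A":
            out_a.append(ai); out_b.append(None); ai += 1
        else:
            out_a.append(None); out_b.append(bi); bi += 1

    def expand(rows: list[str], col_map: list[int | None]) -> list[str]:
        return ["".join(r[c] if c is not None else "-" for c in col_map) for r in rows]

    return expand(rows_a, out_a), expand(rows_b, out_b), float(score)


def _kmer_vectors(seqs: list[str], k: int = 3) -> np.ndarray:
    keys: dict[str, int] = {}
    rows = []
    for s in seqs:
        counts: dict[int, int] = {}
        kk = min(k, len(s))
        for i in range(len(s) - kk + 1):
            key = s[i : i + kk]
            idx = keys.setdefault(key, len(keys))
            counts[idx] = counts.get(idx, 0) + 1
        rows.append(counts)
    mat = np.zeros((len(seqs), max(len(keys), 1)))
    for r, counts in enumerate(rows):
        for idx, c in counts.items():
            mat[r, idx] = c
    return mat


def _cosine_distances(vecs: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    sim = (vecs @ vecs.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def progressive_align(
    records: list[ProteinRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> MultipleAlignment:
    """Progressive MSA over a UPGMA guide tree of k-mer cosine distances.

    The guide tree is built over records sorted by id, so the result (and its
    sum-of-pairs score) does not depend on input order for distinct sequences;
    output rows keep the caller's order.
    """
    if len(records) < 2:
        raise InvalidArgumentError("progressive_align requires >= 2 records")
    ids = [r.seq_id for r in records]
    if len(set(ids)) != len(ids):
        raise InvalidArgumentError("duplicate sequence ids")
    for r in records:
        encode(r.sequence)  # alphabet validation up front

    order = sorted(range(len(records)), key=lambda i: ids[i])
    seqs = [records[i].sequence for i in order]
    mat = _extended_matrix(matrix)

    if len(seqs) == 2:
        ra, rb, _ = _merge_profiles([seqs[0]], [seqs[1]], mat, gap_open, gap_extend)
        final_members, final_rows = [0, 1], ra + rb
    else:
        d = _cosine_distances(_kmer_vectors(seqs))
        condensed = d[np.triu_indices(len(seqs), k=1)]
        Z = linkage(condensed, method="average")
        clusters = {i: ([i], [seqs[i]]) for i in range(len(seqs))}
        nxt = len(seqs)
        for za, zb, _, _ in Z:
            ma, rows_a = clusters.pop(int(za))
            mb, rows_b = clusters.pop(int(zb))
            ra, rb, _ = _merge_profiles(rows_a, rows_b, mat, gap_open, gap_extend)
            clusters[nxt] = (ma + mb, ra + rb)
            nxt += 1
        final_members, final_rows = clusters.popitem()[1]

    # map back: final_members holds indices into `order`
    by_input: dict[int, str] = {}
    for member, row in zip(final_members, final_rows):
        by_input[order[member]] = row
    return MultipleAlignment(ids, [by_input[i] for i in range(len(records))])


def sum_of_pairs_score(
    msa: MultipleAlignment,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> float:
    """Sum-of-pairs score with affine per-pair gap runs (gap-gap columns free)."""
    mat = _extended_matrix(matrix)
    codes = msa.codes()
    total = 0.0
    n = codes.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            both = (a >= 0) & (b >= 0)
            total += mat[a[both].astype(int), b[both].astype(int)].sum()
            # affine gap runs where exactly one of the pair is gapped
            for one_gap in ((a >= 0) & (b < 0), (a < 0) & (b >= 0)):
                run = False
                for col in range(len(a)):
                    if one_gap[col]:
                        total += gap_extend if run else gap_open
                        run = True
                    else:
                        run = False
    return total


def align_with_external(records: list[ProteinRecord], command_template: str) -> MultipleAlignment:
    """Adapter: run an external aligner and validate its FASTA output.

    ``command_template`` must contain ``{input}``; the command must write
    aligned FASTA to stdout. Every output row must ungap back to its input
    sequence, and all input ids must be present.
    """
    import subprocess
    import tempfile

    from .msa import write_fasta

    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        path = fh.name
    write_fasta([(r.seq_id, r.sequence) for r in records], path)
    out = subprocess.run(
        command_template.format(input=path), shell=True, capture_output=True, text=True, check=True
    ).stdout
    import io

    from Bio import SeqIO

    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(io.StringIO(out), "fasta")]
    msa = MultipleAlignment([p[0] for p in pairs], [p[1] for p in pairs])
    by_id = {r.seq_id: r.sequence for r in records}
    if set(msa.ids) != set(by_id):
        raise InvalidArgumentError("external aligner dropped or invented sequences")
    for sid in msa.ids:
        if msa.ungapped(sid).upper() != by_id[sid]:
            raise InvalidArgumentError(f"external aligner altered sequence {sid!r}")
    return msa.take_rows([r.seq_id for r in records])
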