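"""Amino-acid alphabet, background frequencies, and substitution matrices.

The 20-letter alphabet is kept in a fixed order everywhere; ``X`` is accepted
in sequences as an unknown residue (it scores as background, i.e. log-odds 0,
and never counts as a match in identity computations).
"""

from __future__ import annotations

import functools

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
X_INDEX = 20  # sentinel for unknown residue
GAP_CHARS = "-."

# Swiss-Prot-style background amino-acid frequencies, normalised to sum to 1.
_BG = np.array(
    [
        0.0826, 0.0137, 0.0546, 0.0674, 0.0386, 0.0708, 0.0227, 0.0593,
        0.0582, 0.0965, 0.0241, 0.0406, 0.0472, 0.0393, 0.0553, 0.0660,
        0.0535, 0.0686, 0.0110, 0.0292,
    ]
)
BACKGROUND = _BG / _BG.sum()


@functools.lru_cache(maxsize=None)
def substitution_matrix(name: str) -> np.ndarray:
    """Return a 20x20 float score matrix in this package's residue order.

    Matrices are loaded from Biopython's
    :mod:`Bio.Align.substitution_matrices` collection (BLOSUM45/50/62/80/90,
    PAM series, ...). Unknown names raise ``KeyError``.
    """
    from Bio.Align import substitution_matrices

    try:
        raw = substitution_matrices.load(name.upper())
    except FileNotFoundError as exc:
        raise KeyError(f"unknown substitution matrix: {name!r}") from exc
    mat = np.empty((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            mat[i, j] = raw[a, b]
    return mat


def encode(seq: str, *, allow_x: bool = True) -> np.ndarray:
    """Encode an amino-acid string to integer indices (X -> 20).

    Raises ``AlphabetError`` naming the first offending position.
    """
    from .exceptions import AlphabetError

    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        c = ch.upper()
        idx = AA_INDEX.get(c)
        if idx is None:
            if allow_x and c == "X":
                idx = X_INDEX
            else:
                raise AlphabetError(f"invalid residue {ch!r} at position {i}")
        out[i] = idx
    return out


def decode(indices: np.ndarray) -> str:
    return "".join(AA[i] if i < 20 else "X" for i in indices)
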