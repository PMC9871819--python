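"""Profile hidden Markov models: build, calibrate, score, search.

This is the engine behind family collection (hmmsearch-style), neighborhood
domain annotation (hmmscan-style) and the C-terminus cross-search
(hmmbuild-style). The model is the classic match/insert/delete profile HMM;
scores are log2-odds ("bits") against an i.i.d. background.

Alignment modes
---------------
``local`` (default, hmmsearch-like): the core model may align to any target
substring; entry/exit is uniform over (first, last) match-state pairs with
weight 2/(M(M+1)), and unaligned flanking residues are emitted by the
background through a length-dependent wrapper contributing
``log2(2/(L+2))`` bits. With this wrapper the model is (sub-)probabilistic,
so the expected odds on background sequences is <= 1 and null bit scores
center below zero.

``glocal``: the path must traverse the whole model (begin/delete-chain entry,
match/delete-chain exit); target flanks are free. Scores in this mode are not
comparable to calibrated local scores.

E-values follow HMMER semantics: ``E = db_size * P(S >= s)`` under a Gumbel
law fitted by maximum likelihood to forward bit scores of random background
sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gumbel_r

from .alphabet import AA, BACKGROUND, decode, encode
from .exceptions import (
    CalibrationError,
    InvalidArgumentError,
    ModelDegenerateError,
    StateError,
)
from .msa import GAP_CODE, MultipleAlignment
from .records import ProteinRecord

NEG = -np.inf


def _log2(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(x)


@dataclass
class ProfileHMM:
    """A calibratable profile HMM with M match states."""

    name: str
    match_emit: np.ndarray  # (M, 20), rows sum to 1
    bg: np.ndarray  # (20,)
    # transitions out of state k (0-based arrays of length M); the last
    # match row's t_mm is the M->end probability.
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    b_m: float = 1.0  # begin -> M1 (glocal entry)
    b_d: float = 0.0  # begin -> D1
    mean_length: float = 100.0
    mu: Optional[float] = None  # Gumbel location (bits)
    lam: Optional[float] = None  # Gumbel rate = 1/scale

    @property
    def M(self) -> int:
        return self.match_emit.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.mu is not None and self.lam is not None

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        if self.match_emit.ndim != 2 or self.match_emit.shape[1] != 20 or self.M < 1:
            raise InvalidArgumentError("match_emit must be (M, 20) with M >= 1")
        for label, arr in [("emission", self.match_emit)]:
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidArgumentError(f"{label} rows must sum to 1")
        for label, a, b, c in [
            ("match", self.t_mm, self.t_mi, self.t_md),
            ("insert", self.t_im, self.t_ii, None),
            ("delete", self.t_dm, self.t_dd, None),
        ]:
            total = np.asarray(a) + np.asarray(b) + (np.asarray(c) if c is not None else 0.0)
            if not np.allclose(total, 1.0, atol=1e-9):
                raise InvalidArgumentError(f"{label} transition rows must sum to 1")
        if self.lam is not None and self.lam <= 0:
            raise InvalidArgumentError("calibrated lambda must be > 0")

    # -- consensus ------------------------------------------------------

    def consensus(self) -> str:
        return decode(self.match_emit.argmax(axis=1))

    # -- precomputed scoring tables --------------------------------------

    def _tables(self, mode: str):
        M = self.M
        LO = np.zeros((M, 21))
        LO[:, :20] = _log2(self.match_emit) - _log2(self.bg)[None, :]
        lt = {k: _log2(getattr(self, k)) for k in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")}
        entry = np.full(M, NEG)
        exit_ = np.full(M, NEG)
        if mode == "local":
            entry[:] = math.log2(2.0 / (M * (M + 1)))
            exit_[:] = 0.0
        elif mode == "glocal":
            # entry: B->M1, or B->D1->...->D_{k-1}->M_k
            entry[0] = _log2(np.array([self.b_m]))[0]
            acc = _log2(np.array([self.b_d]))[0]
            for k in range(1, M):
                entry[k] = acc + lt["t_dm"][k - 1]
                acc += lt["t_dd"][k - 1]
            # exit: M_M->E, or M_k->D_{k+1}->...->D_M->E (D_M->E free)
            exit_[M - 1] = lt["t_mm"][M - 1]
            acc = 0.0  # sum of D->D hops between M_k's delete chain and the end
            for k in range(M - 2, -1, -1):
                exit_[k] = lt["t_md"][k] + acc
                acc += lt["t_dd"][k]
        else:
            raise InvalidArgumentError(f"unknown alignment mode {mode!r}")
        return LO, lt, entry, exit_

    # -- serialization ----------------------------------------------------

    def to_text(self, path: str | Path) -> None:
        def fmt(v: float) -> str:
            return "%.12g" % v

        lines = [
            "FTSZPROV-HMM 1",
            f"NAME {self.name}",
            f"M {self.M}",
            f"MEANLEN {fmt(self.mean_length)}",
            "CALIB " + (f"{fmt(self.mu)} {fmt(self.lam)}" if self.calibrated else "none"),
            f"BEGIN {fmt(self.b_m)} {fmt(self.b_d)}",
            "BACKGROUND " + " ".join(fmt(v) for v in self.bg),
        ]
        for k in range(self.M):
            lines.append(f"MATCH {k + 1} " + " ".join(fmt(v) for v in self.match_emit[k]))
        for k in range(self.M):
            row = [self.t_mm[k], self.t_mi[k], self.t_md[k], self.t_im[k], self.t_ii[k], self.t_dm[k], self.t_dd[k]]
            lines.append(f"TRANSITIONS {k + 1} " + " ".join(fmt(v) for v in row))
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "ProfileHMM":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("FTSZPROV-HMM"):
            raise InvalidArgumentError(f"{path}: not a ftszprov HMM file")
        kv: dict[str, str] = {}
        match_rows: dict[int, list[float]] = {}
        trans_rows: dict[int, list[float]] = {}
        for ln in lines[1:]:
            if ln == "END":
                break
            tag, rest = ln.split(None, 1)
            if tag == "MATCH":
                idx, *vals = rest.split()
                match_rows[int(idx)] = [float(v) for v in vals]
            elif tag == "TRANSITIONS":
                idx, *vals = rest.split()
                trans_rows[int(idx)] = [float(v) for v in vals]
            else:
                kv[tag] = rest
        M = int(kv["M"])
        emit = np.array([match_rows[k + 1] for k in range(M)])
        # renormalise 12-digit rounding so invariants hold exactly
        emit /= emit.sum(axis=1, keepdims=True)
        tr = np.array([trans_rows[k + 1] for k in range(M)])
        mrow = tr[:, 0:3] / tr[:, 0:3].sum(axis=1, keepdims=True)
        irow = tr[:, 3:5] / tr[:, 3:5].sum(axis=1, keepdims=True)
        drow = tr[:, 5:7] / tr[:, 5:7].sum(axis=1, keepdims=True)
        bm, bd = (float(v) for v in kv["BEGIN"].split())
        mu = lam = None
        if kv["CALIB"] != "none":
            mu, lam = (float(v) for v in kv["CALIB"].split())
        bg = np.array([float(v) for v in kv["BACKGROUND"].split()])
        return cls(
            name=kv["NAME"],
            match_emit=emit,
            bg=bg / bg.sum(),
            t_mm=mrow[:, 0], t_mi=mrow[:, 1], t_md=mrow[:, 2],
            t_im=irow[:, 0], t_ii=irow[:, 1],
            t_dm=drow[:, 0], t_dd=drow[:, 1],
            b_m=bm, b_d=bd,
            mean_length=float(kv["MEANLEN"]),
            mu=mu, lam=lam,
        )


@dataclass
class DomainHit:
    target_id: str
    model: str
    bits: float
    evalue: float
    env_start: int  # 0-based half-open on the target
    env_end: int
    model_start: int  # first/last match state on the best path, 1-based
    model_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.env_start < self.env_end):
            raise InvalidArgumentError("bad hit envelope")
        if self.evalue < 0:
            raise InvalidArgumentError("negative E-value")


# ---------------------------------------------------------------------------
# Building


def build_from_alignment(
    msa: MultipleAlignment,
    occupancy: float = 0.5,
    pseudocount_weight: float = 1.0,
    name: str = "model",
    bg: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with non-gap fraction >= ``occupancy`` become match states.
    Match emissions are (observed counts + pseudocount_weight * background)
    normalised; transitions are counted from each row's implied state path
    and Laplace-smoothed (+1). Insert residues before the first and after the
    last match column are flank, not model.
    """
    if msa.nrows == 0:
        raise InvalidArgumentError("empty alignment")
    if not (0 < occupancy <= 1):
        raise InvalidArgumentError("occupancy must be in (0, 1]")
    if bg is None:
        bg = BACKGROUND
    codes = msa.codes()
    nongap = codes != GAP_CODE
    frac = nongap.mean(axis=0)
    match_cols = np.where(frac >= occupancy)[0]
    if len(match_cols) == 0:
        raise ModelDegenerateError("no alignment column meets the occupancy threshold")
    M = len(match_cols)

    emit = np.tile(bg * pseudocount_weight, (M, 1))
    nobs = np.full(M, float(pseudocount_weight))
    for j, col in enumerate(match_cols):
        for r in range(msa.nrows):
            c = codes[r, col]
            if c == GAP_CODE:
                continue
            if c == 20:  # X: spread as background
                emit[j] += bg
            else:
                emit[j, c] += 1.0
            nobs[j] += 1.0
    degenerate = nobs <= 0
    emit[degenerate] = bg
    emit = emit / emit.sum(axis=1, keepdims=True)

    # transition counts with Laplace smoothing
    cmm = np.ones(M); cmi = np.ones(M); cmd = np.ones(M)
    cim = np.ones(M); cii = np.ones(M)
    cdm = np.ones(M); cdd = np.ones(M)
    cbm, cbd = 1.0, 1.0
    is_match = np.zeros(msa.length, dtype=bool)
    is_match[match_cols] = True
    state_of_col = np.full(msa.length, -1)
    state_of_col[match_cols] = np.arange(M)
    for r in range(msa.nrows):
        path: list[tuple[str, int]] = []  # (state kind, match index)
        k = -1
        for col in range(msa.length):
            if is_match[col]:
                k = state_of_col[col]
                path.append(("M" if nongap[r, col] else "D", k))
            elif nongap[r, col] and 0 <= k < M - 1:
                path.append(("I", k))
        if not path:
            continue
        first = path[0]
        if first[1] == 0:
            if first[0] == "M":
                cbm += 1
            elif first[0] == "D":
                cbd += 1
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 == "M":
                if s2 == "M":
                    cmm[k1] += 1
                elif s2 == "I":
                    cmi[k1] += 1
                else:
                    cmd[k1] += 1
            elif s1 == "I":
                if s2 == "M":
                    cim[k1] += 1
                else:
                    cii[k1] += 1
            else:
                if s2 == "M":
                    cdm[k1] += 1
                elif s2 == "D":
                    cdd[k1] += 1
                else:  # D -> I, rare; fold into D->M
                    cdm[k1] += 1
        if path[-1][0] == "M":
            cmm[path[-1][1]] += 1  # exit through the last visited match
    tm = np.stack([cmm, cmi, cmd], axis=1)
    tm = tm / tm.sum(axis=1, keepdims=True)
    ti = np.stack([cim, cii], axis=1)
    ti = ti / ti.sum(axis=1, keepdims=True)
    td = np.stack([cdm, cdd], axis=1)
    td = td / td.sum(axis=1, keepdims=True)
    bsum = cbm + cbd
    mean_len = float(np.mean([(codes[r] != GAP_CODE).sum() for r in range(msa.nrows)]))
    return ProfileHMM(
        name=name,
        match_emit=emit,
        bg=np.asarray(bg, dtype=float),
        t_mm=tm[:, 0], t_mi=tm[:, 1], t_md=tm[:, 2],
        t_im=ti[:, 0], t_ii=ti[:, 1],
        t_dm=td[:, 0], t_dd=td[:, 1],
        b_m=cbm / bsum, b_d=cbd / bsum,
        mean_length=mean_len,
    )


# ---------------------------------------------------------------------------
# Forward scoring


def _flank_bits(L: int) -> float:
    return math.log2(2.0 / (L + 2))


def forward_bits_many(hmm: ProfileHMM, seqs: Sequence[str], mode: str = "local") -> np.ndarray:
    """Forward bit scores for a batch of sequences (vectorised over the batch)."""
    if len(seqs) == 0:
        return np.empty(0)
    enc = [encode(s) for s in seqs]
    lengths = np.array([len(e) for e in enc])
    if (lengths < 1).any():
        raise InvalidArgumentError("sequences must be non-empty")
    B, Lmax, M = len(enc), int(lengths.max()), hmm.M
    X = np.full((B, Lmax), -1, dtype=int)
    for b, e in enumerate(enc):
        X[b, : len(e)] = e
    LO, lt, entry, exit_ = hmm._tables(mode)
    ltdd = lt["t_dd"]
    C = np.concatenate([[0.0], np.cumsum(ltdd[:-1])])  # C[k] = sum_{j<k} ltdd[j]

    FM = np.full((B, M), NEG)
    FI = np.full((B, M), NEG)
    FD = np.full((B, M), NEG)
    total = np.full(B, NEG)
    with np.errstate(invalid="ignore"):
        for i in range(Lmax):
            active = X[:, i] >= 0
            xi = np.where(active, X[:, i], 0)
            a = LO[:, xi].T  # (B, M)
            prevM, prevI, prevD = FM, FI, FD
            cand = np.full((B, M), NEG)
            cand[:, 1:] = np.logaddexp2(
                np.logaddexp2(prevM[:, :-1] + lt["t_mm"][:-1], prevI[:, :-1] + lt["t_im"][:-1]),
                prevD[:, :-1] + lt["t_dm"][:-1],
            )
            FMn = a + np.logaddexp2(cand, entry[None, :])
            FMn[~active] = NEG
            # delete scan (within position), via log-domain accumulate
            u = np.full((B, M), NEG)
            u[:, 1:] = FMn[:, :-1] + lt["t_md"][:-1]
            Lp = np.logaddexp2.accumulate(u - C[None, :], axis=1)
            FDn = Lp + C[None, :]
            FIn = np.logaddexp2(prevM + lt["t_mi"], prevI + lt["t_ii"])
            FIn[~active] = NEG
            FM, FI, FD = FMn, FIn, FDn
            contrib = _reduce_logaddexp2(FMn + exit_[None, :])
            total = np.where(active, np.logaddexp2(total, contrib), total)
    if mode == "local":
        total = total + np.array([_flank_bits(int(L)) for L in lengths])
    return total


def _reduce_logaddexp2(arr: np.ndarray) -> np.ndarray:
    out = arr[:, 0]
    for k in range(1, arr.shape[1]):
        out = np.logaddexp2(out, arr[:, k])
    return out


def forward_bits(hmm: ProfileHMM, seq: str, mode: str = "local") -> float:
    """log2 of P(seq | hmm, alignment mode) / P(seq | background)."""
    return float(forward_bits_many(hmm, [seq], mode=mode)[0])


# ---------------------------------------------------------------------------
# Viterbi


def viterbi_hit(hmm: ProfileHMM, seq: str, target_id: str = "seq", mode: str = "local") -> DomainHit:
    """Best-path local alignment and its envelope.

    Ties prefer match over delete over insert predecessors, and the leftmost
    placement on the target.
    """
    e = encode(seq)
    L, M = len(e), hmm.M
    if L < 1:
        raise InvalidArgumentError("empty sequence")
    LO, lt, entry, exit_ = hmm._tables(mode)
    VM = np.full((L, M), NEG)
    VI = np.full((L, M), NEG)
    VD = np.full((L, M), NEG)
    bpM = np.zeros((L, M), dtype=np.int8)  # 0 entry, 1 from M, 2 from I, 3 from D
    bpI = np.zeros((L, M), dtype=np.int8)  # 0 from M, 1 from I
    bpD = np.zeros((L, M), dtype=np.int8)  # 0 from M (same position), 1 from D
    prevM = np.full(M, NEG)
    prevI = np.full(M, NEG)
    prevD = np.full(M, NEG)
    for i in range(L):
        a = LO[:, e[i]]
        camm = np.full(M, NEG); cami = np.full(M, NEG); camd = np.full(M, NEG)
        camm[1:] = prevM[:-1] + lt["t_mm"][:-1]
        cami[1:] = prevI[:-1] + lt["t_im"][:-1]
        camd[1:] = prevD[:-1] + lt["t_dm"][:-1]
        stack = np.stack([entry, camm, cami, camd])  # order fixes ties: see below
        # tie preference: continuation-by-match > delete > insert > fresh entry
        order = np.array([1, 3, 2, 0])
        ordered = stack[order]
        pick = ordered.argmax(axis=0)
        VM[i] = a + ordered[pick, np.arange(M)]
        bpM[i] = order[pick]
        vi_m = prevM + lt["t_mi"]
        vi_i = prevI + lt["t_ii"]
        VI[i] = np.maximum(vi_m, vi_i)
        bpI[i] = (vi_i > vi_m).astype(np.int8)
        for k in range(1, M):
            from_m = VM[i, k - 1] + lt["t_md"][k - 1]
            from_d = VD[i, k - 1] + lt["t_dd"][k - 1]
            if from_d > from_m:
                VD[i, k] = from_d
                bpD[i, k] = 1
            else:
                VD[i, k] = from_m
        prevM, prevI, prevD = VM[i], VI[i], VD[i]

    end_scores = VM + exit_[None, :]
    best = NEG
    bi = bk = 0
    for i in range(L):
        for k in range(M):
            if end_scores[i, k] > best:
                best = end_scores[i, k]
                bi, bk = i, k
    if not np.isfinite(best):
        raise InvalidArgumentError("no finite alignment path")
    # traceback
    i, k, state = bi, bk, "M"
    emitted: list[int] = []
    model_states: list[int] = []
    while True:
        if state == "M":
            emitted.append(i)
            model_states.append(k)
            move = bpM[i, k]
            if move == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(move)]
            if state in ("M", "I"):
                i -= 1
            k -= 1
        elif state == "I":
            emitted.append(i)
            move = bpI[i, k]
            state = "I" if move else "M"
            i -= 1
        else:  # D
            if bpD[i, k]:
                k -= 1
            else:
                state = "M"
                k -= 1
    env_start, env_end = min(emitted), max(emitted) + 1
    bits = float(best + (_flank_bits(L) if mode == "local" else 0.0))
    ev = evalue(hmm, bits, db_size=1) if hmm.calibrated else math.inf
    return DomainHit(
        target_id=target_id,
        model=hmm.name,
        bits=bits,
        evalue=ev,
        env_start=env_start,
        env_end=env_end,
        model_start=min(model_states) + 1,
        model_end=max(model_states) + 1,
    )


# ---------------------------------------------------------------------------
# Calibration and E-values


def fit_gumbel_tail(scores: np.ndarray, censor_quantile: float = 0.75) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit, right-censored below a quantile.

    E-values are decided in the upper tail, where forward null scores follow
    the Gumbel law most closely; scores below the censoring threshold enter
    the likelihood only through the cdf. Returns (mu, lambda = 1/scale).
    """
    from scipy.optimize import minimize

    scores = np.asarray(scores, dtype=float)
    thr = float(np.quantile(scores, censor_quantile))
    upper = scores[scores >= thr]
    n_cens = int((scores < thr).sum())

    def nll(p):
        mu, lam = p
        if lam <= 0:
            return 1e9
        ll = np.sum(gumbel_r.logpdf(upper, loc=mu, scale=1.0 / lam))
        if n_cens:
            ll += n_cens * gumbel_r.logcdf(thr, loc=mu, scale=1.0 / lam)
        return -ll

    loc0, scale0 = gumbel_r.fit(scores)
    res = minimize(nll, [loc0, 1.0 / scale0], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9})
    mu, lam = res.x
    if not np.isfinite(mu) or lam <= 0:
        raise CalibrationError("Gumbel tail fit did not converge")
    return float(mu), float(lam)


def calibrate(
    hmm: ProfileHMM,
    n_random: int = 1000,
    len_dist: tuple[float, float] | None = None,
    seed: int = 0,
) -> ProfileHMM:
    """Fit a Gumbel to forward bit scores of random background sequences.

    Lengths are Normal(mean, sd) truncated at 30; the default length
    distribution is Normal(mean family length, 0.2 * mean). The fit is a
    tail-censored maximum-likelihood Gumbel (see :func:`fit_gumbel_tail`).
    """
    if n_random < 100:
        raise InvalidArgumentError("n_random must be >= 100")
    if len_dist is None:
        len_dist = (hmm.mean_length, 0.2 * hmm.mean_length)
    rng = np.random.default_rng(seed)
    lengths = np.maximum(np.round(rng.normal(len_dist[0], len_dist[1], n_random)), 30).astype(int)
    seqs = ["".join(AA[i] for i in rng.choice(20, size=L, p=hmm.bg)) for L in lengths]
    scores = forward_bits_many(hmm, seqs)
    if float(np.std(scores)) < 1e-9:
        raise CalibrationError("degenerate null score variance")
    mu, lam = fit_gumbel_tail(scores)
    return replace(hmm, mu=mu, lam=lam)


def evalue(hmm: ProfileHMM, bits: float, db_size: int) -> float:
    """E = db_size * P(S >= bits) under the fitted Gumbel."""
    if not hmm.calibrated:
        raise StateError(f"model {hmm.name!r} is not calibrated")
    sf = gumbel_r.sf(bits, loc=hmm.mu, scale=1.0 / hmm.lam)
    return float(db_size * sf)


def search(
    hmm: ProfileHMM,
    db: Sequence[ProteinRecord],
    evalue_max: Optional[float] = 1e-3,
) -> list[DomainHit]:
    """One best hit per target, sorted by ascending E-value.

    ``evalue_max=None`` applies no threshold (every target reported).
    ``db_size`` for E-values is the number of sequences in this invocation.
    """
    if not hmm.calibrated:
        raise StateError(f"model {hmm.name!r} must be calibrated before search")
    if len(db) == 0:
        return []
    bits = forward_bits_many(hmm, [r.sequence for r in db])
    db_size = len(db)
    hits = []
    for rec, b in zip(db, bits):
        ev = evalue(hmm, float(b), db_size)
        if evalue_max is not None and ev > evalue_max:
            continue
        vit = viterbi_hit(hmm, rec.sequence, target_id=rec.seq_id)
        hits.append(
            DomainHit(
                target_id=rec.seq_id,
                model=hmm.name,
                bits=float(b),
                evalue=ev,
                env_start=vit.env_start,
                env_end=vit.env_end,
                model_start=vit.model_start,
                model_end=vit.model_end,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


def hits_to_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    """Write a hit table TSV (1-based inclusive envelope coordinates)."""
    import pandas as pd

    df = pd.DataFrame(
        [
            (h.target_id, h.model, "%.6g" % h.bits, "%.6g" % h.evalue, h.env_start + 1, h.env_end)
            for h in hits
        ],
        columns=["target", "model", "bits", "evalue", "env_start", "env_end"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
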