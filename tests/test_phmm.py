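"""Profile HMMs: construction, scoring (vs exhaustive enumeration), calibration."""

import math

import numpy as np
import pytest
from scipy.stats import gumbel_r

from ftszprov.alphabet import AA, AA_INDEX, BACKGROUND
from ftszprov.exceptions import (
    CalibrationError,
    InvalidArgumentError,
    ModelDegenerateError,
    StateError,
)
from ftszprov.msa import MultipleAlignment
from ftszprov.phmm import (
    DomainHit,
    ProfileHMM,
    build_from_alignment,
    calibrate,
    evalue,
    fit_gumbel_tail,
    forward_bits,
    forward_bits_many,
    search,
    viterbi_hit,
)
from ftszprov.records import ProteinRecord

from conftest import noisy_family, random_seq


def make_hmm(emit, **kwargs):
    M = emit.shape[0]
    defaults = dict(
        t_mm=np.full(M, 0.9), t_mi=np.full(M, 0.05), t_md=np.full(M, 0.05),
        t_im=np.full(M, 0.8), t_ii=np.full(M, 0.2),
        t_dm=np.full(M, 0.8), t_dd=np.full(M, 0.2),
    )
    defaults.update(kwargs)
    return ProfileHMM("toy", emit, BACKGROUND.copy(), **defaults)


def random_hmm(rng, M):
    emit = rng.dirichlet(np.ones(20) * 0.5, size=M)
    tm = rng.dirichlet(np.ones(3), size=M)
    ti = rng.dirichlet(np.ones(2), size=M)
    td = rng.dirichlet(np.ones(2), size=M)
    return ProfileHMM(
        "rand", emit, BACKGROUND.copy(),
        t_mm=tm[:, 0], t_mi=tm[:, 1], t_md=tm[:, 2],
        t_im=ti[:, 0], t_ii=ti[:, 1], t_dm=td[:, 0], t_dd=td[:, 1],
    )


def enumerate_forward_local(h, seq):
    """Independent oracle: explicit sum over every local alignment path."""
    e = [AA.index(c) for c in seq]
    L, M = len(e), h.M
    w_pair = 2.0 / (M * (M + 1))
    total = 0.0

    def odds(k, i):
        return h.match_emit[k, e[i]] / h.bg[e[i]]

    def extend(state, k, i, w):
        nonlocal total
        if state == "M":
            total += w  # every match state is a legal exit
            if i + 1 < L:
                if k + 1 < M:
                    extend("M", k + 1, i + 1, w * h.t_mm[k] * odds(k + 1, i + 1))
                extend("I", k, i + 1, w * h.t_mi[k])
            if k + 1 < M:
                extend("D", k + 1, i, w * h.t_md[k])
        elif state == "I":
            if i + 1 < L and k + 1 < M:
                extend("M", k + 1, i + 1, w * h.t_im[k] * odds(k + 1, i + 1))
            if i + 1 < L:
                extend("I", k, i + 1, w * h.t_ii[k])
        else:
            if i + 1 < L and k + 1 < M:
                extend("M", k + 1, i + 1, w * h.t_dm[k] * odds(k + 1, i + 1))
            if k + 1 < M:
                extend("D", k + 1, i, w * h.t_dd[k])

    for i0 in range(L):
        for k0 in range(M):
            extend("M", k0, i0, w_pair * odds(k0, i0))
    return math.log2(total) + math.log2(2.0 / (L + 2))


# ---------------------------------------------------------------------------
# Building


def test_single_conserved_column_without_pseudocounts():
    msa = MultipleAlignment(list("abcd"), ["G", "G", "G", "G"])
    h = build_from_alignment(msa, pseudocount_weight=0.0)
    assert h.M == 1
    assert h.match_emit[0, AA_INDEX["G"]] == pytest.approx(1.0)


def test_occupancy_threshold_selects_match_columns():
    msa = MultipleAlignment(list("abcd"), ["GA-", "GAC", "G-C", "GA-"])
    assert build_from_alignment(msa, occupancy=0.6).M == 2


def test_pseudocount_arithmetic_matches_hand_computation():
    msa = MultipleAlignment(list("abc"), ["GA", "GA", "GC"])
    w = 0.1
    h = build_from_alignment(msa, pseudocount_weight=w)
    for col, counts in enumerate([{"G": 3}, {"A": 2, "C": 1}]):
        for a in AA:
            want = (counts.get(a, 0) + w * BACKGROUND[AA_INDEX[a]]) / (3 + w)
            assert h.match_emit[col, AA_INDEX[a]] == pytest.approx(want)


def test_all_gap_columns_give_degenerate_model():
    msa = MultipleAlignment(list("ab"), ["--", "--"])
    with pytest.raises(ModelDegenerateError):
        build_from_alignment(msa, occupancy=0.5)


# ---------------------------------------------------------------------------
# Forward


def test_glocal_single_state_bit_score():
    emit = np.zeros((1, 20))
    emit[0, AA_INDEX["A"]] = 1.0
    bg = np.full(20, 0.05)
    h = ProfileHMM(
        "one", emit, bg / bg.sum(),
        t_mm=np.ones(1), t_mi=np.zeros(1), t_md=np.zeros(1),
        t_im=np.ones(1), t_ii=np.zeros(1), t_dm=np.ones(1), t_dd=np.zeros(1),
        b_m=1.0, b_d=0.0,
    )
    assert forward_bits(h, "A", mode="glocal") == pytest.approx(math.log2(1 / 0.05))


def test_null_scores_have_negative_median(family_model):
    rng = np.random.default_rng(77)
    nulls = [random_seq(rng, 60) for _ in range(500)]
    assert np.median(forward_bits_many(family_model, nulls)) < 0


def test_forward_equals_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(100):
        h = random_hmm(rng, int(rng.integers(1, 4)))
        seq = random_seq(rng, int(rng.integers(1, 7)))
        assert abs(forward_bits(h, seq) - enumerate_forward_local(h, seq)) < 1e-9


def test_forward_at_least_viterbi():
    rng = np.random.default_rng(3)
    for _ in range(20):
        h = random_hmm(rng, int(rng.integers(2, 5)))
        seq = random_seq(rng, int(rng.integers(4, 10)))
        assert forward_bits(h, seq) >= viterbi_hit(h, seq).bits - 1e-9


# ---------------------------------------------------------------------------
# Viterbi


def test_consensus_envelope_covers_whole_consensus(family_model):
    cons = family_model.consensus()
    hit = viterbi_hit(family_model, cons)
    assert (hit.env_start, hit.env_end) == (0, len(cons))


def test_implanted_consensus_envelope_recovered():
    rng = np.random.default_rng(5)
    _, rows = noisy_family(rng, n=10, length=25)
    model = build_from_alignment(MultipleAlignment([f"s{i}" for i in range(10)], rows))
    core = model.consensus()
    hits = []
    for _ in range(50):
        flank = random_seq(rng, 100)
        seq = flank[:10] + core + flank[10:]
        hit = viterbi_hit(model, seq)
        hits.append((hit.env_start, hit.env_end))
    assert all(8 <= s <= 12 and 32 <= e <= 36 for s, e in hits)


def test_equal_scoring_placements_pick_leftmost():
    emit = np.zeros((1, 20))
    emit[0, AA_INDEX["W"]] = 1.0
    h = make_hmm(emit, t_mm=np.ones(1), t_mi=np.zeros(1), t_md=np.zeros(1))
    hit = viterbi_hit(h, "AWAWA")  # two identical placements at 1 and 3
    assert (hit.env_start, hit.env_end) == (1, 2)


# ---------------------------------------------------------------------------
# Calibration and E-values


def test_gumbel_parameter_recovery():
    rng = np.random.default_rng(11)
    data = gumbel_r.rvs(loc=5.0, scale=1.0 / 0.7, size=5000, random_state=rng)
    mu, lam = fit_gumbel_tail(data)
    assert abs(mu - 5.0) <= 0.1
    assert abs(lam - 0.7) <= 0.05


def test_calibration_self_consistency(family_model):
    rng = np.random.default_rng(13)
    lengths = np.maximum(np.round(rng.normal(60, 12, 1000)), 30).astype(int)
    held_out = [random_seq(rng, int(L)) for L in lengths]
    scores = forward_bits_many(family_model, held_out)
    n_hits = sum(evalue(family_model, float(s), 1000) <= 1.0 for s in scores)
    assert 0 <= n_hits <= 5


def test_evalue_linear_in_db_size(family_model):
    for bits in (-2.0, 0.0, 5.0, 20.0):
        assert evalue(family_model, bits, 2000) == pytest.approx(2 * evalue(family_model, bits, 1000))


def test_evalues_monotone_in_bits(family_model):
    evs = [evalue(family_model, b, 100) for b in np.linspace(-5, 40, 30)]
    assert all(a >= b for a, b in zip(evs, evs[1:]))


def test_degenerate_nulls_raise_calibration_error():
    emit = np.tile(BACKGROUND, (1, 1))
    h = make_hmm(emit)
    with pytest.raises((CalibrationError, InvalidArgumentError)):
        calibrate(h, n_random=99)


# ---------------------------------------------------------------------------
# Search


def test_search_recovers_family_and_rejects_outgroup(family_model, family_records):
    rng = np.random.default_rng(21)
    outgroup = [ProteinRecord(f"o{i}", random_seq(rng, 60), "g1") for i in range(10)]
    hits = search(family_model, family_records + outgroup, evalue_max=1e-3)
    got = {h.target_id for h in hits}
    assert {r.seq_id for r in family_records} <= got
    all_hits = search(family_model, family_records + outgroup, evalue_max=None)
    assert len(all_hits) == len(family_records) + len(outgroup)
    out_evs = [h.evalue for h in all_hits if h.target_id.startswith("o")]
    assert np.median(out_evs) > 1.0


def test_search_requires_calibration(family_msa):
    h = build_from_alignment(family_msa)
    with pytest.raises(StateError):
        search(h, [ProteinRecord("a", "ACDEF", "g")])


def test_hits_sorted_by_evalue(family_model, family_records):
    hits = search(family_model, family_records, evalue_max=None)
    assert [h.evalue for h in hits] == sorted(h.evalue for h in hits)


def test_domain_hit_validates_envelope():
    with pytest.raises(InvalidArgumentError):
        DomainHit("t", "m", 1.0, 0.1, env_start=5, env_end=5, model_start=1, model_end=1)


# ---------------------------------------------------------------------------
# Serialization


def test_text_serialization_roundtrip(family_model, tmp_path):
    path = tmp_path / "fam.hmm"
    family_model.to_text(path)
    back = ProfileHMM.from_text(path)
    assert back.name == family_model.name and back.M == family_model.M
    assert np.allclose(back.match_emit, family_model.match_emit, rtol=1e-11)
    assert back.mu == pytest.approx(family_model.mu, rel=1e-11)
    assert back.lam == pytest.approx(family_model.lam, rel=1e-11)
    seq = family_model.consensus()
    assert forward_bits(back, seq) == pytest.approx(forward_bits(family_model, seq), rel=1e-9)
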