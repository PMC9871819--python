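import numpy as np
import pytest

from ftszprov.alphabet import AA, BACKGROUND
from ftszprov.msa import MultipleAlignment
from ftszprov.records import ProteinRecord


def random_seq(rng, length):
    return "".join(AA[i] for i in rng.choice(20, size=length, p=BACKGROUND))


def noisy_family(rng, n=10, length=60, mutation=0.15):
    """Rows mutated from a common consensus (no indels, so pre-aligned)."""
    cons = rng.choice(20, size=length, p=BACKGROUND)
    rows = []
    for _ in range(n):
        aas = cons.copy()
        flip = rng.random(length) < mutation
        aas[flip] = rng.choice(20, size=int(flip.sum()), p=BACKGROUND)
        rows.append("".join(AA[i] for i in aas))
    return cons, rows


@pytest.fixture(scope="session")
def family_msa():
    rng = np.random.default_rng(101)
    _, rows = noisy_family(rng)
    return MultipleAlignment([f"s{i}" for i in range(len(rows))], rows)


@pytest.fixture(scope="session")
def family_model(family_msa):
    from ftszprov.phmm import build_from_alignment, calibrate

    return calibrate(build_from_alignment(family_msa, name="fam"), n_random=1000, seed=5)


@pytest.fixture(scope="session")
def family_records(family_msa):
    return [ProteinRecord(sid, row, "g0") for sid, row in family_msa]
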