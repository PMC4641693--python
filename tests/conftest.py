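import numpy as np
import pytest

import mirloc as m


@pytest.fixture(scope="session")
def vienna():
    return m.get_engine("vienna")


@pytest.fixture(scope="session")
def maxpair():
    return m.get_engine("maxpair")


@pytest.fixture()
def perfect_hairpin():
    """22-bp perfectly paired stem with a 4-nt loop."""
    arm5 = "GCAUCGGAUCGAUGCAUGCAGC"
    loop = "AAAA"
    from mirloc.datasets import reverse_complement

    seq = arm5 + loop + reverse_complement(arm5)
    db = "(" * 22 + "." * 4 + ")" * 22
    return m.PreMiRNA.from_dotbracket("perfect", seq, db, mfe=-30.0)


@pytest.fixture()
def toy_hairpin():
    """60-nt hairpin with one 1-nt bulge at position 10 (5' side).

    Pairs traced by hand: (i, 59-i) for i in 0..9, position 10 unpaired,
    (i, 60-i) for i in 11..24, terminal loop spanning positions 25..35.
    """
    pt = np.full(60, -1, dtype=np.int64)
    for i in range(0, 10):
        pt[i], pt[59 - i] = 59 - i, i
    for i in range(11, 25):
        pt[i], pt[60 - i] = 60 - i, i
    db = m.serialize_pairtable(pt)
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGU"), size=60))
    return m.PreMiRNA.from_dotbracket("toy", seq, db, mfe=-20.0)


@pytest.fixture(scope="session")
def small_corpus(vienna):
    """40 folded synthetic hairpins with truth annotations and a dataset."""
    hairpins = m.make_corpus(40, seed=42)
    premirnas, annotations = m.fold_corpus(hairpins, vienna)
    dataset = m.build_dataset(premirnas, annotations, rpns=5, engine=vienna, seed=42)
    return hairpins, premirnas, annotations, dataset


@pytest.fixture(scope="session")
def small_model(small_corpus):
    _, _, _, dataset = small_corpus
    return m.train(dataset, "rf", {"n_estimators": 100}, seed=7)
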