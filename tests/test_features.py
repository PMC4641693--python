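"""The 440-feature encoding: schema layout, block encoders, identities."""

import numpy as np
import pytest

import mirloc as m
from mirloc.errors import SchemaMismatch
from mirloc.features import (
    GROUP_CATEGORY,
    FeatureVector,
    entropy_context,
    nt_context,
    pairing_stats,
    seq_composition,
    seq_struct_combos,
)

EXPECTED_GROUP_SIZES = {
    "miRNALen": 1,
    "MNC": 4,
    "DNC": 16,
    "NT5p": 88,
    "NT3p": 88,
    "MFE": 1,
    "mlBulge": 1,
    "bpNum": 1,
    "dist2Loop": 1,
    "dist2Helix": 1,
    "numLoop": 1,
    "numBulges": 1,
    "perfectBP": 6,
    "numBP_Win": 3,
    "Bulges": 14,
    "posEntropy": 22,
    "monoSSq": 13,
    "diSS": 145,
    "triplets": 33,
}


class TestSchema:
    def test_total_and_group_sizes(self):
        assert len(m.SCHEMA) == 440
        assert m.SCHEMA.group_sizes() == EXPECTED_GROUP_SIZES

    def test_category_partition(self):
        assert m.SCHEMA.category_sizes() == {
            "sequence": 197,
            "structural": 30,
            "entropy": 22,
            "combination": 191,
        }
        assert set(GROUP_CATEGORY) == set(EXPECTED_GROUP_SIZES)

    def test_names_unique(self):
        assert len(set(m.SCHEMA.names)) == 440

    def test_wrong_width_rejected(self):
        with pytest.raises(SchemaMismatch):
            FeatureVector(values=np.zeros(439), sample_id="x")


class TestSeqComposition:
    def test_acgu(self):
        v = seq_composition("ACGU")
        assert v[0] == 4
        assert np.allclose(v[1:5], 0.25)  # MNC
        dnc = dict(zip([f"{a}{b}" for a in "ACGU" for b in "ACGU"], v[5:]))
        assert dnc["AC"] == dnc["CG"] == dnc["GU"] == pytest.approx(1 / 3)

    def test_homopolymer(self):
        v = seq_composition("AAAA")
        assert v[1] == 1.0 and v[2:5].sum() == 0
        assert v[5] == 1.0  # DNC AA

    def test_acaca_hand_count(self):
        v = seq_composition("ACACA")
        dnc = dict(zip([f"{a}{b}" for a in "ACGU" for b in "ACGU"], v[5:]))
        assert dnc["AC"] == pytest.approx(0.5)
        assert dnc["CA"] == pytest.approx(0.5)

    def test_mnc_sums_to_one_without_n(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(16, 31))))
            assert seq_composition(seq)[1:5].sum() == pytest.approx(1.0)


class TestNtContext:
    def test_one_hot_codes(self):
        pre = m.PreMiRNA.from_dotbracket("x", "ACGUACGUACGUACGU", "." * 16)
        v = nt_context(pre, 8)  # window positions 3..13
        # offset 0 (slot 5) holds an A: code 0001 in bit order U,G,C,A
        assert list(v[5 * 4 : 5 * 4 + 4]) == [0, 0, 0, 1]
        # offset +1 (slot 6) holds a C: 0010
        assert list(v[6 * 4 : 6 * 4 + 4]) == [0, 0, 1, 0]
        assert v.sum() == 11  # every in-window slot is one-hot

    def test_out_of_bounds_pads_zero(self):
        pre = m.PreMiRNA.from_dotbracket("x", "ACGUACGUACGU", "." * 12)
        v = nt_context(pre, 0)  # offsets -5..-1 fall before the sequence
        assert v[: 5 * 4].sum() == 0
        assert v.sum() == 6

    def test_n_encodes_all_zero(self):
        pre = m.PreMiRNA.from_dotbracket("x", "NNNNNNNNNNNN", "." * 12)
        assert nt_context(pre, 6).sum() == 0


def _fake_duplex(states):
    return m.Duplex(
        pre_ref="x",
        guide=(0, len(states)),
        star=(0, 0),
        arm="5p",
        guide_states=tuple(states),
        star_states=(),
    )


class TestPairingStats:
    def test_perfect_twenty(self):
        v = pairing_stats(_fake_duplex([True] * 20))
        # perfectBP_{5,10,20}: presence 1 at start 0
        assert list(v[:6]) == [1, 0, 1, 0, 1, 0]
        assert np.allclose(v[6:], [4.0, 6.0, 8.0])  # numBP_Win 4/6/8

    def test_alternating_window_density(self):
        states = [True, False] * 10
        v = pairing_stats(_fake_duplex(states))
        assert v[6] == pytest.approx(2.0)  # every 4-nt window holds 2 pairs

    def test_absent_run_sentinel(self):
        states = [True] * 8 + [False] + [True] * 8
        v = pairing_stats(_fake_duplex(states))
        assert list(v[:2]) == [1, 0]  # run of >=5 starting at 0
        assert list(v[2:4]) == [0, -1]  # no run of >=10
        assert list(v[4:6]) == [0, -1]

    def test_short_guide_single_window(self):
        v = pairing_stats(_fake_duplex([True, True, False]))
        assert v[6] == 2.0  # guide shorter than the window: one full-guide count


class TestEntropyContext:
    def test_degenerate_bppm_gives_zeros(self):
        pre = m.PreMiRNA.from_dotbracket("x", "GGGGGAAAACCCCC" * 2, "." * 28)
        with pytest.warns(UserWarning):
            v = entropy_context(pre, (6, 20))
        assert (v == 0).all()

    def test_uniform_position_reaches_log2_n(self):
        n = 30
        bppm = np.zeros((n, n))
        bppm[10, 15:25] = 0.1
        bppm[15:25, 10] = 0.1
        pre = m.PreMiRNA.from_dotbracket("x", "A" * n, "." * n, bppm=bppm)
        v = entropy_context(pre, (10, 26))
        assert v[5] == pytest.approx(np.log2(10))  # start anchor, offset 0

    def test_out_of_bounds_offsets_are_zero(self, vienna):
        pre = m.fold("GCGCUUCGAUCGGGAAACCCGAUCGAAGCGC", vienna)
        v = entropy_context(pre, (0, len(pre)))
        assert (v[:5] == 0).all()  # before position 0
        assert (v[11 + 6 :] == 0).all()  # beyond the 3' end


class TestSeqStructCombos:
    def test_monossq_direct_count(self):
        pre = m.PreMiRNA.from_dotbracket("x", "ACGUAAAAGU", "((......))")
        v = seq_struct_combos(pre, (0, 4))
        mono = dict(zip([f"{n}{s}" for n in "ACGU" for s in "()."], v[:12]))
        assert mono["A("] == mono["C("] == mono["G."] == mono["U."] == 1
        assert sum(mono.values()) == 4 and v[12] == 0

    def test_unpaired_a_between_paired_neighbors(self):
        pre = m.PreMiRNA.from_dotbracket("x", "GAGGAAACCC", "(.((...)))")
        v = seq_struct_combos(pre, (0, 3))
        tri = v[145 + 13 :]
        names = [f"{n}_{p}" for n in "ACGU" for p in
                 ["".join(t) for t in __import__("itertools").product("(.", repeat=3)]]
        counts = dict(zip(names, tri[:32]))
        assert counts["A_(.("] == 1  # the class written as an unpaired A between pairs
        assert tri.sum() == 1

    def test_n_routes_to_undefined(self):
        pre = m.PreMiRNA.from_dotbracket("x", "ANGUAAAAGU", "((......))")
        v = seq_struct_combos(pre, (0, 4))
        assert v[12] >= 1  # monoSSq undefined bucket
        assert v[13 + 144] >= 1  # diSS undefined bucket

    def test_counting_identities_on_corpus(self, small_corpus):
        hairpins, premirnas, _, _ = small_corpus
        for hp in hairpins[:8]:
            pre = premirnas[hp.id]
            gs, ge = hp.guide
            L = ge - gs
            v = seq_struct_combos(pre, hp.guide)
            assert v[:13].sum() == L
            assert v[13:158].sum() == L - 1
            assert v[158:].sum() == L - 2


class TestFeaturize:
    def test_length_and_purity(self, small_corpus, vienna):
        hairpins, premirnas, _, _ = small_corpus
        hp = hairpins[0]
        pre = premirnas[hp.id]
        dup = m.derive_duplex(pre, hp.guide)
        a = m.featurize(pre, dup, vienna)
        b = m.featurize(pre, dup, vienna)
        assert a.values.shape == (440,)
        assert np.array_equal(a.values, b.values)  # bit-identical

    def test_one_hot_blocks_are_binary(self, small_corpus, vienna):
        hairpins, premirnas, _, _ = small_corpus
        hp = hairpins[1]
        pre = premirnas[hp.id]
        fv = m.featurize(pre, m.derive_duplex(pre, hp.guide), vienna)
        nt_cols = [i for i, g in enumerate(m.SCHEMA.groups) if g in ("NT5p", "NT3p")]
        assert set(np.unique(fv.values[nt_cols])) <= {0.0, 1.0}

    def test_nt_anchors_swap_for_3p_guide(self, toy_hairpin):
        # guide on the 3' arm: the duplex's 5p strand is the star
        dup = m.derive_duplex(toy_hairpin, (38, 58))
        fv = m.featurize(toy_hairpin, dup)
        i0 = m.SCHEMA.index("NT5p_start_0_A")
        star_start_nt = toy_hairpin.sequence[dup.star[0]]
        expected = [0.0] * 4
        expected["UGCA".index(star_start_nt)] = 1.0
        block = list(fv.values[i0 - "UGCA".index("A") : i0 - "UGCA".index("A") + 4])
        assert block == expected

    def test_all_a_unpaired_guide_composition(self):
        pre = m.PreMiRNA.from_dotbracket(
            "x", "G" + "A" * 20 + "UUUCUUU" + "C" + "A" * 3, "(" + "." * 27 + ")" + "..."
        )
        dup = m.derive_duplex(pre, (0, 19))
        fv = m.featurize(pre, dup)
        mnc_a = fv.values[m.SCHEMA.index("MNC_A")]
        dnc_aa = fv.values[m.SCHEMA.index("DNC_AA")]
        assert mnc_a > 0.9 and dnc_aa > 0.9
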