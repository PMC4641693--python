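"""Corpus construction: positives, negative sampling, folds, generator."""

import logging

import numpy as np
import pytest

import mirloc as m
from mirloc.datasets import NEGATIVE_START_EXCLUSION, reverse_complement
from mirloc.errors import EmptyPositiveSet, InvalidParams, TooFewSamples
from mirloc.structure import UNPAIRED


class TestGenerateHairpin:
    def test_deterministic_for_fixed_seed(self):
        a = m.generate_hairpin(seed=123)
        b = m.generate_hairpin(seed=123)
        assert a.sequence == b.sequence and a.guide == b.guide

    def test_zero_bulge_rate_gives_exact_reverse_complement(self):
        hp = m.generate_hairpin(stem_len=30, loop_len=6, bulge_rate=0.0, seed=5)
        arm5, arm3 = hp.sequence[:30], hp.sequence[36:]
        assert arm3 == reverse_complement(arm5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"stem_len": 15, "guide_len": 16},  # stem shorter than guide
            {"guide_len": 15},  # guide below the candidate minimum
            {"loop_len": 2},
            {"bulge_rate": 0.5},
            {"bulge_rate": -0.1},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(InvalidParams):
            m.generate_hairpin(**kwargs)

    def test_guide_sits_in_five_prime_arm(self):
        for seed in range(10):
            hp = m.generate_hairpin(seed=seed)
            gs, ge = hp.guide
            assert 0 <= gs < ge <= hp.params["stem_len"]
            assert ge - gs == hp.params["guide_len"]

    def test_folding_recovers_planted_pairs(self, vienna):
        # With a 5% perturbation rate the thermodynamic fold should still
        # pair the large majority of planted guide positions.
        fractions = []
        for seed in range(20):
            hp = m.generate_hairpin(bulge_rate=0.05, seed=seed)
            pre = m.fold(hp.sequence, vienna, id=hp.id, with_bppm=False)
            gs, ge = hp.guide
            fractions.append(
                float((pre.pair_table[gs:ge] != UNPAIRED).mean())
            )
        assert np.mean(fractions) >= 0.8

    def test_perfect_hairpin_guide_fully_paired(self, vienna):
        hp = m.generate_hairpin(bulge_rate=0.0, seed=2)
        pre = m.fold(hp.sequence, vienna, id=hp.id, with_bppm=False)
        dup = m.derive_duplex(pre, hp.guide)
        el = m.structural_elements(pre, dup)
        assert el.bp_num == dup.guide_length


class TestBuildPositiveSet:
    def test_both_arms_give_one_duplex(self, small_corpus):
        _, premirnas, _, _ = small_corpus
        pre = next(iter(premirnas.values()))
        dup5 = m.derive_duplex(pre, (5, 26))
        star = dup5.star
        anns = [
            m.Annotation(premirna_id=pre.id, start=5, end=26),
            m.Annotation(premirna_id=pre.id, start=star[0], end=star[1]),
        ]
        samples = m.build_positive_set({pre.id: pre}, anns)
        assert len(samples) == 1
        assert samples[0].duplex.arm == "5p"

    def test_sequence_annotation_resolved(self, small_corpus):
        hairpins, premirnas, _, _ = small_corpus
        hp = hairpins[0]
        pre = premirnas[hp.id]
        seq = pre.sequence[hp.guide[0] : hp.guide[1]]
        samples = m.build_positive_set(
            {pre.id: pre}, [m.Annotation(premirna_id=pre.id, mature_seq=seq)]
        )
        assert samples[0].duplex.guide == hp.guide

    def test_absent_sequence_skipped_with_warning(self, small_corpus, caplog):
        _, premirnas, _, _ = small_corpus
        ids = list(premirnas)
        good = premirnas[ids[0]]
        anns = [
            m.Annotation(premirna_id=good.id, start=5, end=26),
            m.Annotation(premirna_id=ids[1], mature_seq="U" * 40),
        ]
        with caplog.at_level(logging.WARNING):
            samples = m.build_positive_set(premirnas, anns)
        assert len(samples) == 1
        assert any("not found" in r.message for r in caplog.records)

    def test_empty_raises(self, small_corpus):
        _, premirnas, _, _ = small_corpus
        pre = next(iter(premirnas.values()))
        with pytest.raises(EmptyPositiveSet):
            m.build_positive_set(
                {pre.id: pre},
                [m.Annotation(premirna_id=pre.id, mature_seq="ACGU" * 10)],
            )


class TestSampleNegatives:
    def test_length_and_exclusion_zone(self, small_corpus):
        hairpins, premirnas, _, _ = small_corpus
        hp = hairpins[2]
        pre = premirnas[hp.id]
        rng = np.random.default_rng(0)
        negs = m.sample_negatives(pre, hp.guide, 5, rng)
        assert len(negs) == 5
        L = hp.guide[1] - hp.guide[0]
        for s, e in negs:
            assert e - s == L
            assert abs(s - hp.guide[0]) > NEGATIVE_START_EXCLUSION
        assert len(set(negs)) == 5  # drawn without replacement

    def test_shortfall_logged_not_raised(self, caplog):
        pre = m.PreMiRNA.from_dotbracket(
            "tiny", "GGGGGGGGGGGGGGGGAAAACCCCCCCCCCCCCCCC", "(" * 16 + "...." + ")" * 16
        )
        rng = np.random.default_rng(1)
        with caplog.at_level(logging.WARNING):
            negs = m.sample_negatives(pre, (0, 30), 10, rng)
        assert len(negs) < 10
        assert any("negative segments" in r.message for r in caplog.records)

    def test_reproducible_with_seed(self, small_corpus):
        hairpins, premirnas, _, _ = small_corpus
        hp = hairpins[3]
        pre = premirnas[hp.id]
        a = m.sample_negatives(pre, hp.guide, 5, np.random.default_rng(9))
        b = m.sample_negatives(pre, hp.guide, 5, np.random.default_rng(9))
        assert a == b


class TestDataset:
    def test_rpns_respected(self, small_corpus):
        _, _, _, dataset = small_corpus
        assert dataset.n_neg == dataset.rpns * dataset.n_pos

    def test_no_duplicate_sample_ids(self, small_corpus):
        _, _, _, dataset = small_corpus
        assert len(set(dataset.sample_ids)) == len(dataset.sample_ids)

    def test_negative_never_equals_positive_interval(self, small_corpus):
        _, _, _, dataset = small_corpus
        pos_ids = {sid for sid, y in zip(dataset.sample_ids, dataset.y) if y == 1}
        neg_ids = {sid for sid, y in zip(dataset.sample_ids, dataset.y) if y == 0}
        assert not pos_ids & neg_ids

    def test_construction_reproducible(self, small_corpus, vienna):
        hairpins, premirnas, annotations, dataset = small_corpus
        again = m.build_dataset(premirnas, annotations, rpns=5, engine=vienna, seed=42)
        assert np.array_equal(dataset.X, again.X)
        assert dataset.sample_ids == again.sample_ids


def _singleton_dataset(n_pos: int, n_neg: int) -> m.LabeledDataset:
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    return m.LabeledDataset(
        X=np.zeros((n, m.N_FEATURES)),
        y=y,
        sample_ids=[f"s{i}" for i in range(n)],
        groups=[f"g{i}" for i in range(n)],  # each sample its own pre-miRNA
        rpns=1,
        seed=0,
    )


class TestSplitFolds:
    def test_even_split(self):
        folds = m.split_folds(_singleton_dataset(50, 50), 10, seed=0)
        assert sorted(len(f) for f in folds) == [10] * 10

    def test_uneven_split_within_one(self):
        folds = m.split_folds(_singleton_dataset(51, 50), 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes[:9] == [10] * 9 and sizes[9] == 11

    def test_stratified_within_one_per_class(self):
        ds = _singleton_dataset(23, 77)
        folds = m.split_folds(ds, 10, seed=1)
        pos_counts = [int(ds.y[f].sum()) for f in folds]
        neg_counts = [len(f) - p for f, p in zip(folds, pos_counts)]
        assert max(pos_counts) - min(pos_counts) <= 1
        assert max(neg_counts) - min(neg_counts) <= 1

    def test_union_and_disjointness(self, small_corpus):
        _, _, _, dataset = small_corpus
        folds = m.split_folds(dataset, 5, seed=3)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(dataset.y)
        assert len(np.unique(all_idx)) == len(all_idx)

    def test_groups_never_straddle_folds(self, small_corpus):
        _, _, _, dataset = small_corpus
        folds = m.split_folds(dataset, 5, seed=3)
        seen: dict[str, int] = {}
        for f, idx in enumerate(folds):
            for i in idx:
                g = dataset.groups[i]
                assert seen.setdefault(g, f) == f

    def test_too_few_samples(self):
        with pytest.raises(TooFewSamples):
            m.split_folds(_singleton_dataset(3, 3), 10, seed=0)
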