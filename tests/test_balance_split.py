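"""Class-balanced augmentation, stratified splitting, leakage auditing."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy.special import comb

from cogtext.balance import (
    ORIGIN_LEVEL,
    SAMPLE_LEVEL,
    SUBJECT_LEVEL,
    AugmentationPlan,
    SplitSpec,
    balance_augment,
    leakage_audit,
    make_splits,
)
from cogtext.corpus import (
    AugmentationTag,
    CognitiveLabel,
    Subject,
    TaskId,
    TranscriptSample,
    make_original,
)
from cogtext.eda import EdaParams


def _toy_corpus(n_mci=2, n_hc=6):
    samples = []
    for i in range(n_mci):
        subject = Subject(f"M{i}", mmse=25, age=74, sex="F")
        samples.append(make_original(subject, TaskId.EP1A, "it was a sad day then"))
    for i in range(n_hc):
        subject = Subject(f"H{i}", mmse=29, age=72, sex="M")
        samples.append(make_original(subject, TaskId.EP1A, "the garden walk was long"))
    return samples


class TestBalanceAugment:
    def test_toy_count_arithmetic(self, toy_lexicon, toy_stopwords):
        corpus = _toy_corpus(n_mci=2, n_hc=6)
        plan = AugmentationPlan(multiplier_mci=3, multiplier_hc=1)
        out = balance_augment(corpus, plan, toy_lexicon, toy_stopwords, seed=0)
        assert len(out) == 2 * 3 + 6 * 1
        counts = Counter(s.label for s in out)
        assert counts[CognitiveLabel.MCI] == 6
        assert counts[CognitiveLabel.HEALTHY] == 6

    def test_unit_multipliers_identity(self, toy_lexicon, toy_stopwords):
        corpus = _toy_corpus()
        plan = AugmentationPlan(multiplier_mci=1, multiplier_hc=1)
        assert balance_augment(corpus, plan, toy_lexicon, toy_stopwords) == corpus

    def test_default_corpus_balances_exactly(
        self, default_corpus, fixture_lexicon, fixture_stopwords
    ):
        out = balance_augment(
            default_corpus, AugmentationPlan(), fixture_lexicon, fixture_stopwords,
            seed=1,
        )
        assert len(out) == 10_800
        counts = Counter(s.label for s in out)
        assert counts[CognitiveLabel.MCI] == 5400
        assert counts[CognitiveLabel.HEALTHY] == 5400
        originals = [s for s in out if s.augmentation_tag is AugmentationTag.ORIGINAL]
        assert len(originals) == 720

    def test_excluded_range_rejected(self, toy_lexicon, toy_stopwords):
        subject = Subject("D0", mmse=20, age=80, sex="M")
        corpus = [make_original(subject, TaskId.EP1A, "x y z")]
        with pytest.raises(ValueError, match="excluded"):
            balance_augment(corpus, AugmentationPlan(), toy_lexicon, toy_stopwords)

    def test_output_size_formula(self, toy_lexicon, toy_stopwords):
        corpus = _toy_corpus(n_mci=3, n_hc=5)
        plan = AugmentationPlan(multiplier_mci=7, multiplier_hc=2)
        out = balance_augment(corpus, plan, toy_lexicon, toy_stopwords, seed=0)
        assert len(out) == 3 * 7 + 5 * 2


def _augmented_toy(n_mci_origins=5, n_hc_origins=10, m_mci=10, m_hc=5, seed=0):
    corpus = _toy_corpus(n_mci=n_mci_origins, n_hc=n_hc_origins)
    from cogtext.synthetic import generate_fixture_lexicon

    lex = generate_fixture_lexicon(
        sorted({t for s in corpus for t in s.text.split()}), 2, seed=seed
    )
    plan = AugmentationPlan(
        multiplier_mci=m_mci, multiplier_hc=m_hc, eda=EdaParams(seed=seed)
    )
    from cogtext.lexicon import EMPTY_STOPWORDS

    return balance_augment(corpus, plan, lex, EMPTY_STOPWORDS, seed=seed)


class TestMakeSplits:
    def test_sizes_and_partition(
        self, default_corpus, fixture_lexicon, fixture_stopwords
    ):
        dataset = balance_augment(
            default_corpus, AugmentationPlan(), fixture_lexicon, fixture_stopwords,
            seed=2,
        )
        spec = SplitSpec(n_repeats=3, mode=SAMPLE_LEVEL, seed=0)
        splits = make_splits(dataset, spec)
        assert len(splits) == 3
        n = len(dataset)
        for triple in splits:
            assert len(triple.test) == round(0.2 * n) == 2160
            assert len(triple.validation) == round(0.1 * n)
            combined = sorted(triple.train + triple.validation + triple.test)
            assert combined == list(range(n))

    def test_sample_level_stratification_within_one(self):
        dataset = _augmented_toy()
        spec = SplitSpec(n_repeats=5, mode=SAMPLE_LEVEL, seed=1)
        global_mci = sum(1 for s in dataset if s.label is CognitiveLabel.MCI) / len(dataset)
        for triple in make_splits(dataset, spec):
            for part in (triple.train, triple.validation, triple.test):
                mci = sum(1 for i in part if dataset[i].label is CognitiveLabel.MCI)
                assert abs(mci - global_mci * len(part)) <= 1

    def test_origin_level_keeps_origins_together(self):
        dataset = _augmented_toy()
        spec = SplitSpec(n_repeats=4, mode=ORIGIN_LEVEL, seed=2)
        for triple in make_splits(dataset, spec):
            sides = {}
            for name, part in (("tr", triple.train), ("va", triple.validation), ("te", triple.test)):
                for i in part:
                    sides.setdefault(dataset[i].origin_id, set()).add(name)
            assert all(len(v) == 1 for v in sides.values())

    def test_repeats_are_distinct(self):
        dataset = _augmented_toy()
        splits = make_splits(dataset, SplitSpec(n_repeats=10, mode=SAMPLE_LEVEL, seed=3))
        assert len(splits) == 10
        assert len({triple.test for triple in splits}) > 1

    def test_deterministic_for_fixed_seed(self):
        dataset = _augmented_toy()
        spec = SplitSpec(n_repeats=2, mode=SUBJECT_LEVEL, seed=4)
        assert make_splits(dataset, spec) == make_splits(dataset, spec)

    def test_infeasible_group_stratification_raises(self):
        # one origin's block alone exceeds the per-class test target
        dataset = _augmented_toy(n_mci_origins=1, n_hc_origins=1, m_mci=50, m_hc=50)
        spec = SplitSpec(test_fraction=0.2, mode=ORIGIN_LEVEL, n_repeats=1, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            make_splits(dataset, spec)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_splits([], SplitSpec())


class TestLeakageAudit:
    def test_origin_level_zero_overlap(self):
        dataset = _augmented_toy()
        for triple in make_splits(dataset, SplitSpec(n_repeats=3, mode=ORIGIN_LEVEL, seed=5)):
            report = leakage_audit(triple, dataset)
            assert report.origin_overlap_fraction == 0.0

    def test_subject_level_zero_overlap(self):
        dataset = _augmented_toy()
        for triple in make_splits(dataset, SplitSpec(n_repeats=3, mode=SUBJECT_LEVEL, seed=6)):
            report = leakage_audit(triple, dataset)
            assert report.subject_overlap_fraction == 0.0
            assert report.origin_overlap_fraction == 0.0

    def test_sample_level_overlap_matches_enumeration_oracle(self):
        """Expected origin-overlap fraction of a stratified sample-level split,
        computed by direct enumeration of the hypergeometric allocation of one
        origin's copies over (test, validation, train), vs the empirical mean
        over repeated splits of a 12-origin single-class toy dataset."""
        k, n_origins = 10, 12
        corpus = []
        for i in range(n_origins):
            subject = Subject(f"S{i}", mmse=29, age=70, sex="M")
            corpus.append(make_original(subject, TaskId.EP1A, "a b c d e f"))
        from cogtext.lexicon import EMPTY_STOPWORDS
        from cogtext.synthetic import generate_fixture_lexicon

        lex = generate_fixture_lexicon(["a", "b", "c", "d", "e", "f"], 2, seed=0)
        plan = AugmentationPlan(multiplier_mci=k, multiplier_hc=k)
        dataset = balance_augment(corpus, plan, lex, EMPTY_STOPWORDS, seed=0)
        n = len(dataset)
        n_test, n_val = round(0.2 * n), round(0.1 * n)
        n_train = n - n_test - n_val

        # oracle: E[#test copies of an origin that also has >=1 train copy]
        expected_overlap = 0.0
        for j_test in range(k + 1):
            for j_val in range(k - j_test + 1):
                j_train = k - j_test - j_val
                p = (
                    comb(n_test, j_test)
                    * comb(n_val, j_val)
                    * comb(n_train, j_train)
                    / comb(n, k)
                )
                if j_train >= 1:
                    expected_overlap += p * j_test
        expected_fraction = n_origins * expected_overlap / n_test

        spec = SplitSpec(n_repeats=400, mode=SAMPLE_LEVEL, seed=7)
        fractions = [
            leakage_audit(t, dataset).origin_overlap_fraction
            for t in make_splits(dataset, spec)
        ]
        assert abs(np.mean(fractions) - expected_fraction) < 0.01
        assert expected_fraction > 0.9  # >=10 copies per origin, 20% test

    def test_default_augmented_dataset_overlap_above_090(
        self, default_corpus, fixture_lexicon, fixture_stopwords
    ):
        dataset = balance_augment(
            default_corpus, AugmentationPlan(), fixture_lexicon, fixture_stopwords,
            seed=3,
        )
        triple = make_splits(dataset, SplitSpec(n_repeats=1, mode=SAMPLE_LEVEL, seed=8))[0]
        report = leakage_audit(triple, dataset)
        assert report.origin_overlap_fraction > 0.9
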