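"""EDA operators: examples, edit bounds, conservation and determinism."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogtext.corpus import AugmentationTag, CognitiveLabel, TaskId, TranscriptSample
from cogtext.eda import (
    CYCLE,
    DUPLICATE,
    EdaParams,
    OPERATOR_CYCLE,
    SYNONYM,
    UNIFORM_RANDOM,
    augment_sentence,
    n_changes,
    random_deletion,
    random_insertion,
    random_swap,
    synonym_replacement,
)
from cogtext.lexicon import EMPTY_STOPWORDS, StopwordList, SynonymLexicon

tokens_strategy = st.lists(
    st.sampled_from(["the", "dog", "walk", "cat", "park", "ran", "a"]),
    min_size=1,
    max_size=30,
)


class TestNChanges:
    @pytest.mark.parametrize(
        "length,alpha,expected",
        [(20, 0.05, 1), (10, 0.05, 1), (100, 0.1, 10), (0, 0.5, 0), (1, 0.0, 1)],
    )
    def test_examples(self, length, alpha, expected):
        assert n_changes(length, alpha) == expected

    @given(length=st.integers(1, 1000), alpha=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_at_least_one_for_nonempty(self, length, alpha):
        assert 1 <= n_changes(length, alpha) <= max(1, length)


class TestSynonymReplacement:
    def test_only_eligible_token_replaced(self, rng):
        lex = SynonymLexicon.from_dict({"dog": {"puppy"}})
        stops = StopwordList(words=frozenset({"the"}))
        out = synonym_replacement(["the", "dog", "runs"], 1, lex, stops, rng)
        assert out == ["the", "puppy", "runs"]

    def test_n_zero_is_identity(self, rng, toy_lexicon, toy_stopwords):
        tokens = ["the", "dog", "walk"]
        assert synonym_replacement(tokens, 0, toy_lexicon, toy_stopwords, rng) == tokens

    def test_all_stopwords_unchanged(self, rng, toy_lexicon):
        stops = StopwordList(words=frozenset({"dog", "walk"}))
        tokens = ["dog", "walk"]
        assert synonym_replacement(tokens, 5, toy_lexicon, stops, rng) == tokens

    @given(tokens=tokens_strategy, n=st.integers(0, 10))
    @settings(max_examples=100, derandomize=True)
    def test_edit_bound_and_stopword_protection(self, tokens, n):
        rng = np.random.default_rng(0)
        lex = SynonymLexicon.from_dict(
            {w: {w + "_s1", w + "_s2"} for w in set(tokens)}
        )
        stops = StopwordList(words=frozenset({"the", "a"}))
        out = synonym_replacement(tokens, n, lex, stops, rng)
        assert len(out) == len(tokens)
        changed = [i for i, (x, y) in enumerate(zip(tokens, out)) if x != y]
        assert len(changed) <= n
        for i in changed:
            assert tokens[i] not in stops
            assert out[i] in lex.synonyms(tokens[i])


class TestRandomInsertion:
    def test_single_token_duplicate(self, rng, toy_lexicon):
        out = random_insertion(["dog"], 1, toy_lexicon, EMPTY_STOPWORDS, rng)
        assert out == ["dog", "dog"]

    def test_n_zero_identity(self, rng, toy_lexicon):
        assert random_insertion(["a", "b"], 0, toy_lexicon, EMPTY_STOPWORDS, rng) == ["a", "b"]

    def test_stopword_never_inserted(self, rng, toy_lexicon):
        stops = StopwordList(words=frozenset({"the"}))
        out = random_insertion(["the", "dog"], 2, toy_lexicon, stops, rng)
        assert len(out) == 4
        inserted = list((Counter(out) - Counter(["the", "dog"])).elements())
        assert inserted == ["dog", "dog"]

    def test_no_eligible_source_returns_input(self, rng, toy_lexicon):
        stops = StopwordList(words=frozenset({"the"}))
        assert random_insertion(["the"], 3, toy_lexicon, stops, rng) == ["the"]

    def test_synonym_mode_inserts_synonyms(self, rng):
        lex = SynonymLexicon.from_dict({"dog": {"puppy"}})
        out = random_insertion(["dog"], 2, lex, EMPTY_STOPWORDS, rng, mode=SYNONYM)
        assert len(out) == 3
        assert Counter(out)["puppy"] == 2

    @given(tokens=tokens_strategy, n=st.integers(0, 8))
    @settings(max_examples=100, derandomize=True)
    def test_duplicate_mode_grows_multiset(self, tokens, n):
        rng = np.random.default_rng(1)
        lex = SynonymLexicon.from_dict({})
        out = random_insertion(tokens, n, lex, EMPTY_STOPWORDS, rng, mode=DUPLICATE)
        assert len(out) == len(tokens) + n
        assert not Counter(tokens) - Counter(out)  # superset of input multiset


class TestRandomSwap:
    def test_two_tokens_swap(self, rng):
        assert random_swap(["a", "b"], 1, rng) == ["b", "a"]

    def test_degenerate_lengths(self, rng):
        assert random_swap(["a"], 5, rng) == ["a"]
        assert random_swap([], 5, rng) == []

    @given(tokens=tokens_strategy, n=st.integers(0, 10))
    @settings(max_examples=100, derandomize=True)
    def test_preserves_multiset(self, tokens, n):
        rng = np.random.default_rng(2)
        assert Counter(random_swap(tokens, n, rng)) == Counter(tokens)


class TestRandomDeletion:
    def test_p_zero_identity(self, rng):
        assert random_deletion(["a", "b", "c"], 0.0, rng) == ["a", "b", "c"]

    def test_p_one_never_empty(self, rng):
        out = random_deletion(["a", "b", "c"], 1.0, rng)
        assert len(out) == 1
        assert out[0] in {"a", "b", "c"}

    def test_mean_surviving_length_matches_binomial_expectation(self):
        """Oracle: with the never-empty rule, E[len] = n(1-p) + P(all deleted)
        * (1 - 0); at n=20, p=0.3 the correction term p^20 is negligible, so
        E[len] ~= 14 with s.e. of the mean sqrt(n p (1-p)) / sqrt(trials)."""
        n_tok, p, trials = 20, 0.3, 10_000
        expected = n_tok * (1 - p) + (p ** n_tok) * 1.0
        rng = np.random.default_rng(42)
        tokens = [f"t{i}" for i in range(n_tok)]
        lengths = [len(random_deletion(tokens, p, rng)) for _ in range(trials)]
        se = np.sqrt(n_tok * p * (1 - p)) / np.sqrt(trials)
        assert abs(np.mean(lengths) - expected) < 3 * se

    @given(tokens=tokens_strategy, p=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_output_submultiset_and_nonempty(self, tokens, p):
        rng = np.random.default_rng(3)
        out = random_deletion(tokens, p, rng)
        assert len(out) >= 1
        assert not Counter(out) - Counter(tokens)


def _original(text="the dog and the cat walk in the park today"):
    return TranscriptSample(
        sample_id="s1",
        subject_id="sub1",
        task=TaskId.PICTURE,
        label=CognitiveLabel.MCI,
        text=text,
        origin_id="s1",
    )


class TestAugmentSentence:
    def test_n_out_one_returns_only_original(self, toy_lexicon):
        sample = _original()
        out = augment_sentence(sample, EdaParams(), toy_lexicon, n_out=1)
        assert out == [sample]

    def test_cycle_policy_tags(self, toy_lexicon):
        out = augment_sentence(_original(), EdaParams(), toy_lexicon, n_out=30)
        assert len(out) == 30
        assert out[0].augmentation_tag is AugmentationTag.ORIGINAL
        expected = [OPERATOR_CYCLE[k % 4] for k in range(29)]
        assert [s.augmentation_tag for s in out[1:]] == expected

    def test_provenance_conserved(self, toy_lexicon, toy_stopwords):
        sample = _original()
        out = augment_sentence(
            sample, EdaParams(), toy_lexicon, toy_stopwords, n_out=12
        )
        for s in out:
            assert s.label is sample.label
            assert s.task is sample.task
            assert s.subject_id == sample.subject_id
            assert s.origin_id == sample.sample_id

    def test_deterministic_under_fixed_seed(self, toy_lexicon):
        a = augment_sentence(_original(), EdaParams(seed=9), toy_lexicon, n_out=20)
        b = augment_sentence(_original(), EdaParams(seed=9), toy_lexicon, n_out=20)
        assert a == b

    def test_distinct_seeds_differ(self, toy_lexicon):
        a = augment_sentence(_original(), EdaParams(seed=1), toy_lexicon, n_out=20)
        b = augment_sentence(_original(), EdaParams(seed=2), toy_lexicon, n_out=20)
        assert [s.text for s in a] != [s.text for s in b]

    def test_rejects_already_augmented_input(self, toy_lexicon):
        derived = _original().derived("s1#a1.SR", "x", AugmentationTag.SR)
        with pytest.raises(ValueError):
            augment_sentence(derived, EdaParams(), toy_lexicon, n_out=2)

    def test_uniform_random_policy_uses_operator_tags(self, toy_lexicon):
        out = augment_sentence(
            _original(),
            EdaParams(operator_policy=UNIFORM_RANDOM, seed=5),
            toy_lexicon,
            n_out=40,
        )
        tags = {s.augmentation_tag for s in out[1:]}
        assert tags <= set(OPERATOR_CYCLE)
        assert len(tags) > 1

    def test_fixed_policy(self, toy_lexicon):
        out = augment_sentence(
            _original(),
            EdaParams(operator_policy="fixed:RS"),
            toy_lexicon,
            n_out=5,
        )
        assert all(s.augmentation_tag is AugmentationTag.RS for s in out[1:])
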