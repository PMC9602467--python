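"""Synthetic corpus generator emulating an imbalanced HC/MCI speech study.

The real corpus this package targets is private, so every downstream
stage is exercised on generated data with the same structure: 45 healthy
controls and 15 subjects with mild cognitive impairment, 12 speaking
tasks each (720 transcripts), MMSE scores drawn per group (29.3 +/- 0.7
healthy, 25.9 +/- 1.0 MCI) and clamped into the label-consistent band.

The text itself is a whitespace-joinable token stream, not grammatical
language: the pipeline under test operates on token sequences, so the
goal is controllable statistical structure, not linguistic realism.
Group differences are injected through three knobs with support in the
clinical-linguistics literature:

* pronoun rate — impaired speakers substitute pronouns for content words
  more often;
* type-token ratio (TTR) — lexical diversity drops with impairment, here
  realised by drawing content words from a smaller effective vocabulary;
* event coverage — on the picture/animation tasks (which have a known
  set of key events) impaired speakers mention fewer of them.

Episodic-task templates carry topic vocabulary only (no key events),
reflecting that free personal recall differs from subject to subject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import (
    CognitiveLabel,
    Subject,
    TaskId,
    TranscriptSample,
    assign_label,
    make_original,
)
from .lexicon import StopwordList, SynonymLexicon

PRONOUNS: tuple[str, ...] = ("it", "that", "this", "he", "she", "they", "there", "one")
FILLERS: tuple[str, ...] = ("um", "uh", "well", "so", "like")

#: generic content words shared across all task templates
SHARED_VOCABULARY: tuple[str, ...] = (
    "today", "yesterday", "morning", "evening", "home", "family", "friend",
    "garden", "walk", "town", "shop", "dinner", "weather", "remember",
    "happened", "together", "went", "came", "talked", "watched", "felt",
    "really", "very", "long", "small", "large", "quiet", "busy", "nice", "old",
)

_MMSE_BANDS: dict[CognitiveLabel, tuple[int, int]] = {
    CognitiveLabel.HEALTHY: (28, 30),
    CognitiveLabel.MCI: (23, 27),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure: group sizes and per-group MMSE/age distributions."""

    n_healthy: int = 45
    n_mci: int = 15
    mmse_mean_hc: float = 29.3
    mmse_sd_hc: float = 0.7
    mmse_mean_mci: float = 25.9
    mmse_sd_mci: float = 1.0
    age_mean: float = 73.7
    age_sd: float = 4.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_mci < 0:
            raise ValueError("group counts must be non-negative")


@dataclass(frozen=True)
class LinguisticEffectSpec:
    """Group-dependent lexical effect sizes (all rates in [0,1]).

    Defaults encode moderate HC/MCI differences: a higher pronoun rate,
    lower lexical diversity and lower key-event coverage on the MCI side.
    ``disjoint_group_vocab=True`` gives the two groups disjoint halves of
    each topic vocabulary — the maximum-separation setting used to sanity
    check that a classifier can exploit the injected signal.
    """

    pronoun_rate_hc: float = 0.05
    pronoun_rate_mci: float = 0.18
    ttr_hc: float = 0.75
    ttr_mci: float = 0.45
    event_coverage_hc: float = 0.95
    event_coverage_mci: float = 0.55
    mean_len: float = 60.0
    len_sd: float = 12.0
    filler_rate: float = 0.06
    disjoint_group_vocab: bool = False

    def __post_init__(self) -> None:
        for name in (
            "pronoun_rate_hc", "pronoun_rate_mci", "ttr_hc", "ttr_mci",
            "event_coverage_hc", "event_coverage_mci", "filler_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.mean_len <= 0:
            raise ValueError("mean_len must be positive")

    def pronoun_rate(self, label: CognitiveLabel) -> float:
        return self.pronoun_rate_hc if label is CognitiveLabel.HEALTHY else self.pronoun_rate_mci

    def ttr(self, label: CognitiveLabel) -> float:
        return self.ttr_hc if label is CognitiveLabel.HEALTHY else self.ttr_mci

    def event_coverage(self, label: CognitiveLabel) -> float:
        return (
            self.event_coverage_hc
            if label is CognitiveLabel.HEALTHY
            else self.event_coverage_mci
        )

    @classmethod
    def no_group_difference(cls, **kwargs) -> "LinguisticEffectSpec":
        """Null setting: both groups share the HC-side parameters."""
        base = cls(**kwargs)
        return dataclasses.replace(
            base,
            pronoun_rate_mci=base.pronoun_rate_hc,
            ttr_mci=base.ttr_hc,
            event_coverage_mci=base.event_coverage_hc,
            disjoint_group_vocab=False,
        )


@dataclass(frozen=True)
class TaskTemplate:
    """Per-task generation material: topic words plus ordered key events."""

    task: TaskId
    topic_vocabulary: tuple[str, ...]
    key_events: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.task in (TaskId.PICTURE, TaskId.ANIMATION) and len(self.key_events) < 4:
            raise ValueError(
                f"{self.task.value} template needs >= 4 key events, "
                f"got {len(self.key_events)}"
            )


_PICTURE_EVENTS: tuple[tuple[str, ...], ...] = (
    ("mother", "washing", "dishes"),
    ("boy", "reaching", "cookie", "jar"),
    ("stool", "tipping", "over"),
    ("water", "overflowing", "sink"),
)

_ANIMATION_EVENTS: tuple[tuple[str, ...], ...] = (
    ("blue", "dog", "red", "dog", "walking"),
    ("big", "creature", "tormenting", "small", "creature"),
    ("blue", "dog", "surprises", "big", "creature"),
    ("small", "creature", "thanks", "dogs", "rides", "away"),
)

_EPISODIC_THEMES: dict[TaskId, str] = {
    TaskId.EP1A: "sad",
    TaskId.EP1B: "sadwhen",
    TaskId.EP2A: "anxious",
    TaskId.EP3A: "angry",
    TaskId.EP4A: "disgust",
    TaskId.EP5A: "surprise",
    TaskId.EP6A: "pleasant",
    TaskId.EP6B: "pleasantwhen",
    TaskId.EP7A: "admire",
    TaskId.EP8A: "passion",
}


def default_templates(topic_words_per_task: int = 24) -> dict[TaskId, TaskTemplate]:
    """One template per task: themed topic tokens, key events where defined."""
    templates: dict[TaskId, TaskTemplate] = {}
    for task in TaskId:
        if task is TaskId.PICTURE:
            theme, events = "kitchen", _PICTURE_EVENTS
        elif task is TaskId.ANIMATION:
            theme, events = "dogs", _ANIMATION_EVENTS
        else:
            theme, events = _EPISODIC_THEMES[task], ()
        vocab = tuple(f"{theme}{i:02d}" for i in range(topic_words_per_task))
        templates[task] = TaskTemplate(
            task=task, topic_vocabulary=vocab, key_events=events
        )
    return templates


def generate_cohort(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[Subject]:
    """Sample a labeled cohort; deterministic for a fixed spec/seed.

    Per-group MMSE scores are drawn from the group normal, rounded, then
    clamped into the label-consistent band ([28,30] healthy, [23,27] MCI)
    — the reported group means are conditional on group membership, so a
    draw outside the band would contradict the subject's group.  Sexes
    alternate M/F within each group, reproducing near-balanced ratios.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    groups = (
        (CognitiveLabel.HEALTHY, spec.n_healthy, spec.mmse_mean_hc, spec.mmse_sd_hc, "H"),
        (CognitiveLabel.MCI, spec.n_mci, spec.mmse_mean_mci, spec.mmse_sd_mci, "M"),
    )
    for label, count, mean, sd, prefix in groups:
        lo, hi = _MMSE_BANDS[label]
        for i in range(count):
            mmse = int(np.clip(round(rng.normal(mean, sd)), lo, hi))
            age = int(np.clip(round(rng.normal(spec.age_mean, spec.age_sd)), 55, 95))
            subjects.append(
                Subject(
                    subject_id=f"{prefix}{i + 1:03d}",
                    mmse=mmse,
                    age=age,
                    sex="M" if i % 2 == 0 else "F",
                )
            )
    return subjects


def _content_pool(
    template: TaskTemplate, label: CognitiveLabel, effects: LinguisticEffectSpec
) -> list[str]:
    topic = list(template.topic_vocabulary)
    if effects.disjoint_group_vocab:
        half = len(topic) // 2
        topic = topic[:half] if label is CognitiveLabel.HEALTHY else topic[half:]
    return topic + list(SHARED_VOCABULARY)


def generate_sample(
    subject: Subject,
    template: TaskTemplate,
    effects: LinguisticEffectSpec,
    rng: np.random.Generator,
) -> TranscriptSample:
    """Generate one transcript for one subject on one task.

    Token count is drawn from N(mean_len, len_sd) and floored at 1.  For
    tasks with key events, round(coverage * n_events) events are chosen
    (a random subset, template order preserved) and embedded as contiguous
    phrases; remaining slots are fillers (prob ``filler_rate``) or content
    words drawn from an effective vocabulary of round(ttr * pool) words,
    each content draw replaced by a pronoun with probability
    ``pronoun_rate``.
    """
    label = subject.label
    pool = _content_pool(template, label, effects)
    k_eff = max(2, int(round(effects.ttr(label) * len(pool))))
    perm = rng.permutation(len(pool))
    effective = [pool[int(i)] for i in perm[:k_eff]]

    events: list[tuple[str, ...]] = []
    if template.key_events:
        n_events = int(round(effects.event_coverage(label) * len(template.key_events)))
        if n_events > 0:
            idx = sorted(
                int(i)
                for i in rng.choice(
                    len(template.key_events), size=n_events, replace=False
                )
            )
            events = [template.key_events[i] for i in idx]

    length = max(1, int(round(rng.normal(effects.mean_len, effects.len_sd))))
    n_event_tokens = sum(len(e) for e in events)
    n_slots = max(0, length - n_event_tokens)

    def draw_slot() -> str:
        if rng.random() < effects.filler_rate:
            return FILLERS[int(rng.integers(len(FILLERS)))]
        if rng.random() < effects.pronoun_rate(label):
            return PRONOUNS[int(rng.integers(len(PRONOUNS)))]
        return effective[int(rng.integers(len(effective)))]

    # split the free slots into |events|+1 chunks so events appear in order
    chunk_sizes = [n_slots // (len(events) + 1)] * (len(events) + 1)
    chunk_sizes[-1] += n_slots - sum(chunk_sizes)
    tokens: list[str] = []
    for i, size in enumerate(chunk_sizes):
        tokens.extend(draw_slot() for _ in range(size))
        if i < len(events):
            tokens.extend(events[i])
    if not tokens:
        tokens = [draw_slot()]
    return make_original(subject, template.task, " ".join(tokens))


def generate_corpus(
    cohort_spec: CohortSpec,
    effects: LinguisticEffectSpec,
    templates: Mapping[TaskId, TaskTemplate],
    seed: int,
) -> list[TranscriptSample]:
    """One transcript per subject per task: (n_healthy + n_mci) * 12 samples."""
    missing = [t.value for t in TaskId if t not in templates]
    if missing:
        raise ValueError(f"missing templates for tasks: {missing}")
    ss = np.random.SeedSequence(seed)
    rng_cohort, rng_text = (np.random.default_rng(s) for s in ss.spawn(2))
    cohort = generate_cohort(cohort_spec, rng=rng_cohort)
    samples: list[TranscriptSample] = []
    for subject in cohort:
        for task in TaskId:
            samples.append(
                generate_sample(subject, templates[task], effects, rng_text)
            )
    return samples


def generate_default_corpus(seed: int = 0, **effect_kwargs):
    """Convenience wrapper: default cohort, default effects, default templates."""
    return generate_corpus(
        CohortSpec(seed=seed),
        LinguisticEffectSpec(**effect_kwargs),
        default_templates(),
        seed=seed,
    )


def corpus_vocabulary(templates: Mapping[TaskId, TaskTemplate]) -> list[str]:
    """Every token the generator can emit, sorted."""
    words: set[str] = set(SHARED_VOCABULARY) | set(PRONOUNS) | set(FILLERS)
    for template in templates.values():
        words.update(template.topic_vocabulary)
        for event in template.key_events:
            words.update(event)
    return sorted(words)


_SYNONYM_SUFFIXES = tuple(chr(ord("a") + i) for i in range(26))


def generate_fixture_lexicon(
    vocabulary: Sequence[str], synonyms_per_word: int, seed: int = 0
) -> SynonymLexicon:
    """A synthetic synonym lexicon: each word maps to ``synonyms_per_word``
    distinct derived tokens (never the word itself).  Stands in for a real
    WordNet-style resource in tests and synthetic runs."""
    if synonyms_per_word < 0:
        raise ValueError("synonyms_per_word must be >= 0")
    rng = np.random.default_rng(seed)
    entries: dict[str, set[str]] = {}
    for word in vocabulary:
        suffixes = rng.permutation(len(_SYNONYM_SUFFIXES))[:synonyms_per_word]
        entries[word] = {f"{word}~{_SYNONYM_SUFFIXES[int(s)]}" for s in suffixes}
    return SynonymLexicon.from_dict(entries)


def generate_fixture_stopwords(
    vocabulary: Sequence[str], fraction: float = 0.1
) -> StopwordList:
    """A deterministic stopword subset: the first round(fraction*n) of the
    sorted vocabulary.  Synthetic stand-in for a curated stopword list."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0,1]")
    ordered = sorted(set(vocabulary))
    k = int(round(fraction * len(ordered)))
    return StopwordList(words=frozenset(ordered[:k]), source_name="synthetic-fixture")
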