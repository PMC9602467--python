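"""Class-balanced augmentation and train/validation/test splitting.

With 540 healthy-control and 180 MCI originals, augmenting MCI 30x and
healthy 10x yields 5,400 samples per class (10,800 total) — an exactly
balanced training pool.  The multiplier counts the total copies per
original, original included.

Splitting supports three granularities:

* SAMPLE_LEVEL — each (possibly augmented) sample is assigned
  independently.  This replicates the evaluation procedure of augmenting
  first and splitting afterwards, but lets augmented siblings of one
  original fall on both sides of the split, which inflates test scores.
* ORIGIN_LEVEL — all samples sharing an ``origin_id`` stay together.
* SUBJECT_LEVEL — all samples of a subject stay together (the strictest,
  recommended mode: no information about a test subject ever reaches
  training).

``leakage_audit`` quantifies the difference: the fraction of test
samples whose origin (or subject) also appears in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import CognitiveLabel, TranscriptSample
from .eda import EdaParams, augment_sentence
from .lexicon import StopwordList, SynonymLexicon

SAMPLE_LEVEL = "sample"
ORIGIN_LEVEL = "origin"
SUBJECT_LEVEL = "subject"


@dataclass(frozen=True)
class AugmentationPlan:
    """Per-class multipliers (total copies per original, original included)."""

    multiplier_mci: int = 30
    multiplier_hc: int = 10
    eda: EdaParams = field(default_factory=EdaParams)

    def __post_init__(self) -> None:
        if self.multiplier_mci < 1 or self.multiplier_hc < 1:
            raise ValueError("multipliers must be >= 1")

    def multiplier(self, label: CognitiveLabel) -> int:
        if label is CognitiveLabel.MCI:
            return self.multiplier_mci
        if label is CognitiveLabel.HEALTHY:
            return self.multiplier_hc
        raise ValueError(f"no multiplier for label {label}")


def balance_augment(
    corpus: Sequence[TranscriptSample],
    plan: AugmentationPlan,
    lexicon: SynonymLexicon,
    stopwords: StopwordList,
    seed: int | None = None,
) -> list[TranscriptSample]:
    """Expand every original by its class multiplier via ``augment_sentence``.

    Output size is exactly sum over classes of multiplier * n_originals.
    Samples in the dementia screening range are invalid input here.
    """
    bad = [s.sample_id for s in corpus if s.label is CognitiveLabel.EXCLUDED_DEMENTIA_RANGE]
    if bad:
        raise ValueError(
            f"corpus contains {len(bad)} samples in the excluded dementia range "
            f"(e.g. {bad[0]}); remove them before augmentation"
        )
    rng = np.random.default_rng(plan.eda.seed if seed is None else seed)
    out: list[TranscriptSample] = []
    for sample in corpus:
        out.extend(
            augment_sentence(
                sample,
                plan.eda,
                lexicon,
                stopwords,
                n_out=plan.multiplier(sample.label),
                rng=rng,
            )
        )
    return out


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.20
    validation_fraction: float = 0.10
    n_repeats: int = 10
    mode: str = SAMPLE_LEVEL
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0,1)")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0,1)")
        if self.test_fraction + self.validation_fraction >= 1.0:
            raise ValueError("test + validation fractions must leave room for train")
        if self.mode not in (SAMPLE_LEVEL, ORIGIN_LEVEL, SUBJECT_LEVEL):
            raise ValueError(f"unknown split mode {self.mode!r}")


@dataclass(frozen=True)
class SplitTriple:
    """Index sets into the dataset; train/validation/test partition it."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]


def _apportion(total: int, class_sizes: dict) -> dict:
    """Largest-remainder apportionment of ``total`` across classes."""
    n = sum(class_sizes.values())
    quotas = {c: total * size / n for c, size in class_sizes.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    remainder = total - sum(counts.values())
    order = sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)
    for c in order[:remainder]:
        counts[c] += 1
    return counts


def _split_one(
    dataset: Sequence[TranscriptSample],
    spec: SplitSpec,
    rng: np.random.Generator,
) -> SplitTriple:
    n = len(dataset)
    by_class: dict[CognitiveLabel, list[int]] = {}
    for i, sample in enumerate(dataset):
        by_class.setdefault(sample.label, []).append(i)
    class_sizes = {c: len(ix) for c, ix in by_class.items()}
    test_targets = _apportion(int(round(spec.test_fraction * n)), class_sizes)
    val_targets = _apportion(int(round(spec.validation_fraction * n)), class_sizes)

    train: list[int] = []
    validation: list[int] = []
    test: list[int] = []
    for label in sorted(by_class, key=lambda c: c.value):
        indices = by_class[label]
        if spec.mode == SAMPLE_LEVEL:
            groups = [[i] for i in indices]
        else:
            key = (
                (lambda s: s.origin_id)
                if spec.mode == ORIGIN_LEVEL
                else (lambda s: s.subject_id)
            )
            grouped: dict[str, list[int]] = {}
            for i in indices:
                grouped.setdefault(key(dataset[i]), []).append(i)
            groups = [grouped[k] for k in sorted(grouped)]
            biggest = max(len(g) for g in groups)
            if biggest > test_targets[label]:
                raise ValueError(
                    f"{spec.mode}-level stratification infeasible for {label.value}: "
                    f"a single group of {biggest} samples exceeds the per-class "
                    f"test target of {test_targets[label]}"
                )
        order = rng.permutation(len(groups))
        t_need, v_need = test_targets[label], val_targets[label]
        for g in (groups[int(i)] for i in order):
            if g and len(g) <= t_need:
                test.extend(g)
                t_need -= len(g)
            elif len(g) <= v_need:
                validation.extend(g)
                v_need -= len(g)
            else:
                train.extend(g)
    return SplitTriple(
        train=tuple(sorted(train)),
        validation=tuple(sorted(validation)),
        test=tuple(sorted(test)),
    )


def make_splits(
    dataset: Sequence[TranscriptSample], spec: SplitSpec
) -> list[SplitTriple]:
    """``n_repeats`` independent stratified train/validation/test splits.

    Each repeat draws its own RNG stream from the spec seed.  Test and
    validation sizes target round(fraction * N), apportioned across
    classes by largest remainder; at origin/subject granularity the
    targets are met as closely as whole groups allow (shortfall goes to
    train).
    """
    if not dataset:
        raise ValueError("dataset is empty")
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_repeats)
    return [
        _split_one(dataset, spec, np.random.default_rng(s)) for s in streams
    ]


@dataclass(frozen=True)
class LeakageReport:
    """How much of the test set shares an origin or subject with training."""

    n_test: int
    origin_overlap_count: int
    origin_overlap_fraction: float
    subject_overlap_count: int
    subject_overlap_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_test": self.n_test,
            "origin_overlap_count": self.origin_overlap_count,
            "origin_overlap_fraction": self.origin_overlap_fraction,
            "subject_overlap_count": self.subject_overlap_count,
            "subject_overlap_fraction": self.subject_overlap_fraction,
        }


def leakage_audit(
    triple: SplitTriple, dataset: Sequence[TranscriptSample]
) -> LeakageReport:
    """Count test samples whose origin_id / subject_id also occurs in train."""
    train_origins = {dataset[i].origin_id for i in triple.train}
    train_subjects = {dataset[i].subject_id for i in triple.train}
    n_test = len(triple.test)
    o_count = sum(1 for i in triple.test if dataset[i].origin_id in train_origins)
    s_count = sum(1 for i in triple.test if dataset[i].subject_id in train_subjects)
    return LeakageReport(
        n_test=n_test,
        origin_overlap_count=o_count,
        origin_overlap_fraction=o_count / n_test if n_test else 0.0,
        subject_overlap_count=s_count,
        subject_overlap_fraction=s_count / n_test if n_test else 0.0,
    )
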