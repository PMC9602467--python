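"""Domain types for speech-transcript cognitive screening corpora.

A corpus is a set of subjects, each of whom performed 12 short speaking
tasks (10 episodic-recall prompts, one picture description, one animation
description).  Each subject carries an MMSE score (Mini-Mental State
Examination, 0-30) from which the classification label is derived:
scores of 28 or more are treated as healthy controls, 23-27 as mild
cognitive impairment (MCI), and scores below 23 fall in the dementia
screening range and are excluded from classification altogether.

Every transcript sample records provenance: ``origin_id`` points at the
un-augmented sample it descends from, and ``augmentation_tag`` records
which augmentation operator (if any) produced it.  This is what makes
leakage audits of train/test splits possible downstream.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MMSE_HEALTHY_MIN = 28
MMSE_MCI_MIN = 23
DEFAULT_MAX_LEN = 512


class TaskId(str, enum.Enum):
    """The 12 speaking tasks: 10 episodic prompts plus picture and animation."""

    EP1A = "EP1a"
    EP1B = "EP1b"
    EP2A = "EP2a"
    EP3A = "EP3a"
    EP4A = "EP4a"
    EP5A = "EP5a"
    EP6A = "EP6a"
    EP6B = "EP6b"
    EP7A = "EP7a"
    EP8A = "EP8a"
    PICTURE = "Picture"
    ANIMATION = "Animation"


EPISODIC_TASKS: tuple[TaskId, ...] = tuple(
    t for t in TaskId if t not in (TaskId.PICTURE, TaskId.ANIMATION)
)


class CognitiveLabel(enum.Enum):
    HEALTHY = "HEALTHY"
    MCI = "MCI"
    EXCLUDED_DEMENTIA_RANGE = "EXCLUDED_DEMENTIA_RANGE"


class AugmentationTag(enum.Enum):
    ORIGINAL = "ORIGINAL"
    SR = "SR"  # synonym replacement
    RI = "RI"  # random insertion
    RS = "RS"  # random swap
    RD = "RD"  # random deletion


def assign_label(mmse: int) -> CognitiveLabel:
    """Map an MMSE score to a screening label.

    28-30 -> HEALTHY, 23-27 -> MCI, 0-22 -> EXCLUDED_DEMENTIA_RANGE
    (potential-dementia band, never used for HC/MCI classification).
    """
    if not 0 <= mmse <= 30:
        raise ValueError(f"MMSE score must be in 0..30, got {mmse}")
    if mmse >= MMSE_HEALTHY_MIN:
        return CognitiveLabel.HEALTHY
    if mmse >= MMSE_MCI_MIN:
        return CognitiveLabel.MCI
    return CognitiveLabel.EXCLUDED_DEMENTIA_RANGE


@dataclass(frozen=True)
class Subject:
    subject_id: str
    mmse: int
    age: int
    sex: str  # "M" or "F"

    def __post_init__(self) -> None:
        if not 0 <= self.mmse <= 30:
            raise ValueError(f"MMSE out of range for {self.subject_id}: {self.mmse}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")

    @property
    def label(self) -> CognitiveLabel:
        return assign_label(self.mmse)


@dataclass(frozen=True)
class Tokenizer:
    """A raw-string -> token-sequence function together with its inverse join.

    The default whitespace tokenizer is the right choice for the synthetic,
    whitespace-joinable corpora produced here; a morphological analyser
    (e.g. MeCab for Japanese) can be plugged in behind the same contract.
    ``join(tokenize(x))`` must be a fixed point of ``tokenize``.
    """

    tokenize: Callable[[str], list[str]]
    join: Callable[[Sequence[str]], str]


WHITESPACE_TOKENIZER = Tokenizer(tokenize=str.split, join=" ".join)


@dataclass(frozen=True)
class TranscriptSample:
    """One (possibly augmented) transcript of one subject on one task."""

    sample_id: str
    subject_id: str
    task: TaskId
    label: CognitiveLabel
    text: str
    origin_id: str
    augmentation_tag: AugmentationTag = AugmentationTag.ORIGINAL

    def __post_init__(self) -> None:
        is_original = self.augmentation_tag is AugmentationTag.ORIGINAL
        if is_original != (self.origin_id == self.sample_id):
            raise ValueError(
                f"sample {self.sample_id}: augmentation_tag=ORIGINAL must hold "
                "exactly when origin_id equals the sample's own id"
            )

    def tokens(self, tokenizer: Tokenizer = WHITESPACE_TOKENIZER) -> list[str]:
        return tokenizer.tokenize(self.text)

    def derived(
        self, sample_id: str, text: str, tag: AugmentationTag
    ) -> "TranscriptSample":
        """An augmented copy; label/task/subject/origin provenance is conserved."""
        if tag is AugmentationTag.ORIGINAL:
            raise ValueError("derived samples cannot carry the ORIGINAL tag")
        return dataclasses.replace(
            self, sample_id=sample_id, text=text, augmentation_tag=tag
        )


def make_original(
    subject: Subject, task: TaskId, text: str, sample_id: str | None = None
) -> TranscriptSample:
    sid = sample_id if sample_id is not None else f"{subject.subject_id}:{task.value}"
    return TranscriptSample(
        sample_id=sid,
        subject_id=subject.subject_id,
        task=task,
        label=subject.label,
        text=text,
        origin_id=sid,
        augmentation_tag=AugmentationTag.ORIGINAL,
    )


def clean_transcript(
    raw: str,
    recording_markers: Iterable[str] = (),
    max_len: int = DEFAULT_MAX_LEN,
    tokenizer: Tokenizer = WHITESPACE_TOKENIZER,
) -> str:
    """Cleanse one raw transcript.

    Removes every occurrence of each recording marker (the strings a
    recording protocol inserts to mark start/end of capture), strips
    line breaks, and truncates to at most ``max_len`` tokenizer units,
    keeping the prefix.  Idempotent on its own output.
    """
    if max_len <= 0:
        raise ValueError(f"max_len must be positive, got {max_len}")
    text = raw
    # longest first, so a marker that contains another is removed intact
    for marker in sorted(set(recording_markers), key=len, reverse=True):
        if marker:
            text = text.replace(marker, " ")
    text = text.replace("\r", " ").replace("\n", " ")
    tokens = tokenizer.tokenize(text)
    if not tokens:
        logger.warning("clean_transcript produced an empty transcript")
    return tokenizer.join(tokens[:max_len])


# ---------------------------------------------------------------------------
# On-disk dialects: JSON-lines (single file) and directory (metadata table +
# one UTF-8 text file per sample).


def sample_to_record(sample: TranscriptSample) -> dict:
    return {
        "sample_id": sample.sample_id,
        "subject_id": sample.subject_id,
        "task": sample.task.value,
        "label": sample.label.value,
        "text": sample.text,
        "origin_id": sample.origin_id,
        "augmentation_tag": sample.augmentation_tag.value,
    }


def sample_from_record(record: dict) -> TranscriptSample:
    return TranscriptSample(
        sample_id=record["sample_id"],
        subject_id=record["subject_id"],
        task=TaskId(record["task"]),
        label=CognitiveLabel(record["label"]),
        text=record["text"],
        origin_id=record["origin_id"],
        augmentation_tag=AugmentationTag(record["augmentation_tag"]),
    )


def write_jsonl(samples: Iterable[TranscriptSample], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sample in samples:
            fh.write(json.dumps(sample_to_record(sample), ensure_ascii=False))
            fh.write("\n")


def read_jsonl(path: str | Path) -> list[TranscriptSample]:
    samples = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                samples.append(sample_from_record(json.loads(line)))
    return samples


def write_corpus_dir(
    subjects: Sequence[Subject],
    samples: Sequence[TranscriptSample],
    directory: str | Path,
) -> None:
    """Directory dialect: metadata.tsv + one text file per sample."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for sample in samples:
        subject = by_id[sample.subject_id]
        rel = f"{sample.sample_id.replace(':', '_')}.txt"
        (directory / rel).write_text(sample.text, encoding="utf-8")
        rows.append(
            {
                "subject_id": sample.subject_id,
                "task": sample.task.value,
                "mmse": subject.mmse,
                "age": subject.age,
                "sex": subject.sex,
                "path": rel,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "metadata.tsv", sep="\t", index=False)


def read_corpus_dir(
    directory: str | Path,
) -> tuple[list[Subject], list[TranscriptSample]]:
    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t")
    subjects: dict[str, Subject] = {}
    samples: list[TranscriptSample] = []
    for row in meta.itertuples(index=False):
        if row.subject_id not in subjects:
            subjects[row.subject_id] = Subject(
                subject_id=str(row.subject_id),
                mmse=int(row.mmse),
                age=int(row.age),
                sex=str(row.sex),
            )
        text = (directory / row.path).read_text(encoding="utf-8")
        samples.append(
            make_original(subjects[row.subject_id], TaskId(row.task), text)
        )
    return list(subjects.values()), samples
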