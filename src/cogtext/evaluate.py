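"""Weighted F1 and the per-task correctness report.

The headline score for the binary HC/MCI problem is the support-weighted
mean of per-class F1 scores (appropriate under class imbalance, where
plain accuracy rewards always predicting the majority class).  The
per-task report breaks the test set down by speaking task: each task row
carries its correct-prediction rate, its test count, and its within-task
weighted F1 — rate-of-correct-predictions and F1 are reported side by
side rather than conflated.  The summary row is the unweighted mean over
tasks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from sklearn.metrics import f1_score

from .corpus import CognitiveLabel, TaskId


def _validate(predictions: Sequence, labels: Sequence) -> None:
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    if len(predictions) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(labels)} labels"
        )


def _values(seq: Sequence[CognitiveLabel]) -> list[str]:
    return [x.value for x in seq]


def f1_per_class(
    predictions: Sequence[CognitiveLabel],
    labels: Sequence[CognitiveLabel],
    cls: CognitiveLabel,
) -> float:
    """One-vs-rest F1 for ``cls``; 0.0 when precision + recall is 0."""
    _validate(predictions, labels)
    return float(
        f1_score(
            _values(labels),
            _values(predictions),
            labels=[cls.value],
            average=None,
            zero_division=0,
        )[0]
    )


def weighted_f1(
    predictions: Sequence[CognitiveLabel], labels: Sequence[CognitiveLabel]
) -> float:
    """Support-weighted mean of per-class F1 over the classes present in labels."""
    _validate(predictions, labels)
    return float(
        f1_score(
            _values(labels), _values(predictions), average="weighted", zero_division=0
        )
    )


@dataclass(frozen=True)
class TaskRow:
    task: TaskId
    n_test: int
    correct_rate: float | None  # None when the task has no test samples
    f1: float | None


@dataclass(frozen=True)
class EvaluationReport:
    weighted_f1: float
    per_class_f1: Mapping[CognitiveLabel, float]
    per_task: tuple[TaskRow, ...]
    average_correct_rate: float
    average_n_test: float

    def to_frame(self) -> pd.DataFrame:
        """Table in the per-task layout: task, rate, n, F1, plus an Average row."""
        rows = [
            {
                "task": row.task.value,
                "correct_rate": row.correct_rate,
                "n_test": row.n_test,
                "f1": row.f1,
            }
            for row in self.per_task
        ]
        rows.append(
            {
                "task": "Average",
                "correct_rate": self.average_correct_rate,
                "n_test": self.average_n_test,
                "f1": None,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "weighted_f1": self.weighted_f1,
            "per_class_f1": {c.value: v for c, v in self.per_class_f1.items()},
            "per_task": [
                {
                    "task": r.task.value,
                    "correct_rate": r.correct_rate,
                    "n_test": r.n_test,
                    "f1": r.f1,
                }
                for r in self.per_task
            ],
            "average_correct_rate": self.average_correct_rate,
            "average_n_test": self.average_n_test,
        }


def per_task_report(
    predictions: Sequence[CognitiveLabel],
    labels: Sequence[CognitiveLabel],
    task_ids: Sequence[TaskId],
) -> EvaluationReport:
    """Full evaluation: overall weighted F1, per-class F1, per-task breakdown.

    Task rows cover all 12 tasks; a task absent from the test set gets
    n_test 0 and an undefined (None) rate, and is excluded from the
    unweighted task averages.  The n_test column always sums to the test
    set size.
    """
    _validate(predictions, labels)
    if len(task_ids) != len(labels):
        raise ValueError("task_ids must align with labels")
    present_classes = sorted({l for l in labels}, key=lambda c: c.value)
    per_class = {
        c: f1_per_class(predictions, labels, c) for c in present_classes
    }
    rows: list[TaskRow] = []
    for task in TaskId:
        idx = [i for i, t in enumerate(task_ids) if t is task]
        if not idx:
            rows.append(TaskRow(task=task, n_test=0, correct_rate=None, f1=None))
            continue
        correct = sum(1 for i in idx if predictions[i] is labels[i])
        task_f1 = weighted_f1([predictions[i] for i in idx], [labels[i] for i in idx])
        rows.append(
            TaskRow(
                task=task,
                n_test=len(idx),
                correct_rate=correct / len(idx),
                f1=task_f1,
            )
        )
    populated = [r for r in rows if r.n_test > 0]
    avg_rate = (
        sum(r.correct_rate for r in populated) / len(populated)
        if populated
        else math.nan
    )
    avg_n = (
        sum(r.n_test for r in populated) / len(populated) if populated else math.nan
    )
    return EvaluationReport(
        weighted_f1=weighted_f1(predictions, labels),
        per_class_f1=per_class,
        per_task=tuple(rows),
        average_correct_rate=avg_rate,
        average_n_test=avg_n,
    )
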