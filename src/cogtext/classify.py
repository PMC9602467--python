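"""Classifier harness: backends, the hyperparameter grid, early stopping.

The harness is backend-agnostic.  A backend turns (train, validation,
setting, seed) into a fitted model and predicts a label per sample; the
harness guarantees that a backend never sees test data.  The grid mirrors
the fine-tuning search used for long-transcript transformer models —
batch sizes 1..32 crossed with learning rates 5e-5/3e-5/2e-5, epochs
capped at 4 with validation-based early stopping — so grid bookkeeping
is identical whichever backend runs.

The shipped default is a deterministic desk-scale baseline:
bag-of-words counts (vocabulary built from training data only) fed to a
logistic-regression decision rule, trained in epoch increments with
early stopping on validation log-loss.  For this backend batch size and
learning rate have no analogous optimizer knob; they are recorded in the
run metadata but inert, so grid reports stay comparable across backends.
A transformer fine-tuning backend plugs in behind the same contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.preprocessing import normalize

from .balance import SplitTriple
from .corpus import CognitiveLabel, TranscriptSample
from .evaluate import weighted_f1


@dataclass(frozen=True)
class HyperparamSetting:
    batch_size: int
    learning_rate: float
    n_epochs: int = 4
    early_stopping: bool = True
    patience: int = 1


@dataclass(frozen=True)
class HyperparamGrid:
    batch_sizes: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    learning_rates: tuple[float, ...] = (5e-5, 3e-5, 2e-5)
    n_epochs: int = 4
    early_stopping: bool = True
    patience: int = 1

    def __len__(self) -> int:
        return len(self.batch_sizes) * len(self.learning_rates)


def grid_configs(grid: HyperparamGrid) -> list[HyperparamSetting]:
    """Cartesian product in deterministic order: batch ascending, rate descending."""
    if not grid.batch_sizes or not grid.learning_rates:
        raise ValueError("grid axes must be nonempty")
    return [
        HyperparamSetting(
            batch_size=b,
            learning_rate=lr,
            n_epochs=grid.n_epochs,
            early_stopping=grid.early_stopping,
            patience=grid.patience,
        )
        for b, lr in itertools.product(
            sorted(grid.batch_sizes), sorted(grid.learning_rates, reverse=True)
        )
    ]


class ClassifierBackend(Protocol):
    """Contract every backend satisfies; fit never receives test data."""

    def fit(
        self,
        train: Sequence[TranscriptSample],
        validation: Sequence[TranscriptSample],
        setting: HyperparamSetting,
        seed: int,
    ) -> tuple[object, dict]:
        """Return (model, metadata); metadata records epochs actually run."""
        ...

    def predict(
        self, model: object, samples: Sequence[TranscriptSample]
    ) -> list[CognitiveLabel]:
        ...


def early_stopping_epochs(
    losses: Sequence[float], patience: int
) -> int:
    """Number of epochs retained under patience-based early stopping.

    Training stops once the validation objective has failed to improve
    for ``patience + 1`` consecutive evaluations; the returned count is
    the epoch index (1-based) of the best observed loss.
    """
    best, best_epoch, stale = np.inf, 0, 0
    for epoch, loss in enumerate(losses, start=1):
        if loss < best - 1e-12:
            best, best_epoch, stale = loss, epoch, 0
        else:
            stale += 1
            if stale > patience:
                break
    return best_epoch


class BaselineBackend:
    """Deterministic bag-of-words + logistic-regression backend.

    Epochs are realised as warm-started lbfgs iteration budgets
    (``iters_per_epoch`` each); after every epoch the validation log-loss
    is evaluated and patience-based early stopping applies.  The feature
    vocabulary is built from training text only.
    """

    def __init__(self, iters_per_epoch: int = 40, C: float = 1.0) -> None:
        self.iters_per_epoch = iters_per_epoch
        self.C = C

    def _features(self, vectorizer, samples: Sequence[TranscriptSample]):
        X = vectorizer.transform([s.text for s in samples])
        return normalize(X, norm="l2")

    def fit(
        self,
        train: Sequence[TranscriptSample],
        validation: Sequence[TranscriptSample],
        setting: HyperparamSetting,
        seed: int,
    ) -> tuple[object, dict]:
        vectorizer = CountVectorizer(analyzer=str.split, lowercase=False)
        vectorizer.fit([s.text for s in train])
        X_train = self._features(vectorizer, train)
        y_train = np.array([s.label.value for s in train])
        X_val = self._features(vectorizer, validation)
        y_val = np.array([s.label.value for s in validation])

        classes = sorted(set(y_train))
        clf = LogisticRegression(
            C=self.C,
            solver="lbfgs",
            warm_start=True,
            max_iter=self.iters_per_epoch,
            random_state=seed,
        )
        losses: list[float] = []
        models: list[np.ndarray] = []
        stale = 0
        best = np.inf
        for epoch in range(setting.n_epochs):
            clf.max_iter = self.iters_per_epoch * (epoch + 1)
            clf.fit(X_train, y_train)
            loss = log_loss(y_val, clf.predict_proba(X_val), labels=clf.classes_)
            losses.append(loss)
            models.append((clf.coef_.copy(), clf.intercept_.copy()))
            if setting.early_stopping:
                if loss < best - 1e-12:
                    best, stale = loss, 0
                else:
                    stale += 1
                    if stale > setting.patience:
                        break
        best_epoch = early_stopping_epochs(losses, setting.patience)
        coef, intercept = models[best_epoch - 1]
        clf.coef_, clf.intercept_ = coef, intercept
        meta = {
            "epochs_run": len(losses),
            "epochs_used": best_epoch,
            "validation_losses": losses,
            "seed": seed,
            "batch_size": setting.batch_size,
            "learning_rate": setting.learning_rate,
        }
        return (vectorizer, clf), meta

    def predict(
        self, model: object, samples: Sequence[TranscriptSample]
    ) -> list[CognitiveLabel]:
        vectorizer, clf = model
        X = self._features(vectorizer, samples)
        return [CognitiveLabel(v) for v in clf.predict(X)]


@dataclass(frozen=True)
class RunResult:
    predictions: tuple[CognitiveLabel, ...]
    test_indices: tuple[int, ...]
    metadata: dict


def train_eval(
    dataset: Sequence[TranscriptSample],
    triple: SplitTriple,
    backend: ClassifierBackend,
    setting: HyperparamSetting,
    seed: int = 0,
) -> RunResult:
    """Fit on train (validation drives early stopping), predict the test part.

    The backend receives only train and validation samples; test samples
    reach it exclusively through ``predict``.
    """
    train = [dataset[i] for i in triple.train]
    validation = [dataset[i] for i in triple.validation]
    test = [dataset[i] for i in triple.test]
    try:
        model, meta = backend.fit(train, validation, setting, seed)
        predictions = backend.predict(model, test)
    except Exception as exc:
        raise RuntimeError(f"backend failed under setting {setting}") from exc
    if len(predictions) != len(test):
        raise RuntimeError("backend must predict exactly one label per test sample")
    meta = dict(meta)
    meta["setting"] = setting
    return RunResult(
        predictions=tuple(predictions),
        test_indices=tuple(triple.test),
        metadata=meta,
    )


@dataclass(frozen=True)
class GridReportRow:
    setting: HyperparamSetting
    scores: tuple[float, ...]  # weighted F1 per split repeat
    mean_weighted_f1: float


@dataclass(frozen=True)
class GridReport:
    rows: tuple[GridReportRow, ...]
    best: GridReportRow


def run_grid(
    dataset: Sequence[TranscriptSample],
    splits: Sequence[SplitTriple],
    backend: ClassifierBackend,
    grid: HyperparamGrid,
    seed: int = 0,
) -> GridReport:
    """Mean weighted F1 per grid setting over the split repeats; best = argmax."""
    rows: list[GridReportRow] = []
    for setting in grid_configs(grid):
        scores = []
        for r, triple in enumerate(splits):
            result = train_eval(dataset, triple, backend, setting, seed=seed + r)
            truth = [dataset[i].label for i in result.test_indices]
            scores.append(weighted_f1(result.predictions, truth))
        rows.append(
            GridReportRow(
                setting=setting,
                scores=tuple(scores),
                mean_weighted_f1=float(np.mean(scores)),
            )
        )
    best = max(rows, key=lambda row: row.mean_weighted_f1)
    return GridReport(rows=tuple(rows), best=best)
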