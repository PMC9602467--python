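"""Per-task evaluation report: which speaking task classifies best?

Trains the baseline on the augmented pool (subject-level split) and
breaks the test predictions down by the 12 tasks — correct-prediction
rate, test count and within-task F1, plus the unweighted average row.
Writes results/per_task_report.csv.
"""

import argparse
from pathlib import Path

from cogtext import synthetic
from cogtext.balance import (
    AugmentationPlan,
    SplitSpec,
    balance_augment,
    make_splits,
)
from cogtext.classify import BaselineBackend, HyperparamSetting, train_eval
from cogtext.eda import EdaParams
from cogtext.evaluate import per_task_report


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    corpus = synthetic.generate_default_corpus(seed=args.seed)
    templates = synthetic.default_templates()
    vocab = synthetic.corpus_vocabulary(templates)
    lexicon = synthetic.generate_fixture_lexicon(vocab, 3, seed=args.seed)
    stopwords = synthetic.generate_fixture_stopwords(vocab, 0.1)
    dataset = balance_augment(
        corpus, AugmentationPlan(eda=EdaParams(seed=args.seed)), lexicon, stopwords,
        seed=args.seed,
    )

    triple = make_splits(
        dataset, SplitSpec(n_repeats=1, mode="subject", seed=args.seed)
    )[0]
    result = train_eval(
        dataset, triple, BaselineBackend(), HyperparamSetting(1, 2e-5),
        seed=args.seed,
    )
    truth = [dataset[i].label for i in result.test_indices]
    tasks = [dataset[i].task for i in result.test_indices]
    report = per_task_report(result.predictions, truth, tasks)

    frame = report.to_frame()
    frame.to_csv(args.out / "per_task_report.csv", index=False)
    print(frame.to_string(index=False))
    print(f"\noverall weighted F1: {report.weighted_f1:.3f}")
    populated = [r for r in report.per_task if r.n_test > 0]
    best = max(populated, key=lambda r: r.correct_rate)
    worst = min(populated, key=lambda r: r.correct_rate)
    print(
        f"finding: correct rate ranges from {worst.correct_rate:.3f} "
        f"({worst.task.value}) to {best.correct_rate:.3f} ({best.task.value}); "
        "picture/animation tasks add an event-coverage signal on top of the "
        "pronoun-rate and lexical-diversity effects shared by all tasks."
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
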