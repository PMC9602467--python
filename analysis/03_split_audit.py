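"""Audit train/test leakage under the three split granularities.

Splitting the augmented pool at sample level lets augmented siblings of
one original land on both sides of the split; this script quantifies
that, against origin-level and subject-level splitting which forbid it.
Writes a per-mode audit table to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cogtext import synthetic
from cogtext.balance import (
    AugmentationPlan,
    SplitSpec,
    balance_augment,
    leakage_audit,
    make_splits,
)
from cogtext.corpus import read_jsonl
from cogtext.eda import EdaParams


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--repeats", type=int, default=10)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    aug_path = args.out / "augmented.jsonl"
    if aug_path.exists():
        dataset = read_jsonl(aug_path)
    else:
        corpus = synthetic.generate_default_corpus(seed=args.seed)
        templates = synthetic.default_templates()
        vocab = synthetic.corpus_vocabulary(templates)
        lexicon = synthetic.generate_fixture_lexicon(vocab, 3, seed=args.seed)
        stopwords = synthetic.generate_fixture_stopwords(vocab, 0.1)
        dataset = balance_augment(
            corpus, AugmentationPlan(eda=EdaParams(seed=args.seed)),
            lexicon, stopwords, seed=args.seed,
        )

    rows = []
    for mode in ("sample", "origin", "subject"):
        spec = SplitSpec(n_repeats=args.repeats, mode=mode, seed=args.seed)
        audits = [leakage_audit(t, dataset) for t in make_splits(dataset, spec)]
        rows.append(
            {
                "mode": mode,
                "n_test": audits[0].n_test,
                "origin_overlap_mean": np.mean(
                    [a.origin_overlap_fraction for a in audits]
                ),
                "subject_overlap_mean": np.mean(
                    [a.subject_overlap_fraction for a in audits]
                ),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "leakage_audit.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nfinding: at sample level essentially every test transcript has "
        "augmented siblings in training (overlap ~1.0), so scores from that "
        "protocol are optimistic; origin- and subject-level splits audit at 0."
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
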