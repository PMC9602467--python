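"""Easy Data Augmentation (EDA) operators and the per-sentence driver.

Four token-level perturbations create augmented copies of a transcript:

* synonym replacement (SR): replace non-stopword tokens by lexicon synonyms,
* random insertion (RI): insert copies (or synonyms) of non-stopword tokens,
* random swap (RS): swap token pairs,
* random deletion (RD): drop each token independently with probability p.

The perturbation strength is governed by alpha, the fraction of a
sentence's tokens each operator application touches; n = max(1,
round(alpha * length)) tokens are changed (deletion instead uses the
per-token probability ``p_delete``).  Stopwords are never replaced and
never inserted, so curated function words survive augmentation intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import (
    AugmentationTag,
    Tokenizer,
    TranscriptSample,
    WHITESPACE_TOKENIZER,
)
from .lexicon import EMPTY_STOPWORDS, StopwordList, SynonymLexicon

logger = logging.getLogger(__name__)

#: operator application order under the CYCLE policy
OPERATOR_CYCLE = (
    AugmentationTag.SR,
    AugmentationTag.RI,
    AugmentationTag.RS,
    AugmentationTag.RD,
)

CYCLE = "cycle"
UNIFORM_RANDOM = "uniform_random"
DUPLICATE = "duplicate"
SYNONYM = "synonym"


@dataclass(frozen=True)
class EdaParams:
    """Augmentation hyperparameters.

    alpha: fraction of tokens perturbed per operator application (0.05 is
        the conservative setting recommended for small datasets; larger
        values degrade downstream accuracy).
    p_delete: per-token deletion probability; defaults to alpha.
    operator_policy: "cycle" (SR,RI,RS,RD,SR,... — deterministic, balanced),
        "uniform_random", or "fixed:<TAG>".
    insertion_mode: "duplicate" inserts a copy of a chosen non-stopword
        token; "synonym" inserts one of its lexicon synonyms.
    """

    alpha: float = 0.05
    p_delete: float | None = None
    operator_policy: str = CYCLE
    insertion_mode: str = DUPLICATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.p_delete is not None and not 0.0 <= self.p_delete <= 1.0:
            raise ValueError(f"p_delete must be in [0,1], got {self.p_delete}")

    @property
    def deletion_probability(self) -> float:
        return self.alpha if self.p_delete is None else self.p_delete


def n_changes(length: int, alpha: float) -> int:
    """Tokens to perturb for a sentence of ``length`` tokens: max(1, round(alpha*length))."""
    if length < 0:
        raise ValueError("length must be non-negative")
    if length == 0:
        return 0
    return max(1, int(round(alpha * length)))


def synonym_replacement(
    tokens: Sequence[str],
    n: int,
    lexicon: SynonymLexicon,
    stopwords: StopwordList,
    rng: np.random.Generator,
) -> list[str]:
    """Replace up to ``n`` eligible tokens by uniformly chosen synonyms.

    Eligible = not a stopword and has at least one synonym.  Positions are
    chosen without replacement; if fewer than n are eligible, all are used.
    """
    out = list(tokens)
    eligible = [
        i
        for i, tok in enumerate(out)
        if tok not in stopwords and lexicon.synonyms(tok)
    ]
    if n <= 0 or not eligible:
        return out
    k = min(n, len(eligible))
    chosen = rng.choice(len(eligible), size=k, replace=False)
    for j in chosen:
        pos = eligible[int(j)]
        candidates = sorted(lexicon.synonyms(out[pos]))
        out[pos] = candidates[int(rng.integers(len(candidates)))]
    return out


def random_insertion(
    tokens: Sequence[str],
    n: int,
    lexicon: SynonymLexicon,
    stopwords: StopwordList,
    rng: np.random.Generator,
    mode: str = DUPLICATE,
) -> list[str]:
    """Insert ``n`` tokens at uniform gap positions.

    DUPLICATE mode inserts a copy of a uniformly chosen non-stopword token;
    SYNONYM mode inserts a synonym of a chosen non-stopword token (the
    original EDA formulation).  With no eligible source token the input is
    returned unchanged and a warning is logged.
    """
    out = list(tokens)
    if n <= 0:
        return out
    for _ in range(n):
        if mode == SYNONYM:
            sources = [
                t for t in out if t not in stopwords and lexicon.synonyms(t)
            ]
        else:
            sources = [t for t in out if t not in stopwords]
        if not sources:
            logger.warning("random_insertion: no eligible source token")
            return list(tokens)
        src = sources[int(rng.integers(len(sources)))]
        if mode == SYNONYM:
            candidates = sorted(lexicon.synonyms(src))
            content = candidates[int(rng.integers(len(candidates)))]
        else:
            content = src
        gap = int(rng.integers(len(out) + 1))
        out.insert(gap, content)
    return out


def random_swap(
    tokens: Sequence[str], n: int, rng: np.random.Generator
) -> list[str]:
    """Apply ``n`` sequential swaps of two uniformly chosen distinct positions."""
    out = list(tokens)
    if len(out) < 2:
        return out
    for _ in range(max(0, n)):
        i, j = rng.choice(len(out), size=2, replace=False)
        out[int(i)], out[int(j)] = out[int(j)], out[int(i)]
    return out


def random_deletion(
    tokens: Sequence[str], p: float, rng: np.random.Generator
) -> list[str]:
    """Keep each token independently with probability 1-p.

    A nonempty input never yields an empty output: if every token is
    deleted, one uniformly chosen token is returned instead.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    out = list(tokens)
    if not out:
        return out
    keep = rng.random(len(out)) >= p
    kept = [tok for tok, k in zip(out, keep) if k]
    if not kept:
        return [out[int(rng.integers(len(out)))]]
    return kept


def _pick_operator(
    policy: str, k: int, rng: np.random.Generator
) -> AugmentationTag:
    if policy == CYCLE:
        return OPERATOR_CYCLE[k % len(OPERATOR_CYCLE)]
    if policy == UNIFORM_RANDOM:
        return OPERATOR_CYCLE[int(rng.integers(len(OPERATOR_CYCLE)))]
    if policy.startswith("fixed:"):
        return AugmentationTag(policy.split(":", 1)[1])
    raise ValueError(f"unknown operator policy {policy!r}")


def apply_operator(
    tag: AugmentationTag,
    tokens: Sequence[str],
    params: EdaParams,
    lexicon: SynonymLexicon,
    stopwords: StopwordList,
    rng: np.random.Generator,
) -> list[str]:
    n = n_changes(len(tokens), params.alpha)
    if tag is AugmentationTag.SR:
        return synonym_replacement(tokens, n, lexicon, stopwords, rng)
    if tag is AugmentationTag.RI:
        return random_insertion(
            tokens, n, lexicon, stopwords, rng, mode=params.insertion_mode
        )
    if tag is AugmentationTag.RS:
        return random_swap(tokens, n, rng)
    if tag is AugmentationTag.RD:
        return random_deletion(tokens, params.deletion_probability, rng)
    raise ValueError(f"not an operator tag: {tag}")


def augment_sentence(
    sample: TranscriptSample,
    params: EdaParams,
    lexicon: SynonymLexicon,
    stopwords: StopwordList = EMPTY_STOPWORDS,
    n_out: int = 1,
    rng: np.random.Generator | None = None,
    tokenizer: Tokenizer = WHITESPACE_TOKENIZER,
) -> list[TranscriptSample]:
    """Expand one original sample into ``n_out`` samples.

    The first output is the original itself; each of the remaining
    ``n_out - 1`` applies exactly one operator chosen by the operator
    policy.  Label, task, subject and origin provenance are conserved on
    every output.
    """
    if sample.augmentation_tag is not AugmentationTag.ORIGINAL:
        raise ValueError("augment_sentence requires an un-augmented sample")
    if n_out < 1:
        raise ValueError(f"n_out must be >= 1, got {n_out}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out = [sample]
    tokens = sample.tokens(tokenizer)
    for k in range(n_out - 1):
        tag = _pick_operator(params.operator_policy, k, rng)
        new_tokens = apply_operator(tag, tokens, params, lexicon, stopwords, rng)
        out.append(
            sample.derived(
                sample_id=f"{sample.sample_id}#a{k + 1}.{tag.value}",
                text=tokenizer.join(new_tokens),
                tag=tag,
            )
        )
    return out
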