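"""Synonym lexicons and stopword lists for augmentation.

Synonym replacement needs a word -> synonym-set mapping (a WordNet-style
resource in a real deployment); the other operators need a stopword list
naming tokens that must never be replaced or inserted.  Because people
with cognitive impairment tend to over-use pronouns, off-the-shelf
stopword lists that contain pronouns/directives are filtered through an
exclusion set before use — the exclusions stay augmentable signal.

File formats: stopwords are one token per line, UTF-8, ``#`` comments
ignored; synonym lexicons are tab-separated ``word<TAB>syn1,syn2,...``,
or a synset dump of ``synset_id<TAB>word`` lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

_EMPTY: frozenset[str] = frozenset()


class LexiconParseError(ValueError):
    """Raised for a malformed lexicon line; names the offending line number."""


@dataclass(frozen=True)
class SynonymLexicon:
    """Mapping word -> nonempty synonym set; absent words map to the empty set."""

    entries: Mapping[str, frozenset[str]]

    @classmethod
    def from_dict(cls, raw: Mapping[str, Iterable[str]]) -> "SynonymLexicon":
        entries: dict[str, frozenset[str]] = {}
        for word, syns in raw.items():
            cleaned = frozenset(s for s in syns if s and s != word)
            if cleaned:
                entries[word] = cleaned
        return cls(entries=entries)

    def synonyms(self, word: str) -> frozenset[str]:
        return self.entries.get(word, _EMPTY)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SynonymLexicon):
            return NotImplemented
        return dict(self.entries) == dict(other.entries)


@dataclass(frozen=True)
class StopwordList:
    """Exact-match token set excluded from augmentation operations."""

    words: frozenset[str]
    source_name: str = "unnamed"

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)


EMPTY_STOPWORDS = StopwordList(words=frozenset(), source_name="empty")


def _iter_content_lines(path: Path):
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped


def load_synonyms(path: str | Path, fmt: str = "tsv") -> SynonymLexicon:
    """Load a synonym lexicon.

    ``fmt="tsv"``: ``word<TAB>comma,separated,synonyms`` per line.
    ``fmt="synset"``: ``synset_id<TAB>word`` per line; all words sharing a
    synset id become synonyms of one another.
    Duplicate entries merge by set union; self-mappings are dropped.
    """
    path = Path(path)
    merged: dict[str, set[str]] = {}
    if fmt == "tsv":
        for lineno, line in _iter_content_lines(path):
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0]:
                raise LexiconParseError(
                    f"{path.name}:{lineno}: expected 'word<TAB>synonyms', got {line!r}"
                )
            word, syns = parts
            merged.setdefault(word, set()).update(
                s for s in syns.split(",") if s
            )
    elif fmt == "synset":
        synsets: dict[str, set[str]] = {}
        for lineno, line in _iter_content_lines(path):
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise LexiconParseError(
                    f"{path.name}:{lineno}: expected 'synset_id<TAB>word', got {line!r}"
                )
            synsets.setdefault(parts[0], set()).add(parts[1])
        for members in synsets.values():
            for word in members:
                merged.setdefault(word, set()).update(members - {word})
    else:
        raise ValueError(f"unknown lexicon format {fmt!r}")
    return SynonymLexicon.from_dict(merged)


def write_synonyms(lexicon: SynonymLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word in sorted(lexicon.entries):
            fh.write(f"{word}\t{','.join(sorted(lexicon.entries[word]))}\n")


def load_stopwords(
    path: str | Path, exclusions: Iterable[str] = ()
) -> StopwordList:
    """Load a stopword list, dropping the given exclusions.

    The exclusion mechanism mirrors curating a general-purpose list down
    to augmentation-safe stopwords (e.g. removing pronouns/directives that
    carry diagnostic signal and must remain augmentable).
    """
    path = Path(path)
    words = {word for _, word in _iter_content_lines(path)}
    result = frozenset(words - set(exclusions))
    logger.info("loaded %d stopwords from %s", len(result), path.name)
    return StopwordList(words=result, source_name=path.name)


def write_stopwords(stopwords: StopwordList, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word in sorted(stopwords.words):
            fh.write(word + "\n")


def is_stopword(word: str, stopwords: StopwordList) -> bool:
    """Exact-match membership; no case or width normalization is applied."""
    return word in stopwords
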