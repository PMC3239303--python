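"""Dictionary-based named-entity recognition with grounding.

Entries map a surface form (one or more tokens) to a grounding identifier
(e.g. a UniProt accession) and a set of ontology concept labels.  One
surface form may legitimately carry several labels -- gene/protein
metonymy means ``himA`` is both a Gene and (as its product) a
TranscriptionFactor -- and downstream concept constraints accept a mention
if ANY of its labels satisfies them.

Recognition is left-to-right longest match over contiguous tokens,
case-sensitive by default (``fimA`` vs ``FimA`` is meaningful for
bacterial gene symbols).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable

from .ontology import Ontology
from .syntax import DependencyGraph

__all__ = ["Dictionary", "DictionaryError", "EntityMention", "load_dictionary", "recognize"]


class DictionaryError(ValueError):
    pass


@dataclass(frozen=True)
class EntityMention:
    """A grounded dictionary hit on a token span (half-open)."""

    doc_id: str
    sentence_index: int
    start: int  # first token index (1-based)
    end: int  # one past the last token index
    surface: str
    grounding_id: str
    concepts: tuple[str, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Dictionary:
    """surface form -> (grounding ID, concept labels)."""

    entries: dict[tuple[str, ...], tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    case_sensitive: bool = True

    def __len__(self) -> int:
        return len(self.entries)

    def _key(self, tokens: Iterable[str]) -> tuple[str, ...]:
        return tuple(t if self.case_sensitive else t.lower() for t in tokens)

    def add(self, surface: str, grounding_id: str, concepts: Iterable[str], ont: Ontology) -> None:
        tokens = surface.split()
        if not tokens:
            raise DictionaryError("empty surface form")
        labels = tuple(ont.require_concept(c) for c in concepts)
        if not labels:
            raise DictionaryError(f"entry {surface!r} has no concept labels")
        self.entries[self._key(tokens)] = (grounding_id, labels)

    def lookup(self, tokens: Iterable[str]) -> tuple[str, tuple[str, ...]] | None:
        return self.entries.get(self._key(tokens))

    @property
    def max_len(self) -> int:
        return max((len(k) for k in self.entries), default=0)


def load_dictionary(source: str | IO[str], ont: Ontology, case_sensitive: bool = True) -> Dictionary:
    """Load a TSV dictionary: ``surface<TAB>grounding-id<TAB>label,label``."""
    if hasattr(source, "read"):
        rows = list(csv.reader(source, delimiter="\t"))  # type: ignore[arg-type]
    else:
        with open(source, encoding="utf-8", newline="") as handle:
            rows = list(csv.reader(handle, delimiter="\t"))
    dictionary = Dictionary(case_sensitive=case_sensitive)
    for rowno, row in enumerate(rows, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if row[0].lstrip().startswith("#"):
            continue
        if len(row) != 3:
            raise DictionaryError(f"row {rowno}: expected 3 tab-separated columns, got {len(row)}")
        surface, grounding_id, labels = (col.strip() for col in row)
        try:
            dictionary.add(surface, grounding_id, [c.strip() for c in labels.split(",") if c.strip()], ont)
        except (DictionaryError, Exception) as exc:
            raise DictionaryError(f"row {rowno}: {exc}") from exc
    return dictionary


def recognize(sentence: DependencyGraph, dictionary: Dictionary) -> list[EntityMention]:
    """Left-to-right longest-match recognition; mentions never overlap."""
    forms = [tok.form for tok in sentence]
    n = len(forms)
    mentions: list[EntityMention] = []
    i = 0
    limit = dictionary.max_len
    while i < n:
        hit = None
        for width in range(min(limit, n - i), 0, -1):
            entry = dictionary.lookup(forms[i : i + width])
            if entry is not None:
                hit = (width, entry)
                break
        if hit is None:
            i += 1
            continue
        width, (grounding_id, labels) = hit
        mentions.append(
            EntityMention(
                doc_id=sentence.doc_id,
                sentence_index=sentence.sentence_index,
                start=i + 1,
                end=i + 1 + width,
                surface=" ".join(forms[i : i + width]),
                grounding_id=grounding_id,
                concepts=labels,
            )
        )
        i += width
    return mentions


def mention_head(mention: EntityMention, graph: DependencyGraph) -> int:
    """The token of a mention whose head lies outside the span (its
    syntactic head), falling back to the last token."""
    span = range(mention.start, mention.end)
    for index in span:
        if graph.token(index).head not in span:
            return index
    return mention.end - 1
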