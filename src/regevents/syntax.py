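"""Per-sentence dependency trees and a CoNLL-U/CoNLL-X reader.

Patterns speak a small fixed vocabulary -- coarse POS tags ``Verb``,
``Noun``, ``Prep``, ``Adj``, ``Other`` and normalized syntactic roles
``Subject``, ``Object``, ``PrepObject``, ``Conj``, ``Other`` -- so a
:class:`TagMap` is the porting layer from whatever tagset and relation
inventory the upstream parser used.  The default map covers both UD-style
(nsubj/obj/nmod) and Stanford-style (nsubj/dobj/prep/pobj) labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "Token",
    "DependencyGraph",
    "TagMap",
    "SyntaxError_",
    "DEFAULT_TAGMAP",
    "read_conll",
    "parse_conll",
    "descendants",
]

COARSE_POS = ("Verb", "Noun", "Prep", "Adj", "Other")
ROLES = ("Subject", "Object", "PrepObject", "Conj", "Other")


class SyntaxError_(ValueError):
    """Malformed CoNLL input or an invalid tree."""


@dataclass(frozen=True)
class Token:
    index: int  # 1-based, CoNLL convention
    form: str
    lemma: str
    pos: str  # coarse POS
    head: int  # 0 for root
    relation: str  # raw dependency label
    role: str  # normalized role


@dataclass
class TagMap:
    """POS-tag and relation-label normalization tables.

    Unknown tags normalize to ``Other``, so the map is total over any
    input.  Files use two whitespace-separated columns with ``pos`` /
    ``rel`` section headers (``pos NOUN Noun``, ``rel nsubj Subject``).
    """

    pos: dict[str, str] = field(default_factory=dict)
    relations: dict[str, str] = field(default_factory=dict)

    def coarse_pos(self, tag: str) -> str:
        return self.pos.get(tag, "Other")

    def role(self, relation: str) -> str:
        return self.relations.get(relation, self.relations.get(relation.split(":")[0], "Other"))

    @classmethod
    def load(cls, source: str | IO[str]) -> "TagMap":
        if hasattr(source, "read"):
            lines = source.read().splitlines()  # type: ignore[union-attr]
        else:
            with open(source, encoding="utf-8") as handle:
                lines = handle.read().splitlines()
        out = cls()
        for lineno, raw in enumerate(lines, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3 or parts[0] not in ("pos", "rel"):
                raise SyntaxError_(f"line {lineno}: cannot parse tagmap entry {raw!r}")
            (out.pos if parts[0] == "pos" else out.relations)[parts[1]] = parts[2]
        return out


DEFAULT_TAGMAP = TagMap(
    pos={
        "VERB": "Verb", "AUX": "Verb",
        "NOUN": "Noun", "PROPN": "Noun", "PRON": "Noun",
        "ADP": "Prep", "IN": "Prep",
        "ADJ": "Adj",
        # Penn tags, for CoNLL-X input
        "VB": "Verb", "VBD": "Verb", "VBG": "Verb", "VBN": "Verb", "VBP": "Verb", "VBZ": "Verb",
        "NN": "Noun", "NNS": "Noun", "NNP": "Noun", "NNPS": "Noun",
        "JJ": "Adj",
        # identity on the coarse tags themselves, so serialized output re-reads
        "Verb": "Verb", "Noun": "Noun", "Prep": "Prep", "Adj": "Adj",
    },
    relations={
        "nsubj": "Subject", "nsubjpass": "Subject", "csubj": "Subject",
        "obj": "Object", "dobj": "Object",
        "pobj": "PrepObject", "obl": "PrepObject", "nmod": "PrepObject", "iobj": "PrepObject",
        "conj": "Conj",
    },
)


@dataclass
class DependencyGraph:
    """A rooted dependency tree for one sentence."""

    tokens: dict[int, Token]
    sentence_index: int = 0
    doc_id: str = "doc"
    sent_id: str | None = None

    def __post_init__(self) -> None:
        self._children: dict[int, list[int]] = {}
        self.validate()

    def validate(self) -> None:
        indices = sorted(self.tokens)
        if not indices:
            raise SyntaxError_("empty sentence")
        if indices != list(range(1, len(indices) + 1)):
            raise SyntaxError_(f"token indices not contiguous from 1: {indices}")
        roots = [t.index for t in self.tokens.values() if t.head == 0]
        if len(roots) != 1:
            raise SyntaxError_(f"expected exactly one root, found {roots}")
        children: dict[int, list[int]] = {i: [] for i in indices}
        for tok in self.tokens.values():
            if tok.head != 0:
                if tok.head not in self.tokens:
                    raise SyntaxError_(f"token {tok.index} heads to missing index {tok.head}")
                children[tok.head].append(tok.index)
        # reachability from the root proves acyclicity (n tokens, n-1 edges)
        seen = set()
        stack = [roots[0]]
        while stack:
            node = stack.pop()
            seen.add(node)
            stack.extend(children[node])
        if len(seen) != len(indices):
            cyclic = sorted(set(indices) - seen)
            raise SyntaxError_(f"head links contain a cycle involving tokens {cyclic}")
        self._children = {i: sorted(kids) for i, kids in children.items()}
        self.root = roots[0]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens[i] for i in sorted(self.tokens))

    def token(self, index: int) -> Token:
        try:
            return self.tokens[index]
        except KeyError:
            raise SyntaxError_(f"no token with index {index}") from None

    def children(self, index: int) -> list[int]:
        self.token(index)
        return list(self._children[index])

    def depth(self, index: int) -> int:
        depth = 0
        tok = self.token(index)
        while tok.head != 0:
            depth += 1
            tok = self.tokens[tok.head]
        return depth

    def path_from(self, ancestor: int, node: int) -> list[int] | None:
        """Token indices from *ancestor* (exclusive) down to *node*
        (inclusive), or None if *ancestor* does not dominate *node*."""
        path = []
        current = node
        while current != ancestor:
            path.append(current)
            head = self.token(current).head
            if head == 0:
                return None
            current = head
        return list(reversed(path))

    def dominates(self, ancestor: int, node: int) -> bool:
        return ancestor != node and self.path_from(ancestor, node) is not None

    def text(self) -> str:
        return " ".join(tok.form for tok in self)

    def postorder(self) -> list[int]:
        out: list[int] = []

        def visit(node: int) -> None:
            for child in self._children[node]:
                visit(child)
            out.append(node)

        visit(self.root)
        return out


def descendants(graph: DependencyGraph, node: int) -> list[int]:
    """All strict descendants, ordered by (tree depth, surface position)."""
    graph.token(node)
    out: list[tuple[int, int]] = []
    frontier = [(1, child) for child in graph.children(node)]
    while frontier:
        depth, current = frontier.pop()
        out.append((depth, current))
        frontier.extend((depth + 1, child) for child in graph.children(current))
    return [index for _, index in sorted(out)]


def _conll_sentences(lines: Iterable[str]) -> Iterator[tuple[str, str | None, list[tuple[int, str]]]]:
    doc_id = "doc"
    sent_id: str | None = None
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.startswith("#"):
            comment = line[1:].strip()
            if comment.startswith("newdoc"):
                if block:
                    yield doc_id, sent_id, block
                    block, sent_id = [], None
                doc_id = comment.split("=", 1)[1].strip() if "=" in comment else "doc"
            elif comment.startswith("sent_id"):
                sent_id = comment.split("=", 1)[1].strip() if "=" in comment else None
            continue
        if not line.strip():
            if block:
                yield doc_id, sent_id, block
                block, sent_id = [], None
            continue
        block.append((lineno, line))
    if block:
        yield doc_id, sent_id, block


def parse_conll(text: str, tagmap: TagMap | None = None) -> list[DependencyGraph]:
    return read_conll(text.splitlines(), tagmap)


def read_conll(source: str | IO[str] | Iterable[str], tagmap: TagMap | None = None) -> list[DependencyGraph]:
    """Read CoNLL-U or CoNLL-X sentences into dependency graphs.

    ``# newdoc id = X`` comments set the document ID of the following
    sentences; multiword-token and empty-node lines (IDs with ``-`` or
    ``.``) are skipped.
    """
    tagmap = tagmap or DEFAULT_TAGMAP
    if hasattr(source, "read"):
        lines: Iterable[str] = source.read().splitlines()  # type: ignore[union-attr]
    elif isinstance(source, str):
        with open(source, encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    else:
        lines = source

    graphs: list[DependencyGraph] = []
    per_doc_counter: dict[str, int] = {}
    for doc_id, sent_id, block in _conll_sentences(lines):
        tokens: dict[int, Token] = {}
        for lineno, line in block:
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 8:
                raise SyntaxError_(f"line {lineno}: expected >=8 CoNLL columns, got {len(cols)}")
            if "-" in cols[0] or "." in cols[0]:
                continue  # multiword token / empty node
            try:
                index = int(cols[0])
                head = int(cols[6]) if cols[6] != "_" else 0
            except ValueError as exc:
                raise SyntaxError_(f"line {lineno}: bad index/head field: {exc}") from None
            form = cols[1]
            lemma = cols[2] if cols[2] != "_" else form.lower()
            upos = cols[3] if cols[3] != "_" else cols[4]
            relation = cols[7]
            tokens[index] = Token(
                index=index,
                form=form,
                lemma=lemma,
                pos=tagmap.coarse_pos(upos),
                head=head,
                relation=relation,
                role=tagmap.role(relation),
            )
        index_in_doc = per_doc_counter.get(doc_id, 0)
        per_doc_counter[doc_id] = index_in_doc + 1
        graphs.append(
            DependencyGraph(tokens=tokens, sentence_index=index_in_doc, doc_id=doc_id, sent_id=sent_id)
        )
    return graphs


def to_conll(graphs: Iterable[DependencyGraph]) -> str:
    """Serialize graphs back to CoNLL-U (10 columns, one doc per newdoc)."""
    out: list[str] = []
    last_doc = None
    for graph in graphs:
        if graph.doc_id != last_doc:
            out.append(f"# newdoc id = {graph.doc_id}")
            last_doc = graph.doc_id
        if graph.sent_id:
            out.append(f"# sent_id = {graph.sent_id}")
        out.append(f"# text = {graph.text()}")
        for tok in graph:
            out.append(
                "\t".join(
                    [
                        str(tok.index), tok.form, tok.lemma, tok.pos, "_", "_",
                        str(tok.head), tok.relation, "_", "_",
                    ]
                )
            )
        out.append("")
    return "\n".join(out) + "\n"
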