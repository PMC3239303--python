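"""Syntactic-semantic paired patterns and bottom-up event composition.

A pattern pairs a syntactic tree fragment with a semantic structure that
shares its variables::

    (cause_Verb Subject:Agent Object:Patient)    <RegulatoryProcess hasAgent=Agent hasPatient=Patient>

The syntactic head (``cause_Verb``) must match a token by lemma and coarse
POS.  Dependent items are matched *loosely*: a dependent may bind any
descendant of the head-matched node, not only a direct child, under three
restrictive conditions:

1. an item with a syntactic role (``Subject:``/``Object:``) only matches
   inside a subtree that actually bears that role -- some node on the path
   from the head down to the candidate must carry the role (a
   ``PrepObject`` satisfies an ``Object`` requirement, since a
   prepositional object is the object of its preposition);
2. distinct branches of one pattern instance claim disjoint, mutually
   non-dominating subtrees -- once a branch has matched a node, no other
   branch may match that node or anything above/below it;
3. the head-to-candidate path may not cross a clausal boundary (a node
   whose lemma, or one of whose direct children's lemmas, is a relative
   pronoun / complementizer) nor an exception word (``except``,
   ``unless``, ``without``); both lists are configurable.

Composition walks each sentence tree in post-order.  Entity mentions seed
their head tokens with atomic semantics; every pattern match instantiates
its semantic half with the semantics of the bound descendants and stacks
the result on the matched node, so phrase semantics grows into sentential
semantics.  When a dependent has several eligible candidates naming
different entities (coordination), one instantiation per candidate is
produced; alternatives that bind the *same* entities (e.g. a structure and
the bare mention inside it) collapse onto the structurally preferred one
(minimal depth, then leftmost).  Structures consumed as slot fillers of a
larger structure are not emitted as separate events: only the maximal
structures become explicit events.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import IO, Iterator, Sequence

from .entities import EntityMention, mention_head
from .ontology import Ontology, OntologyError
from .semantics import (
    Call,
    EntityRef,
    Event,
    Literal,
    SemanticStructure,
    Value,
    Var,
    canonical,
    iter_entity_refs,
    value_satisfies_concept,
)
from .syntax import DependencyGraph, descendants

__all__ = [
    "MatchConfig",
    "PatternError",
    "PatternPair",
    "SynItem",
    "MatchResult",
    "parse_pattern",
    "load_patterns",
    "default_patterns",
    "match_at",
    "compose",
    "annotate",
    "SentenceAnnotation",
]


class PatternError(ValueError):
    pass


DEFAULT_BOUNDARY = frozenset(
    {"which", "that", "who", "whom", "whose", "when", "where", "because", "although", "while", "if"}
)
DEFAULT_EXCEPTIONS = frozenset({"except", "unless", "without"})
DEFAULT_NEGATION_CUES = frozenset({"not", "no", "never", "cannot", "fail"})


@dataclass(frozen=True)
class MatchConfig:
    """Tunable lists for loose matching; defaults follow the module doc."""

    boundary_lemmas: frozenset[str] = DEFAULT_BOUNDARY
    exception_lemmas: frozenset[str] = DEFAULT_EXCEPTIONS
    negation_cues: frozenset[str] = DEFAULT_NEGATION_CUES
    # roles accepted when a pattern item demands a given role
    role_satisfiers: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("Subject", ("Subject",)),
        ("Object", ("Object", "PrepObject")),
    )

    def satisfies_role(self, required: str, actual: str) -> bool:
        for role, accepted in self.role_satisfiers:
            if role == required:
                return actual in accepted
        return actual == required


@dataclass
class SynItem:
    """One node of a syntactic pattern tree."""

    lexeme: str | None = None
    pos: str | None = None
    role: str | None = None
    var: Var | None = None
    children: list["SynItem"] = field(default_factory=list)

    def variables(self) -> list[Var]:
        out = [self.var] if self.var else []
        for child in self.children:
            out.extend(child.variables())
        return out


@dataclass
class PatternPair:
    id: str
    syntax: SynItem
    semantics: SemanticStructure
    source: str = ""

    def variables(self) -> set[str]:
        return {v.name for v in self.syntax.variables()}


@dataclass
class MatchResult:
    pattern_id: str
    head_node: int
    bindings: dict[str, tuple[int, Value]]
    matched_nodes: tuple[int, ...]  # nodes claimed by dependent branches
    structure: SemanticStructure


# --------------------------------------------------------------------------
# DSL parsing

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_POS_TAGS = ("Verb", "Noun", "Prep", "Adj", "Other")


def _tokenize_syn(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def _make_var(name: str, ont: Ontology) -> Var:
    # A variable named after a declared concept carries that concept as a
    # binding constraint (e.g. Gene, TranscriptionFactor); other names
    # (Agent, Patient) are unconstrained.
    if ont.is_concept(name):
        return Var(name, ont.resolve(name))
    return Var(name)


def _parse_syn_item(tokens: list[str], pos_: list[int], ont: Ontology) -> SynItem:
    tok = tokens[pos_[0]]
    if tok == "(":
        pos_[0] += 1
        head = _parse_syn_atom(tokens[pos_[0]], ont, head=True)
        pos_[0] += 1
        while pos_[0] < len(tokens) and tokens[pos_[0]] != ")":
            head.children.append(_parse_syn_item(tokens, pos_, ont))
        if pos_[0] >= len(tokens):
            raise PatternError("unbalanced parentheses in syntactic pattern")
        pos_[0] += 1  # consume ')'
        return head
    pos_[0] += 1
    return _parse_syn_atom(tok, ont, head=False)


def _parse_syn_atom(token: str, ont: Ontology, head: bool) -> SynItem:
    if token in ("(", ")"):
        raise PatternError(f"unexpected {token!r} in syntactic pattern")
    if ":" in token:
        role, varname = token.split(":", 1)
        if role not in ("Subject", "Object", "PrepObject", "Conj"):
            raise PatternError(f"unknown syntactic role {role!r}")
        return SynItem(role=role, var=_make_var(varname, ont))
    if "_" in token:
        lexeme, pos = token.rsplit("_", 1)
        if pos in _POS_TAGS:
            return SynItem(lexeme=lexeme, pos=pos)
    if head:
        raise PatternError(f"pattern head must be lexeme_POS, got {token!r}")
    return SynItem(var=_make_var(token, ont))


def _parse_sem_value(text: str, pos_: list[int], ont: Ontology, allow_calls: bool) -> Value:
    text = text
    if text[pos_[0]] == "<":
        return _parse_sem_struct(text, pos_, ont, allow_calls)
    if text[pos_[0]] in "\"'":
        quote = text[pos_[0]]
        end = text.index(quote, pos_[0] + 1)
        value = text[pos_[0] + 1 : end]
        pos_[0] = end + 1
        return Literal(value)
    match = re.match(r"[A-Za-z_][A-Za-z0-9_]*", text[pos_[0] :])
    if not match:
        raise PatternError(f"cannot parse semantic value at ...{text[pos_[0]:pos_[0]+20]!r}")
    name = match.group(0)
    pos_[0] += len(name)
    if pos_[0] < len(text) and text[pos_[0]] == "(":
        if not allow_calls:
            raise PatternError(f"function call {name!r} not allowed here")
        pos_[0] += 1
        args: list[Var | Literal] = []
        while text[pos_[0]] != ")":
            if text[pos_[0]] in ", ":
                pos_[0] += 1
                continue
            arg = _parse_sem_value(text, pos_, ont, allow_calls=False)
            if isinstance(arg, (Var, Literal)):
                args.append(arg)
            else:
                raise PatternError("function arguments must be variables or literals")
        pos_[0] += 1
        return Call(name, tuple(args))
    return _make_var(name, ont)


def _parse_sem_struct(text: str, pos_: list[int], ont: Ontology, allow_calls: bool) -> SemanticStructure:
    if text[pos_[0]] != "<":
        raise PatternError(f"expected '<' at position {pos_[0]} of {text!r}")
    pos_[0] += 1
    match = re.match(r"\s*([A-Za-z_][A-Za-z0-9_]*)", text[pos_[0] :])
    if not match:
        raise PatternError(f"missing concept name in {text!r}")
    concept = ont.require_concept(match.group(1))
    pos_[0] += match.end()
    slots: dict[str, Value] = {}
    while True:
        while pos_[0] < len(text) and text[pos_[0]].isspace():
            pos_[0] += 1
        if pos_[0] >= len(text):
            raise PatternError(f"unterminated structure in {text!r}")
        if text[pos_[0]] == ">":
            pos_[0] += 1
            return SemanticStructure(concept, slots)
        match = re.match(r"([A-Za-z_][A-Za-z0-9_]*)\s*=\s*", text[pos_[0] :])
        if not match:
            raise PatternError(f"cannot parse slot at ...{text[pos_[0]:pos_[0]+25]!r}")
        prop = ont.require_property(match.group(1))
        pos_[0] += match.end()
        slots[prop] = _parse_sem_value(text, pos_, ont, allow_calls)


def parse_semantic_structure(text: str, ont: Ontology, allow_calls: bool = False) -> SemanticStructure:
    """Parse one angle-bracket semantic structure (curly quotes accepted)."""
    text = text.strip().replace("“", '"').replace("”", '"').replace("‘", "'").replace("’", "'")
    pos_ = [0]
    struct = _parse_sem_struct(text, pos_, ont, allow_calls)
    if text[pos_[0] :].strip():
        raise PatternError(f"trailing text after structure: {text[pos_[0]:]!r}")
    return struct


def parse_pattern(text: str, ont: Ontology, pattern_id: str = "p") -> PatternPair:
    """Parse one ``SYNTACTIC<TAB>SEMANTIC`` pattern line."""
    parts = [p for p in text.split("\t") if p.strip()]
    if len(parts) == 3:
        pattern_id, syn_text, sem_text = (p.strip() for p in parts)
    elif len(parts) == 2:
        syn_text, sem_text = (p.strip() for p in parts)
    else:
        raise PatternError("pattern line must be 'SYNTACTIC<TAB>SEMANTIC' (optionally 'id<TAB>...')")
    tokens = _tokenize_syn(syn_text)
    if not tokens or tokens[0] != "(":
        raise PatternError(f"syntactic pattern must start with '(': {syn_text!r}")
    pos_ = [0]
    syntax = _parse_syn_item(tokens, pos_, ont)
    if pos_[0] != len(tokens):
        raise PatternError(f"trailing tokens in syntactic pattern: {tokens[pos_[0]:]}")
    if syntax.lexeme is None or syntax.pos is None:
        raise PatternError("pattern head must carry a lexeme and POS")
    semantics = parse_semantic_structure(sem_text, ont, allow_calls=False)
    syn_vars = {v.name for v in syntax.variables()}
    unbound = semantics.variables() - syn_vars
    if unbound:
        raise PatternError(f"semantic variables {sorted(unbound)} are not bound by the syntactic pattern")
    return PatternPair(id=pattern_id, syntax=syntax, semantics=semantics, source=text.strip())


def load_patterns(source: str | IO[str], ont: Ontology) -> list[PatternPair]:
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        with open(source, encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    patterns: list[PatternPair] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            patterns.append(parse_pattern(raw, ont, pattern_id=f"p{len(patterns) + 1}"))
        except (PatternError, OntologyError) as exc:
            raise PatternError(f"line {lineno}: {exc}") from exc
    return patterns


def default_patterns(ont: Ontology) -> list[PatternPair]:
    text = _importlib_resources.files("regevents.resources").joinpath("patterns.tsv").read_text()
    import io

    return load_patterns(io.StringIO(text), ont)


# --------------------------------------------------------------------------
# Loose matching

def _path_clear(graph: DependencyGraph, anchor: int, node: int, config: MatchConfig) -> bool:
    path = graph.path_from(anchor, node)
    if path is None:
        return False
    blocked = config.boundary_lemmas | config.exception_lemmas
    for mid in path[:-1]:  # nodes strictly between anchor and candidate
        tok = graph.token(mid)
        if tok.lemma.lower() in blocked:
            return False
        for child in graph.children(mid):
            if graph.token(child).lemma.lower() in config.boundary_lemmas:
                return False  # mid heads a clause (relativizer/complementizer child)
    return True


def _role_on_path(graph: DependencyGraph, anchor: int, node: int, role: str, config: MatchConfig) -> bool:
    path = graph.path_from(anchor, node)
    if path is None:
        return False
    return any(config.satisfies_role(role, graph.token(n).role) for n in path)


def _lemma_matches(item: SynItem, graph: DependencyGraph, node: int) -> bool:
    tok = graph.token(node)
    return tok.lemma.lower() == (item.lexeme or "").lower() and tok.pos == item.pos


def _candidates(
    item: SynItem,
    anchor: int,
    chain: frozenset[int],
    taken: tuple[int, ...],
    graph: DependencyGraph,
    semantics_index: dict[int, list[Value]],
    ont: Ontology,
    config: MatchConfig,
) -> Iterator[tuple[int, Value | None]]:
    for node in descendants(graph, anchor):  # ordered by (depth, surface position)
        if any(
            t == node or graph.dominates(t, node) or graph.dominates(node, t)
            for t in taken
            if t not in chain
        ):
            continue  # condition 2: branches claim non-dominating subtrees
        if not _path_clear(graph, anchor, node, config):
            continue  # condition 3
        if item.role and not _role_on_path(graph, anchor, node, item.role, config):
            continue  # condition 1
        if item.lexeme is not None and not _lemma_matches(item, graph, node):
            continue
        if item.var is not None:
            for sem in semantics_index.get(node, []):
                if item.var.concept is not None and not value_satisfies_concept(sem, item.var.concept, ont):
                    continue
                yield node, sem
        else:
            yield node, None


def _assign(
    items: Sequence[SynItem],
    index: int,
    anchor: int,
    chain: frozenset[int],
    taken: tuple[int, ...],
    binding: dict[str, tuple[int, Value]],
    graph: DependencyGraph,
    semantics_index: dict[int, list[Value]],
    ont: Ontology,
    config: MatchConfig,
) -> Iterator[tuple[dict[str, tuple[int, Value]], tuple[int, ...]]]:
    if index == len(items):
        yield dict(binding), taken
        return
    item = items[index]
    for node, sem in _candidates(item, anchor, chain, taken, graph, semantics_index, ont, config):
        new_binding = dict(binding)
        if item.var is not None:
            assert sem is not None
            new_binding[item.var.name] = (node, sem)
        new_taken = taken + (node,)
        if item.children:
            sub_chain = chain | {node}
            for deep_binding, deep_taken in _assign(
                item.children, 0, node, sub_chain, new_taken, new_binding,
                graph, semantics_index, ont, config,
            ):
                yield from _assign(
                    items, index + 1, anchor, chain, deep_taken, deep_binding,
                    graph, semantics_index, ont, config,
                )
        else:
            yield from _assign(
                items, index + 1, anchor, chain, new_taken, new_binding,
                graph, semantics_index, ont, config,
            )


def _instantiate(pattern_sem: SemanticStructure, binding: dict[str, tuple[int, Value]]) -> SemanticStructure:
    slots: dict[str, Value] = {}
    for prop, value in pattern_sem.slots.items():
        if isinstance(value, Var):
            slots[prop] = binding[value.name][1]
        elif isinstance(value, SemanticStructure):
            slots[prop] = _instantiate(value, binding)
        elif isinstance(value, Literal):
            slots[prop] = value
        else:
            raise PatternError(f"unexpected value in pattern semantics: {value!r}")
    return SemanticStructure(pattern_sem.concept, slots)


def _signature(binding: dict[str, tuple[int, Value]]):
    parts = []
    for name in sorted(binding):
        _, value = binding[name]
        mentions = frozenset(ref.grounding_id for ref in iter_entity_refs(value))
        parts.append((name, mentions if mentions else canonical(value)))
    return tuple(parts)


def match_at(
    pattern: PatternPair,
    node: int,
    graph: DependencyGraph,
    semantics_index: dict[int, list[Value]],
    ont: Ontology,
    config: MatchConfig | None = None,
) -> list[MatchResult]:
    """All loose matches of *pattern* rooted at *node*.

    ``semantics_index`` must already hold the semantics of all strict
    descendants of *node* (the bottom-up discipline of :func:`compose`).
    Alternatives that bind the same entities collapse onto the
    structurally preferred assignment; alternatives binding different
    entities (coordination) are all returned.
    """
    config = config or MatchConfig()
    head = pattern.syntax
    if not _lemma_matches(head, graph, node):
        return []
    results: list[MatchResult] = []
    seen = set()
    for binding, taken in _assign(
        head.children, 0, node, frozenset({node}), (node,), {},
        graph, semantics_index, ont, config,
    ):
        signature = _signature(binding)
        if signature in seen:
            continue
        seen.add(signature)
        results.append(
            MatchResult(
                pattern_id=pattern.id,
                head_node=node,
                bindings=binding,
                matched_nodes=tuple(t for t in taken if t != node),
                structure=_instantiate(pattern.semantics, binding),
            )
        )
    return results


# --------------------------------------------------------------------------
# Bottom-up composition

@dataclass
class SentenceAnnotation:
    """Per-node semantics accumulated while composing one sentence."""

    graph: DependencyGraph
    semantics_index: dict[int, list[Value]]
    matches: list[MatchResult]
    consumed: set[int]  # id() of structures used as slot fillers
    entity_index: dict[int, EntityRef]

    def pattern_semantics(self, node: int) -> list[SemanticStructure]:
        """Pattern-assigned (non-entity) semantic structures at *node*."""
        return [v for v in self.semantics_index.get(node, []) if isinstance(v, SemanticStructure)]


def annotate(
    graph: DependencyGraph,
    mentions: Sequence[EntityMention],
    patterns: Sequence[PatternPair],
    ont: Ontology,
    config: MatchConfig | None = None,
) -> SentenceAnnotation:
    """Run bottom-up pattern matching over one sentence."""
    config = config or MatchConfig()
    semantics_index: dict[int, list[Value]] = {}
    entity_index: dict[int, EntityRef] = {}
    for mention in mentions:
        head = mention_head(mention, graph)
        ref = EntityRef(mention)
        semantics_index.setdefault(head, []).append(ref)
        entity_index[head] = ref
    matches: list[MatchResult] = []
    consumed: set[int] = set()
    for node in graph.postorder():
        node_results: list[MatchResult] = []
        for pattern in patterns:
            node_results.extend(match_at(pattern, node, graph, semantics_index, ont, config))
        for result in node_results:
            semantics_index.setdefault(node, []).append(result.structure)
            for _, value in result.bindings.values():
                consumed.add(id(value))
        matches.extend(node_results)
    return SentenceAnnotation(graph, semantics_index, matches, consumed, entity_index)


def compose(
    graph: DependencyGraph,
    mentions: Sequence[EntityMention],
    patterns: Sequence[PatternPair],
    ont: Ontology,
    config: MatchConfig | None = None,
) -> list[Event]:
    """Compose the maximal explicit events of one sentence."""
    config = config or MatchConfig()
    ann = annotate(graph, mentions, patterns, ont, config)
    events: list[Event] = []
    for result in ann.matches:
        if id(result.structure) in ann.consumed:
            continue  # absorbed into a larger structure; not a maximal event
        negated = any(
            graph.token(child).lemma.lower() in config.negation_cues
            for child in graph.children(result.head_node)
        )
        events.append(
            Event(
                struct=result.structure,
                origin="explicit",
                doc_id=graph.doc_id,
                sentences=(graph.sentence_index,),
                source_id=result.pattern_id,
                head_token=result.head_node,
                negated=negated,
            )
        )
    return events
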