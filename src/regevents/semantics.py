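"""Concept-rooted semantic structures and events.

A :class:`SemanticStructure` is a GRO concept with a slot map from property
names to values.  The same recursive shape serves four roles: the semantic
half of a syntactic-semantic pattern, the condition/conclusion of an
inference rule, a database-style extraction template, and a concrete
(ground) event.  Slot values are:

* another :class:`SemanticStructure` (compositional events -- an event
  participant may itself be an event),
* an :class:`EntityRef` pointing at a recognized entity mention,
* a :class:`Literal` string (e.g. polarity ``"negative"``, contact ``"yes"``),
* a :class:`Var` (pattern/rule/template side only), or
* a :class:`Call` (rule conclusions only, e.g. ``polarity_sum(P1,P2)``).

Ground structures have a canonical form -- a nested tuple in which entity
references collapse to their grounding IDs -- used for deduplication and
for the fixpoint test of the inference closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterator, Union

if TYPE_CHECKING:  # pragma: no cover
    from .entities import EntityMention
    from .ontology import Ontology

__all__ = [
    "Var",
    "Literal",
    "Call",
    "EntityRef",
    "SemanticStructure",
    "Event",
    "Value",
    "canonical",
    "value_satisfies_concept",
    "count_basic_instances",
    "iter_entity_refs",
]

POLARITY_VALUES = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class Var:
    """A variable slot; ``concept`` restricts what it may bind, if set."""

    name: str
    concept: str | None = None


@dataclass(frozen=True)
class Literal:
    value: str


@dataclass(frozen=True)
class Call:
    """A function application in a rule conclusion (``polarity_sum``)."""

    func: str
    args: tuple[Union[Var, Literal], ...]


@dataclass(frozen=True)
class EntityRef:
    """A ground reference to a recognized entity mention."""

    mention: "EntityMention"

    @property
    def grounding_id(self) -> str:
        return self.mention.grounding_id

    @property
    def labels(self) -> tuple[str, ...]:
        return self.mention.concepts


@dataclass
class SemanticStructure:
    concept: str
    slots: dict[str, "Value"] = field(default_factory=dict)

    def get(self, prop: str) -> "Value | None":
        return self.slots.get(prop)

    def is_ground(self) -> bool:
        return not any(isinstance(v, (Var, Call)) for v in _walk_values(self))

    def variables(self) -> set[str]:
        out: set[str] = set()
        for value in _walk_values(self):
            if isinstance(value, Var):
                out.add(value.name)
            elif isinstance(value, Call):
                out.update(a.name for a in value.args if isinstance(a, Var))
        return out

    def __repr__(self) -> str:  # compact angle-bracket form, mirrors the DSL
        inner = " ".join(f"{p}={_short(v)}" for p, v in self.slots.items())
        return f"<{self.concept}{' ' + inner if inner else ''}>"


Value = Union[SemanticStructure, EntityRef, Literal, Var, Call]


def _short(value: Value) -> str:
    if isinstance(value, SemanticStructure):
        return repr(value)
    if isinstance(value, EntityRef):
        return f"{value.mention.surface}[{value.grounding_id}]"
    if isinstance(value, Literal):
        return f'"{value.value}"'
    if isinstance(value, Var):
        return value.name
    return f"{value.func}({', '.join(_short(a) for a in value.args)})"


def _walk_values(struct: SemanticStructure) -> Iterator[Value]:
    for value in struct.slots.values():
        yield value
        if isinstance(value, SemanticStructure):
            yield from _walk_values(value)


def canonical(value: Value):
    """Canonical hashable form of a ground value.

    Entity references are identified by grounding ID, so the same name
    mentioned in two sentences canonicalizes identically -- this is what
    lets cross-sentence rule conditions unify on a shared participant.
    """
    if isinstance(value, SemanticStructure):
        return ("S", value.concept, tuple(sorted((p, canonical(v)) for p, v in value.slots.items())))
    if isinstance(value, EntityRef):
        return ("E", value.grounding_id)
    if isinstance(value, Literal):
        return ("L", value.value)
    raise TypeError(f"non-ground value has no canonical form: {value!r}")


def value_satisfies_concept(value: Value, concept: str, ont: "Ontology") -> bool:
    """Is *value* an instance of *concept* (or a sub-concept)?

    An entity mention satisfies the constraint if ANY of its concept labels
    does -- gene/protein metonymy means one surface form may be labelled
    both Gene and TranscriptionFactor.
    """
    concept = ont.require_concept(concept)
    if isinstance(value, SemanticStructure):
        return ont.is_subconcept(value.concept, concept)
    if isinstance(value, EntityRef):
        return any(ont.is_subconcept(label, concept) for label in value.labels)
    return False


def iter_entity_refs(value: Value) -> Iterator[EntityRef]:
    if isinstance(value, EntityRef):
        yield value
    elif isinstance(value, SemanticStructure):
        for sub in value.slots.values():
            yield from iter_entity_refs(sub)


def count_basic_instances(struct: SemanticStructure) -> int:
    """Number of concept-rooted event nodes in a compositional structure."""
    return 1 + sum(
        count_basic_instances(v) for v in struct.slots.values() if isinstance(v, SemanticStructure)
    )


@dataclass
class Event:
    """A ground semantic structure plus provenance.

    ``origin`` is ``"explicit"`` for events composed directly from a
    sentence by pattern matching and ``"inferred"`` for events deduced by
    forward chaining; inferred events reference their supporting events,
    so every provenance chain bottoms out in explicit events.
    """

    struct: SemanticStructure
    origin: str  # "explicit" | "inferred"
    doc_id: str
    sentences: tuple[int, ...] = ()
    source_id: str | None = None  # pattern id or rule id
    supports: tuple["Event", ...] = ()
    head_token: int | None = None  # trigger token of explicit events
    negated: bool = False

    def __post_init__(self) -> None:
        if not self.struct.is_ground():
            raise ValueError(f"event structure is not ground: {self.struct!r}")

    @property
    def key(self):
        return canonical(self.struct)

    def with_struct(self, struct: SemanticStructure) -> "Event":
        return replace(self, struct=struct)

    def trigger(self) -> tuple[int, int] | None:
        """(sentence, token) of the nearest explicit trigger in the chain."""
        if self.head_token is not None and self.sentences:
            return self.sentences[0], self.head_token
        for support in self.supports:
            found = support.trigger()
            if found is not None:
                return found
        return None
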