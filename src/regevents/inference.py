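"""Forward-chaining deduction of implicit events.

Inference rules have the propositional form ``P -> Q``: a list of
condition structures (sharing variables, which unify across conditions)
and a conclusion whose value positions may be variables, literals or a
``polarity_sum(P1,P2)`` call.  Rules are applied to a document's event set
with modus ponens -- whenever every condition matches some event, the
instantiated conclusion is added as an inferred event -- and re-applied
until no new event appears (the closure fixpoint).

Three semantic choices matter here:

* **Condition matching is one-way and subsumptive**: the event's concept
  must be the condition's concept or a sub-concept, every condition slot
  must exist in the event with a recursively matching value, and extra
  event slots are permitted.
* **Missing polarity defaults to positive**: a ``hasPolarity=Var``
  condition slot matches an event that carries no polarity by binding the
  variable to ``positive``, the NXOR identity, so defaulting is inert
  under composition.
* **Conclusions inherit**: the conclusion starts from the top-level slots
  of the event matched by the rule's first condition and applies its
  printed overrides, so a flattening rule rewrites one participant
  without discarding the rest of the event.

``polarity_sum`` composes two polarities as NXOR over
{positive -> true, negative -> false}; ``unknown`` absorbs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources as _importlib_resources
from typing import IO, Sequence

from .ontology import Ontology, OntologyError
from .patterns import PatternError, parse_semantic_structure
from .semantics import (
    Call,
    Event,
    Literal,
    POLARITY_VALUES,
    SemanticStructure,
    Value,
    Var,
    canonical,
    value_satisfies_concept,
)

__all__ = [
    "InferenceRule",
    "RuleError",
    "ClosureError",
    "parse_rule",
    "load_rules",
    "default_rules",
    "polarity_sum",
    "match_condition",
    "closure",
]

KNOWN_FUNCTIONS = ("polarity_sum",)


class RuleError(ValueError):
    pass


class ClosureError(RuntimeError):
    """Raised when the iteration cap is hit (a runaway rule set)."""


@dataclass
class InferenceRule:
    id: str
    conditions: list[SemanticStructure]
    conclusion: SemanticStructure
    source: str = ""

    def validate(self) -> None:
        condition_vars: set[str] = set()
        for cond in self.conditions:
            condition_vars |= cond.variables()
        unbound = self.conclusion.variables() - condition_vars
        if unbound:
            raise RuleError(f"rule {self.id}: conclusion variables {sorted(unbound)} unbound by conditions")
        for value in _walk(self.conclusion):
            if isinstance(value, Call) and value.func not in KNOWN_FUNCTIONS:
                raise RuleError(f"rule {self.id}: unknown function {value.func!r}")


def _walk(struct: SemanticStructure):
    for value in struct.slots.values():
        yield value
        if isinstance(value, SemanticStructure):
            yield from _walk(value)


def polarity_sum(p1: str, p2: str) -> str:
    """NXOR composition of regulation polarities.

    positive is the identity; two negatives make a positive; ``unknown``
    absorbs.  Restricted to {positive, negative} this is a commutative
    group in which every element is its own inverse.
    """
    for p in (p1, p2):
        if p not in POLARITY_VALUES:
            raise ValueError(f"not a polarity value: {p!r}")
    if "unknown" in (p1, p2):
        return "unknown"
    return "positive" if p1 == p2 else "negative"


def parse_rule(text: str, ont: Ontology, rule_id: str | None = None) -> InferenceRule:
    """Parse ``RULEID: <Cond> + <Cond> => <Conclusion>``."""
    body = text.strip()
    head_match = re.match(r"([A-Za-z0-9_.-]+)\s*:\s*(?=<)", body)
    if head_match:
        rule_id = head_match.group(1)
        body = body[head_match.end() :]
    if rule_id is None:
        rule_id = "rule"
    if "=>" not in body:
        raise RuleError(f"rule {rule_id}: missing '=>'")
    cond_text, concl_text = body.split("=>", 1)
    try:
        conditions = [
            parse_semantic_structure(part, ont, allow_calls=False)
            for part in cond_text.split("+")
            if part.strip()
        ]
        conclusion = parse_semantic_structure(concl_text, ont, allow_calls=True)
    except (PatternError, OntologyError) as exc:
        raise RuleError(f"rule {rule_id}: {exc}") from exc
    if not conditions:
        raise RuleError(f"rule {rule_id}: no conditions")
    rule = InferenceRule(id=rule_id, conditions=conditions, conclusion=conclusion, source=text.strip())
    rule.validate()
    return rule


def load_rules(source: str | IO[str], ont: Ontology) -> list[InferenceRule]:
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        with open(source, encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    rules = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rules.append(parse_rule(line, ont))
        except RuleError as exc:
            raise RuleError(f"line {lineno}: {exc}") from exc
    return rules


def default_rules(ont: Ontology) -> list[InferenceRule]:
    import io

    text = _importlib_resources.files("regevents.resources").joinpath("rules.txt").read_text()
    return load_rules(io.StringIO(text), ont)


# --------------------------------------------------------------------------
# Condition matching (one-way unification: pattern -> ground event)

def _bind(binding: dict[str, Value], var: Var, value: Value, ont: Ontology) -> dict[str, Value] | None:
    if var.concept is not None and not value_satisfies_concept(value, var.concept, ont):
        return None
    if var.name in binding:
        try:
            if canonical(binding[var.name]) != canonical(value):
                return None
        except TypeError:
            return None
        return binding
    out = dict(binding)
    out[var.name] = value
    return out


def _match_value(cval: Value, value: Value, binding: dict[str, Value], ont: Ontology) -> list[dict[str, Value]]:
    if isinstance(cval, Var):
        extended = _bind(binding, cval, value, ont)
        return [extended] if extended is not None else []
    if isinstance(cval, Literal):
        return [binding] if isinstance(value, Literal) and value.value == cval.value else []
    if isinstance(cval, SemanticStructure):
        if not isinstance(value, SemanticStructure):
            return []
        if not ont.is_subconcept(value.concept, cval.concept):
            return []
        return _match_slots(cval, value, binding, ont)
    raise RuleError(f"unexpected value in condition: {cval!r}")


def _match_slots(cond: SemanticStructure, struct: SemanticStructure, binding: dict[str, Value], ont: Ontology) -> list[dict[str, Value]]:
    bindings = [binding]
    for prop, cval in cond.slots.items():
        value = struct.slots.get(prop)
        if value is None:
            # missing polarity matches a polarity variable as the default
            if prop == "hasPolarity" and isinstance(cval, Var):
                value = Literal("positive")
            else:
                return []
        bindings = [b for current in bindings for b in _match_value(cval, value, current, ont)]
        if not bindings:
            return []
    return bindings


def match_condition(cond: SemanticStructure, event: Event | SemanticStructure, binding: dict[str, Value] | None, ont: Ontology) -> list[dict[str, Value]]:
    """All consistent extensions of *binding* matching *cond* to *event*."""
    struct = event.struct if isinstance(event, Event) else event
    if not ont.is_subconcept(struct.concept, cond.concept):
        return []
    return _match_slots(cond, struct, dict(binding or {}), ont)


# --------------------------------------------------------------------------
# Conclusion instantiation and closure

def _resolve(value: Value, binding: dict[str, Value]) -> Value:
    if isinstance(value, Var):
        try:
            return binding[value.name]
        except KeyError:
            raise RuleError(f"conclusion variable {value.name!r} unbound") from None
    if isinstance(value, Literal):
        return value
    if isinstance(value, Call):
        args = []
        for arg in value.args:
            resolved = _resolve(arg, binding)
            if not isinstance(resolved, Literal):
                raise RuleError(f"{value.func} applied to a non-polarity value: {resolved!r}")
            args.append(resolved.value)
        if value.func == "polarity_sum":
            if len(args) != 2:
                raise RuleError("polarity_sum takes exactly two arguments")
            return Literal(polarity_sum(*args))
        raise RuleError(f"unknown function {value.func!r}")
    if isinstance(value, SemanticStructure):
        return SemanticStructure(value.concept, {p: _resolve(v, binding) for p, v in value.slots.items()})
    return value


def instantiate_conclusion(rule: InferenceRule, binding: dict[str, Value], primary: Event) -> SemanticStructure:
    """Build the concluded structure: primary event's top-level slots,
    overridden by the conclusion's explicit slots."""
    slots: dict[str, Value] = dict(primary.struct.slots)
    for prop, cval in rule.conclusion.slots.items():
        slots[prop] = _resolve(cval, binding)
    return SemanticStructure(rule.conclusion.concept, slots)


def _rule_firings(rule: InferenceRule, universe: Sequence[Event], ont: Ontology):
    states: list[tuple[dict[str, Value], list[Event]]] = [({}, [])]
    for cond in rule.conditions:
        next_states = []
        for binding, supports in states:
            for event in universe:
                for extended in match_condition(cond, event, binding, ont):
                    next_states.append((extended, supports + [event]))
        states = next_states
        if not states:
            return
    yield from states


def closure(
    events: Sequence[Event],
    rules: Sequence[InferenceRule],
    ont: Ontology,
    max_passes: int = 100,
) -> list[Event]:
    """Smallest superset of *events* closed under *rules*.

    Input events are returned unchanged (closure is extensive); inferred
    events are deduplicated by the canonical form of their structure and
    carry the rule ID and supporting events as provenance.  The scope is
    intended to be one document, which is what lets multi-condition rules
    combine evidence from different sentences.
    """
    out = list(events)
    index: dict[object, Event] = {}
    unique: list[Event] = []
    for event in events:
        key = event.key
        if key not in index:
            index[key] = event
            unique.append(event)
    for _ in range(max_passes):
        added_this_pass = False
        for rule in rules:
            for binding, supports in _rule_firings(rule, list(unique), ont):
                struct = instantiate_conclusion(rule, binding, supports[0])
                key = canonical(struct)
                if key in index:
                    continue
                sentences = tuple(sorted({s for ev in supports for s in ev.sentences}))
                inferred = Event(
                    struct=struct,
                    origin="inferred",
                    doc_id=supports[0].doc_id,
                    sentences=sentences,
                    source_id=rule.id,
                    supports=tuple(supports),
                )
                index[key] = inferred
                unique.append(inferred)
                out.append(inferred)
                added_this_pass = True
        if not added_this_pass:
            return out
    raise ClosureError(f"no fixpoint after {max_passes} passes; rule set may generate unbounded structures")
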