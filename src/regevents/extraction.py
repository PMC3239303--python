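"""Template-based event selection, output writers and the scorer.

A template is a semantic structure whose ``?Concept`` positions are
variables that must bind recognized entities (label subsumption applies:
``?Protein`` accepts a mention labelled TranscriptionFactor) and whose
fixed parts restrict the event structure under concept subsumption.  Both
explicit and inferred events are candidates.  Each match yields a
database-ready :class:`ExtractionRecord` grounding its participants by
dictionary ID.

The scorer follows the standard two-participant criterion: a predicted
record is correct iff its document, agent ID and patient ID agree with a
gold record and its event type is the gold type or a sub-concept (a
RegulationOfTranscription prediction satisfies a RegulationOfGeneExpression
gold); polarity and physical contact are reported but excluded from
correctness.  ``unique`` mode collapses per-document duplicates before
counting, the protocol used when comparing against curated databases.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import IO, Sequence

import networkx as nx
import pandas as pd

from .entities import EntityMention
from .ontology import Ontology
from .patterns import PatternError, parse_semantic_structure
from .semantics import (
    EntityRef,
    Event,
    Literal,
    SemanticStructure,
    Value,
    Var,
)

__all__ = [
    "EventTemplate",
    "ExtractionRecord",
    "Metrics",
    "TemplateError",
    "parse_template",
    "load_templates",
    "default_templates",
    "match_template",
    "extract",
    "evaluate",
    "write_outputs",
    "events_to_json",
    "events_from_json",
]

_ROLE_BY_PROP = {"hasAgent": "agent", "hasPatient": "patient", "hasPart": "part"}


class TemplateError(ValueError):
    pass


@dataclass
class EventTemplate:
    id: str
    pattern: SemanticStructure
    label: str = ""
    roles: dict[str, str] = field(default_factory=dict)  # variable -> agent|patient|part

    def validate(self) -> None:
        if not self.pattern.variables():
            raise TemplateError(f"template {self.id} has no variables")


@dataclass(frozen=True)
class ExtractionRecord:
    template_id: str
    doc_id: str
    event_type: str
    bindings: tuple[tuple[str, tuple[str, str]], ...]  # var -> (grounding id, surface)
    polarity: str | None = None
    physical_contact: str | None = None
    event: Event | None = field(default=None, compare=False, hash=False)

    @property
    def binding_map(self) -> dict[str, tuple[str, str]]:
        return dict(self.bindings)

    @property
    def agent_id(self) -> str | None:
        return self.binding_map.get("agent", (None, None))[0]

    @property
    def patient_id(self) -> str | None:
        return self.binding_map.get("patient", (None, None))[0]


def _qvar_sub(text: str) -> str:
    counter = [0]

    def repl(match: re.Match) -> str:
        counter[0] += 1
        return f"QVAR{counter[0]}__{match.group(1)}"

    return re.sub(r"\?([A-Za-z_][A-Za-z0-9_]*)", repl, text)


def _rebind_qvars(struct: SemanticStructure, ont: Ontology) -> SemanticStructure:
    slots: dict[str, Value] = {}
    for prop, value in struct.slots.items():
        if isinstance(value, Var) and value.name.startswith("QVAR"):
            concept = value.name.split("__", 1)[1]
            slots[prop] = Var(value.name, ont.require_concept(concept))
        elif isinstance(value, SemanticStructure):
            slots[prop] = _rebind_qvars(value, ont)
        else:
            slots[prop] = value
    return SemanticStructure(struct.concept, slots)


def _assign_roles(struct: SemanticStructure, roles: dict[str, str], current: str | None = None) -> None:
    for prop, value in struct.slots.items():
        role = _ROLE_BY_PROP.get(prop, current) if current is None else current
        if isinstance(value, Var):
            roles[value.name] = role or "other"
        elif isinstance(value, SemanticStructure):
            _assign_roles(value, roles, role)


def parse_template(text: str, ont: Ontology, template_id: str = "t") -> EventTemplate:
    """Parse ``ID<TAB>TEMPLATE<TAB>label`` (or a bare template)."""
    parts = [p for p in text.split("\t") if p.strip()]
    label = ""
    if len(parts) == 3:
        template_id, body, label = (p.strip() for p in parts)
    elif len(parts) == 2:
        template_id, body = (p.strip() for p in parts)
    else:
        body = parts[0].strip()
    try:
        struct = parse_semantic_structure(_qvar_sub(body), ont, allow_calls=False)
    except PatternError as exc:
        raise TemplateError(f"template {template_id}: {exc}") from exc
    struct = _rebind_qvars(struct, ont)
    roles: dict[str, str] = {}
    _assign_roles(struct, roles)
    template = EventTemplate(id=template_id, pattern=struct, label=label, roles=roles)
    template.validate()
    return template


def load_templates(source: str | IO[str], ont: Ontology) -> list[EventTemplate]:
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        with open(source, encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    templates = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            templates.append(parse_template(raw, ont, template_id=f"t{len(templates) + 1}"))
        except TemplateError as exc:
            raise TemplateError(f"line {lineno}: {exc}") from exc
    return templates


def default_templates(ont: Ontology) -> list[EventTemplate]:
    import io

    text = _importlib_resources.files("regevents.resources").joinpath("templates.tsv").read_text()
    return load_templates(io.StringIO(text), ont)


# --------------------------------------------------------------------------
# Template matching

def _match_fixed(tval: Value, value: Value, binding: dict[str, EntityRef], ont: Ontology) -> bool:
    if isinstance(tval, Var):
        if not isinstance(value, EntityRef):
            return False
        assert tval.concept is not None
        if not any(ont.is_subconcept(label, tval.concept) for label in value.labels):
            return False
        binding[tval.name] = value
        return True
    if isinstance(tval, Literal):
        return isinstance(value, Literal) and value.value == tval.value
    if isinstance(tval, SemanticStructure):
        if not isinstance(value, SemanticStructure):
            return False
        if not ont.is_subconcept(value.concept, tval.concept):
            return False
        for prop, sub in tval.slots.items():
            if prop not in value.slots or not _match_fixed(sub, value.slots[prop], binding, ont):
                return False
        return True
    return False


def match_template(template: EventTemplate, event: Event, ont: Ontology) -> ExtractionRecord | None:
    """Match one ground event against one template."""
    binding: dict[str, EntityRef] = {}
    if not _match_fixed(template.pattern, event.struct, binding, ont):
        return None
    polarity = event.struct.slots.get("hasPolarity")
    contact = event.struct.slots.get("hasPhysicalContact")
    bindings = tuple(
        sorted(
            (template.roles.get(var, "other"), (ref.grounding_id, ref.mention.surface))
            for var, ref in binding.items()
        )
    )
    return ExtractionRecord(
        template_id=template.id,
        doc_id=event.doc_id,
        event_type=event.struct.concept,
        bindings=bindings,
        polarity=polarity.value if isinstance(polarity, Literal) else None,
        physical_contact=contact.value if isinstance(contact, Literal) else None,
        event=event,
    )


def extract(events: Sequence[Event], templates: Sequence[EventTemplate], ont: Ontology) -> list[ExtractionRecord]:
    """All unique records over (event, template) pairs; explicit and
    inferred events are equally eligible."""
    records: list[ExtractionRecord] = []
    seen = set()
    for event in events:
        for template in templates:
            record = match_template(template, event, ont)
            if record is None:
                continue
            key = (record.template_id, record.doc_id, record.bindings, record.polarity, record.physical_contact)
            if key in seen:
                continue
            seen.add(key)
            records.append(record)
    return records


# --------------------------------------------------------------------------
# Scoring

@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _unique_key(record: ExtractionRecord):
    return (record.doc_id, record.agent_id, record.patient_id, record.event_type)


def _record_matches(pred: ExtractionRecord, gold: ExtractionRecord, ont: Ontology | None) -> bool:
    if pred.doc_id != gold.doc_id:
        return False
    if pred.agent_id != gold.agent_id or pred.patient_id != gold.patient_id:
        return False
    if ont is None:
        return pred.event_type == gold.event_type
    return ont.is_subconcept(pred.event_type, gold.event_type)


def evaluate(
    predicted: Sequence[ExtractionRecord],
    gold: Sequence[ExtractionRecord],
    mode: str = "instance",
    ont: Ontology | None = None,
) -> Metrics:
    """Score predictions on the two-participants-and-roles criterion.

    A maximum bipartite matching pairs predictions with gold records so
    each gold record is credited at most once.
    """
    if mode not in ("instance", "unique"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "unique":
        predicted = list({_unique_key(r): r for r in predicted}.values())
        gold = list({_unique_key(r): r for r in gold}.values())
    graph = nx.Graph()
    pred_nodes = [("p", i) for i in range(len(predicted))]
    gold_nodes = [("g", j) for j in range(len(gold))]
    graph.add_nodes_from(pred_nodes)
    graph.add_nodes_from(gold_nodes)
    for i, pred in enumerate(predicted):
        for j, gold_record in enumerate(gold):
            if _record_matches(pred, gold_record, ont):
                graph.add_edge(("p", i), ("g", j))
    matching = nx.algorithms.bipartite.maximum_matching(graph, top_nodes=set(pred_nodes))
    tp = sum(1 for node in pred_nodes if node in matching)
    return Metrics(tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)


# --------------------------------------------------------------------------
# Output writers

def _value_to_json(value: Value):
    if isinstance(value, SemanticStructure):
        return {"concept": value.concept, "slots": {p: _value_to_json(v) for p, v in value.slots.items()}}
    if isinstance(value, EntityRef):
        m = value.mention
        return {
            "entity": {
                "doc": m.doc_id, "sentence": m.sentence_index, "span": [m.start, m.end],
                "surface": m.surface, "id": m.grounding_id, "labels": list(m.concepts),
            }
        }
    if isinstance(value, Literal):
        return {"literal": value.value}
    raise TypeError(f"cannot serialize {value!r}")


def _value_from_json(data) -> Value:
    if "literal" in data:
        return Literal(data["literal"])
    if "entity" in data:
        e = data["entity"]
        mention = EntityMention(
            doc_id=e["doc"], sentence_index=e["sentence"], start=e["span"][0], end=e["span"][1],
            surface=e["surface"], grounding_id=e["id"], concepts=tuple(e["labels"]),
        )
        return EntityRef(mention)
    return SemanticStructure(data["concept"], {p: _value_from_json(v) for p, v in data["slots"].items()})


def events_to_json(events: Sequence[Event]) -> list[dict]:
    ids = {id(event): f"E{i + 1}" for i, event in enumerate(events)}
    out = []
    for event in events:
        out.append(
            {
                "id": ids[id(event)],
                "origin": event.origin,
                "doc": event.doc_id,
                "sentences": list(event.sentences),
                "source": event.source_id,
                "negated": event.negated,
                "supports": [ids[id(s)] for s in event.supports if id(s) in ids],
                "structure": _value_to_json(event.struct),
            }
        )
    return out


def events_from_json(data: Sequence[dict]) -> list[Event]:
    by_id: dict[str, Event] = {}
    events = []
    for item in data:
        event = Event(
            struct=_value_from_json(item["structure"]),
            origin=item.get("origin", "explicit"),
            doc_id=item.get("doc", "doc"),
            sentences=tuple(item.get("sentences", ())),
            source_id=item.get("source"),
            supports=tuple(by_id[s] for s in item.get("supports", ()) if s in by_id),
            negated=item.get("negated", False),
        )
        by_id[item.get("id", f"E{len(events) + 1}")] = event
        events.append(event)
    return events


def _records_to_json(records: Sequence[ExtractionRecord], event_ids: dict[int, str]) -> list[dict]:
    out = []
    for record in records:
        out.append(
            {
                "template": record.template_id,
                "doc": record.doc_id,
                "event_type": record.event_type,
                "agent": record.agent_id,
                "patient": record.patient_id,
                "bindings": {var: {"id": gid, "surface": surface} for var, (gid, surface) in record.bindings},
                "polarity": record.polarity,
                "physical_contact": record.physical_contact,
                "event": event_ids.get(id(record.event)),
            }
        )
    return out


def _token_offsets(graphs) -> dict[tuple[str, int], tuple[list[int], str]]:
    """Per (doc, sentence): character start offset of each token (0-based,
    tokens joined by single spaces, sentences joined by newlines)."""
    out: dict[tuple[str, int], tuple[list[int], str]] = {}
    cursor: dict[str, int] = {}
    for graph in graphs:
        start = cursor.get(graph.doc_id, 0)
        offsets = []
        pos = start
        for tok in graph:
            offsets.append(pos)
            pos += len(tok.form) + 1
        out[(graph.doc_id, graph.sentence_index)] = (offsets, graph.text())
        cursor[graph.doc_id] = pos  # +1 already covers the newline separator
    return out


def _write_standoff(out_dir: Path, events: Sequence[Event], mentions: Sequence[EntityMention], graphs) -> list[Path]:
    offsets = _token_offsets(graphs or [])
    docs = sorted({m.doc_id for m in mentions} | {e.doc_id for e in events})
    written = []
    for doc in docs:
        a1_lines: list[str] = []  # entity T-lines (given entities)
        a2_lines: list[str] = []  # trigger T-lines, E-lines, A-lines
        t_ids: dict[tuple, str] = {}
        n_t = 0

        def new_tid() -> str:
            nonlocal n_t
            n_t += 1
            return f"T{n_t}"

        for mention in [m for m in mentions if m.doc_id == doc]:
            key = (mention.sentence_index, mention.start, mention.end)
            if key in t_ids:
                continue
            t_ids[key] = new_tid()
            if (doc, mention.sentence_index) in offsets:
                sent_offsets, _ = offsets[(doc, mention.sentence_index)]
                start = sent_offsets[mention.start - 1]
                end = sent_offsets[mention.end - 2] + len(mention.surface.split()[-1])
            else:
                start, end = 0, len(mention.surface)
            a1_lines.append(f"{t_ids[key]}\t{mention.concepts[0]} {start} {end}\t{mention.surface}")

        e_counter = [0]
        a_lines: list[str] = []

        def emit(struct: SemanticStructure, trigger_ref: str) -> str:
            e_counter[0] += 1
            eid = f"E{e_counter[0]}"
            args = []
            for prop, value in struct.slots.items():
                role = {"hasAgent": "Agent", "hasPatient": "Patient", "hasPart": "Part"}.get(prop)
                if role is None:
                    continue
                if isinstance(value, EntityRef):
                    m = value.mention
                    ref = t_ids.get((m.sentence_index, m.start, m.end))
                    if ref:
                        args.append(f"{role}:{ref}")
                elif isinstance(value, SemanticStructure):
                    args.append(f"{role}:{emit(value, trigger_ref)}")
            a2_lines.append(f"{eid}\t{struct.concept}:{trigger_ref}" + ("".join(" " + a for a in args)))
            for prop, attr in (("hasPolarity", "Polarity"), ("hasPhysicalContact", "PhysicalContact")):
                value = struct.slots.get(prop)
                if isinstance(value, Literal):
                    a_lines.append(f"A{len(a_lines) + 1}\t{attr} {eid} {value.value}")
            return eid

        for event in [e for e in events if e.doc_id == doc]:
            trigger = event.trigger()
            ref = None
            if trigger is not None and (doc, trigger[0]) in offsets:
                sent, tok_index = trigger
                key = ("trigger", sent, tok_index, event.struct.concept)
                if key not in t_ids:
                    sent_offsets, text = offsets[(doc, sent)]
                    form = text.split(" ")[tok_index - 1]
                    start = sent_offsets[tok_index - 1]
                    t_ids[key] = new_tid()
                    a2_lines.append(f"{t_ids[key]}\t{event.struct.concept} {start} {start + len(form)}\t{form}")
                ref = t_ids[key]
            if ref is None:  # no textual trigger reachable; skip this event
                continue
            emit(event.struct, ref)
        a2_lines.extend(a_lines)

        a1 = out_dir / f"{doc}.a1"
        a2 = out_dir / f"{doc}.a2"
        a1.write_text("\n".join(a1_lines) + ("\n" if a1_lines else ""))
        a2.write_text("\n".join(a2_lines) + ("\n" if a2_lines else ""))
        written.extend([a1, a2])
    return written


def write_outputs(
    records: Sequence[ExtractionRecord],
    events: Sequence[Event],
    mentions: Sequence[EntityMention],
    fmt: str,
    out_dir: str | Path,
    graphs=None,
) -> list[Path]:
    """Write extraction results as ``json``, ``standoff`` or ``edges``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        event_ids = {id(event): f"E{i + 1}" for i, event in enumerate(events)}
        payload = {
            "events": events_to_json(events),
            "records": _records_to_json(records, event_ids),
        }
        path = out_dir / "events.json"
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return [path]
    if fmt == "standoff":
        return _write_standoff(out_dir, events, mentions, graphs)
    if fmt == "edges":
        frame = pd.DataFrame(
            [
                {
                    "doc": r.doc_id,
                    "agent": r.agent_id,
                    "patient": r.patient_id,
                    "type": r.event_type,
                    "polarity": r.polarity or "",
                    "physical_contact": r.physical_contact or "",
                }
                for r in records
            ],
            columns=["doc", "agent", "patient", "type", "polarity", "physical_contact"],
        )
        path = out_dir / "edges.tsv"
        frame.to_csv(path, sep="\t", index=False)
        return [path]
    raise ValueError(f"unknown format {fmt!r}")
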