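"""Template matching, record extraction, scoring and output writers."""

import json
import random
import re

import pytest

import regevents as rg
from regevents.extraction import (
    ExtractionRecord,
    Metrics,
    TemplateError,
    evaluate,
    events_from_json,
    events_to_json,
    extract,
    match_template,
    parse_template,
    write_outputs,
)
from regevents.semantics import Event, Literal, SemanticStructure, canonical

from .generators import entity_ref


def template_by_id(templates, tid):
    return next(t for t in templates if t.id == tid)


def flattened_event(doc="d", polarity="positive"):
    return Event(
        SemanticStructure(
            "RegulationOfGeneExpression",
            {
                "hasAgent": entity_ref("himA", ("Gene", "TranscriptionFactor"), doc=doc),
                "hasPatient": SemanticStructure(
                    "GeneExpression", {"hasPatient": entity_ref("fimA", ("Gene",), doc=doc)}
                ),
                "hasPolarity": Literal(polarity),
            },
        ),
        "inferred", doc, (0,), "R3",
    )


# --------------------------------------------------------------------------
# Template parsing and matching

def test_parse_template_assigns_variable_constraints_and_roles(ont):
    t = parse_template(
        "RGE\t<RegulationOfGeneExpression hasAgent=?Protein hasPatient=<GeneExpression hasPatient=?Gene>>",
        ont,
    )
    constraints = {v.concept for v in [t.pattern.slots["hasAgent"],
                                       t.pattern.slots["hasPatient"].slots["hasPatient"]]}
    assert constraints == {"Protein", "Gene"}
    assert set(t.roles.values()) == {"agent", "patient"}


def test_template_without_variables_rejected(ont):
    with pytest.raises(TemplateError, match="no variables"):
        parse_template('X\t<RegulatoryProcess hasPolarity="negative">', ont)


def test_template_matches_flattened_event_via_label_subsumption(ont, templates):
    """A TranscriptionFactor-labelled mention satisfies ?Protein because
    TranscriptionFactor is a Protein."""
    record = match_template(template_by_id(templates, "RGE"), flattened_event(), ont)
    assert record is not None
    assert record.agent_id == "ID:himA" and record.patient_id == "ID:fimA"
    assert record.polarity == "positive" and record.event_type == "RegulationOfGeneExpression"


def test_template_restriction_matches_subconcept_root(ont, templates):
    event = Event(
        SemanticStructure(
            "NegativeRegulation",
            {
                "hasAgent": entity_ref("geneX", ("Gene",)),
                "hasPatient": SemanticStructure("CellDeath", {"hasAgent": entity_ref("cellY", ("Cell",))}),
            },
        ),
        "explicit", "d", (0,), "p",
    )
    record = match_template(template_by_id(templates, "RCD"), event, ont)
    assert record is not None  # NegativeRegulation is a RegulatoryProcess; Gene is a MolecularEntity
    assert record.agent_id == "ID:geneX" and record.patient_id == "ID:cellY"


def test_template_requires_embedded_structure(ont, templates):
    bare = Event(
        SemanticStructure(
            "RegulationOfGeneExpression",
            {"hasAgent": entity_ref("himA", ("Gene", "TranscriptionFactor")),
             "hasPatient": entity_ref("fimA", ("Gene",))},
        ),
        "explicit", "d", (0,), "p",
    )
    assert match_template(template_by_id(templates, "RGE"), bare, ont) is None


def test_variable_never_binds_wrong_label(ont, templates):
    event = flattened_event()
    event.struct.slots["hasAgent"] = entity_ref("plainGene", ("Gene",))  # Gene is not a Protein
    assert match_template(template_by_id(templates, "RGE"), event, ont) is None


def test_extract_unions_and_deduplicates(ont, templates):
    event = flattened_event()
    records = extract([event, flattened_event()], templates, ont)
    assert len(records) == 1
    # soundness: the record re-verifies against its template
    again = match_template(template_by_id(templates, "RGE"), records[0].event, ont)
    assert again is not None and again.bindings == records[0].bindings
    assert extract([], templates, ont) == []


# --------------------------------------------------------------------------
# Scoring

def record(doc="d", agent="A", patient="B", etype="RegulationOfGeneExpression", tid="RGE", pol=None):
    return ExtractionRecord(
        template_id=tid, doc_id=doc, event_type=etype,
        bindings=(("agent", (agent, agent)), ("patient", (patient, patient))),
        polarity=pol,
    )


def test_identical_sets_score_perfectly(ont):
    records = [record(agent=f"A{i}") for i in range(5)]
    metrics = evaluate(records, list(records), ont=ont)
    assert (metrics.precision, metrics.recall, metrics.f_score) == (1.0, 1.0, 1.0)


def test_empty_predictions_have_zero_recall(ont):
    metrics = evaluate([], [record()], ont=ont)
    assert metrics.recall == 0.0 and metrics.fn == 1 and metrics.precision == 0.0


def test_precision_84_percent_from_79_tp_15_fp(ont):
    gold = [record(agent=f"A{i}") for i in range(375)]
    predicted = [record(agent=f"A{i}") for i in range(79)] + [
        record(agent=f"FP{i}", patient="Z") for i in range(15)
    ]
    metrics = evaluate(predicted, gold, ont=ont)
    assert (metrics.tp, metrics.fp) == (79, 15)
    assert round(metrics.precision * 100, 1) == 84.0
    assert round(metrics.recall * 100, 1) == 21.1


def test_event_type_matches_up_to_subsumption_one_way(ont):
    specific = record(etype="RegulationOfTranscription")
    general = record(etype="RegulationOfGeneExpression")
    assert evaluate([specific], [general], ont=ont).tp == 1  # prediction may be more specific
    assert evaluate([general], [specific], ont=ont).tp == 0  # but not more general


def test_polarity_and_contact_excluded_from_correctness(ont):
    assert evaluate([record(pol="negative")], [record(pol="positive")], ont=ont).tp == 1


def test_unique_mode_collapses_per_document_duplicates(ont):
    pred = [record(), record(), record(doc="e")]
    gold = [record(), record(doc="e")]
    instance = evaluate(pred, gold, mode="instance", ont=ont)
    unique = evaluate(pred, gold, mode="unique", ont=ont)
    assert (instance.tp, instance.fp) == (2, 1)
    assert (unique.tp, unique.fp) == (2, 0)


def test_swap_symmetry_exchanges_precision_and_recall(ont):
    rng = random.Random(13)
    for _ in range(20):
        pred = [record(agent=f"A{rng.randrange(6)}", patient=f"B{rng.randrange(3)}") for _ in range(rng.randrange(8))]
        gold = [record(agent=f"A{rng.randrange(6)}", patient=f"B{rng.randrange(3)}") for _ in range(rng.randrange(8))]
        forward = evaluate(pred, gold, ont=None)  # equality typing keeps the relation symmetric
        backward = evaluate(gold, pred, ont=None)
        assert forward.precision == backward.recall
        assert forward.recall == backward.precision


def test_metrics_harmonic_mean():
    metrics = Metrics(tp=2, fp=2, fn=6)
    assert metrics.precision == 0.5 and metrics.recall == 0.25
    assert metrics.f_score == pytest.approx(2 * 0.5 * 0.25 / 0.75)


# --------------------------------------------------------------------------
# Writers

def pipeline_outputs(ont, patterns, rules, templates):
    from .conftest import make_dictionary

    doc = rg.worked_binding_document()
    graphs = rg.parse_conll(doc.conllu)
    d = make_dictionary(doc.dict_rows, ont)
    result = rg.process_document(graphs, d, patterns, rules, templates, ont)
    return result


def test_json_roundtrip_preserves_events(tmp_path, ont, patterns, rules, templates):
    result = pipeline_outputs(ont, patterns, rules, templates)
    (path,) = write_outputs(result.records, result.events, result.mentions, "json", tmp_path,
                            graphs=result.graphs)
    payload = json.loads(path.read_text())
    restored = events_from_json(payload["events"])
    assert [canonical(e.struct) for e in restored] == [canonical(e.struct) for e in result.events]
    assert [e.origin for e in restored] == [e.origin for e in result.events]
    assert len(payload["records"]) == len(result.records)


T_LINE = re.compile(r"^T\d+\t\S+ \d+ \d+\t.+$")
E_LINE = re.compile(r"^E\d+\t\S+:T\d+( (Agent|Patient|Part):[TE]\d+)*$")
A_LINE = re.compile(r"^A\d+\t(Polarity|PhysicalContact) E\d+ \S+$")


def test_standoff_output_parses_under_strict_grammar(tmp_path, ont, patterns, rules, templates):
    result = pipeline_outputs(ont, patterns, rules, templates)
    paths = write_outputs(result.records, result.events, result.mentions, "standoff", tmp_path,
                          graphs=result.graphs)
    defined = set()
    referenced = set()
    for path in paths:
        for line in path.read_text().splitlines():
            if line.startswith("T"):
                assert T_LINE.match(line), line
                defined.add(line.split("\t")[0])
            elif line.startswith("E"):
                assert E_LINE.match(line), line
                defined.add(line.split("\t")[0])
                body = line.split("\t")[1]
                referenced.add(body.split(" ")[0].split(":")[1])
                for arg in body.split(" ")[1:]:
                    referenced.add(arg.split(":")[1])
            elif line.startswith("A"):
                assert A_LINE.match(line), line
                referenced.add(line.split("\t")[1].split(" ")[1])
            else:
                pytest.fail(f"unexpected standoff line: {line!r}")
    assert referenced <= defined
    assert any(r for r in referenced)


def test_standoff_character_offsets_match_document_text(tmp_path, ont, patterns, rules, templates):
    result = pipeline_outputs(ont, patterns, rules, templates)
    write_outputs(result.records, result.events, result.mentions, "standoff", tmp_path,
                  graphs=result.graphs)
    text = "\n".join(g.text() for g in result.graphs)
    a1 = (tmp_path / f"{result.doc_id}.a1").read_text()
    for line in a1.splitlines():
        _, type_span, surface = line.split("\t")
        start, end = map(int, type_span.split(" ")[1:])
        assert text[start:end] == surface


def test_edges_tsv_shape(tmp_path, ont, patterns, rules, templates):
    import pandas as pd

    result = pipeline_outputs(ont, patterns, rules, templates)
    (path,) = write_outputs(result.records, result.events, result.mentions, "edges", tmp_path)
    frame = pd.read_csv(path, sep="\t")
    assert list(frame.columns) == ["doc", "agent", "patient", "type", "polarity", "physical_contact"]
    assert len(frame) == len(result.records)
    assert set(frame["agent"]) == {"P0A6X7"}


def test_empty_records_give_valid_empty_files(tmp_path):
    for fmt in ("json", "standoff", "edges"):
        paths = write_outputs([], [], [], fmt, tmp_path / fmt)
        for path in paths:
            assert path.exists()
    payload = json.loads((tmp_path / "json" / "events.json").read_text())
    assert payload == {"events": [], "records": []}
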