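"""Pattern parsing, loose matching conditions and bottom-up composition."""

import random

import pytest

import regevents as rg
from regevents.patterns import MatchConfig, PatternError, match_at, parse_pattern
from regevents.semantics import EntityRef, SemanticStructure, canonical, count_basic_instances

from .conftest import make_dictionary
from .generators import entity_ref, random_labeled_tree, seed_entities
from .oracles import enumerate_matches, strict_matches

CONFIG = MatchConfig()


def pattern_by_id(patterns, pid):
    return next(p for p in patterns if p.id == pid)


# --------------------------------------------------------------------------
# Parsing

def test_parse_two_dependent_verb_pattern(ont):
    p = parse_pattern(
        "(cause_Verb Subject:Agent Object:Patient)\t<RegulatoryProcess hasAgent=Agent hasPatient=Patient>",
        ont,
    )
    assert p.syntax.lexeme == "cause" and p.syntax.pos == "Verb"
    assert [(c.role, c.var.name) for c in p.syntax.children] == [("Subject", "Agent"), ("Object", "Patient")]
    assert p.semantics.concept == "RegulatoryProcess"


def test_parse_nested_pattern_with_polarity_literal(ont):
    p = parse_pattern(
        '(reduction_Noun (in_Prep Object:Patient))\t<RegulatoryProcess hasPatient=Patient hasPolarity="negative">',
        ont,
    )
    nested = p.syntax.children[0]
    assert nested.lexeme == "in" and nested.pos == "Prep"
    assert nested.children[0].role == "Object"
    polarity = p.semantics.slots["hasPolarity"]
    assert polarity.value == "negative"


def test_concept_named_variable_carries_constraint(ont):
    p = parse_pattern("(expression_Noun (of_Prep Object:Gene))\t<GeneExpression hasPatient=Gene>", ont)
    var = p.syntax.children[0].children[0].var
    assert var.concept == "Gene"


@pytest.mark.parametrize(
    "line,match",
    [
        ("(cause_Verb Subject:Agent)\t<RegulatoryProcess hasPatient=Theme>", "not bound"),
        ("(cause_Verb Subject:Agent\t<RegulatoryProcess hasAgent=Agent>", "parenthes"),
        ("(cause_Verb Subject:Agent)\t<Widget hasAgent=Agent>", "unknown concept"),
        ("(cause_Verb Subject:Agent)\t<RegulatoryProcess hasWidget=Agent>", "unknown property"),
        ("cause_Verb\t<RegulatoryProcess>", "must start"),
    ],
)
def test_malformed_patterns_rejected(ont, line, match):
    with pytest.raises(Exception, match=match):
        parse_pattern(line, ont)


# --------------------------------------------------------------------------
# Loose matching

def build_sentence(rows, doc="d1"):
    lines = [f"# newdoc id = {doc}"]
    for i, (form, lemma, upos, head, rel) in enumerate(rows, start=1):
        lines.append(f"{i}\t{form}\t{lemma}\t{upos}\t_\t_\t{head}\t{rel}\t_\t_")
    return rg.parse_conll("\n".join(lines) + "\n")[0]


FUSION_ROWS = [
    ("expression", "expression", "NOUN", 0, "root"),
    ("of", "of", "ADP", 1, "prep"),
    ("a", "a", "DET", 5, "det"),
    ("fimA", "fimA", "PROPN", 5, "compound"),
    ("fusion", "fusion", "NOUN", 2, "pobj"),
]


def test_descendant_binding_when_gene_is_not_direct_child(ont, patterns):
    """'expression of a fimA ... fusion': fimA is two levels below 'of'."""
    g = build_sentence(FUSION_ROWS)
    sems = {4: [entity_ref("fimA", ("Gene",))]}
    results = match_at(pattern_by_id(patterns, "exp-of"), 1, g, sems, ont=ont, config=CONFIG)
    assert len(results) == 1
    (node, value), = [results[0].bindings["Gene"]]
    assert node == 4 and isinstance(value, EntityRef)
    assert results[0].structure.concept == "GeneExpression"


def test_no_gene_below_means_no_match(ont, patterns):
    g = build_sentence(FUSION_ROWS)
    assert match_at(pattern_by_id(patterns, "exp-of"), 1, g, {}, ont=ont, config=CONFIG) == []


def test_clausal_boundary_blocks_descent(ont, patterns):
    rows = [
        ("expression", "expression", "NOUN", 0, "root"),
        ("of", "of", "ADP", 1, "prep"),
        ("the", "the", "DET", 4, "det"),
        ("gene", "gene", "NOUN", 2, "pobj"),
        ("which", "which", "PRON", 6, "nsubj"),
        ("encodes", "encode", "VERB", 4, "rcmod"),
        ("himA", "himA", "PROPN", 6, "dobj"),
    ]
    g = build_sentence(rows)
    sems = {7: [entity_ref("himA", ("Gene",))]}
    assert match_at(pattern_by_id(patterns, "exp-of"), 1, g, sems, ont=ont, config=CONFIG) == []


def test_exception_word_blocks_descent(ont, patterns):
    rows = [
        ("expression", "expression", "NOUN", 0, "root"),
        ("of", "of", "ADP", 1, "prep"),
        ("genes", "gene", "NOUN", 2, "pobj"),
        ("except", "except", "ADP", 3, "prep"),
        ("fimA", "fimA", "PROPN", 4, "pobj"),
    ]
    g = build_sentence(rows)
    sems = {5: [entity_ref("fimA", ("Gene",))]}
    assert match_at(pattern_by_id(patterns, "exp-of"), 1, g, sems, ont=ont, config=CONFIG) == []


def test_role_constraint_confines_to_role_subtree(ont):
    # Patient may only bind inside an Object-bearing subtree: the subject
    # side entity is invisible to an Object: item.
    p = parse_pattern("(cause_Verb Object:Patient)\t<RegulatoryProcess hasPatient=Patient>", ont)
    rows = [
        ("himA", "himA", "PROPN", 2, "nsubj"),
        ("causes", "cause", "VERB", 0, "root"),
    ]
    g = build_sentence(rows)
    sems = {1: [entity_ref("himA", ("Gene",))]}
    assert match_at(p, 2, g, sems, ont=ont, config=CONFIG) == []


def test_matches_agree_with_exhaustive_assignment_oracle(ont, patterns):
    """Loose matching equals brute-force enumeration of all assignments
    filtered by conditions 1-3 (small random trees)."""
    rng = random.Random(42)
    test_patterns = [
        pattern_by_id(patterns, "cause-svo"),
        pattern_by_id(patterns, "exp-of"),
        pattern_by_id(patterns, "lesion-obj"),
        parse_pattern(
            "(cause_Verb Object:A Object:B)\t<RegulatoryProcess hasAgent=A hasPatient=B>", ont
        ),
    ]
    checked = 0
    for _ in range(120):
        g = random_labeled_tree(rng, rng.randint(2, 8))
        sems = seed_entities(rng, g)
        for pattern in test_patterns:
            for node in g.tokens:
                got = match_at(pattern, node, g, sems, ont=ont, config=CONFIG)
                expected = enumerate_matches(pattern, node, g, sems, ont, CONFIG)
                got_keys = {
                    (
                        tuple(sorted((v, (n, canonical(s))) for v, (n, s) in r.bindings.items())),
                        frozenset(r.matched_nodes),
                    )
                    for r in got
                }
                exp_keys = {
                    (tuple(sorted((v, (n, canonical(s))) for v, (n, s) in b.items())), frozenset(nodes))
                    for b, nodes in expected
                }
                assert got_keys == exp_keys
                checked += len(got)
    assert checked > 50  # the comparison was not vacuous


def test_loose_matching_superset_of_strict(ont, patterns):
    """Every strict (direct-child, exact-role) match is also found by
    loose matching, on 100 random trees."""
    rng = random.Random(7)
    test_patterns = [
        pattern_by_id(patterns, "cause-svo"),
        pattern_by_id(patterns, "lesion-obj"),
        pattern_by_id(patterns, "exp-of"),
    ]
    strict_total = 0
    for _ in range(100):
        g = random_labeled_tree(rng, rng.randint(2, 9))
        sems = seed_entities(rng, g)
        for pattern in test_patterns:
            for node in g.tokens:
                strict = strict_matches(pattern, node, g, sems, ont, CONFIG)
                if not strict:
                    continue
                loose = {
                    canonical(r.structure)
                    for r in match_at(pattern, node, g, sems, ont=ont, config=CONFIG)
                }
                assert strict <= loose
                strict_total += len(strict)
    assert strict_total > 20


def test_condition2_branches_never_dominate_each_other(ont, patterns):
    rng = random.Random(3)
    for _ in range(60):
        g = random_labeled_tree(rng, rng.randint(3, 9))
        sems = seed_entities(rng, g)
        for pattern in patterns:
            for node in g.tokens:
                for result in match_at(pattern, node, g, sems, ont=ont, config=CONFIG):
                    nodes = result.matched_nodes
                    for a in nodes:
                        for b in nodes:
                            if a != b:
                                assert not (g.dominates(a, b) and g.dominates(b, a))


# --------------------------------------------------------------------------
# Composition

CASCADE = rg.worked_cascade_document()


def cascade_graph_and_mentions(ont, coordinated=False):
    doc = rg.worked_cascade_document(coordinated=coordinated)
    g = rg.parse_conll(doc.conllu)[0]
    d = make_dictionary(doc.dict_rows, ont)
    return g, rg.recognize(g, d)


def test_compose_cascade_yields_single_four_instance_event(ont, patterns):
    g, mentions = cascade_graph_and_mentions(ont)
    events = rg.compose(g, mentions, patterns, ont)
    assert len(events) == 1
    event = events[0]
    assert event.origin == "explicit" and event.struct.is_ground()
    assert count_basic_instances(event.struct) == 4
    concepts = _concept_multiset(event.struct)
    assert sorted(concepts) == ["GeneExpression"] + ["RegulatoryProcess"] * 3
    # agent side: lesions-in-himA with negative polarity
    agent = event.struct.slots["hasAgent"]
    assert agent.slots["hasPolarity"].value == "negative"
    assert agent.slots["hasPatient"].grounding_id == "P0A6X7"
    # patient side: reduction of expression of fimA, negative
    patient = event.struct.slots["hasPatient"]
    assert patient.slots["hasPolarity"].value == "negative"
    assert patient.slots["hasPatient"].concept == "GeneExpression"


def _concept_multiset(struct):
    out = [struct.concept]
    for value in struct.slots.values():
        if isinstance(value, SemanticStructure):
            out.extend(_concept_multiset(value))
    return out


def test_coordination_distributes_over_conjuncts(ont, patterns):
    g, mentions = cascade_graph_and_mentions(ont, coordinated=True)
    ann = rg.annotate(g, mentions, patterns, ont)
    lesions_sems = ann.pattern_semantics(1)
    assert len(lesions_sems) == 2
    bound = {s.slots["hasPatient"].grounding_id for s in lesions_sems}
    assert bound == {"P0A6X7", "P0A6Y1"}
    events = rg.compose(g, mentions, patterns, ont)
    assert len(events) == 2
    agents = {e.struct.slots["hasAgent"].slots["hasPatient"].grounding_id for e in events}
    assert agents == {"P0A6X7", "P0A6Y1"}


def test_no_patterns_fire_yields_no_events(ont, patterns):
    g = build_sentence(
        [
            ("Cells", "cell", "NOUN", 3, "nsubjpass"),
            ("were", "be", "AUX", 3, "aux"),
            ("grown", "grow", "VERB", 0, "root"),
        ]
    )
    assert rg.compose(g, [], patterns, ont) == []


def test_consumed_structures_are_not_emitted_separately(ont, patterns):
    g, mentions = cascade_graph_and_mentions(ont)
    ann = rg.annotate(g, mentions, patterns, ont)
    events = rg.compose(g, mentions, patterns, ont)
    emitted = {canonical(e.struct) for e in events}
    for node in g.tokens:
        for struct in ann.pattern_semantics(node):
            if id(struct) in ann.consumed:
                assert canonical(struct) not in emitted


def test_all_event_concepts_and_properties_are_declared(ont, patterns):
    g, mentions = cascade_graph_and_mentions(ont, coordinated=True)
    for event in rg.compose(g, mentions, patterns, ont):
        _check_declared(event.struct, ont)


def _check_declared(struct, ont):
    assert ont.is_concept(struct.concept)
    for prop, value in struct.slots.items():
        assert prop in ont.properties
        if isinstance(value, SemanticStructure):
            _check_declared(value, ont)
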