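"""Seeded random input generators shared by property tests."""

from __future__ import annotations

import random

from regevents.entities import EntityMention
from regevents.semantics import EntityRef, Event, Literal, SemanticStructure
from regevents.syntax import DependencyGraph, Token

ROLE_POOL = ("Subject", "Object", "Object", "PrepObject", "PrepObject", "Conj", "Other")
# lemma/POS pairs biased toward the shipped pattern vocabulary so random
# trees actually produce matches
WORD_POOL = (
    ("cause", "Verb"), ("cause", "Verb"), ("lesion", "Noun"), ("expression", "Noun"),
    ("expression", "Noun"), ("reduction", "Noun"), ("of", "Prep"), ("of", "Prep"),
    ("in", "Prep"), ("operon", "Noun"), ("fusion", "Noun"), ("sevenfold", "Other"),
)


def random_labeled_tree(rng: random.Random, n: int, doc: str = "d") -> DependencyGraph:
    """A random tree with lemmas/POS/roles drawn from the pattern vocabulary."""
    tokens = {}
    for i in range(1, n + 1):
        lemma, pos = rng.choice(WORD_POOL)
        tokens[i] = Token(
            index=i,
            form=lemma,
            lemma=lemma,
            pos=pos,
            head=0 if i == 1 else rng.randint(1, i - 1),
            relation="dep",
            role="Other" if i == 1 else rng.choice(ROLE_POOL),
        )
    return DependencyGraph(tokens=tokens, doc_id=doc)


def entity_ref(name: str, labels=("Gene",), doc: str = "d", sent: int = 0, start: int = 1) -> EntityRef:
    return EntityRef(
        EntityMention(
            doc_id=doc, sentence_index=sent, start=start, end=start + 1,
            surface=name, grounding_id=f"ID:{name}", concepts=tuple(labels),
        )
    )


def seed_entities(rng: random.Random, graph: DependencyGraph) -> dict[int, list]:
    """Seed a random subset of nodes with unique entity semantics."""
    index: dict[int, list] = {}
    for i in sorted(graph.tokens):
        if rng.random() < 0.7:
            labels = rng.choice((("Gene",), ("Gene", "TranscriptionFactor"), ("Protein",)))
            index[i] = [entity_ref(f"{graph.doc_id}-n{i}", labels, start=i)]
    return index


_ENTITY_POOL = [("tfA", ("Gene", "TranscriptionFactor")), ("tfB", ("Gene", "TranscriptionFactor")),
                ("geneX", ("Gene",)), ("geneY", ("Gene",))]


def _random_struct(rng: random.Random, depth: int) -> SemanticStructure:
    concept = rng.choice(
        ("RegulatoryProcess", "PositiveRegulation", "NegativeRegulation",
         "RegulationOfGeneExpression", "GeneExpression", "Transcription")
    )
    slots = {}
    for prop in ("hasAgent", "hasPatient"):
        roll = rng.random()
        if roll < 0.35:
            name, labels = rng.choice(_ENTITY_POOL)
            slots[prop] = entity_ref(name, labels)
        elif roll < 0.6 and depth > 0:
            slots[prop] = _random_struct(rng, depth - 1)
    if rng.random() < 0.6:
        slots["hasPolarity"] = Literal(rng.choice(("positive", "negative")))
    return SemanticStructure(concept, slots)


def _random_region(rng: random.Random) -> SemanticStructure:
    gene, glabels = rng.choice(_ENTITY_POOL[2:])
    tf, tlabels = rng.choice(_ENTITY_POOL[:2])
    return SemanticStructure(
        "RegulatoryDNARegion",
        {
            "hasAgent": entity_ref(gene, glabels),
            "hasPart": SemanticStructure(
                "TranscriptionFactorBindingSiteOfDNA", {"hasAgent": entity_ref(tf, tlabels)}
            ),
        },
    )


def random_event_set(rng: random.Random, n: int, doc: str = "d") -> list[Event]:
    """Small random ground event sets exercising every shipped rule shape."""
    events = []
    for k in range(n):
        if rng.random() < 0.25:
            struct = _random_region(rng)
        else:
            struct = _random_struct(rng, depth=2)
        events.append(
            Event(struct=struct, origin="explicit", doc_id=doc, sentences=(k,), source_id="gen")
        )
    return events
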