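"""Synthetic pre-parsed corpora with gold annotations.

The generator emits small MEDLINE-abstract-like documents as CoNLL-U text
built from hand-written dependency-tree skeletons, together with the
dictionary rows they use and the gold extraction records the shipped
patterns and rules are expected to recover.  Five sentence frames cover
the constructions the extraction method exercises:

* ``direct`` -- "TF activates/represses expression of G." (recoverable
  without inference);
* ``cascade`` -- "Lesions in TF cause a reduction in expression of G."
  (a nominalized compositional cascade; the record requires the
  flattening/specialization rules, with polarity negative*negative =
  positive);
* ``coordination`` -- the cascade with a coordinated pair "TF or TF2"
  (one gold record per conjunct);
* ``binding`` -- the sentence pair "TF regulates expression of G." +
  "The regulatory region of G contains a TF binding site." (the
  cross-sentence evidence-combination rule adds a direct
  transcription-regulation record with physical contact);
* ``distractor`` -- sentences with no gold events (with or without an
  entity mention).

Trees are template skeletons rather than parser output, so the gold
derivations are exact; prepositions head their objects
(governor ->prep-> preposition ->pobj-> noun), the representation the
prepositional patterns expect.  Name inventories are synthetic
(``TF01`` .., ``g0001`` ..); the worked-example documents use the
classic IHF/fimbriae names himA, himD and fimA.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .extraction import ExtractionRecord

__all__ = [
    "FixtureConfig",
    "GoldRecord",
    "GoldDocument",
    "generate",
    "write_fixture_dir",
    "worked_cascade_document",
    "worked_binding_document",
    "gold_to_records",
]

FRAMES = ("direct", "cascade", "coordination", "binding", "distractor")

DEFAULT_WEIGHTS = {
    "direct": 0.25,
    "cascade": 0.2,
    "coordination": 0.15,
    "binding": 0.2,
    "distractor": 0.2,
}


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_docs: int = 20
    weights: tuple[tuple[str, float], ...] = tuple(DEFAULT_WEIGHTS.items())
    n_tfs: int = 12
    n_genes: int = 30

    def weight_map(self) -> dict[str, float]:
        weights = dict(self.weights)
        unknown = set(weights) - set(FRAMES)
        if unknown:
            raise ValueError(f"unknown frames in weights: {sorted(unknown)}")
        if any(w < 0 for w in weights.values()) or not any(w > 0 for w in weights.values()):
            raise ValueError("frame weights must be non-negative with at least one positive")
        return weights


@dataclass(frozen=True)
class GoldRecord:
    doc_id: str
    template_id: str
    event_type: str
    agent_id: str
    patient_id: str
    polarity: str | None
    physical_contact: str | None
    requires_inference: bool


@dataclass
class GoldDocument:
    doc_id: str
    frame: str
    conllu: str
    dict_rows: list[tuple[str, str, str]] = field(default_factory=list)
    gold_records: list[GoldRecord] = field(default_factory=list)


# --------------------------------------------------------------------------
# Tree skeletons.  Row = (form, lemma, upos, head, deprel).

Row = tuple[str, str, str, int, str]


def _conllu(doc_id: str, sentences: Sequence[Sequence[Row]]) -> str:
    lines = [f"# newdoc id = {doc_id}"]
    for s_index, rows in enumerate(sentences):
        lines.append(f"# sent_id = {doc_id}.s{s_index}")
        lines.append("# text = " + " ".join(row[0] for row in rows))
        for i, (form, lemma, upos, head, deprel) in enumerate(rows, start=1):
            lines.append(f"{i}\t{form}\t{lemma}\t{upos}\t_\t_\t{head}\t{deprel}\t_\t_")
        lines.append("")
    return "\n".join(lines) + "\n"


def _direct_rows(tf: str, gene: str, verb: str) -> list[Row]:
    lemma = {"activates": "activate", "represses": "repress", "regulates": "regulate"}[verb]
    return [
        (tf, tf, "PROPN", 2, "nsubj"),
        (verb, lemma, "VERB", 0, "root"),
        ("expression", "expression", "NOUN", 2, "dobj"),
        ("of", "of", "ADP", 3, "prep"),
        (gene, gene, "PROPN", 4, "pobj"),
        (".", ".", "PUNCT", 2, "punct"),
    ]


def _cascade_rows(tf: str, gene: str) -> list[Row]:
    return [
        ("Lesions", "lesion", "NOUN", 4, "nsubj"),
        ("in", "in", "ADP", 1, "prep"),
        (tf, tf, "PROPN", 2, "pobj"),
        ("cause", "cause", "VERB", 0, "root"),
        ("a", "a", "DET", 6, "det"),
        ("reduction", "reduction", "NOUN", 4, "dobj"),
        ("in", "in", "ADP", 6, "prep"),
        ("expression", "expression", "NOUN", 7, "pobj"),
        ("of", "of", "ADP", 8, "prep"),
        (gene, gene, "PROPN", 9, "pobj"),
        (".", ".", "PUNCT", 4, "punct"),
    ]


def _coordination_rows(tf1: str, tf2: str, gene: str) -> list[Row]:
    return [
        ("Lesions", "lesion", "NOUN", 6, "nsubj"),
        ("in", "in", "ADP", 1, "prep"),
        (tf1, tf1, "PROPN", 2, "pobj"),
        ("or", "or", "CCONJ", 3, "cc"),
        (tf2, tf2, "PROPN", 3, "conj"),
        ("cause", "cause", "VERB", 0, "root"),
        ("a", "a", "DET", 8, "det"),
        ("reduction", "reduction", "NOUN", 6, "dobj"),
        ("in", "in", "ADP", 8, "prep"),
        ("expression", "expression", "NOUN", 9, "pobj"),
        ("of", "of", "ADP", 10, "prep"),
        (gene, gene, "PROPN", 11, "pobj"),
        (".", ".", "PUNCT", 6, "punct"),
    ]


def _binding_site_rows(tf: str, gene: str) -> list[Row]:
    return [
        ("The", "the", "DET", 3, "det"),
        ("regulatory", "regulatory", "ADJ", 3, "amod"),
        ("region", "region", "NOUN", 6, "nsubj"),
        ("of", "of", "ADP", 3, "prep"),
        (gene, gene, "PROPN", 4, "pobj"),
        ("contains", "contain", "VERB", 0, "root"),
        ("a", "a", "DET", 10, "det"),
        (tf, tf, "PROPN", 10, "compound"),
        ("binding", "binding", "NOUN", 10, "compound"),
        ("site", "site", "NOUN", 6, "dobj"),
        (".", ".", "PUNCT", 6, "punct"),
    ]


def _distractor_rows(gene: str | None) -> list[Row]:
    if gene is None:
        return [
            ("Cells", "cell", "NOUN", 3, "nsubjpass"),
            ("were", "be", "AUX", 3, "aux"),
            ("grown", "grow", "VERB", 0, "root"),
            ("in", "in", "ADP", 3, "prep"),
            ("minimal", "minimal", "ADJ", 6, "amod"),
            ("medium", "medium", "NOUN", 4, "pobj"),
            (".", ".", "PUNCT", 3, "punct"),
        ]
    return [
        ("The", "the", "DET", 3, "det"),
        (gene, gene, "PROPN", 3, "compound"),
        ("promoter", "promoter", "NOUN", 5, "nsubjpass"),
        ("was", "be", "AUX", 5, "aux"),
        ("sequenced", "sequence", "VERB", 0, "root"),
        (".", ".", "PUNCT", 5, "punct"),
    ]


# --------------------------------------------------------------------------
# Document builders

def _tf_row(name: str) -> tuple[str, str, str]:
    return (name, f"UP:{name}", "Gene,TranscriptionFactor")


def _gene_row(name: str) -> tuple[str, str, str]:
    return (name, f"UP:{name}", "Gene")


def _build_direct(doc_id: str, tf: str, gene: str, positive: bool) -> GoldDocument:
    verb = "activates" if positive else "represses"
    doc = GoldDocument(
        doc_id=doc_id,
        frame="direct",
        conllu=_conllu(doc_id, [_direct_rows(tf, gene, verb)]),
        dict_rows=[_tf_row(tf), _gene_row(gene)],
    )
    doc.gold_records.append(
        GoldRecord(doc_id, "RGE", "RegulationOfGeneExpression", f"UP:{tf}", f"UP:{gene}",
                   "positive" if positive else "negative", None, requires_inference=False)
    )
    return doc


def _build_cascade(doc_id: str, tf: str, gene: str) -> GoldDocument:
    doc = GoldDocument(
        doc_id=doc_id,
        frame="cascade",
        conllu=_conllu(doc_id, [_cascade_rows(tf, gene)]),
        dict_rows=[_tf_row(tf), _gene_row(gene)],
    )
    # lesion(negative) composed with reduction(negative): NXOR gives positive
    doc.gold_records.append(
        GoldRecord(doc_id, "RGE", "RegulationOfGeneExpression", f"UP:{tf}", f"UP:{gene}",
                   "positive", None, requires_inference=True)
    )
    return doc


def _build_coordination(doc_id: str, tf1: str, tf2: str, gene: str) -> GoldDocument:
    doc = GoldDocument(
        doc_id=doc_id,
        frame="coordination",
        conllu=_conllu(doc_id, [_coordination_rows(tf1, tf2, gene)]),
        dict_rows=[_tf_row(tf1), _tf_row(tf2), _gene_row(gene)],
    )
    for tf in (tf1, tf2):
        doc.gold_records.append(
            GoldRecord(doc_id, "RGE", "RegulationOfGeneExpression", f"UP:{tf}", f"UP:{gene}",
                       "positive", None, requires_inference=True)
        )
    return doc


def _build_binding(doc_id: str, tf: str, gene: str) -> GoldDocument:
    doc = GoldDocument(
        doc_id=doc_id,
        frame="binding",
        conllu=_conllu(doc_id, [_direct_rows(tf, gene, "regulates"), _binding_site_rows(tf, gene)]),
        dict_rows=[_tf_row(tf), _gene_row(gene)],
    )
    doc.gold_records.append(
        GoldRecord(doc_id, "RGE", "RegulationOfGeneExpression", f"UP:{tf}", f"UP:{gene}",
                   None, None, requires_inference=False)
    )
    doc.gold_records.append(
        GoldRecord(doc_id, "RT", "RegulationOfTranscription", f"UP:{tf}", f"UP:{gene}",
                   None, "yes", requires_inference=True)
    )
    return doc


def _build_distractor(doc_id: str, gene: str | None) -> GoldDocument:
    return GoldDocument(
        doc_id=doc_id,
        frame="distractor",
        conllu=_conllu(doc_id, [_distractor_rows(gene)]),
        dict_rows=[_gene_row(gene)] if gene else [],
    )


def worked_cascade_document(coordinated: bool = False) -> GoldDocument:
    """The IHF/fimbriae worked example ("Lesions in himA [or himD] cause a
    reduction in expression of fimA.")."""
    if coordinated:
        doc = _build_coordination("worked-cascade-coord", "himA", "himD", "fimA")
    else:
        doc = _build_cascade("worked-cascade", "himA", "fimA")
    doc.dict_rows = [
        ("himA", "P0A6X7", "Gene,TranscriptionFactor"),
        ("himD", "P0A6Y1", "Gene,TranscriptionFactor"),
        ("fimA", "P04128", "Gene"),
    ]
    doc.gold_records = [
        GoldRecord(doc.doc_id, r.template_id, r.event_type,
                   {"UP:himA": "P0A6X7", "UP:himD": "P0A6Y1"}.get(r.agent_id, r.agent_id),
                   "P04128", r.polarity, r.physical_contact, r.requires_inference)
        for r in doc.gold_records
    ]
    return doc


def worked_binding_document() -> GoldDocument:
    """Cross-sentence binding-site worked example with himA regulating fimA."""
    doc = _build_binding("worked-binding", "himA", "fimA")
    doc.dict_rows = [
        ("himA", "P0A6X7", "Gene,TranscriptionFactor"),
        ("fimA", "P04128", "Gene"),
    ]
    doc.gold_records = [
        GoldRecord(doc.doc_id, r.template_id, r.event_type, "P0A6X7", "P04128",
                   r.polarity, r.physical_contact, r.requires_inference)
        for r in doc.gold_records
    ]
    return doc


def generate(config: FixtureConfig) -> list[GoldDocument]:
    """Generate a deterministic synthetic corpus under *config*."""
    weights = config.weight_map()
    rng = random.Random(config.seed)
    tfs = [f"TF{i:02d}" for i in range(1, config.n_tfs + 1)]
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    frames = [f for f in FRAMES if weights.get(f, 0) > 0]
    frame_weights = [weights[f] for f in frames]
    docs: list[GoldDocument] = []
    for d in range(config.n_docs):
        doc_id = f"doc{d + 1:04d}"
        frame = rng.choices(frames, weights=frame_weights, k=1)[0]
        if frame == "direct":
            docs.append(_build_direct(doc_id, rng.choice(tfs), rng.choice(genes), rng.random() < 0.5))
        elif frame == "cascade":
            docs.append(_build_cascade(doc_id, rng.choice(tfs), rng.choice(genes)))
        elif frame == "coordination":
            tf1, tf2 = rng.sample(tfs, 2)
            docs.append(_build_coordination(doc_id, tf1, tf2, rng.choice(genes)))
        elif frame == "binding":
            docs.append(_build_binding(doc_id, rng.choice(tfs), rng.choice(genes)))
        else:
            docs.append(_build_distractor(doc_id, rng.choice(genes) if rng.random() < 0.5 else None))
    return docs


def corpus_conllu(docs: Sequence[GoldDocument]) -> str:
    return "".join(doc.conllu for doc in docs)


def dictionary_rows(docs: Sequence[GoldDocument]) -> list[tuple[str, str, str]]:
    rows = {}
    for doc in docs:
        for surface, gid, labels in doc.dict_rows:
            rows[surface] = (surface, gid, labels)
    return [rows[k] for k in sorted(rows)]


def gold_to_records(docs: Sequence[GoldDocument], requires_inference: bool | None = None) -> list[ExtractionRecord]:
    """Gold records as scorer-ready :class:`ExtractionRecord` objects.

    ``requires_inference=False`` selects the subset recoverable without
    the inference module (the ablation gold)."""
    out = []
    for doc in docs:
        for record in doc.gold_records:
            if requires_inference is not None and record.requires_inference != requires_inference:
                continue
            out.append(
                ExtractionRecord(
                    template_id=record.template_id,
                    doc_id=record.doc_id,
                    event_type=record.event_type,
                    bindings=(
                        ("agent", (record.agent_id, record.agent_id)),
                        ("patient", (record.patient_id, record.patient_id)),
                    ),
                    polarity=record.polarity,
                    physical_contact=record.physical_contact,
                )
            )
    return out


def write_fixture_dir(docs: Sequence[GoldDocument], out_dir: str | Path, config: FixtureConfig | None = None) -> dict[str, Path]:
    """Write corpus.conllu, dictionary.tsv, gold.json (and a config echo)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out_dir / "corpus.conllu",
        "dictionary": out_dir / "dictionary.tsv",
        "gold": out_dir / "gold.json",
    }
    paths["corpus"].write_text(corpus_conllu(docs))
    paths["dictionary"].write_text(
        "\n".join("\t".join(row) for row in dictionary_rows(docs)) + "\n"
    )
    gold = [
        {
            "doc": r.doc_id, "template": r.template_id, "type": r.event_type,
            "agent": r.agent_id, "patient": r.patient_id, "polarity": r.polarity,
            "physical_contact": r.physical_contact, "requires_inference": r.requires_inference,
        }
        for doc in docs
        for r in doc.gold_records
    ]
    paths["gold"].write_text(json.dumps(gold, indent=2) + "\n")
    if config is not None:
        paths["config"] = out_dir / "config.json"
        paths["config"].write_text(
            json.dumps(
                {
                    "seed": config.seed, "n_docs": config.n_docs,
                    "weights": dict(config.weights), "n_tfs": config.n_tfs,
                    "n_genes": config.n_genes,
                },
                indent=2,
            )
            + "\n"
        )
    return paths
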