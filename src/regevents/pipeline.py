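"""Document-level orchestration: NER -> composition -> closure -> extraction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .entities import Dictionary, EntityMention, recognize
from .extraction import EventTemplate, ExtractionRecord, extract
from .inference import InferenceRule, closure
from .ontology import Ontology
from .patterns import MatchConfig, PatternPair, compose
from .syntax import DependencyGraph

__all__ = ["DocumentResult", "process_document", "process_corpus"]


@dataclass
class DocumentResult:
    doc_id: str
    graphs: list[DependencyGraph]
    mentions: list[EntityMention] = field(default_factory=list)
    explicit_events: list = field(default_factory=list)
    events: list = field(default_factory=list)  # explicit + inferred
    records: list[ExtractionRecord] = field(default_factory=list)


def process_document(
    graphs: Sequence[DependencyGraph],
    dictionary: Dictionary,
    patterns: Sequence[PatternPair],
    rules: Sequence[InferenceRule],
    templates: Sequence[EventTemplate],
    ont: Ontology,
    config: MatchConfig | None = None,
    infer: bool = True,
) -> DocumentResult:
    """Run the full extraction pipeline over one document's sentences.

    With ``infer=False`` the inference closure is skipped, the ablation
    configuration in which only explicitly composed events can reach the
    templates.
    """
    config = config or MatchConfig()
    doc_id = graphs[0].doc_id if graphs else "doc"
    result = DocumentResult(doc_id=doc_id, graphs=list(graphs))
    for graph in graphs:
        mentions = recognize(graph, dictionary)
        result.mentions.extend(mentions)
        result.explicit_events.extend(compose(graph, mentions, patterns, ont, config))
    result.events = (
        closure(result.explicit_events, rules, ont) if infer else list(result.explicit_events)
    )
    result.records = extract(result.events, templates, ont)
    return result


def process_corpus(
    graphs: Sequence[DependencyGraph],
    dictionary: Dictionary,
    patterns: Sequence[PatternPair],
    rules: Sequence[InferenceRule],
    templates: Sequence[EventTemplate],
    ont: Ontology,
    config: MatchConfig | None = None,
    infer: bool = True,
) -> list[DocumentResult]:
    """Group sentences by document ID and process each document.

    The document is the closure scope: multi-condition rules may combine
    evidence across a document's sentences but never across documents.
    """
    by_doc: dict[str, list[DependencyGraph]] = {}
    for graph in graphs:
        by_doc.setdefault(graph.doc_id, []).append(graph)
    return [
        process_document(doc_graphs, dictionary, patterns, rules, templates, ont, config, infer)
        for doc_graphs in by_doc.values()
    ]
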