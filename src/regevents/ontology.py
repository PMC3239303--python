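"""Miniature Gene Regulation Ontology (GRO).

The ontology is an is-a DAG over concept names plus a flat vocabulary of
property names (``hasAgent``, ``hasPatient``, ``hasPolarity``,
``hasPhysicalContact``, ``hasPart``) and an alias map for common
abbreviations (``TFBS`` -> ``TranscriptionFactorBindingSiteOfDNA``).
It answers the subsumption queries that pattern matching, inference and
template extraction all rely on: ``a`` is a sub-concept of ``b`` iff
``a == b`` or ``a`` reaches ``b`` through is-a edges.

The on-disk format is a line-oriented declaration file::

    concept Gene
    isa Gene MolecularEntity
    property hasAgent
    alias TFBS TranscriptionFactorBindingSiteOfDNA

Blank lines and ``#`` comments are ignored.  The default file shipped with
the package covers the concepts used by the gene-regulation templates and
rules (regulatory processes, gene expression/transcription, TF binding
sites, cell activities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import IO, Iterable

import networkx as nx

__all__ = [
    "Ontology",
    "OntologyError",
    "load_ontology",
    "default_ontology",
    "is_subconcept",
]


class OntologyError(ValueError):
    """Raised for malformed ontology files or invalid concept queries."""


@dataclass
class Ontology:
    """Is-a DAG of concepts plus property and alias vocabularies."""

    concepts: set[str] = field(default_factory=set)
    isa_edges: dict[str, set[str]] = field(default_factory=dict)  # child -> parents
    properties: set[str] = field(default_factory=set)
    abbreviations: dict[str, str] = field(default_factory=dict)
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def resolve(self, name: str) -> str:
        """Resolve an alias to its declared concept (idempotent)."""
        seen = set()
        while name in self.abbreviations:
            if name in seen:  # alias cycle; cannot happen via load_ontology
                raise OntologyError(f"cyclic alias chain at {name!r}")
            seen.add(name)
            name = self.abbreviations[name]
        return name

    def is_concept(self, name: str) -> bool:
        return self.resolve(name) in self.concepts

    def require_concept(self, name: str) -> str:
        resolved = self.resolve(name)
        if resolved not in self.concepts:
            raise OntologyError(f"unknown concept {name!r}")
        return resolved

    def require_property(self, name: str) -> str:
        if name not in self.properties:
            raise OntologyError(f"unknown property {name!r}")
        return name

    def ancestors(self, name: str) -> frozenset[str]:
        """Reflexive-transitive is-a closure of *name*."""
        name = self.require_concept(name)
        cached = self._ancestors.get(name)
        if cached is None:
            out = {name}
            stack = [name]
            while stack:
                for parent in self.isa_edges.get(stack.pop(), ()):
                    if parent not in out:
                        out.add(parent)
                        stack.append(parent)
            cached = self._ancestors[name] = frozenset(out)
        return cached

    def is_subconcept(self, a: str, b: str) -> bool:
        """True iff *a* = *b* or *a* reaches *b* through is-a edges."""
        return self.require_concept(b) in self.ancestors(a)

    def validate(self) -> None:
        if not self.concepts:
            raise OntologyError("ontology declares no concepts")
        for child, parents in self.isa_edges.items():
            for name in (child, *parents):
                if name not in self.concepts:
                    raise OntologyError(f"isa edge endpoint {name!r} is not a declared concept")
        for alias, target in self.abbreviations.items():
            if self.resolve(alias) not in self.concepts:
                raise OntologyError(f"alias {alias!r} -> {target!r} does not resolve to a concept")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.concepts)
        for child, parents in self.isa_edges.items():
            graph.add_edges_from((child, parent) for parent in parents)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            return
        chain = " -> ".join(edge[0] for edge in cycle) + " -> " + cycle[-1][1]
        raise OntologyError(f"is-a graph contains a cycle: {chain}")


def _parse_lines(lines: Iterable[str]) -> Ontology:
    ont = Ontology()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind, args = parts[0], parts[1:]
        if kind == "concept" and len(args) == 1:
            ont.concepts.add(args[0])
        elif kind == "isa" and len(args) == 2:
            ont.isa_edges.setdefault(args[0], set()).add(args[1])
        elif kind == "property" and len(args) == 1:
            ont.properties.add(args[0])
        elif kind == "alias" and len(args) == 2:
            ont.abbreviations[args[0]] = args[1]
        else:
            raise OntologyError(f"line {lineno}: cannot parse ontology declaration {raw.strip()!r}")
    ont.validate()
    return ont


def load_ontology(source: str | IO[str]) -> Ontology:
    """Load and validate an ontology from a path or open text stream."""
    if hasattr(source, "read"):
        return _parse_lines(source)  # type: ignore[arg-type]
    with open(source, encoding="utf-8") as handle:
        return _parse_lines(handle)


def default_ontology() -> Ontology:
    """The ontology shipped with the package."""
    text = _importlib_resources.files("regevents.resources").joinpath("gro.ont").read_text()
    return _parse_lines(text.splitlines())


def is_subconcept(ont: Ontology, a: str, b: str) -> bool:
    """Functional form of :meth:`Ontology.is_subconcept`."""
    return ont.is_subconcept(a, b)
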