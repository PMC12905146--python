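"""Ontology term hierarchies and transitive subClassOf queries.

Two loaders are provided: a 3-column term table (id, label, parent ids) for
compact fixtures and exports, and an RDF reader (RDF/XML, Turtle, or any
format rdflib sniffs) restricted to ``rdfs:subClassOf`` assertions between
named classes.  No OWL reasoning beyond the subClassOf closure is attempted.

Hierarchies are DAGs: a term may have several parents (FluMist sits under
both 'trivalent influenza vaccine' and 'live attenuated influenza vaccine'),
but a subClassOf cycle is an error.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "OntologyError",
    "load_ontology",
    "load_term_table",
    "load_rdf",
    "descendants",
    "label_to_id",
]


class OntologyError(ValueError):
    """Cyclic hierarchy or unknown term."""


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    label: str
    parents: tuple[str, ...] = ()
    uri: str | None = None


@dataclass
class OntologyGraph:
    """Terms plus the child→parent subClassOf edge set.

    ``graph`` is a directed networkx graph with edges child→parent, so
    descendant queries walk edges backwards (``predecessors``).
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    dangling_parents: set[str] = field(default_factory=set)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)


def _finalize(graph: OntologyGraph) -> OntologyGraph:
    for term in graph.terms.values():
        graph.graph.add_node(term.id)
        for parent in term.parents:
            if parent not in graph.terms:
                graph.dangling_parents.add(parent)
                warnings.warn(f"term {term.id}: parent {parent} not loaded", stacklevel=3)
            graph.graph.add_edge(term.id, parent)
    if not nx.is_directed_acyclic_graph(graph.graph):
        cycle = nx.find_cycle(graph.graph)
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyError(f"subClassOf cycle detected: {path}")
    return graph


def load_term_table(path: str | Path) -> OntologyGraph:
    """Load the 3-column term table: id, label, parent ids ('|'-separated)."""
    graph = OntologyGraph()
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            term_id = (row.get("id") or "").strip()
            if not term_id:
                continue
            parents = tuple(
                p.strip() for p in (row.get("parents") or "").split("|") if p.strip()
            )
            graph.terms[term_id] = OntologyTerm(
                id=term_id, label=(row.get("label") or "").strip(), parents=parents
            )
    return _finalize(graph)


def _curie(uri: str) -> str:
    """Compact a term URI to its CURIE-style local identifier."""
    local = uri.rstrip("/#").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    return local


def load_rdf(path: str | Path, fmt: str | None = None) -> OntologyGraph:
    """Load an RDF/OWL subset: named classes with rdfs:label and
    rdfs:subClassOf edges between named classes (anonymous restriction
    superclasses are ignored)."""
    import rdflib
    from rdflib.namespace import RDFS

    g = rdflib.Graph()
    g.parse(str(path), format=fmt)
    labels: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    uris: dict[str, str] = {}

    for s, o in g.subject_objects(RDFS.subClassOf):
        if isinstance(s, rdflib.URIRef) and isinstance(o, rdflib.URIRef):
            sid, oid = _curie(str(s)), _curie(str(o))
            parents.setdefault(sid, set()).add(oid)
            parents.setdefault(oid, set())
            uris[sid], uris[oid] = str(s), str(o)
    for s, o in g.subject_objects(RDFS.label):
        if isinstance(s, rdflib.URIRef):
            sid = _curie(str(s))
            labels.setdefault(sid, str(o))
            parents.setdefault(sid, set())
            uris[sid] = str(s)

    graph = OntologyGraph()
    for term_id in parents:
        graph.terms[term_id] = OntologyTerm(
            id=term_id,
            label=labels.get(term_id, term_id),
            parents=tuple(sorted(parents[term_id])),
            uri=uris.get(term_id),
        )
    return _finalize(graph)


def load_ontology(path: str | Path, fmt: str | None = None) -> OntologyGraph:
    """Load an ontology, dispatching on file extension: ``.csv``/``.tsv``
    use the term-table reader, anything else the RDF reader."""
    suffix = Path(path).suffix.lower()
    if suffix in (".csv", ".tsv"):
        return load_term_table(path)
    return load_rdf(path, fmt=fmt)


def descendants(graph: OntologyGraph, term_id: str, include_self: bool = False) -> set[str]:
    """Transitive subClassOf closure below a term.

    ``include_self=False`` matches SPARQL ``rdfs:subClassOf+`` (one or more
    hops); ``include_self=True`` matches the Cypher ``[:subClassOf*]``
    star quantifier (zero or more hops).
    """
    if term_id not in graph:
        raise OntologyError(f"unknown term {term_id!r}")
    # edges run child -> parent, so the subclass closure is every node with a
    # directed path to term_id, i.e. its "ancestors" in networkx's edge sense
    closure = nx.ancestors(graph.graph, term_id)
    if include_self:
        closure = set(closure) | {term_id}
    return set(closure)


def label_to_id(graph: OntologyGraph, label: str) -> str | None:
    """Exact, case-insensitive label lookup.  When several terms share a
    label, the lexicographically lowest id wins with a warning; unknown
    labels return None."""
    needle = label.strip().lower()
    hits = sorted(t.id for t in graph.terms.values() if t.label.lower() == needle)
    if not hits:
        return None
    if len(hits) > 1:
        warnings.warn(
            f"label {label!r} is ambiguous ({', '.join(hits)}); using {hits[0]}", stacklevel=2
        )
    return hits[0]
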