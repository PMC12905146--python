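"""Property-graph construction and export.

Builds an in-memory property graph from a validated bundle plus an ontology:
one node per record (labelled with its class), one node per ontology term
(labelled ``OntologyTerm``), one edge per non-null foreign key (typed by the
FK column), ``subClassOf`` edges between terms, and ``instance_of_term``
edges from any record whose ``*_ontology_id`` value matches a loaded term.

Exports target a graph database without requiring one: bulk-import-style
node/edge CSVs (``:ID``, ``:LABEL``, ``:START_ID``, ``:END_ID``, ``:TYPE``
headers) and an executable Cypher script of MERGE statements.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .bundle import RecordBundle, _norm_value
from .ontology import OntologyGraph
from .schema import SchemaRegistry

__all__ = ["KGNode", "build_graph", "materials_under", "node_detail", "export_graph", "import_graph_tables"]

TERM_LABEL = "OntologyTerm"
SUBCLASS = "subClassOf"
INSTANCE = "instance_of_term"


@dataclass(frozen=True)
class KGNode:
    id: str
    label: str
    properties: dict[str, str]


def build_graph(
    bundle: RecordBundle,
    ontology: OntologyGraph | None = None,
    registry: SchemaRegistry | None = None,
) -> nx.MultiDiGraph:
    """Assemble the property graph.  Record node ids are ``Class:primary_key``;
    term node ids are the term CURIEs."""
    from .schema import build_default_registry

    registry = registry or build_default_registry()
    g = nx.MultiDiGraph()

    if ontology is not None:
        for term in ontology.terms.values():
            props = {"label": term.label}
            if term.uri:
                props["uri"] = term.uri
            g.add_node(term.id, label=TERM_LABEL, properties=props)
        for child, parent in ontology.edges:
            if child in g and parent in g:
                g.add_edge(child, parent, key=SUBCLASS, type=SUBCLASS)

    node_ids: dict[tuple[str, str], str] = {}
    for class_name, rows in bundle.tables.items():
        if class_name not in registry:
            continue
        cdef = registry[class_name]
        for rec in rows:
            pk = _norm_value(rec.get(cdef.primary_key))
            if pk is None:
                continue
            node_id = f"{class_name}:{pk}"
            props = {k: v for k, v in ((k, _norm_value(v)) for k, v in rec.items()) if v is not None}
            g.add_node(node_id, label=class_name, properties=props)
            node_ids[(class_name, pk)] = node_id

    for class_name, rows in bundle.tables.items():
        if class_name not in registry:
            continue
        cdef = registry[class_name]
        for rec in rows:
            pk = _norm_value(rec.get(cdef.primary_key))
            if pk is None:
                continue
            src = f"{class_name}:{pk}"
            for fk in cdef.foreign_keys:
                value = _norm_value(rec.get(fk.column))
                if value is None:
                    continue
                target = node_ids.get((fk.target_class, value))
                if target is not None:
                    g.add_edge(src, target, key=fk.column, type=fk.column)
            if ontology is not None:
                for field_name, value in rec.items():
                    if not field_name.endswith("_ontology_id"):
                        continue
                    term = _norm_value(value)
                    if term is not None and term in ontology:
                        g.add_edge(src, term, key=f"{INSTANCE}:{field_name}", type=INSTANCE)
    return g


def _term_closure(g: nx.MultiDiGraph, term_id: str) -> set[str]:
    """Terms reachable from term_id by zero or more reversed subClassOf hops."""
    closure = {term_id}
    frontier = [term_id]
    while frontier:
        node = frontier.pop()
        for child, _, data in g.in_edges(node, data=True):
            if data.get("type") == SUBCLASS and child not in closure:
                closure.add(child)
                frontier.append(child)
    return closure


def materials_under(g: nx.MultiDiGraph, term_id: str) -> list[str]:
    """Material node ids linked (via instance_of_term) to the term or any of
    its transitive subclasses — zero-or-more-hop star semantics."""
    if term_id not in g or g.nodes[term_id].get("label") != TERM_LABEL:
        raise KeyError(f"unknown ontology term node {term_id!r}")
    closure = _term_closure(g, term_id)
    out = set()
    for src, dst, data in g.edges(data=True):
        if data.get("type") == INSTANCE and dst in closure:
            if g.nodes[src].get("label") == "Material":
                out.add(src)
    return sorted(out)


def node_detail(g: nx.MultiDiGraph, node_id: str) -> KGNode:
    """Full property map of one node."""
    if node_id not in g:
        raise KeyError(f"unknown node {node_id!r}")
    data = g.nodes[node_id]
    return KGNode(id=node_id, label=data.get("label", ""), properties=dict(data.get("properties", {})))


def export_graph(g: nx.MultiDiGraph, fmt: str, out_dir: str | Path) -> list[Path]:
    """Write the graph as bulk-import node/edge CSVs or as a Cypher script.

    ``node_edge_tables``: one ``nodes_<LABEL>.csv`` per label (``:ID``,
    ``:LABEL``, then that label's property columns) plus ``edges.csv``
    (``:START_ID``, ``:END_ID``, ``:TYPE``).  ``cypher_script``: one MERGE
    statement per node and per edge in ``graph.cypher``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    if fmt == "node_edge_tables":
        by_label: dict[str, list[tuple[str, dict[str, str]]]] = {}
        for node_id, data in g.nodes(data=True):
            by_label.setdefault(data.get("label", "Node"), []).append(
                (node_id, data.get("properties", {}))
            )
        for label in sorted(by_label):
            rows = by_label[label]
            prop_cols = sorted({k for _, props in rows for k in props})
            path = out / f"nodes_{label}.csv"
            with path.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow([":ID", ":LABEL", *prop_cols])
                for node_id, props in sorted(rows):
                    writer.writerow([node_id, label, *(props.get(c, "") for c in prop_cols)])
            paths.append(path)
        path = out / "edges.csv"
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([":START_ID", ":END_ID", ":TYPE"])
            for src, dst, data in sorted(g.edges(data=True), key=lambda e: (e[0], e[1], e[2].get("type", ""))):
                writer.writerow([src, dst, data.get("type", "")])
        paths.append(path)
    elif fmt == "cypher_script":
        path = out / "graph.cypher"
        lines: list[str] = []
        for node_id, data in sorted(g.nodes(data=True)):
            props = data.get("properties", {})
            prop_str = ", ".join(
                f"{k}: {_cypher_str(v)}" for k, v in sorted(props.items())
            )
            body = f"{{id: {_cypher_str(node_id)}" + (f", {prop_str}" if prop_str else "") + "}"
            lines.append(f"MERGE (n:{_cypher_label(data.get('label', 'Node'))} {body});")
        for src, dst, data in sorted(g.edges(data=True), key=lambda e: (e[0], e[1], e[2].get("type", ""))):
            rel = _cypher_label(data.get("type", "RELATED"))
            lines.append(
                f"MATCH (a {{id: {_cypher_str(src)}}}), (b {{id: {_cypher_str(dst)}}}) "
                f"MERGE (a)-[:{rel}]->(b);"
            )
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return paths


def _cypher_str(value: str) -> str:
    escaped = str(value).replace("\\", "\\\\").replace("'", "\\'")
    return f"'{escaped}'"


def _cypher_label(name: str) -> str:
    return "".join(c if c.isalnum() or c == "_" else "_" for c in name)


def import_graph_tables(in_dir: str | Path) -> nx.MultiDiGraph:
    """Re-parse a node_edge_tables export back into a graph (for round-trip
    verification; isomorphic to the exported graph)."""
    src = Path(in_dir)
    g = nx.MultiDiGraph()
    for path in sorted(src.glob("nodes_*.csv")):
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                node_id = row.pop(":ID")
                label = row.pop(":LABEL")
                props = {k: v for k, v in row.items() if v != ""}
                g.add_node(node_id, label=label, properties=props)
    edges = src / "edges.csv"
    if edges.exists():
        with edges.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                g.add_edge(row[":START_ID"], row[":END_ID"], type=row[":TYPE"])
    return g
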