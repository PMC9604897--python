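"""Network export formats: SIF and GraphML.

SIF (simple interaction format) writes one edge per line,
``source <TAB> kind <TAB> target``, where kind is the edge kind
(reactant / product / modifier).  GraphML preserves node kind and label
plus edge kind as typed attribute keys, and round-trips losslessly
through :func:`read_graphml`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from lxml import etree

from .netanalysis import DirectedGraph, GraphEdge, GraphNode

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_sif(graph: DirectedGraph) -> str:
    """One line per edge; isolated graph nodes are emitted as bare names."""
    lines = [f"{e.source}\t{e.kind}\t{e.target}" for e in graph.edges]
    touched = {e.source for e in graph.edges} | {e.target for e in graph.edges}
    lines += [n.id for n in graph.nodes if n.id not in touched]
    return "\n".join(lines) + "\n"


def _q(tag: str) -> str:
    return f"{{{GRAPHML_NS}}}{tag}"


def write_graphml(graph: DirectedGraph) -> str:
    root = etree.Element(_q("graphml"), nsmap={None: GRAPHML_NS})
    for key_id, attr in (("kind", "kind"), ("label", "label"), ("ekind", "kind")):
        el = etree.SubElement(root, _q("key"))
        el.set("id", key_id)
        el.set("for", "edge" if key_id == "ekind" else "node")
        el.set("attr.name", attr)
        el.set("attr.type", "string")
    g = etree.SubElement(root, _q("graph"), edgedefault="directed")
    g.set("id", "G")
    for n in graph.nodes:
        el = etree.SubElement(g, _q("node"))
        el.set("id", n.id)
        for key, value in (("kind", n.kind), ("label", n.label)):
            d = etree.SubElement(el, _q("data"))
            d.set("key", key)
            d.text = value
    for e in graph.edges:
        el = etree.SubElement(g, _q("edge"))
        el.set("source", e.source)
        el.set("target", e.target)
        d = etree.SubElement(el, _q("data"))
        d.set("key", "ekind")
        d.text = e.kind
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()


def read_graphml(source: Union[str, Path]) -> DirectedGraph:
    text = source if isinstance(source, str) and "\n" in source else Path(source).read_text()
    root = etree.fromstring(text.encode())
    g = root.find(_q("graph"))
    if g is None:
        raise ValueError("no <graph> element")
    nodes = []
    for el in g.findall(_q("node")):
        data = {d.get("key"): (d.text or "") for d in el.findall(_q("data"))}
        nodes.append(GraphNode(el.get("id"), data.get("kind", "species"), data.get("label", "")))
    edges = []
    for el in g.findall(_q("edge")):
        data = {d.get("key"): (d.text or "") for d in el.findall(_q("data"))}
        edges.append(GraphEdge(el.get("source"), el.get("target"), data.get("ekind", "link")))
    return DirectedGraph(nodes=nodes, edges=edges)


def export_network(graph: DirectedGraph, format: str) -> str:
    """Dispatch on format name ("SIF" or "GraphML")."""
    fmt = format.strip().lower()
    if fmt == "sif":
        return write_sif(graph)
    if fmt == "graphml":
        return write_graphml(graph)
    raise ValueError(f"unknown network format {format!r}")
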