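"""Serialization of gene networks: SIF, GraphML, TSV edge list.

SIF (simple interaction format) is the 3-column tab-separated dialect used by
Cytoscape: ``source<TAB>interaction-type<TAB>target``, one record per
(edge, type) pair, no header.  Node identifiers are namespace-prefixed
(``hsa:5290`` in native mode, ``EntrezGene:5290`` after identifier
conversion).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import TextIO, Union

import networkx as nx

from .model import GeneNetwork, NodeRef, PathnetError, TypedEdge

Sink = Union[str, Path, TextIO]


def _node_label(network: GeneNetwork, node_id: str) -> str:
    node = network.nodes.get(node_id)
    return node.primary_label if node is not None else node_id


def _open_sink(sink: Sink):
    if isinstance(sink, (str, Path)):
        try:
            return open(sink, "w"), True
        except OSError as exc:
            raise PathnetError(f"cannot write to {sink}: {exc}") from exc
    return sink, False


def write_sif(network: GeneNetwork, sink: Sink, expand_undirected: bool = False) -> int:
    """Write SIF records in canonical (source, type, target) order.

    Undirected edges are written once (endpoints in label order) or, with
    ``expand_undirected``, as two reciprocal directed records.  Returns the
    number of records written.
    """
    records: set[tuple[str, str, str]] = set()
    for edge in network.edges.values():
        src, dst = _node_label(network, edge.src), _node_label(network, edge.dst)
        pairs = [(src, dst)]
        if not edge.directed:
            if expand_undirected:
                pairs.append((dst, src))
            else:
                pairs = [tuple(sorted((src, dst)))]
        for a, b in pairs:
            for t in edge.types:
                records.add((a, t, b))
    handle, owned = _open_sink(sink)
    try:
        for record in sorted(records):
            handle.write("\t".join(record) + "\n")
    finally:
        if owned:
            handle.close()
    return len(records)


def read_sif(source: Union[str, Path, TextIO, io.StringIO]) -> set[tuple[str, str, str]]:
    """Parse SIF back into its (source, type, target) record set."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    records = set()
    for line in text.splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise PathnetError(f"malformed SIF record: {line!r}")
        records.add(tuple(fields))
    return records


def to_networkx(network: GeneNetwork) -> nx.MultiDiGraph:
    """Lossless graph view: one arc per merged edge, attributes carry the
    type set (``;``-joined), the directedness flag and provenance."""
    graph = nx.MultiDiGraph(pathway_id=network.pathway_id, title=network.title,
                            id_namespace=network.id_namespace)
    for node_id in sorted(network.nodes):
        node = network.nodes[node_id]
        graph.add_node(node_id, label=node.primary_label, display=node.display_label)
    for edge in network.edge_records():
        graph.add_edge(
            edge.src,
            edge.dst,
            types=";".join(sorted(edge.types)),
            directed=edge.directed,
            provenance=";".join(edge.provenance),
        )
    return graph


def write_graph(network: GeneNetwork, fmt: str, sink: Union[str, Path]) -> int:
    """Write GraphML or a TSV edge list; returns the number of edges written."""
    path = Path(sink)
    if fmt == "graphml":
        graph = to_networkx(network)
        try:
            nx.write_graphml(graph, path)
        except OSError as exc:
            raise PathnetError(f"cannot write to {path}: {exc}") from exc
        return graph.number_of_edges()
    if fmt == "edgelist":
        lines = [
            f"{_node_label(network, e.src)}\t{_node_label(network, e.dst)}\t"
            f"{';'.join(sorted(e.types))}\t{'directed' if e.directed else 'undirected'}"
            for e in network.edge_records()
        ]
        try:
            path.write_text("\n".join(lines) + ("\n" if lines else ""))
        except OSError as exc:
            raise PathnetError(f"cannot write to {path}: {exc}") from exc
        return len(lines)
    raise PathnetError(f"unknown graph format {fmt!r}; use graphml or edgelist")
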