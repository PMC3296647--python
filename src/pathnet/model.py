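"""Core data model for pathway topologies and derived gene networks.

A pathway, as annotated in KGML or BioPAX, is a mixed graph whose nodes are
genes/proteins, chemical compounds, and *groups* (protein complexes or sets of
alternative gene-family members).  Converting such a topology to a plain
gene-gene network requires expanding groups and propagating signal through
compounds; this module holds the containers shared by every stage of that
pipeline and the edge-merging rule that keeps parallel relations as a single
edge with a set of interaction types.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Union

__all__ = [
    "PathnetError",
    "StructuralError",
    "EmptyInputError",
    "NodeRef",
    "GroupNode",
    "TypedEdge",
    "PathwayTopology",
    "GeneNetwork",
    "NetworkSummary",
    "merge_edge",
    "summarize",
    "validate_gene_network",
]


class PathnetError(Exception):
    """Base class for all errors raised by this package."""


class StructuralError(PathnetError):
    """A graph invariant is violated (dangling edge, bad group member, ...)."""


class EmptyInputError(PathnetError):
    """An operation requiring non-empty input received nothing."""


GENE = "gene"
COMPOUND = "compound"
GROUP = "group"

AND = "AND"
OR = "OR"


@dataclass(frozen=True)
class NodeRef:
    """A simple (non-group) pathway node: a gene product or a chemical compound.

    ``native_ids`` is an ordered tuple of ``(namespace, identifier)`` pairs as
    found in the source annotation (e.g. ``("hsa", "5290")`` from KGML or
    ``("EntrezGene", "5290")`` from a BioPAX xref).
    """

    node_id: str
    kind: str  # GENE or COMPOUND
    native_ids: tuple[tuple[str, str], ...] = ()
    display_label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (GENE, COMPOUND):
            raise StructuralError(f"invalid node kind {self.kind!r} for {self.node_id!r}")
        if self.kind == GENE and not self.native_ids:
            raise StructuralError(f"gene node {self.node_id!r} has no native identifiers")

    @property
    def primary_label(self) -> str:
        """Namespace-prefixed identifier used in exports, e.g. ``hsa:5290``."""
        if self.native_ids:
            ns, ident = self.native_ids[0]
            return f"{ns}:{ident}" if ns else ident
        return self.node_id


@dataclass(frozen=True)
class GroupNode:
    """A container node: an AND group (protein complex, expanded to a clique)
    or an OR group (alternative members, expanded without mutual edges).

    ``members`` holds node ids of other nodes in the same pathway; nesting
    (a group member that is itself a group) is allowed, e.g. OR groups of
    protein variants inside an AND complex.
    """

    node_id: str
    semantics: str  # AND or OR
    members: tuple[str, ...]
    display_label: str = ""

    def __post_init__(self) -> None:
        if self.semantics not in (AND, OR):
            raise StructuralError(
                f"group {self.node_id!r}: semantics must be AND or OR, got {self.semantics!r}"
            )
        if not self.members:
            raise StructuralError(f"group {self.node_id!r} has no members")

    @property
    def kind(self) -> str:
        return GROUP


Node = Union[NodeRef, GroupNode]


@dataclass(frozen=True)
class TypedEdge:
    """A typed, optionally directed edge.

    ``types`` is an open set of interaction-type strings seeded from the
    source annotation (``activation``, ``catalysisOut (ACTIVATION)``, ...)
    plus types synthesized during conversion.  ``compartment`` carries the
    cellular location of a compound occurrence when one endpoint is a
    compound in a specific reaction; ``None`` means unannotated and is
    treated as the distinguished label ``"unknown"``.  ``via_compound``
    records a still-unsplit bridging compound from a KGML relation subtype.
    """

    src: str
    dst: str
    directed: bool = True
    types: frozenset[str] = frozenset()
    compartment: Optional[str] = None
    provenance: tuple[str, ...] = ()
    via_compound: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.types:
            raise StructuralError(f"edge {self.src!r}->{self.dst!r} has an empty type set")
        if not isinstance(self.types, frozenset):
            object.__setattr__(self, "types", frozenset(self.types))

    def key(self) -> tuple[str, str, bool]:
        """Merge key: undirected edges are canonicalized by endpoint order."""
        if self.directed:
            return (self.src, self.dst, True)
        a, b = sorted((self.src, self.dst))
        return (a, b, False)

    def compartment_label(self) -> str:
        return self.compartment if self.compartment is not None else "unknown"


@dataclass
class PathwayTopology:
    """Raw mixed graph parsed from one pathway annotation."""

    pathway_id: str
    title: str = ""
    database_tag: str = "synthetic"  # kegg | reactome | biocarta | nci | synthetic
    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[TypedEdge] = field(default_factory=list)
    retrieved_on: str = ""

    def add_node(self, node: Node) -> None:
        if node.node_id in self.nodes:
            raise StructuralError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def add_edge(self, edge: TypedEdge) -> None:
        for endpoint in (edge.src, edge.dst):
            if endpoint not in self.nodes:
                raise StructuralError(
                    f"edge {edge.src!r}->{edge.dst!r} references unknown node {endpoint!r}"
                )
        self.edges.append(edge)

    def groups(self) -> Iterator[GroupNode]:
        return (n for n in self.nodes.values() if isinstance(n, GroupNode))

    def has_groups(self) -> bool:
        return any(True for _ in self.groups())

    def validate(self) -> None:
        for edge in self.edges:
            for endpoint in (edge.src, edge.dst):
                if endpoint not in self.nodes:
                    raise StructuralError(
                        f"dangling edge endpoint {endpoint!r} in pathway {self.pathway_id!r}"
                    )
        for group in self.groups():
            for member in group.members:
                if member not in self.nodes:
                    raise StructuralError(
                        f"group {group.node_id!r} references missing member {member!r}"
                    )


@dataclass
class GeneNetwork:
    """Final genes-only network.

    Parallel same-direction edges are merged: ``edges`` maps the canonical
    edge key to a single :class:`TypedEdge` whose type set is the union of
    everything observed between that node pair.
    """

    pathway_id: str
    title: str = ""
    nodes: dict[str, NodeRef] = field(default_factory=dict)
    edges: dict[tuple[str, str, bool], TypedEdge] = field(default_factory=dict)
    id_namespace: str = "native"  # native | entrez | symbol

    def add_node(self, node: NodeRef) -> None:
        if node.kind != GENE:
            raise StructuralError(
                f"gene network {self.pathway_id!r} rejects {node.kind} node {node.node_id!r}"
            )
        self.nodes.setdefault(node.node_id, node)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_records(self) -> list[TypedEdge]:
        """Edges in a canonical, deterministic order."""
        return [self.edges[k] for k in sorted(self.edges, key=lambda k: (k[0], k[1], k[2]))]

    def canonical_form(self) -> tuple:
        """Hashable canonical serialization used in determinism checks."""
        nodes = tuple(sorted((n.node_id, n.native_ids) for n in self.nodes.values()))
        edges = []
        for e in self.edge_records():
            src, dst = e.src, e.dst
            if not e.directed and dst < src:
                src, dst = dst, src
            edges.append((src, dst, e.directed, tuple(sorted(e.types))))
        return (self.pathway_id, self.id_namespace, nodes, tuple(edges))

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(
            pathway_id=self.pathway_id,
            title=self.title,
            nodes=dict(self.nodes),
            edges=dict(self.edges),
            id_namespace=self.id_namespace,
        )


def merge_edge(network: GeneNetwork, edge: TypedEdge) -> GeneNetwork:
    """Insert ``edge`` into ``network``, merging with any parallel edge.

    Two edges are parallel when they share source, target and directedness
    (undirected edges compare without endpoint order).  Merging unions the
    type sets and provenance, so the result is independent of insertion
    order.  The network is modified in place and returned.
    """
    for endpoint in (edge.src, edge.dst):
        if endpoint not in network.nodes:
            raise StructuralError(
                f"edge endpoint {endpoint!r} is not a node of network {network.pathway_id!r}"
            )
    key = edge.key()
    existing = network.edges.get(key)
    if existing is None:
        network.edges[key] = replace(edge, via_compound=None)
    else:
        merged_prov = existing.provenance + tuple(
            p for p in edge.provenance if p not in existing.provenance
        )
        network.edges[key] = replace(
            existing,
            types=existing.types | edge.types,
            provenance=merged_prov,
        )
    return network


def validate_gene_network(network: GeneNetwork) -> None:
    """Raise unless ``network`` satisfies all gene-network invariants."""
    for node in network.nodes.values():
        if not isinstance(node, NodeRef) or node.kind != GENE:
            kind = getattr(node, "kind", type(node).__name__)
            raise StructuralError(
                f"network {network.pathway_id!r} contains a {kind} node: {node.node_id!r}"
            )
    for key, edge in network.edges.items():
        if edge.key() != key:
            raise StructuralError(f"edge stored under wrong key: {key} vs {edge.key()}")
        for endpoint in (edge.src, edge.dst):
            if endpoint not in network.nodes:
                raise StructuralError(f"dangling edge endpoint {endpoint!r}")


@dataclass(frozen=True)
class NetworkSummary:
    """Per-collection node/edge statistics (counts are per network)."""

    n_pathways: int
    mean_nodes: float
    median_nodes: float
    mean_edges: float
    median_edges: float


def summarize(networks: Iterable[GeneNetwork]) -> NetworkSummary:
    """Mean and median node/edge counts over a collection of networks."""
    networks = list(networks)
    if not networks:
        raise EmptyInputError("summarize requires at least one network")
    node_counts = [n.n_nodes for n in networks]
    edge_counts = [n.n_edges for n in networks]
    return NetworkSummary(
        n_pathways=len(networks),
        mean_nodes=statistics.fmean(node_counts),
        median_nodes=float(statistics.median(node_counts)),
        mean_edges=statistics.fmean(edge_counts),
        median_edges=float(statistics.median(edge_counts)),
    )
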