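"""Pathway topology to gene network conversion.

Three rules turn a raw mixed pathway graph into a genes-only network:

* **Group expansion** — an AND group (protein complex) becomes a clique of
  undirected ``binding`` edges between leaf genes drawn from *different*
  direct children, so alternative variants collected in a nested OR child are
  never linked to each other; an OR group (gene family / alternatives) adds
  no internal edges.  Edges incident to a group are replicated to every leaf.

* **Compound propagation** — chemical compounds are not measured by
  expression assays and must leave the network, but simply deleting them
  breaks signal cascades.  For every direction-respecting simple path
  ``gene A -> c1 -> ... -> cm -> gene B`` whose interior is entirely
  non-blacklisted compounds and whose compartment labels agree at every
  shared compound, a direct ``A -> B`` edge is synthesized.  Ubiquitous
  species (water, ATP, H+, ...) are blacklisted because propagating through
  them creates degenerate, arbitrarily long chains.

* **Edge merging** — parallel relations collapse to one edge carrying the
  union of interaction types.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .model import (
    AND,
    COMPOUND,
    GENE,
    OR,
    EmptyInputError,
    GeneNetwork,
    GroupNode,
    NodeRef,
    PathnetError,
    PathwayTopology,
    StructuralError,
    TypedEdge,
    merge_edge,
    validate_gene_network,
)

log = logging.getLogger(__name__)

BINDING_TYPE = "binding"
INDIRECT_TYPE = "indirect (compound-mediated)"

#: Ubiquitous small molecules never used for signal propagation.  Entries are
#: matched (case-insensitively) against a compound's bare identifiers,
#: namespace-prefixed identifiers and display label.  KEGG COMPOUND ids cover
#: hydrogen ion, water, ATP/ADP, NAD(+/H), NADP(+/H), CO2 and phosphate; the
#: names catch the same species in BioPAX sources.
DEFAULT_BLACKLIST: frozenset[str] = frozenset(
    s.lower()
    for s in (
        "cpd:C00080", "C00080", "h+", "hydrogen ion", "proton",
        "cpd:C00001", "C00001", "h2o", "water",
        "cpd:C00002", "C00002", "atp",
        "cpd:C00008", "C00008", "adp",
        "cpd:C00003", "C00003", "nad+", "nad",
        "cpd:C00004", "C00004", "nadh",
        "cpd:C00006", "C00006", "nadp+", "nadp",
        "cpd:C00005", "C00005", "nadph",
        "cpd:C00011", "C00011", "co2", "carbon dioxide",
        "cpd:C00009", "C00009", "pi", "phosphate", "orthophosphate",
    )
)


@dataclass(frozen=True)
class ConversionConfig:
    """Tunable knobs of the topology-to-network conversion.

    max_chain_length caps the gene-to-gene path length in *edges* (a single
    bridging compound is a length-2 chain); observed chains in curated
    databases top out at 9, so the default of 10 is permissive.
    """

    compound_blacklist: frozenset[str] = DEFAULT_BLACKLIST
    max_chain_length: int = 10
    require_compartment_match: bool = True
    propagate_direction: bool = True
    enable_propagation: bool = True

    def __post_init__(self) -> None:
        if self.max_chain_length < 2:
            raise PathnetError("max_chain_length must be >= 2")
        norm = frozenset(str(s).lower() for s in self.compound_blacklist)
        object.__setattr__(self, "compound_blacklist", norm)

    @classmethod
    def from_file(cls, path: str | Path) -> "ConversionConfig":
        """Load a config from YAML or JSON (keys = field names)."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        data = data or {}
        if "compound_blacklist" in data:
            data["compound_blacklist"] = frozenset(data["compound_blacklist"])
        return cls(**data)


@dataclass
class ChainHistogram:
    """Frequency of propagated compound-chain lengths.

    Keys are chain lengths in edges (>= 2); values count realized
    gene-to-gene connections propagated through a chain of that length.
    """

    counts: dict[int, int] = field(default_factory=dict)

    def record(self, length: int) -> None:
        if length < 2:
            raise PathnetError(f"chain length must be >= 2, got {length}")
        self.counts[length] = self.counts.get(length, 0) + 1

    def merge(self, other: "ChainHistogram") -> None:
        for length, count in other.counts.items():
            self.counts[length] = self.counts.get(length, 0) + count

    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict[int, int]:
        return dict(sorted(self.counts.items()))


def is_blacklisted(node: NodeRef, blacklist: frozenset[str]) -> bool:
    """True when a compound matches the ubiquitous-species blacklist."""
    candidates = {node.display_label.lower()} if node.display_label else set()
    for ns, ident in node.native_ids:
        candidates.add(ident.lower())
        candidates.add(f"{ns}:{ident}".lower())
    return bool(candidates & blacklist)


# ---------------------------------------------------------------------------
# Group expansion


def expand_groups(topology: PathwayTopology) -> PathwayTopology:
    """Replace every group node by its leaf genes.

    AND groups add an undirected ``binding`` edge between every pair of leaf
    genes from different direct children (a plain AND of k genes yields the
    full k(k-1)/2 clique); OR groups add nothing internally.  External edges
    incident to a group are replicated to all of its leaves with direction
    and types preserved.
    """
    leaf_cache: dict[str, tuple[str, ...]] = {}
    binding_pairs: set[tuple[str, str]] = set()

    def leaves(node_id: str, stack: tuple[str, ...] = ()) -> tuple[str, ...]:
        if node_id in stack:
            raise StructuralError(f"group nesting cycle through {node_id!r}")
        node = topology.nodes.get(node_id)
        if node is None:
            raise StructuralError(f"group member {node_id!r} not found in pathway")
        if isinstance(node, NodeRef):
            if node.kind == COMPOUND:
                raise StructuralError(
                    f"group member {node_id!r} is a compound; groups contain only gene products"
                )
            return (node_id,)
        if node_id in leaf_cache:
            return leaf_cache[node_id]
        child_leaf_sets = [leaves(m, stack + (node_id,)) for m in node.members]
        if node.semantics == AND:
            for i in range(len(child_leaf_sets)):
                for j in range(i + 1, len(child_leaf_sets)):
                    for a in child_leaf_sets[i]:
                        for b in child_leaf_sets[j]:
                            if a != b:
                                binding_pairs.add(tuple(sorted((a, b))))
        flat = tuple(dict.fromkeys(x for leaf_set in child_leaf_sets for x in leaf_set))
        leaf_cache[node_id] = flat
        return flat

    for group in list(topology.groups()):
        leaves(group.node_id)

    out = PathwayTopology(
        pathway_id=topology.pathway_id,
        title=topology.title,
        database_tag=topology.database_tag,
        retrieved_on=topology.retrieved_on,
    )
    for node in topology.nodes.values():
        if isinstance(node, NodeRef):
            out.add_node(node)

    for edge in topology.edges:
        src_leaves = leaf_cache.get(edge.src, (edge.src,))
        dst_leaves = leaf_cache.get(edge.dst, (edge.dst,))
        for s in src_leaves:
            for d in dst_leaves:
                out.add_edge(replace(edge, src=s, dst=d))

    for a, b in sorted(binding_pairs):
        out.add_edge(TypedEdge(src=a, dst=b, directed=False, types=frozenset({BINDING_TYPE})))
    return out


# ---------------------------------------------------------------------------
# Compound propagation


def _compartments_agree(incoming: TypedEdge, outgoing: TypedEdge) -> bool:
    # "unknown" only matches another "unknown": conservative reading of the
    # localization rule when annotation is missing on one side.
    return incoming.compartment_label() == outgoing.compartment_label()


def propagate_compounds(
    topology: PathwayTopology, config: ConversionConfig | None = None
) -> tuple[GeneNetwork, ChainHistogram]:
    """Remove compounds, bridging the signal that flowed through them.

    Requires a group-free topology.  Returns the genes-only network plus a
    histogram of realized chain lengths (each distinct simple compound chain
    counts once, whatever pair of genes it connects).
    """
    config = config or ConversionConfig()
    if topology.has_groups():
        raise PathnetError(
            "propagate_compounds requires a group-free topology; call expand_groups first"
        )

    network = GeneNetwork(pathway_id=topology.pathway_id, title=topology.title)
    genes = {nid for nid, n in topology.nodes.items() if n.kind == GENE}
    for nid in genes:
        network.add_node(topology.nodes[nid])

    histogram = ChainHistogram()

    # Gene-gene edges pass through unchanged.
    for edge in topology.edges:
        if edge.src in genes and edge.dst in genes:
            merge_edge(network, edge)

    if not config.enable_propagation:
        return network, histogram

    compounds = {
        nid
        for nid, n in topology.nodes.items()
        if n.kind == COMPOUND and not is_blacklisted(n, config.compound_blacklist)
    }

    # Traversal arcs: (neighbour, edge index, followed in stored direction).
    edge_index = {i: e for i, e in enumerate(topology.edges)}
    arcs: dict[str, list[tuple[str, int, bool]]] = defaultdict(list)
    for i, e in edge_index.items():
        arcs[e.src].append((e.dst, i, True))
        if not e.directed or not config.propagate_direction:
            arcs[e.dst].append((e.src, i, False))

    seen_chains: set[tuple[int, ...]] = set()

    def emit(start: str, end: str, path: list[tuple[int, bool]]) -> None:
        directed = all(edge_index[i].directed and fwd for i, fwd in path)
        signature = tuple(i for i, _ in path)
        canonical = signature if directed else min(signature, tuple(reversed(signature)))
        if canonical in seen_chains:
            return
        seen_chains.add(canonical)
        first, last = edge_index[path[0][0]], edge_index[path[-1][0]]
        merge_edge(
            network,
            TypedEdge(
                src=start,
                dst=end,
                directed=directed,
                types=first.types | last.types | {INDIRECT_TYPE},
                provenance=first.provenance + last.provenance,
            ),
        )
        histogram.record(len(path))

    def walk(
        start: str,
        at: str,
        path: list[tuple[int, bool]],
        visited: frozenset[str],
    ) -> None:
        if len(path) >= config.max_chain_length:
            return
        last_index = path[-1][0]
        last_edge = edge_index[last_index]
        for nbr, i, fwd in arcs[at]:
            if i == last_index:
                continue  # no immediate backtracking along the same edge
            edge = edge_index[i]
            if config.require_compartment_match and not _compartments_agree(last_edge, edge):
                continue
            if nbr in genes:
                emit(start, nbr, path + [(i, fwd)])
            elif nbr in compounds and nbr not in visited:
                walk(start, nbr, path + [(i, fwd)], visited | {nbr})

    for gene in sorted(genes):
        for nbr, i, fwd in arcs[gene]:
            if nbr in compounds:
                walk(gene, nbr, [(i, fwd)], frozenset({nbr}))

    return network, histogram


# ---------------------------------------------------------------------------
# Full pipeline


def convert(
    topology: PathwayTopology, config: ConversionConfig | None = None
) -> tuple[GeneNetwork, ChainHistogram]:
    """Full conversion with chain accounting: split KGML compound subtypes,
    expand groups, propagate compounds, merge edges."""
    from .kgml import split_compound_subtype  # local import: avoid cycle

    config = config or ConversionConfig()
    topology = split_compound_subtype(topology)
    topology = expand_groups(topology)
    network, histogram = propagate_compounds(topology, config)
    validate_gene_network(network)
    return network, histogram


def build_network(
    topology: PathwayTopology, config: ConversionConfig | None = None
) -> GeneNetwork:
    """Convert a parsed pathway topology to its gene network."""
    network, _ = convert(topology, config)
    return network


def filter_edges(network: GeneNetwork, keep_types: Iterable[str]) -> GeneNetwork:
    """Keep edges carrying at least one of ``keep_types`` (full type sets are
    preserved); nodes — including newly isolated ones — are all retained."""
    keep = frozenset(keep_types)
    if not keep:
        raise EmptyInputError("keep_types must be non-empty")
    out = network.copy()
    out.edges = {k: e for k, e in network.edges.items() if e.types & keep}
    return out
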