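"""Brute-force reference conversion used to validate the converter.

This module re-derives the gene network of a small topology by exhaustive
enumeration: group leaves are resolved by a standalone recursion, compound
chains are found by enumerating *all* simple node paths between every ordered
gene pair and then checking every combination of parallel edges along each
path against the blacklist, compartment and length constraints.  It favours
obviousness over speed (intended for topologies of a few dozen nodes) and is
deliberately kept free of the incremental pruning and merging the production
converter performs.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import replace
from typing import Optional

from .converter import ConversionConfig, is_blacklisted
from .kgml import COMPOUND_SPLIT_TYPE, split_compound_subtype
from .model import (
    AND,
    COMPOUND,
    GENE,
    GroupNode,
    NodeRef,
    PathwayTopology,
    StructuralError,
    TypedEdge,
)

EdgeRecord = tuple[str, str, bool, frozenset]
INDIRECT_TYPE = "indirect (compound-mediated)"
BINDING_TYPE = "binding"


def _group_leaves(topology: PathwayTopology, node_id: str) -> tuple[list[str], set[tuple[str, str]]]:
    """Leaf genes of a node plus the binding pairs its AND structure implies."""
    node = topology.nodes[node_id]
    if isinstance(node, NodeRef):
        if node.kind == COMPOUND:
            raise StructuralError(f"compound {node_id!r} inside a group")
        return [node_id], set()
    child_results = [_group_leaves(topology, m) for m in node.members]
    pairs: set[tuple[str, str]] = set()
    for _, child_pairs in child_results:
        pairs |= child_pairs
    if node.semantics == AND:
        for (la, _), (lb, _) in itertools.combinations(child_results, 2):
            for a in la:
                for b in lb:
                    if a != b:
                        pairs.add(tuple(sorted((a, b))))
    leaves = list(dict.fromkeys(x for child, _ in child_results for x in child))
    return leaves, pairs


def oracle_convert(
    topology: PathwayTopology, config: Optional[ConversionConfig] = None
) -> tuple[set[EdgeRecord], Counter]:
    """Expected (edge records, chain-length histogram) for a full conversion.

    Edge records are ``(src, dst, directed, types)`` with undirected records
    canonicalized by sorted endpoints.
    """
    config = config or ConversionConfig()

    # 1. split compound-subtype relations (independent re-derivation)
    edges: list[TypedEdge] = []
    for e in split_compound_subtype(topology).edges:
        edges.append(e)

    # 2. expand groups
    leaf_of: dict[str, list[str]] = {}
    binding_pairs: set[tuple[str, str]] = set()
    for node in topology.nodes.values():
        if isinstance(node, NodeRef):
            leaf_of[node.node_id] = [node.node_id]
        else:
            leaves, pairs = _group_leaves(topology, node.node_id)
            leaf_of[node.node_id] = leaves
            binding_pairs |= pairs

    flat_edges: list[TypedEdge] = []
    for e in edges:
        for s in leaf_of[e.src]:
            for d in leaf_of[e.dst]:
                flat_edges.append(replace(e, src=s, dst=d))
    for a, b in binding_pairs:
        flat_edges.append(TypedEdge(src=a, dst=b, directed=False, types=frozenset({BINDING_TYPE})))

    genes = {nid for nid, n in topology.nodes.items() if isinstance(n, NodeRef) and n.kind == GENE}
    compounds = {
        nid
        for nid, n in topology.nodes.items()
        if isinstance(n, NodeRef)
        and n.kind == COMPOUND
        and not is_blacklisted(n, config.compound_blacklist)
    }

    records: dict[tuple[str, str, bool], set] = defaultdict(set)

    def add_record(src: str, dst: str, directed: bool, types: frozenset) -> None:
        if not directed and dst < src:
            src, dst = dst, src
        records[(src, dst, directed)] |= set(types)

    # 3. gene-gene edges pass through
    for e in flat_edges:
        if e.src in genes and e.dst in genes:
            add_record(e.src, e.dst, e.directed, e.types)

    histogram: Counter = Counter()
    if config.enable_propagation:
        # arcs: (u, v, arc_id, forward)
        arcs = []
        for i, e in enumerate(flat_edges):
            arcs.append((e.src, e.dst, i, True))
            if not e.directed or not config.propagate_direction:
                arcs.append((e.dst, e.src, i, False))
        arcs_between: dict[tuple[str, str], list[tuple[int, bool]]] = defaultdict(list)
        neighbours: dict[str, set[str]] = defaultdict(set)
        for u, v, i, fwd in arcs:
            arcs_between[(u, v)].append((i, fwd))
            neighbours[u].add(v)

        def node_paths(start: str):
            """All simple node paths start -> compounds* -> gene, <= cap edges."""
            stack = [(start, [start])]
            while stack:
                at, path = stack.pop()
                if len(path) - 1 >= config.max_chain_length:
                    continue
                for nxt in sorted(neighbours[at]):
                    if nxt in genes:
                        if len(path) >= 2:
                            yield path + [nxt]
                    elif nxt in compounds and nxt not in path[1:]:
                        stack.append((nxt, path + [nxt]))

        seen_chains: set[tuple[int, ...]] = set()
        for gene in sorted(genes):
            for path in node_paths(gene):
                hops = list(zip(path, path[1:]))
                for combo in itertools.product(*(arcs_between[h] for h in hops)):
                    ok = True
                    for (i1, _), (i2, _) in zip(combo, combo[1:]):
                        if i1 == i2:  # same undirected edge walked out and back
                            ok = False
                            break
                        e1, e2 = flat_edges[i1], flat_edges[i2]
                        if config.require_compartment_match and (
                            e1.compartment_label() != e2.compartment_label()
                        ):
                            ok = False
                            break
                    if not ok:
                        continue
                    directed = all(flat_edges[i].directed and fwd for i, fwd in combo)
                    sig = tuple(i for i, _ in combo)
                    canonical = sig if directed else min(sig, tuple(reversed(sig)))
                    if canonical in seen_chains:
                        continue
                    seen_chains.add(canonical)
                    first, last = flat_edges[combo[0][0]], flat_edges[combo[-1][0]]
                    add_record(
                        path[0], path[-1], directed, first.types | last.types | {INDIRECT_TYPE}
                    )
                    histogram[len(combo)] += 1

    final = {(s, d, direc, frozenset(t)) for (s, d, direc), t in records.items()}
    return final, histogram


def network_records(network) -> set[EdgeRecord]:
    """Canonical edge records of a GeneNetwork, comparable to oracle output."""
    out = set()
    for e in network.edges.values():
        s, d = e.src, e.dst
        if not e.directed and d < s:
            s, d = d, s
        out.add((s, d, e.directed, frozenset(e.types)))
    return out
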