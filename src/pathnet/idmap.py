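"""Identifier conversion for gene networks.

Pathway sources annotate nodes with heterogeneous native identifiers; a
topological analysis needs one uniform namespace (EntrezGene or gene symbol).
Mapping tables are user-supplied 4-column TSV files; conversion handles
one-to-many splits (a node duplicates, inheriting its edges), many-to-one
collapses (edge sets are unioned, purely collapse-induced self-edges are
dropped), and unmapped nodes (removed with a warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .model import (
    EmptyInputError,
    GeneNetwork,
    NodeRef,
    PathnetError,
    StructuralError,
    merge_edge,
)

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["source_namespace", "source_id", "target_namespace", "target_id"]


@dataclass
class MappingTable:
    """(source_namespace, source_id) -> set of target ids, one target namespace."""

    target_namespace: str
    mapping: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def lookup(self, namespace: str, identifier: str) -> tuple[str, ...]:
        return self.mapping.get((namespace, identifier), ())

    def __len__(self) -> int:
        return sum(len(v) for v in self.mapping.values())

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str]]
    ) -> "MappingTable":
        records = list(records)
        if not records:
            raise EmptyInputError("mapping table is empty")
        targets = {r[2] for r in records}
        if len(targets) != 1:
            raise PathnetError(
                f"mapping table must have a uniform target namespace, found {sorted(targets)}"
            )
        seen: set[tuple[str, str, str]] = set()
        mapping: dict[tuple[str, str], list[str]] = {}
        for src_ns, src_id, _tgt_ns, tgt_id in records:
            triple = (src_ns, src_id, tgt_id)
            if triple in seen:
                raise PathnetError(f"duplicate mapping row {triple}")
            seen.add(triple)
            mapping.setdefault((src_ns, src_id), []).append(tgt_id)
        return cls(
            target_namespace=targets.pop(),
            mapping={k: tuple(v) for k, v in mapping.items()},
        )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "MappingTable":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise PathnetError(f"mapping table {path} lacks column(s) {missing}")
        return cls.from_records(frame[REQUIRED_COLUMNS].itertuples(index=False, name=None))


def convert_identifiers(network: GeneNetwork, table: MappingTable) -> GeneNetwork:
    """Re-express a native-namespace network in the table's target namespace.

    A node mapping to m target ids becomes m nodes, each inheriting every
    incident edge; distinct nodes sharing a target id collapse into one node
    with the union of their edges (self-edges arising purely from that
    collapse are dropped); unmapped nodes are removed with their edges.
    """
    if network.id_namespace == table.target_namespace:
        raise PathnetError(
            f"network is already in namespace {table.target_namespace!r}"
        )
    if not table.mapping:
        raise EmptyInputError("mapping table is empty")

    images: dict[str, tuple[str, ...]] = {}
    dropped = 0
    for node in network.nodes.values():
        targets: list[str] = []
        for ns, ident in node.native_ids:
            targets.extend(t for t in table.lookup(ns, ident) if t not in targets)
        if targets:
            images[node.node_id] = tuple(targets)
        else:
            dropped += 1
            log.warning(
                "node %s (%s) has no mapping to %s; dropped",
                node.node_id,
                node.primary_label,
                table.target_namespace,
            )
    if dropped:
        log.info("identifier conversion dropped %d unmapped node(s)", dropped)

    out = GeneNetwork(
        pathway_id=network.pathway_id,
        title=network.title,
        id_namespace=table.target_namespace,
    )
    for node in network.nodes.values():
        for target in images.get(node.node_id, ()):
            out.add_node(
                NodeRef(
                    node_id=target,
                    kind="gene",
                    native_ids=((table.target_namespace, target),),
                    display_label=node.display_label or target,
                )
            )

    for edge in network.edges.values():
        src_images = images.get(edge.src, ())
        dst_images = images.get(edge.dst, ())
        for s in src_images:
            for d in dst_images:
                if s == d and edge.src != edge.dst:
                    continue  # self-edge arising purely from a collapse
                merge_edge(out, replace(edge, src=s, dst=d))
    return out
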