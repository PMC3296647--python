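"""KGML (KEGG Markup Language) reader.

KGML encodes a pathway as ``entry`` elements (genes, compounds, groups, maps)
joined by ``relation`` elements.  Two conventions matter for topology
conversion:

* an entry of type ``group`` is a protein complex (AND group over its
  ``component`` children), while a *gene* entry listing several names is a
  set of alternative members (OR group);
* a ``PPrel`` relation may carry a ``compound`` subtype naming the chemical
  that actually mediates the interaction — the direct A->B relation then has
  to be split into A->c and c->B before compound propagation, otherwise the
  signal through the compound is lost.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace
from typing import BinaryIO, Union

from lxml import etree

from .model import (
    AND,
    COMPOUND,
    GENE,
    OR,
    GroupNode,
    NodeRef,
    PathnetError,
    PathwayTopology,
    StructuralError,
    TypedEdge,
)

log = logging.getLogger(__name__)

COMPOUND_SPLIT_TYPE = "indirect (compound split)"

# entry types treated as gene products; "map" entries (links to other
# pathways) are dropped with a notice, as are their relations.
_GENE_LIKE = {"gene", "ortholog", "enzyme"}


class KgmlParseError(PathnetError):
    """Malformed KGML input."""


@dataclass(frozen=True)
class KgmlEntry:
    entry_id: str
    entry_type: str
    names: tuple[str, ...]
    components: tuple[str, ...] = ()
    graphics_name: str = ""


@dataclass(frozen=True)
class KgmlRelation:
    entry1: str
    entry2: str
    rel_type: str  # PPrel | PCrel | ECrel | GErel
    subtypes: tuple[tuple[str, str], ...] = ()


def _split_name(name: str) -> tuple[str, str]:
    """``hsa:5290`` -> ("hsa", "5290"); un-prefixed names get namespace ``kegg``."""
    if ":" in name:
        ns, ident = name.split(":", 1)
        return ns, ident
    return "kegg", name


def parse_kgml(source: Union[bytes, str, BinaryIO], strict: bool = True) -> PathwayTopology:
    """Parse one KGML document into a :class:`PathwayTopology`.

    In lenient mode (``strict=False``) relations referencing unknown entries
    are skipped with a warning instead of raising.
    """
    if isinstance(source, str):
        source = source.encode()
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise KgmlParseError(f"malformed KGML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise KgmlParseError(f"expected <pathway> root element, found <{root.tag}>")

    topology = PathwayTopology(
        pathway_id=root.get("name", "unknown"),
        title=root.get("title", ""),
        database_tag="kegg",
    )

    entries: dict[str, KgmlEntry] = {}
    dropped: set[str] = set()
    for el in root.findall("entry"):
        graphics = el.find("graphics")
        entry = KgmlEntry(
            entry_id=el.get("id"),
            entry_type=el.get("type", "gene"),
            names=tuple(el.get("name", "").split()),
            components=tuple(c.get("id") for c in el.findall("component")),
            graphics_name=(graphics.get("name", "") if graphics is not None else ""),
        )
        if entry.entry_id is None:
            raise KgmlParseError("entry without id attribute")
        entries[entry.entry_id] = entry

    # Entries in two passes so that group components can reference any entry.
    for entry in entries.values():
        label = entry.graphics_name.split(",")[0].strip() if entry.graphics_name else ""
        if entry.entry_type == "map":
            dropped.add(entry.entry_id)
            log.info("dropping KGML map entry %s (%s)", entry.entry_id, entry.names)
            continue
        if entry.entry_type == "compound":
            topology.add_node(
                NodeRef(
                    node_id=entry.entry_id,
                    kind=COMPOUND,
                    native_ids=tuple(_split_name(n) for n in entry.names),
                    display_label=label,
                )
            )
        elif entry.entry_type == "group":
            if not entry.components:
                raise StructuralError(f"KGML group entry {entry.entry_id} has no components")
            topology.nodes[entry.entry_id] = GroupNode(
                node_id=entry.entry_id,
                semantics=AND,
                members=entry.components,
                display_label=label,
            )
        elif entry.entry_type in _GENE_LIKE:
            if not entry.names:
                raise StructuralError(f"KGML gene entry {entry.entry_id} has no name")
            if len(entry.names) == 1:
                topology.add_node(
                    NodeRef(
                        node_id=entry.entry_id,
                        kind=GENE,
                        native_ids=(_split_name(entry.names[0]),),
                        display_label=label,
                    )
                )
            else:
                # multiple names on one gene entry = alternative members
                member_ids = []
                for i, name in enumerate(entry.names):
                    member_id = f"{entry.entry_id}.{i}"
                    topology.add_node(
                        NodeRef(
                            node_id=member_id,
                            kind=GENE,
                            native_ids=(_split_name(name),),
                            display_label=name,
                        )
                    )
                    member_ids.append(member_id)
                topology.nodes[entry.entry_id] = GroupNode(
                    node_id=entry.entry_id,
                    semantics=OR,
                    members=tuple(member_ids),
                    display_label=label,
                )
        else:
            log.warning(
                "dropping KGML entry %s of unsupported type %r", entry.entry_id, entry.entry_type
            )
            dropped.add(entry.entry_id)

    # Validate group components resolve to retained entries.
    for group in list(topology.groups()):
        missing = [m for m in group.members if m not in topology.nodes]
        if missing:
            raise StructuralError(
                f"KGML group {group.node_id} references missing component(s) {missing}"
            )

    for rel in root.findall("relation"):
        relation = KgmlRelation(
            entry1=rel.get("entry1"),
            entry2=rel.get("entry2"),
            rel_type=rel.get("type", "PPrel"),
            subtypes=tuple((s.get("name", ""), s.get("value", "")) for s in rel.findall("subtype")),
        )
        if relation.entry1 in dropped or relation.entry2 in dropped:
            log.info(
                "skipping relation %s->%s: endpoint entry was dropped",
                relation.entry1,
                relation.entry2,
            )
            continue
        unknown = [e for e in (relation.entry1, relation.entry2) if e not in topology.nodes]
        if unknown:
            msg = f"relation {relation.entry1}->{relation.entry2} references unknown entry {unknown}"
            if strict:
                raise StructuralError(msg)
            log.warning("%s (skipped)", msg)
            continue

        via = None
        subtype_names = []
        for name, value in relation.subtypes:
            if name == "compound":
                if value in dropped or value not in topology.nodes:
                    msg = (
                        f"relation {relation.entry1}->{relation.entry2}: compound subtype "
                        f"references unknown entry {value!r}"
                    )
                    if strict:
                        raise StructuralError(msg)
                    log.warning("%s (subtype ignored)", msg)
                    continue
                via = value
            elif name:
                subtype_names.append(name)
        types = frozenset({relation.rel_type, *subtype_names})
        topology.add_edge(
            TypedEdge(
                src=relation.entry1,
                dst=relation.entry2,
                directed=True,
                types=types,
                via_compound=via,
                provenance=(f"kgml:{relation.entry1}->{relation.entry2}",),
            )
        )

    topology.validate()
    return topology


def split_compound_subtype(
    topology: PathwayTopology, include_ecrel: bool = True
) -> PathwayTopology:
    """Split relations mediated by a ``compound`` subtype.

    A direct PPrel A->B annotated with bridging compound c becomes the pair
    A->c and c->B (each keeping the relation's other subtype names), so the
    chemical actually carrying the signal enters the graph and compound
    propagation can reconstruct the cascade.  ECrel (enzyme-enzyme via
    shared compound) follows the same logic unless ``include_ecrel=False``;
    PCrel relations are already gene<->compound and pass through.
    """
    split_types = {"PPrel"} | ({"ECrel"} if include_ecrel else set())
    out = PathwayTopology(
        pathway_id=topology.pathway_id,
        title=topology.title,
        database_tag=topology.database_tag,
        nodes=dict(topology.nodes),
        retrieved_on=topology.retrieved_on,
    )
    for edge in topology.edges:
        if edge.via_compound is None or not (edge.types & split_types):
            out.edges.append(edge)
            continue
        compound = topology.nodes.get(edge.via_compound)
        if compound is None or compound.kind != COMPOUND:
            raise StructuralError(
                f"relation {edge.src}->{edge.dst}: compound subtype {edge.via_compound!r} "
                "does not resolve to a compound entry"
            )
        types = edge.types | {COMPOUND_SPLIT_TYPE}
        out.edges.append(
            replace(edge, dst=edge.via_compound, types=types, via_compound=None)
        )
        out.edges.append(
            replace(edge, src=edge.via_compound, types=types, via_compound=None)
        )
    out.validate()
    return out
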