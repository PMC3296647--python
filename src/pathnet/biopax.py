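"""BioPAX (Level 2 / Level 3) reader for a pairwise-reduction subset.

BioPAX models pathways as RDF/OWL: physical entities (proteins, complexes,
small molecules) take part in conversions, and control interactions
(catalysis, modulation) link a controller entity to a reaction.  This reader
reduces that structure to the mixed pathway graph used by the converter:

* a ``complex`` is the only grouping construct BioPAX offers and is always a
  protein complex, hence an AND group (clique expansion later);
* a protein whose reference carries several gene-identifying xrefs denotes
  alternative members of the process, hence an OR group;
* small molecules become compound nodes; every occurrence keeps its own
  cellular location, which ends up on the derived edges so that compound
  propagation can enforce same-compartment matching;
* each conversion contributes left x right directed edges, each control a
  ``catalysisOut (SIGN)`` / ``controlOut (SIGN)`` edge from the controller to
  every right-side participant of the controlled conversion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import rdflib
from rdflib import RDF, Graph, URIRef

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

BP3 = "http://www.biopax.org/release/biopax-level3.owl#"
BP2 = "http://www.biopax.org/release/biopax-level2.owl#"

#: xref databases that identify a gene record; only these can turn a
#: multi-xref protein into an OR group.
GENE_XREF_NAMESPACES = frozenset(
    {"entrezgene", "entrez gene", "entrez", "ncbi gene", "ncbigene",
     "hgnc", "hgnc symbol", "uniprot", "uniprotkb", "kegg genes"}
)

_PHYSICAL_CLASSES_L3 = {
    "Protein": "protein",
    "Complex": "complex",
    "SmallMolecule": "smallMolecule",
    "Rna": "protein",
    "Dna": "protein",
    "PhysicalEntity": "protein",
}
_PHYSICAL_CLASSES_L2 = {
    "protein": "protein",
    "complex": "complex",
    "smallMolecule": "smallMolecule",
    "rna": "protein",
    "dna": "protein",
    "physicalEntity": "protein",
}
_CONVERSION_CLASSES_L3 = {
    "BiochemicalReaction", "Conversion", "ComplexAssembly", "Transport",
    "TransportWithBiochemicalReaction", "Degradation",
}
_CONVERSION_CLASSES_L2 = {
    "biochemicalReaction", "conversion", "complexAssembly", "transport",
    "transportWithBiochemicalReaction",
}
_CONTROL_CLASSES_L3 = {"Catalysis", "Control", "Modulation", "TemplateReactionRegulation"}
_CONTROL_CLASSES_L2 = {"catalysis", "control", "modulation"}


class BiopaxParseError(PathnetError):
    """Malformed or unsupported BioPAX input."""


@dataclass
class BiopaxEntity:
    rdf_id: str
    bp_class: str  # protein | complex | smallMolecule
    xrefs: tuple[tuple[str, str], ...] = ()
    cellular_location: Optional[str] = None
    components: tuple[str, ...] = ()
    reference: Optional[str] = None
    display: str = ""

    def gene_xrefs(self) -> tuple[tuple[str, str], ...]:
        return tuple((db, i) for db, i in self.xrefs if db.lower() in GENE_XREF_NAMESPACES)


@dataclass
class BiopaxReaction:
    rdf_id: str
    reaction_class: str  # conversion-like or control-like class name
    left: tuple[str, ...] = ()
    right: tuple[str, ...] = ()
    controller: tuple[str, ...] = ()
    controlled: Optional[str] = None
    control_sign: str = ""

    @property
    def is_control(self) -> bool:
        return self.controlled is not None or bool(self.controller)


def _local(uri: Union[URIRef, str]) -> str:
    s = str(uri)
    s = re.split(r"[#/]", s)[-1]
    return s


class _Doc:
    """One parsed BioPAX document with level-agnostic property access."""

    def __init__(self, graph: Graph):
        self.graph = graph
        used = {str(o) for o in graph.objects(None, RDF.type)}
        self.level3 = any(u.startswith(BP3) for u in used)
        self.ns = BP3 if self.level3 else BP2

    def prop(self, subject: URIRef, *names: str) -> list:
        out = []
        for name in names:
            out.extend(self.graph.objects(subject, URIRef(self.ns + name)))
        return out

    def prop1(self, subject: URIRef, *names: str):
        vals = self.prop(subject, *names)
        return vals[0] if vals else None

    def of_type(self, *class_names: str) -> list[URIRef]:
        subjects: set[URIRef] = set()
        for name in class_names:
            subjects.update(self.graph.subjects(RDF.type, URIRef(self.ns + name)))
        return sorted(subjects, key=str)

    def type_name(self, subject: URIRef) -> Optional[str]:
        for t in self.graph.objects(subject, RDF.type):
            s = str(t)
            if s.startswith(self.ns):
                return s[len(self.ns):]
        return None


def _location_label(doc: _Doc, node) -> Optional[str]:
    if node is None:
        return None
    if isinstance(node, rdflib.Literal):
        return str(node)
    term = doc.prop1(node, "term", "TERM")
    return str(term) if term is not None else _local(node)


def _entity_xrefs(doc: _Doc, subject: URIRef) -> tuple[tuple[str, str], ...]:
    xref_nodes = list(doc.prop(subject, "xref", "XREF"))
    ref = doc.prop1(subject, "entityReference")
    if ref is not None:
        xref_nodes.extend(doc.prop(ref, "xref", "XREF"))
    out = []
    for x in xref_nodes:
        db = doc.prop1(x, "db", "DB")
        ident = doc.prop1(x, "id", "ID")
        if db is not None and ident is not None:
            out.append((str(db), str(ident)))
    return tuple(dict.fromkeys(out))


def _unwrap_participant(doc: _Doc, node) -> tuple[URIRef, Optional[str]]:
    """Resolve a participant to (entity, location).

    Level 2 wraps entities in physicalEntityParticipant occurrences carrying
    the location; Level 3 points at the physical entity directly (which owns
    its own cellularLocation).
    """
    wrapped = doc.prop1(node, "PHYSICAL-ENTITY")
    if wrapped is not None:
        loc = _location_label(doc, doc.prop1(node, "CELLULAR-LOCATION"))
        return wrapped, loc
    loc = _location_label(doc, doc.prop1(node, "cellularLocation", "CELLULAR-LOCATION"))
    return node, loc


def _parse_entities(doc: _Doc) -> dict[str, BiopaxEntity]:
    classes = _PHYSICAL_CLASSES_L3 if doc.level3 else _PHYSICAL_CLASSES_L2
    entities: dict[str, BiopaxEntity] = {}
    for class_name, normalized in classes.items():
        for subj in doc.of_type(class_name):
            rdf_id = _local(subj)
            if rdf_id in entities:
                continue
            display = doc.prop1(subj, "displayName", "standardName", "name", "NAME", "SHORT-NAME")
            ref = doc.prop1(subj, "entityReference")
            components = tuple(
                _local(_unwrap_participant(doc, c)[0])
                for c in doc.prop(subj, "component", "COMPONENTS")
            )
            entities[rdf_id] = BiopaxEntity(
                rdf_id=rdf_id,
                bp_class=normalized,
                xrefs=_entity_xrefs(doc, subj),
                cellular_location=_location_label(
                    doc, doc.prop1(subj, "cellularLocation", "CELLULAR-LOCATION")
                ),
                components=components,
                reference=_local(ref) if ref is not None else None,
                display=str(display) if display is not None else rdf_id,
            )
    return entities


def _parse_reactions(
    doc: _Doc,
) -> tuple[dict[str, BiopaxReaction], dict[tuple[str, str], Optional[str]]]:
    reactions: dict[str, BiopaxReaction] = {}
    conv_classes = _CONVERSION_CLASSES_L3 if doc.level3 else _CONVERSION_CLASSES_L2
    ctrl_classes = _CONTROL_CLASSES_L3 if doc.level3 else _CONTROL_CLASSES_L2
    occurrence_locations: dict[tuple[str, str], Optional[str]] = {}

    for class_name in sorted(conv_classes):
        for subj in doc.of_type(class_name):
            rdf_id = _local(subj)
            if rdf_id in reactions:
                continue
            left, right = [], []
            for side, names in (
                (left, ("left", "LEFT", "PARTICIPANTS")),
                (right, ("right", "RIGHT")),
            ):
                for p in doc.prop(subj, *names):
                    entity, loc = _unwrap_participant(doc, p)
                    side.append(_local(entity))
                    occurrence_locations[(rdf_id, _local(entity))] = loc
            reactions[rdf_id] = BiopaxReaction(
                rdf_id=rdf_id,
                reaction_class="conversion",
                left=tuple(left),
                right=tuple(right),
            )

    for class_name in sorted(ctrl_classes):
        for subj in doc.of_type(class_name):
            rdf_id = _local(subj)
            if rdf_id in reactions:
                continue
            controllers = []
            for p in doc.prop(subj, "controller", "CONTROLLER"):
                entity, loc = _unwrap_participant(doc, p)
                controllers.append(_local(entity))
                occurrence_locations[(rdf_id, _local(entity))] = loc
            controlled = doc.prop1(subj, "controlled", "CONTROLLED")
            sign = doc.prop1(subj, "controlType", "CONTROL-TYPE")
            is_catalysis = class_name.lower().startswith("catalysis")
            reactions[rdf_id] = BiopaxReaction(
                rdf_id=rdf_id,
                reaction_class="catalysis" if is_catalysis else "control",
                controller=tuple(controllers),
                controlled=_local(controlled) if controlled is not None else None,
                control_sign=str(sign) if sign is not None else ("ACTIVATION" if is_catalysis else ""),
            )

    return reactions, occurrence_locations


def derive_edges(
    reactions: Iterable[BiopaxReaction],
    entities: dict[str, BiopaxEntity],
    node_of: dict[str, str],
    locations: dict[tuple[str, str], Optional[str]] | None = None,
    strict: bool = True,
) -> list[TypedEdge]:
    """Reduce conversions and controls to pairwise typed edges.

    Every left participant of a conversion points at every right participant
    (type ``conversion``); every controller of a control points at every
    right-side participant of the controlled conversion (type
    ``catalysisOut (SIGN)`` / ``controlOut (SIGN)``).  When a participant is
    a small molecule its occurrence compartment is attached to the edge.
    """
    locations = locations or {}
    reactions = list(reactions)
    by_id = {r.rdf_id: r for r in reactions}
    edges: list[TypedEdge] = []

    def occurrence_location(reaction_id: str, entity_id: str) -> Optional[str]:
        loc = locations.get((reaction_id, entity_id))
        if loc is None:
            ent = entities.get(entity_id)
            loc = ent.cellular_location if ent is not None else None
        return loc

    def compartment_for(reaction_id: str, a: str, b: str) -> Optional[str]:
        labels = [
            occurrence_location(reaction_id, e)
            for e in (a, b)
            if entities.get(e) is not None and entities[e].bp_class == "smallMolecule"
        ]
        labels = [l for l in labels if l is not None]
        if not labels:
            return None
        if len(labels) == 2 and labels[0] != labels[1]:
            log.warning(
                "reaction %s: compound endpoints in different compartments (%s vs %s)",
                reaction_id, labels[0], labels[1],
            )
        return labels[0]

    def emit(reaction_id: str, a: str, b: str, edge_type: str) -> None:
        if a not in node_of or b not in node_of:
            return
        edges.append(
            TypedEdge(
                src=node_of[a],
                dst=node_of[b],
                directed=True,
                types=frozenset({edge_type}),
                compartment=compartment_for(reaction_id, a, b),
                provenance=(f"biopax:{reaction_id}",),
            )
        )

    for reaction in reactions:
        if reaction.is_control:
            continue
        for a in reaction.left:
            for b in reaction.right:
                emit(reaction.rdf_id, a, b, "conversion")

    for reaction in reactions:
        if not reaction.is_control:
            continue
        if reaction.controlled is None:
            continue
        target = by_id.get(reaction.controlled)
        if target is None:
            msg = f"control {reaction.rdf_id} references missing reaction {reaction.controlled!r}"
            if strict:
                raise StructuralError(msg)
            log.warning("%s (skipped)", msg)
            continue
        base = "catalysisOut" if reaction.reaction_class == "catalysis" else "controlOut"
        edge_type = f"{base} ({reaction.control_sign})" if reaction.control_sign else base
        for c in reaction.controller:
            for b in target.right:
                emit(reaction.rdf_id, c, b, edge_type)

    return edges


def _build_topology(
    doc: _Doc,
    pathway_id: str,
    title: str,
    entity_ids: list[str],
    reaction_ids: list[str],
    entities: dict[str, BiopaxEntity],
    reactions: dict[str, BiopaxReaction],
    locations: dict[tuple[str, str], Optional[str]],
    strict: bool,
) -> PathwayTopology:
    topology = PathwayTopology(pathway_id=pathway_id, title=title, database_tag="reactome")
    node_of: dict[str, str] = {}

    def node_key(ent: BiopaxEntity) -> str:
        # merge occurrences of the same molecule (same entity reference)
        return ent.reference or ent.rdf_id

    def add_entity(entity_id: str) -> None:
        if entity_id in node_of:
            return
        ent = entities.get(entity_id)
        if ent is None:
            msg = f"unresolvable entity reference {entity_id!r}"
            if strict:
                raise StructuralError(msg)
            log.warning("%s (skipped)", msg)
            return
        if ent.bp_class == "smallMolecule":
            key = node_key(ent)
            if key not in topology.nodes:
                native = ent.xrefs or (("biopax", key),)
                topology.add_node(
                    NodeRef(node_id=key, kind=COMPOUND, native_ids=native, display_label=ent.display)
                )
            node_of[entity_id] = key
        elif ent.bp_class == "complex":
            for comp in ent.components:
                add_entity(comp)
            members = tuple(
                dict.fromkeys(node_of[c] for c in ent.components if c in node_of)
            )
            if not members:
                msg = f"complex {entity_id!r} has no resolvable components"
                if strict:
                    raise StructuralError(msg)
                log.warning("%s (skipped)", msg)
                return
            if entity_id not in topology.nodes:
                topology.nodes[entity_id] = GroupNode(
                    node_id=entity_id, semantics=AND, members=members, display_label=ent.display
                )
            node_of[entity_id] = entity_id
        else:  # protein-like
            key = node_key(ent)
            gene_xrefs = ent.gene_xrefs()
            if len(gene_xrefs) > 1:
                # alternative gene records behind one protein instance
                if key not in topology.nodes:
                    member_ids = []
                    for i, (db, ident) in enumerate(gene_xrefs):
                        member_id = f"{key}.{i}"
                        if member_id not in topology.nodes:
                            topology.add_node(
                                NodeRef(
                                    node_id=member_id,
                                    kind=GENE,
                                    native_ids=((db, ident),),
                                    display_label=f"{ent.display}[{ident}]",
                                )
                            )
                        member_ids.append(member_id)
                    topology.nodes[key] = GroupNode(
                        node_id=key, semantics=OR, members=tuple(member_ids),
                        display_label=ent.display,
                    )
            else:
                if key not in topology.nodes:
                    native = gene_xrefs or ent.xrefs or (("biopax", key),)
                    topology.add_node(
                        NodeRef(node_id=key, kind=GENE, native_ids=native, display_label=ent.display)
                    )
            node_of[entity_id] = key

    for entity_id in entity_ids:
        add_entity(entity_id)

    pathway_reactions = [reactions[r] for r in reaction_ids if r in reactions]
    for edge in derive_edges(pathway_reactions, entities, node_of, locations, strict=strict):
        topology.add_edge(edge)
    topology.validate()
    return topology


def parse_biopax(source: Union[bytes, str], strict: bool = True) -> list[PathwayTopology]:
    """Parse a BioPAX OWL document into one topology per ``pathway`` instance.

    A document with no pathway instances yields an empty list.  Entities are
    collected through the pathway-component closure: every conversion or
    control reachable from the pathway contributes its participants (and,
    recursively, complex components).
    """
    graph = Graph()
    if isinstance(source, bytes):
        graph.parse(data=source, format="xml")
    else:
        graph.parse(data=str(source), format="xml")
    doc = _Doc(graph)
    entities = _parse_entities(doc)
    reactions, locations = _parse_reactions(doc)
    subjects_by_local = {_local(s): s for s in set(graph.subjects())}

    pathways = doc.of_type("Pathway" if doc.level3 else "pathway")
    out: list[PathwayTopology] = []
    for pw in pathways:
        pw_id = _local(pw)
        title = doc.prop1(pw, "displayName", "standardName", "name", "NAME")
        # closure over pathway components (sub-pathways flattened)
        reaction_ids: list[str] = []
        entity_ids: list[str] = []
        stack = [_local(c) for c in doc.prop(pw, "pathwayComponent", "PATHWAY-COMPONENTS")]
        seen: set[str] = set()
        while stack:
            comp_id = stack.pop()
            if comp_id in seen:
                continue
            seen.add(comp_id)
            if comp_id in reactions:
                reaction_ids.append(comp_id)
                reaction = reactions[comp_id]
                if reaction.controlled is not None:
                    stack.append(reaction.controlled)
                entity_ids.extend(reaction.left + reaction.right + reaction.controller)
            elif comp_id in entities:
                # tolerated: a pathway component pointing straight at an entity
                entity_ids.append(comp_id)
            else:
                subject = subjects_by_local.get(comp_id)
                sub = (
                    doc.prop(subject, "pathwayComponent", "PATHWAY-COMPONENTS")
                    if subject is not None
                    else []
                )
                if sub:
                    stack.extend(_local(c) for c in sub)
                else:
                    msg = f"pathway {pw_id}: unresolvable component {comp_id!r}"
                    if strict:
                        raise StructuralError(msg)
                    log.warning("%s (skipped)", msg)
        # canonical ordering for determinism
        entity_ids = sorted(dict.fromkeys(entity_ids))
        reaction_ids = sorted(dict.fromkeys(reaction_ids))
        out.append(
            _build_topology(
                doc, pw_id, str(title) if title is not None else pw_id,
                entity_ids, reaction_ids, entities, reactions, locations, strict,
            )
        )
    return out
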