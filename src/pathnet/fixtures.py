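"""Synthetic pathway documents with known ground truth.

Every fixture ships three things: the source document (KGML or BioPAX OWL
bytes), the topology that document parses to, and the gene network the
conversion is *expected* to produce.  Expected networks are enumerated by
hand-written formulas or by the brute-force oracle — never by the converter
under test — so the fixtures double as the test harness's ground truth.

Fixture kinds mirror the canonical toy structures of pathway conversion:
an AND group (protein complex), an OR group (gene family), a single
compound bridge, longer compound chains, a fragment of the insulin
signaling cascade whose signal crosses two second-messenger compounds
(PIP3, cAMP), and the gamma-secretase complex with OR groups of protein
variants nested inside the AND complex.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from lxml import etree

from .converter import INDIRECT_TYPE, ConversionConfig
from .kgml import COMPOUND_SPLIT_TYPE, parse_kgml
from .biopax import BP3, parse_biopax
from .model import (
    AND,
    COMPOUND,
    GENE,
    OR,
    GeneNetwork,
    GroupNode,
    NodeRef,
    PathnetError,
    PathwayTopology,
    TypedEdge,
    merge_edge,
)
from .oracle import oracle_convert

FIXTURE_KINDS = (
    "and_group",
    "or_group",
    "compound_bridge",
    "compound_chain",
    "insulin_fragment",
    "gamma_secretase",
    "random",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise PathnetError(f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}")


@dataclass
class Fixture:
    spec: FixtureSpec
    document: Optional[bytes]  # KGML or BioPAX source, None for in-memory-only kinds
    fmt: str  # "kgml" | "biopax" | "memory"
    topology: PathwayTopology
    expected_network: GeneNetwork
    expected_histogram: dict[int, int]


# ---------------------------------------------------------------------------
# document builders


def _kgml_document(
    pathway_id: str,
    title: str,
    entries: list[dict],
    relations: list[dict],
) -> bytes:
    root = etree.Element("pathway", name=pathway_id, title=title, org="hsa")
    for entry in entries:
        el = etree.SubElement(
            root, "entry", id=entry["id"], name=entry.get("name", ""), type=entry["type"]
        )
        if entry.get("label"):
            etree.SubElement(el, "graphics", name=entry["label"])
        for comp in entry.get("components", ()):
            etree.SubElement(el, "component", id=comp)
    for rel in relations:
        el = etree.SubElement(
            root, "relation", entry1=rel["entry1"], entry2=rel["entry2"], type=rel["type"]
        )
        for name, value in rel.get("subtypes", ()):
            etree.SubElement(el, "subtype", name=name, value=value)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def write_kgml(topology: PathwayTopology) -> bytes:
    """Serialize a topology back to KGML (inverse of :func:`parse_kgml`).

    Only KGML-expressible structures are accepted: directed edges whose type
    set contains exactly one relation type, AND groups over plain entries,
    and OR groups whose members follow the ``<entry>.<i>`` naming that
    parsing produces.
    """
    rel_types = {"PPrel", "PCrel", "ECrel", "GErel"}
    entries: list[dict] = []
    or_members: set[str] = set()
    for node in topology.nodes.values():
        if isinstance(node, GroupNode) and node.semantics == OR:
            or_members.update(node.members)
    for node_id in sorted(topology.nodes, key=_entry_sort_key):
        node = topology.nodes[node_id]
        if node_id in or_members:
            continue
        if isinstance(node, GroupNode):
            if node.semantics == AND:
                entries.append(
                    {"id": node.node_id, "type": "group", "components": list(node.members),
                     "label": node.display_label}
                )
            else:
                names = []
                for m in node.members:
                    member = topology.nodes[m]
                    if not isinstance(member, NodeRef):
                        raise PathnetError("nested OR groups are not KGML-expressible")
                    names.append(member.primary_label)
                entries.append(
                    {"id": node.node_id, "type": "gene", "name": " ".join(names),
                     "label": node.display_label}
                )
        else:
            entry_type = "compound" if node.kind == COMPOUND else "gene"
            entries.append(
                {"id": node.node_id, "type": entry_type, "name": node.primary_label,
                 "label": node.display_label}
            )
    relations = []
    for edge in topology.edges:
        if not edge.directed:
            raise PathnetError("undirected edges are not KGML-expressible")
        rel = edge.types & rel_types
        if len(rel) != 1:
            raise PathnetError(
                f"edge {edge.src}->{edge.dst} needs exactly one KGML relation type, has {sorted(edge.types)}"
            )
        rel_type = next(iter(rel))
        subtypes = [(t, "") for t in sorted(edge.types - {rel_type})]
        if edge.via_compound is not None:
            subtypes.append(("compound", edge.via_compound))
        relations.append(
            {"entry1": edge.src, "entry2": edge.dst, "type": rel_type, "subtypes": subtypes}
        )
    return _kgml_document(topology.pathway_id, topology.title, entries, relations)


def _entry_sort_key(node_id: str):
    try:
        return (0, int(node_id), "")
    except ValueError:
        return (1, 0, node_id)


class _BiopaxBuilder:
    """Minimal BioPAX Level 3 RDF/XML document builder for fixtures."""

    def __init__(self, base: str = "http://pathnet.example/fixture#"):
        self.base = base
        self.chunks: list[str] = []

    def _open(self, cls: str, rdf_id: str) -> str:
        return f'  <bp:{cls} rdf:ID="{rdf_id}">'

    def element(self, cls: str, rdf_id: str, props: list[tuple[str, str, str]]) -> None:
        # props: (property, mode "res"|"lit", value)
        lines = [self._open(cls, rdf_id)]
        for prop, mode, value in props:
            if mode == "res":
                lines.append(f'    <bp:{prop} rdf:resource="#{value}"/>')
            else:
                lines.append(
                    f'    <bp:{prop} rdf:datatype="http://www.w3.org/2001/XMLSchema#string">{value}</bp:{prop}>'
                )
        lines.append(f"  </bp:{cls}>")
        self.chunks.append("\n".join(lines))

    def xref(self, rdf_id: str, db: str, ident: str) -> str:
        self.element("UnificationXref", rdf_id, [("db", "lit", db), ("id", "lit", ident)])
        return rdf_id

    def location(self, rdf_id: str, term: str) -> str:
        self.element("CellularLocationVocabulary", rdf_id, [("term", "lit", term)])
        return rdf_id

    def protein(self, rdf_id: str, name: str, xrefs: list[str], location: Optional[str] = None) -> str:
        props: list[tuple[str, str, str]] = [("displayName", "lit", name)]
        props += [("xref", "res", x) for x in xrefs]
        if location:
            props.append(("cellularLocation", "res", location))
        self.element("Protein", rdf_id, props)
        return rdf_id

    def small_molecule(
        self, rdf_id: str, name: str, reference: str, location: Optional[str] = None
    ) -> str:
        props: list[tuple[str, str, str]] = [
            ("displayName", "lit", name),
            ("entityReference", "res", reference),
        ]
        if location:
            props.append(("cellularLocation", "res", location))
        self.element("SmallMolecule", rdf_id, props)
        return rdf_id

    def small_molecule_reference(self, rdf_id: str, name: str, xrefs: list[str]) -> str:
        props = [("displayName", "lit", name)] + [("xref", "res", x) for x in xrefs]
        self.element("SmallMoleculeReference", rdf_id, props)
        return rdf_id

    def complex(self, rdf_id: str, name: str, components: list[str]) -> str:
        props = [("displayName", "lit", name)] + [("component", "res", c) for c in components]
        self.element("Complex", rdf_id, props)
        return rdf_id

    def reaction(self, rdf_id: str, left: list[str], right: list[str]) -> str:
        props = [("left", "res", l) for l in left] + [("right", "res", r) for r in right]
        self.element("BiochemicalReaction", rdf_id, props)
        return rdf_id

    def catalysis(self, rdf_id: str, controller: str, controlled: str, sign: str = "ACTIVATION") -> str:
        self.element(
            "Catalysis",
            rdf_id,
            [
                ("controller", "res", controller),
                ("controlled", "res", controlled),
                ("controlType", "lit", sign),
            ],
        )
        return rdf_id

    def pathway(self, rdf_id: str, name: str, components: list[str]) -> str:
        props = [("displayName", "lit", name)] + [("pathwayComponent", "res", c) for c in components]
        self.element("Pathway", rdf_id, props)
        return rdf_id

    def tobytes(self) -> bytes:
        body = "\n".join(self.chunks)
        doc = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"\n'
            f'         xmlns:bp="{BP3}"\n'
            f'         xml:base="{self.base}">\n'
            f"{body}\n"
            "</rdf:RDF>\n"
        )
        return doc.encode()


# ---------------------------------------------------------------------------
# expected-network construction helpers


def _expected_network(
    pathway_id: str,
    title: str,
    nodes: Iterable[NodeRef],
    records: Iterable[tuple[str, str, bool, Iterable[str]]],
) -> GeneNetwork:
    net = GeneNetwork(pathway_id=pathway_id, title=title)
    for node in nodes:
        net.add_node(node)
    for src, dst, directed, types in records:
        merge_edge(net, TypedEdge(src=src, dst=dst, directed=directed, types=frozenset(types)))
    return net


def _gene(node_id: str, native: tuple[str, str], label: str = "") -> NodeRef:
    return NodeRef(node_id=node_id, kind=GENE, native_ids=(native,), display_label=label)


# ---------------------------------------------------------------------------
# fixture kinds


def _and_group_fixture(spec: FixtureSpec) -> Fixture:
    k = int(spec.params.get("k", 3))
    if k < 1:
        raise PathnetError("and_group fixture requires k >= 1")
    entries = [{"id": "1", "name": "hsa:100", "type": "gene", "label": "X"}]
    member_ids = []
    for i in range(k):
        eid = str(2 + i)
        entries.append({"id": eid, "name": f"hsa:{101 + i}", "type": "gene", "label": f"M{i}"})
        member_ids.append(eid)
    group_id = str(2 + k)
    entries.append({"id": group_id, "type": "group", "components": member_ids})
    relations = [
        {"entry1": "1", "entry2": group_id, "type": "PPrel", "subtypes": [("activation", "-->")]}
    ]
    doc = _kgml_document("syn:and_group", "AND group (protein complex)", entries, relations)
    topology = parse_kgml(doc)

    gene_nodes = [topology.nodes["1"]] + [topology.nodes[m] for m in member_ids]
    records = [("1", m, True, {"PPrel", "activation"}) for m in member_ids]
    records += [
        (a, b, False, {"binding"})
        for i, a in enumerate(member_ids)
        for b in member_ids[i + 1:]
    ]
    expected = _expected_network("syn:and_group", topology.title, gene_nodes, records)
    return Fixture(spec, doc, "kgml", topology, expected, {})


def _or_group_fixture(spec: FixtureSpec) -> Fixture:
    k = int(spec.params.get("k", 2))
    if k < 1:
        raise PathnetError("or_group fixture requires k >= 1")
    names = " ".join(f"hsa:{201 + i}" for i in range(k))
    entries = [
        {"id": "1", "name": "hsa:200", "type": "gene", "label": "X"},
        {"id": "2", "name": names, "type": "gene", "label": "FAMILY"},
    ]
    relations = [{"entry1": "1", "entry2": "2", "type": "PPrel", "subtypes": [("activation", "-->")]}]
    doc = _kgml_document("syn:or_group", "OR group (gene family)", entries, relations)
    topology = parse_kgml(doc)
    member_ids = [f"2.{i}" for i in range(k)]
    gene_nodes = [topology.nodes["1"]] + [topology.nodes[m] for m in member_ids]
    records = [("1", m, True, {"PPrel", "activation"}) for m in member_ids]
    expected = _expected_network("syn:or_group", topology.title, gene_nodes, records)
    return Fixture(spec, doc, "kgml", topology, expected, {})


def _compound_bridge_fixture(spec: FixtureSpec) -> Fixture:
    blacklisted = bool(spec.params.get("blacklisted", False))
    compartments = spec.params.get("compartments")  # None or (loc_in, loc_out)
    if compartments is None:
        cpd_name = "cpd:C00001" if blacklisted else "cpd:C05981"
        entries = [
            {"id": "1", "name": "hsa:300", "type": "gene", "label": "A"},
            {"id": "2", "name": cpd_name, "type": "compound", "label": "c"},
            {"id": "3", "name": "hsa:301", "type": "gene", "label": "B"},
        ]
        relations = [
            {"entry1": "1", "entry2": "2", "type": "PCrel", "subtypes": [("activation", "-->")]},
            {"entry1": "2", "entry2": "3", "type": "PCrel", "subtypes": [("activation", "-->")]},
        ]
        doc = _kgml_document("syn:compound_bridge", "compound bridge", entries, relations)
        topology = parse_kgml(doc)
        gene_nodes = [topology.nodes["1"], topology.nodes["3"]]
        if blacklisted:
            expected = _expected_network("syn:compound_bridge", topology.title, gene_nodes, [])
            hist: dict[int, int] = {}
        else:
            expected = _expected_network(
                "syn:compound_bridge",
                topology.title,
                gene_nodes,
                [("1", "3", True, {"PCrel", "activation", INDIRECT_TYPE})],
            )
            hist = {2: 1}
        return Fixture(spec, doc, "kgml", topology, expected, hist)

    loc_in, loc_out = compartments
    b = _BiopaxBuilder()
    xa = b.xref("xref_A", "EntrezGene", "300")
    xb = b.xref("xref_B", "EntrezGene", "301")
    xc = b.xref("xref_c", "ChEBI", "16618")
    b.protein("prot_A", "A", [xa])
    b.protein("prot_B", "B", [xb])
    b.small_molecule_reference("ref_c", "c", [xc])
    b.small_molecule("c_occ1", "c", "ref_c", b.location("loc1", loc_in))
    b.small_molecule("c_occ2", "c", "ref_c", b.location("loc2", loc_out))
    b.reaction("rxn1", left=["prot_A"], right=["c_occ1"])
    b.reaction("rxn2", left=["c_occ2"], right=["prot_B"])
    b.pathway("pw", "compound bridge (BioPAX)", ["rxn1", "rxn2"])
    doc = b.tobytes()
    topology = parse_biopax(doc)[0]
    gene_nodes = [topology.nodes["prot_A"], topology.nodes["prot_B"]]
    if loc_in == loc_out:
        expected = _expected_network(
            "pw", topology.title, gene_nodes,
            [("prot_A", "prot_B", True, {"conversion", INDIRECT_TYPE})],
        )
        hist = {2: 1}
    else:
        expected = _expected_network("pw", topology.title, gene_nodes, [])
        hist = {}
    return Fixture(spec, doc, "biopax", topology, expected, hist)


def _compound_chain_fixture(spec: FixtureSpec) -> Fixture:
    length = int(spec.params.get("length", 3))
    if length < 2:
        raise PathnetError("compound_chain fixture requires length >= 2")
    entries = [{"id": "1", "name": "hsa:400", "type": "gene", "label": "A"}]
    prev = "1"
    relations = []
    for i in range(length - 1):
        cid = str(2 + i)
        entries.append(
            {"id": cid, "name": f"cpd:C9{9000 + i}", "type": "compound", "label": f"c{i}"}
        )
        relations.append(
            {"entry1": prev, "entry2": cid, "type": "PCrel", "subtypes": [("activation", "-->")]}
        )
        prev = cid
    end = str(length + 1)
    entries.append({"id": end, "name": "hsa:401", "type": "gene", "label": "B"})
    relations.append(
        {"entry1": prev, "entry2": end, "type": "PCrel", "subtypes": [("activation", "-->")]}
    )
    doc = _kgml_document("syn:compound_chain", f"compound chain length {length}", entries, relations)
    topology = parse_kgml(doc)
    gene_nodes = [topology.nodes["1"], topology.nodes[end]]
    expected = _expected_network(
        "syn:compound_chain",
        topology.title,
        gene_nodes,
        [("1", end, True, {"PCrel", "activation", INDIRECT_TYPE})],
    )
    return Fixture(spec, doc, "kgml", topology, expected, {length: 1})


#: designation labels of the insulin-cascade genes used as the DE set in the
#: propagation-benefit simulation (all lie on the signal path of the fixture).
INSULIN_DE_GENES = (
    "hsa:3643",  # IR
    "hsa:3667",  # IRS
    "hsa:5290", "hsa:5295",  # PI3K complex members
    "hsa:5170", "hsa:5171",  # PDK1/2
    "hsa:207", "hsa:208", "hsa:10000",  # AKT1/2/3
    "hsa:5139", "hsa:5140",  # PDE3A/B
    "hsa:5566",  # PKA
    "hsa:3991",  # LIPE
)


def _insulin_fragment_fixture(spec: FixtureSpec) -> Fixture:
    """Fragment of the insulin signaling cascade crossing two compounds.

    IR -> IRS -> PI3K(AND) --[PIP3]--> PDK1/2(OR) -> AKT(OR) -> PDE3(OR)
    --[cAMP]--> PKA -> LIPE, with SKIP and SHIP phosphatases feeding into
    PIP3.  The PI3K->PDK link is a direct PPrel with a compound subtype
    (split before propagation); the PDE3-|cAMP->PKA link uses explicit
    PCrel relations, covering both KGML conventions for compound-mediated
    interactions.  ``n_background`` adds that many bystander genes in short
    activation chains of three, identical under both conversion variants.
    """
    n_background = int(spec.params.get("n_background", 0))
    entries = [
        {"id": "1", "name": "hsa:3643", "type": "gene", "label": "IR"},
        {"id": "2", "name": "hsa:3667", "type": "gene", "label": "IRS"},
        {"id": "3", "name": "hsa:5290", "type": "gene", "label": "p110"},
        {"id": "4", "name": "hsa:5295", "type": "gene", "label": "p85"},
        {"id": "5", "type": "group", "components": ["3", "4"], "label": "PI3K"},
        {"id": "6", "name": "cpd:C05981", "type": "compound", "label": "PIP3"},
        {"id": "7", "name": "hsa:5170 hsa:5171", "type": "gene", "label": "PDK1/2"},
        {"id": "8", "name": "hsa:207 hsa:208 hsa:10000", "type": "gene", "label": "AKT"},
        {"id": "9", "name": "hsa:5139 hsa:5140", "type": "gene", "label": "PDE3"},
        {"id": "10", "name": "cpd:C00575", "type": "compound", "label": "cAMP"},
        {"id": "11", "name": "hsa:5566", "type": "gene", "label": "PKA"},
        {"id": "12", "name": "hsa:3991", "type": "gene", "label": "LIPE"},
        {"id": "13", "name": "hsa:51763", "type": "gene", "label": "SKIP"},
        {"id": "14", "name": "hsa:3635", "type": "gene", "label": "SHIP"},
    ]
    relations = [
        {"entry1": "1", "entry2": "2", "type": "PPrel", "subtypes": [("activation", "-->")]},
        {"entry1": "2", "entry2": "5", "type": "PPrel", "subtypes": [("activation", "-->")]},
        {"entry1": "5", "entry2": "7", "type": "PPrel",
         "subtypes": [("activation", "-->"), ("compound", "6")]},
        {"entry1": "13", "entry2": "6", "type": "PCrel", "subtypes": [("inhibition", "--|")]},
        {"entry1": "14", "entry2": "6", "type": "PCrel", "subtypes": [("inhibition", "--|")]},
        {"entry1": "7", "entry2": "8", "type": "PPrel", "subtypes": [("activation", "-->")]},
        {"entry1": "8", "entry2": "9", "type": "PPrel", "subtypes": [("activation", "-->")]},
        {"entry1": "9", "entry2": "10", "type": "PCrel", "subtypes": [("inhibition", "--|")]},
        {"entry1": "10", "entry2": "11", "type": "PCrel", "subtypes": [("activation", "-->")]},
        {"entry1": "11", "entry2": "12", "type": "PPrel", "subtypes": [("activation", "-->")]},
    ]
    bg_ids = []
    for i in range(n_background):
        eid = str(100 + i)
        entries.append({"id": eid, "name": f"hsa:{9000 + i}", "type": "gene", "label": f"BG{i}"})
        bg_ids.append(eid)
        if i % 3 != 0:
            relations.append(
                {"entry1": str(100 + i - 1), "entry2": eid, "type": "PPrel",
                 "subtypes": [("activation", "-->")]}
            )
    doc = _kgml_document("syn:insulin_fragment", "insulin signaling fragment", entries, relations)
    topology = parse_kgml(doc)

    pdk = ["7.0", "7.1"]
    akt = ["8.0", "8.1", "8.2"]
    pde = ["9.0", "9.1"]
    gene_ids = ["1", "2", "3", "4", *pdk, *akt, *pde, "11", "12", "13", "14", *bg_ids]
    gene_nodes = [topology.nodes[g] for g in gene_ids]

    act = {"PPrel", "activation"}
    split_act = {"PPrel", "activation", COMPOUND_SPLIT_TYPE}
    records: list[tuple[str, str, bool, set]] = [
        ("1", "2", True, act),
        ("2", "3", True, act),
        ("2", "4", True, act),
        ("3", "4", False, {"binding"}),
        ("11", "12", True, act),
    ]
    for up in ("3", "4"):
        for down in pdk:
            records.append((up, down, True, split_act | {INDIRECT_TYPE}))
    for up in ("13", "14"):
        for down in pdk:
            records.append((up, down, True, {"PCrel", "inhibition"} | split_act | {INDIRECT_TYPE}))
    for up in pdk:
        for down in akt:
            records.append((up, down, True, act))
    for up in akt:
        for down in pde:
            records.append((up, down, True, act))
    for up in pde:
        records.append((up, "11", True, {"PCrel", "inhibition", "activation", INDIRECT_TYPE}))
    for i in range(1, n_background):
        if i % 3 != 0:
            records.append((str(100 + i - 1), str(100 + i), True, act))

    expected = _expected_network("syn:insulin_fragment", topology.title, gene_nodes, records)
    return Fixture(spec, doc, "kgml", topology, expected, {2: 10})


def _gamma_secretase_fixture(spec: FixtureSpec) -> Fixture:
    """Gamma-secretase AND complex with OR groups of protein variants nested
    inside, catalyzing the cleavage of NOTCH1 into its intracellular domain."""
    b = _BiopaxBuilder()
    children = {
        "PSEN": ["PSEN1v1", "PSEN1v2", "PSEN1v3", "PSEN1v4", "PSEN1v5", "PSEN2v1", "PSEN2v2"],
        "NCSTN": ["NCSTNv1", "NCSTNv2"],
        "APH1": ["APH1A", "APH1B"],
        "PEN2": ["PEN2"],
    }
    for name, variants in children.items():
        xrefs = [b.xref(f"xref_{v}", "UniProt", v) for v in variants]
        b.protein(f"prot_{name}", name, xrefs)
    b.complex("gamma_secretase", "Gamma-secretase complex",
              [f"prot_{n}" for n in children])
    b.protein("prot_NOTCH1", "NOTCH1", [b.xref("xref_NOTCH1", "EntrezGene", "4851")])
    b.protein("prot_NICD", "NICD", [b.xref("xref_NICD", "EntrezGene", "485100")])
    b.reaction("cleavage", left=["prot_NOTCH1"], right=["prot_NICD"])
    b.catalysis("cat", "gamma_secretase", "cleavage", "ACTIVATION")
    b.pathway("pw_notch", "Notch1 cleavage by gamma-secretase", ["cat", "cleavage"])
    doc = b.tobytes()
    topology = parse_biopax(doc)[0]

    member_ids = {
        name: (
            [f"prot_{name}.{i}" for i in range(len(variants))]
            if len(variants) > 1
            else [f"prot_{name}"]
        )
        for name, variants in children.items()
    }
    leaves = [m for ms in member_ids.values() for m in ms]
    gene_nodes = [topology.nodes[m] for m in leaves]
    gene_nodes += [topology.nodes["prot_NOTCH1"], topology.nodes["prot_NICD"]]

    records: list[tuple[str, str, bool, set]] = [
        ("prot_NOTCH1", "prot_NICD", True, {"conversion"})
    ]
    names = list(children)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            for a in member_ids[na]:
                for c in member_ids[nb]:
                    records.append((a, c, False, {"binding"}))
    for leaf in leaves:
        records.append((leaf, "prot_NICD", True, {"catalysisOut (ACTIVATION)"}))
    expected = _expected_network("pw_notch", topology.title, gene_nodes, records)
    return Fixture(spec, doc, "biopax", topology, expected, {})


def make_random_topology(
    n_genes: int,
    n_compounds: int,
    n_groups: int,
    edge_density: float,
    seed: int,
    p_undirected: float = 0.15,
    with_compartments: bool = True,
    p_blacklisted: float = 0.2,
    p_via_compound: float = 0.15,
    p_or: float = 0.5,
) -> PathwayTopology:
    """Seeded random mixed topology for oracle-equivalence property tests.

    Groups draw 2-4 gene members (later groups may nest an earlier one);
    compound-incident edges draw a compartment from {None, cytosol, plasma
    membrane}; a fraction of compounds is the blacklisted species water; a
    fraction of gene-gene PPrel edges carries a bridging-compound subtype.
    """
    if not 0 <= edge_density <= 1:
        raise PathnetError("edge_density must be within [0, 1]")
    rng = np.random.default_rng(seed)
    topology = PathwayTopology(pathway_id=f"syn:random{seed}", title=f"random topology {seed}",
                               database_tag="synthetic")
    genes = [f"g{i}" for i in range(n_genes)]
    for i, gid in enumerate(genes):
        topology.add_node(_gene(gid, ("syn", f"G{i:03d}"), gid))
    compounds = [f"c{i}" for i in range(n_compounds)]
    for i, cid in enumerate(compounds):
        blacklisted = rng.random() < p_blacklisted
        native = ("cpd", "C00001") if blacklisted else ("cpd", f"X{i:03d}")
        topology.add_node(
            NodeRef(node_id=cid, kind=COMPOUND, native_ids=(native,),
                    display_label="water" if blacklisted else cid)
        )
    groups = []
    for i in range(n_groups):
        if not genes:
            break
        pool = list(genes)
        if groups and rng.random() < 0.3:
            pool = pool + [groups[-1]]
        size = min(len(pool), int(rng.integers(2, 5)))
        members = tuple(rng.choice(pool, size=size, replace=False).tolist())
        gid = f"grp{i}"
        topology.nodes[gid] = GroupNode(
            node_id=gid, semantics=OR if rng.random() < p_or else AND, members=members
        )
        groups.append(gid)

    vocab = ["activation", "inhibition", "expression", "phosphorylation"]
    endpoints = genes + compounds + groups
    compartments = [None, "cytosol", "plasma membrane"]
    for src in endpoints:
        for dst in endpoints:
            if src == dst or rng.random() >= edge_density:
                continue
            src_kind = getattr(topology.nodes[src], "kind", "group")
            dst_kind = getattr(topology.nodes[dst], "kind", "group")
            compound_incident = COMPOUND in (src_kind, dst_kind)
            types = {"PCrel" if compound_incident else "PPrel"}
            types.update(
                rng.choice(vocab, size=int(rng.integers(1, 3)), replace=False).tolist()
            )
            via = None
            if (
                not compound_incident
                and compounds
                and "PPrel" in types
                and rng.random() < p_via_compound
            ):
                via = str(rng.choice(compounds))
            compartment = None
            if compound_incident and with_compartments:
                compartment = compartments[int(rng.integers(0, len(compartments)))]
            topology.add_edge(
                TypedEdge(
                    src=src,
                    dst=dst,
                    directed=bool(rng.random() >= p_undirected),
                    types=frozenset(types),
                    compartment=compartment,
                    via_compound=via,
                )
            )
    return topology


def _random_fixture(spec: FixtureSpec) -> Fixture:
    params = dict(spec.params)
    topology = make_random_topology(
        n_genes=int(params.get("n_genes", 12)),
        n_compounds=int(params.get("n_compounds", 4)),
        n_groups=int(params.get("n_groups", 2)),
        edge_density=float(params.get("edge_density", 0.2)),
        seed=spec.seed,
        with_compartments=bool(params.get("with_compartments", True)),
    )
    config = params.get("config") or ConversionConfig()
    expected_records, histogram = oracle_convert(topology, config)
    expected = GeneNetwork(pathway_id=topology.pathway_id, title=topology.title)
    for node in topology.nodes.values():
        if isinstance(node, NodeRef) and node.kind == GENE:
            expected.add_node(node)
    for src, dst, directed, types in expected_records:
        merge_edge(expected, TypedEdge(src=src, dst=dst, directed=directed, types=types))
    return Fixture(spec, None, "memory", topology, expected, dict(histogram))


_BUILDERS = {
    "and_group": _and_group_fixture,
    "or_group": _or_group_fixture,
    "compound_bridge": _compound_bridge_fixture,
    "compound_chain": _compound_chain_fixture,
    "insulin_fragment": _insulin_fragment_fixture,
    "gamma_secretase": _gamma_secretase_fixture,
    "random": _random_fixture,
}


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the document, parsed topology and expected network for ``spec``."""
    return _BUILDERS[spec.kind](spec)


def fixture_suite() -> list[Fixture]:
    """The standard set materialized by the CLI ``fixtures`` subcommand."""
    specs = [
        FixtureSpec("and_group", {"k": 4}),
        FixtureSpec("or_group", {"k": 3}),
        FixtureSpec("compound_bridge"),
        FixtureSpec("compound_bridge", {"blacklisted": True}),
        FixtureSpec("compound_bridge", {"compartments": ("cytosol", "plasma membrane")}),
        FixtureSpec("compound_chain", {"length": 4}),
        FixtureSpec("insulin_fragment"),
        FixtureSpec("gamma_secretase"),
    ]
    return [make_fixture(s) for s in specs]


def topology_canonical_form(topology: PathwayTopology) -> tuple:
    """Hashable structural form used in round-trip and determinism checks."""
    nodes = []
    for node_id in sorted(topology.nodes):
        node = topology.nodes[node_id]
        if isinstance(node, GroupNode):
            nodes.append((node_id, "group", node.semantics, tuple(node.members)))
        else:
            nodes.append((node_id, node.kind, node.native_ids))
    edges = sorted(
        (e.src, e.dst, e.directed, tuple(sorted(e.types)), e.compartment_label(), e.via_compound)
        for e in topology.edges
    )
    return (tuple(nodes), tuple(edges))
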