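"""KGML parsing: groups, compounds, map entries, compound-subtype splitting."""

import pytest

from pathnet.fixtures import FixtureSpec, make_fixture, topology_canonical_form
from pathnet.kgml import COMPOUND_SPLIT_TYPE, KgmlParseError, parse_kgml, split_compound_subtype
from pathnet.model import GroupNode, StructuralError


def kgml(entries: str, relations: str = "") -> bytes:
    return f'<?xml version="1.0"?><pathway name="path:test" title="t">{entries}{relations}</pathway>'.encode()


def test_group_entry_becomes_and_group():
    doc = kgml(
        '<entry id="1" name="hsa:10" type="gene"/>'
        '<entry id="2" name="hsa:11" type="gene"/>'
        '<entry id="3" type="group"><component id="1"/><component id="2"/></entry>'
    )
    top = parse_kgml(doc)
    group = top.nodes["3"]
    assert isinstance(group, GroupNode)
    assert group.semantics == "AND"
    assert group.members == ("1", "2")


def test_multi_name_gene_entry_becomes_or_group():
    doc = kgml('<entry id="1" name="hsa:1 hsa:2 hsa:3" type="gene"/>')
    top = parse_kgml(doc)
    group = top.nodes["1"]
    assert isinstance(group, GroupNode)
    assert group.semantics == "OR"
    assert len(group.members) == 3
    assert [top.nodes[m].native_ids for m in group.members] == [
        (("hsa", "1"),), (("hsa", "2"),), (("hsa", "3"),),
    ]


def test_empty_pathway_parses_to_empty_topology():
    top = parse_kgml(kgml(""))
    assert not top.nodes and not top.edges


def test_map_entries_dropped_with_their_relations():
    doc = kgml(
        '<entry id="1" name="hsa:10" type="gene"/>'
        '<entry id="2" name="path:hsa00020" type="map"/>',
        '<relation entry1="1" entry2="2" type="maplink"><subtype name="compound" value="9"/></relation>',
    )
    top = parse_kgml(doc)
    assert list(top.nodes) == ["1"]
    assert top.edges == []


def test_malformed_xml_raises_parse_error():
    with pytest.raises(KgmlParseError, match="line"):
        parse_kgml(b"<pathway><entry id='1'")


def test_unknown_relation_endpoint_strict_vs_lenient():
    doc = kgml(
        '<entry id="1" name="hsa:10" type="gene"/>',
        '<relation entry1="1" entry2="99" type="PPrel"/>',
    )
    with pytest.raises(StructuralError, match="99"):
        parse_kgml(doc, strict=True)
    top = parse_kgml(doc, strict=False)
    assert top.edges == []


def test_parse_is_deterministic():
    fixture = make_fixture(FixtureSpec("insulin_fragment"))
    t1 = parse_kgml(fixture.document)
    t2 = parse_kgml(fixture.document)
    assert topology_canonical_form(t1) == topology_canonical_form(t2)


@pytest.mark.parametrize("seed", range(5))
def test_node_count_matches_generator_ground_truth(seed):
    """#nodes = single-name genes + OR members + OR groups + compounds + groups."""
    from pathnet.fixtures import make_random_topology, write_kgml

    top = make_random_topology(
        n_genes=10, n_compounds=3, n_groups=2, edge_density=0.15, seed=seed,
        with_compartments=False, p_undirected=0.0, p_or=0.0,
    )
    reparsed = parse_kgml(write_kgml(top))
    assert len(reparsed.nodes) == len(top.nodes)
    kinds = lambda t: sorted(getattr(n, "kind", "group") for n in t.nodes.values())
    assert kinds(reparsed) == kinds(top)


class TestSplitCompoundSubtype:
    def test_pprel_with_compound_splits_into_two_edges(self):
        doc = kgml(
            '<entry id="52" name="hsa:5290" type="gene"/>'
            '<entry id="62" name="hsa:5170" type="gene"/>'
            '<entry id="15" name="cpd:C05981" type="compound"/>',
            '<relation entry1="52" entry2="62" type="PPrel">'
            '<subtype name="activation" value="--&gt;"/><subtype name="compound" value="15"/></relation>',
        )
        top = split_compound_subtype(parse_kgml(doc))
        got = {(e.src, e.dst) for e in top.edges}
        assert got == {("52", "15"), ("15", "62")}
        for e in top.edges:
            assert COMPOUND_SPLIT_TYPE in e.types
            assert "activation" in e.types

    def test_no_compound_subtypes_is_identity(self):
        doc = kgml(
            '<entry id="1" name="hsa:1" type="gene"/><entry id="2" name="hsa:2" type="gene"/>',
            '<relation entry1="1" entry2="2" type="PPrel"><subtype name="activation" value="--&gt;"/></relation>',
        )
        top = parse_kgml(doc)
        assert topology_canonical_form(split_compound_subtype(top)) == topology_canonical_form(top)

    def test_two_relations_sharing_a_compound_yield_four_edges(self):
        doc = kgml(
            '<entry id="1" name="hsa:1" type="gene"/>'
            '<entry id="2" name="hsa:2" type="gene"/>'
            '<entry id="3" name="hsa:3" type="gene"/>'
            '<entry id="9" name="cpd:C00042" type="compound"/>',
            '<relation entry1="1" entry2="2" type="PPrel"><subtype name="compound" value="9"/></relation>'
            '<relation entry1="2" entry2="3" type="PPrel"><subtype name="compound" value="9"/></relation>',
        )
        top = split_compound_subtype(parse_kgml(doc))
        got = {(e.src, e.dst) for e in top.edges}
        assert got == {("1", "9"), ("9", "2"), ("2", "9"), ("9", "3")}

    def test_split_preserves_node_sets(self):
        fixture = make_fixture(FixtureSpec("insulin_fragment"))
        before = set(fixture.topology.nodes)
        after = set(split_compound_subtype(fixture.topology).nodes)
        assert before == after

    def test_compound_subtype_not_resolving_to_compound_errors(self):
        doc = kgml(
            '<entry id="1" name="hsa:1" type="gene"/><entry id="2" name="hsa:2" type="gene"/>',
            '<relation entry1="1" entry2="2" type="PPrel"><subtype name="compound" value="2"/></relation>',
        )
        with pytest.raises(StructuralError, match="compound"):
            split_compound_subtype(parse_kgml(doc))
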