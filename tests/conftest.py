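import pytest

from pathnet.converter import ConversionConfig
from pathnet.fixtures import FixtureSpec, make_fixture
from pathnet.model import GeneNetwork, NodeRef, TypedEdge, merge_edge


def gene(node_id, ns="syn"):
    return NodeRef(node_id=node_id, kind="gene", native_ids=((ns, node_id),))


def compound(node_id, ident=None, label=""):
    return NodeRef(
        node_id=node_id,
        kind="compound",
        native_ids=(("cpd", ident or node_id),),
        display_label=label,
    )


def network_of(nodes, records, pathway_id="t"):
    net = GeneNetwork(pathway_id)
    for n in nodes:
        net.add_node(gene(n) if isinstance(n, str) else n)
    for src, dst, directed, types in records:
        merge_edge(net, TypedEdge(src=src, dst=dst, directed=directed, types=frozenset(types)))
    return net


@pytest.fixture(scope="session")
def insulin_fixture():
    return make_fixture(FixtureSpec("insulin_fragment"))


@pytest.fixture(scope="session")
def gamma_secretase_fixture():
    return make_fixture(FixtureSpec("gamma_secretase"))


@pytest.fixture
def default_config():
    return ConversionConfig()
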