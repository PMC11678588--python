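import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from litkg.graph import ConceptNode, KnowledgeGraph, SemanticTriple
from litkg.synthetic import GeneratorConfig, generate_graph


@pytest.fixture(scope="session")
def chain_graph() -> KnowledgeGraph:
    """a -r-> b -r-> c, all distinct types."""
    nodes = [
        ConceptNode("a", "node a", "aapp"),
        ConceptNode("b", "node b", "gngm"),
        ConceptNode("c", "node c", "dsyn"),
    ]
    triples = [SemanticTriple("a", "r", "b"), SemanticTriple("b", "r", "c")]
    return KnowledgeGraph(nodes, triples)


@pytest.fixture(scope="session")
def meeting_graph() -> KnowledgeGraph:
    """Two sources sharing one of the target's two midpoint neighbors.

    s1 -> {m1, m2}, s2 -> {m1}; {m1, m2} -> T.
    """
    nodes = [
        ConceptNode("s1", "source one", "aapp"),
        ConceptNode("s2", "source two", "aapp"),
        ConceptNode("m1", "mid one", "gngm"),
        ConceptNode("m2", "mid two", "gngm"),
        ConceptNode("T", "target", "dsyn"),
    ]
    triples = [
        SemanticTriple("s1", "assoc", "m1"),
        SemanticTriple("s1", "assoc", "m2"),
        SemanticTriple("s2", "assoc", "m1"),
        SemanticTriple("m1", "affects", "T"),
        SemanticTriple("m2", "affects", "T"),
    ]
    return KnowledgeGraph(nodes, triples)


@pytest.fixture(scope="session")
def small_fixture():
    """Seeded synthetic graph shared by recovery tests."""
    config = GeneratorConfig(n_aapp=80, seed=11)
    graph, truth = generate_graph(config)
    return config, graph, truth
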