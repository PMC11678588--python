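import numpy as np
import pandas as pd
import pytest

from litkg.graph import ConceptNode, KnowledgeGraph, SemanticTriple
from litkg.metapaths import (
    MetapathSignature,
    aggregate_targets,
    enumerate_signatures,
    hetesim,
    hetesim_reference,
    rank_sources,
)
from litkg.synthetic import random_typed_graph


def sig(node_types, steps):
    return MetapathSignature(tuple(node_types), tuple(steps))


class TestEnumerateSignatures:
    def test_direct_triple_single_signature(self, chain_graph):
        found = enumerate_signatures(chain_graph, "b", "c", 1)
        assert found == {sig(("gngm", "dsyn"), (("r", "forward"),))}

    def test_no_path_within_max_length_empty(self, chain_graph):
        assert enumerate_signatures(chain_graph, "a", "c", 1) == set()

    def test_two_parallel_routes_distinct_signatures(self):
        """Two 2-hop routes through different intermediate types."""
        nodes = [
            ConceptNode("s", "s", "aapp"),
            ConceptNode("g", "g", "gngm"),
            ConceptNode("h", "h", "chem"),
            ConceptNode("T", "T", "dsyn"),
        ]
        triples = [
            SemanticTriple("s", "r", "g"),
            SemanticTriple("g", "r", "T"),
            SemanticTriple("s", "r", "h"),
            SemanticTriple("h", "r", "T"),
        ]
        graph = KnowledgeGraph(nodes, triples)
        found = enumerate_signatures(graph, "s", "T", 2)
        # Exhaustive instance paths: s-g-T and s-h-T, one signature each.
        assert found == {
            sig(("aapp", "gngm", "dsyn"), (("r", "forward"), ("r", "forward"))),
            sig(("aapp", "chem", "dsyn"), (("r", "forward"), ("r", "forward"))),
        }

    def test_simple_path_constraint_excludes_revisits(self, meeting_graph):
        # Any signature's length never exceeds the bound and all are realizable.
        for max_length in (1, 2, 3):
            for s in enumerate_signatures(meeting_graph, "s1", "T", max_length):
                assert 1 <= s.length <= max_length
                assert s.endpoint_types == ("aapp", "dsyn")


class TestHetesim:
    def test_palindromic_self_similarity_is_one(self, meeting_graph):
        palindrome = sig(
            ("aapp", "gngm", "aapp"), (("assoc", "forward"), ("assoc", "reverse"))
        )
        assert hetesim(meeting_graph, "s1", "s1", palindrome) == pytest.approx(1.0)

    def test_no_matching_instance_path_scores_zero(self, meeting_graph):
        missing = sig(
            ("aapp", "gngm", "dsyn"), (("affects", "forward"), ("affects", "forward"))
        )
        assert hetesim(meeting_graph, "s2", "T", missing) == 0.0

    def test_meeting_distribution_cosine_hand_computed(self, meeting_graph):
        """s1 meets T on both midpoints (cos 1); s2 on one of two (cos 1/sqrt 2)."""
        two_hop = sig(
            ("aapp", "gngm", "dsyn"), (("assoc", "forward"), ("affects", "forward"))
        )
        assert hetesim(meeting_graph, "s1", "T", two_hop) == pytest.approx(1.0)
        expected = 1.0 / np.sqrt(2.0)  # u=(1,0) vs v=(1/2,1/2)
        assert hetesim(meeting_graph, "s2", "T", two_hop) == pytest.approx(expected)
        assert hetesim_reference(meeting_graph, "s2", "T", two_hop) == pytest.approx(expected)

    def test_length1_degree_normalization(self, meeting_graph):
        """Single-edge relatedness is 1/sqrt(outdeg * indeg) on the relation."""
        graph = KnowledgeGraph(
            [
                ConceptNode("x", "x", "aapp"),
                ConceptNode("y", "y", "aapp"),
                ConceptNode("T", "T", "dsyn"),
            ],
            [SemanticTriple("x", "r", "T"), SemanticTriple("y", "r", "T")],
        )
        one_hop = sig(("aapp", "dsyn"), (("r", "forward"),))
        assert hetesim(graph, "x", "T", one_hop) == pytest.approx(1 / np.sqrt(2))
        assert hetesim_reference(graph, "x", "T", one_hop) == pytest.approx(1 / np.sqrt(2))

    @pytest.mark.parametrize("seed", range(40))
    def test_matrix_equals_bruteforce_and_symmetry_on_random_graphs(self, seed):
        graph = random_typed_graph(seed, n_nodes=4 + seed % 9)
        cuis = sorted(graph.nodes)
        rng = np.random.default_rng(seed)
        for _ in range(3):
            s, t = (cuis[i] for i in rng.integers(len(cuis), size=2))
            if s == t:
                continue
            for signature in sorted(enumerate_signatures(graph, s, t, 3))[:4]:
                fast = hetesim(graph, s, t, signature)
                slow = hetesim_reference(graph, s, t, signature)
                assert fast == pytest.approx(slow, abs=1e-9)
                assert 0.0 <= fast <= 1.0
                assert hetesim(graph, t, s, signature.reverse()) == pytest.approx(
                    fast, abs=1e-9
                )

    def test_additional_disjoint_two_hop_path_never_decreases_score(self):
        """Controlled family: k parallel midpoints for s, one competitor for s2."""
        previous = 0.0
        for k in range(1, 6):
            nodes = [
                ConceptNode("s", "s", "aapp"),
                ConceptNode("s2", "s2", "aapp"),
                ConceptNode("mx", "mx", "gngm"),
                ConceptNode("T", "T", "dsyn"),
            ] + [ConceptNode(f"m{i}", f"m{i}", "gngm") for i in range(k)]
            triples = [
                SemanticTriple("s2", "a", "mx"),
                SemanticTriple("mx", "b", "T"),
            ]
            for i in range(k):
                triples += [
                    SemanticTriple("s", "a", f"m{i}"),
                    SemanticTriple(f"m{i}", "b", "T"),
                ]
            graph = KnowledgeGraph(nodes, triples)
            scores = rank_sources(graph, ["T"], "aapp", depth=2, max_length=2)
            current = float(
                scores.loc[scores.source_cui == "s", "hetesim"].iloc[0]
            )
            assert current >= previous - 1e-12
            previous = current


class TestRankSources:
    def test_single_source_single_direct_edge(self):
        graph = KnowledgeGraph(
            [ConceptNode("s", "s", "aapp"), ConceptNode("T", "T", "dsyn")],
            [SemanticTriple("s", "r", "T")],
        )
        table = rank_sources(graph, ["T"], "aapp")
        assert len(table) == 1
        one_hop = sig(("aapp", "dsyn"), (("r", "forward"),))
        assert table.hetesim.iloc[0] == pytest.approx(hetesim(graph, "s", "T", one_hop))
        assert table.n_signatures.iloc[0] == 1

    def test_exact_mean_across_targets(self):
        long = pd.DataFrame(
            [("s", "T1", 0.4, 1), ("s", "T2", 0.8, 2)],
            columns=["source_cui", "target_cui", "hetesim", "n_signatures"],
        )
        aggregated = aggregate_targets(long)
        assert aggregated.score.iloc[0] == pytest.approx(0.6)
        assert aggregated.n_targets.iloc[0] == 2

    def test_empty_result_warns(self):
        graph = KnowledgeGraph(
            [ConceptNode("T", "T", "dsyn"), ConceptNode("a", "a", "aapp")], []
        )
        with pytest.warns(UserWarning, match="no source nodes"):
            table = rank_sources(graph, ["T"], "aapp")
        assert table.empty

    def test_deterministic_ordering(self, small_fixture):
        _, graph, _ = small_fixture
        t1 = rank_sources(graph, ["C0002395"], "aapp")
        t2 = rank_sources(graph, ["C0002395"], "aapp")
        pd.testing.assert_frame_equal(t1, t2)
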