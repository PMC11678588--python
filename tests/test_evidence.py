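import pytest
from hypothesis import given
from hypothesis import strategies as st

from litkg.evidence import (
    DIRECT,
    INDIRECT,
    EvidenceLabel,
    classify_evidence,
    evaluate,
    f_measure,
    read_labels,
    write_labels,
)
from litkg.exceptions import ClassificationError, EvaluationError
from litkg.graph import ConceptNode, KnowledgeGraph, SemanticTriple
from litkg.synthetic import DISEASES, GeneratorConfig, generate_graph


@pytest.fixture(scope="module")
def toy_graph():
    nodes = [
        ConceptNode("d1", "direct node", "aapp"),
        ConceptNode("i1", "indirect node", "aapp"),
        ConceptNode("g1", "gene", "gngm"),
        ConceptNode("T", "disease", "dsyn"),
    ]
    triples = [
        SemanticTriple("d1", "affects", "T"),
        SemanticTriple("i1", "assoc", "g1"),
        SemanticTriple("g1", "affects", "T"),
    ]
    return KnowledgeGraph(nodes, triples)


class TestClassify:
    def test_length1_triple_is_direct(self, toy_graph):
        assert classify_evidence(toy_graph, "d1", ["T"]) == DIRECT

    def test_intermediate_only_is_indirect(self, toy_graph):
        assert classify_evidence(toy_graph, "i1", ["T"]) == INDIRECT

    def test_reverse_direction_also_direct(self):
        graph = KnowledgeGraph(
            [ConceptNode("a", "a", "aapp"), ConceptNode("T", "T", "dsyn")],
            [SemanticTriple("T", "affects", "a")],
        )
        assert classify_evidence(graph, "a", ["T"]) == DIRECT

    def test_disconnected_node_with_depth_raises(self):
        graph = KnowledgeGraph(
            [ConceptNode("a", "a", "aapp"), ConceptNode("T", "T", "dsyn")], []
        )
        with pytest.raises(ClassificationError):
            classify_evidence(graph, "a", ["T"], depth=2)

    def test_fixture_predictions_equal_planted_flags(self, small_fixture):
        _, graph, truth = small_fixture
        for cui, flags in truth.direct_flag.items():
            for disease, flag in flags.items():
                predicted = classify_evidence(graph, cui, [DISEASES[disease][0]])
                assert predicted == (DIRECT if flag else INDIRECT)


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = [
            EvidenceLabel("c1", "AD", DIRECT, truth=DIRECT),
            EvidenceLabel("c2", "AD", INDIRECT, truth=INDIRECT),
        ]
        report = evaluate(labels)
        assert report.rounded() == {
            "precision": 1.0,
            "recall": 1.0,
            "f_measure": 1.0,
            "accuracy": 1.0,
        }

    def test_hand_computed_confusion(self):
        labels = (
            [EvidenceLabel(f"t{i}", "AD", DIRECT, truth=DIRECT) for i in range(2)]
            + [EvidenceLabel(f"f{i}", "AD", DIRECT, truth=INDIRECT) for i in range(2)]
        )
        report = evaluate(labels)
        assert (report.tp, report.fp, report.fn, report.tn) == (2, 2, 0, 0)
        assert report.precision == pytest.approx(0.5)
        assert report.recall == pytest.approx(1.0)
        assert report.f_measure == pytest.approx(2 / 3, abs=1e-4)
        assert report.accuracy == pytest.approx(0.5)

    def test_f_measure_rounding_from_reported_pair(self):
        assert round(f_measure(0.94, 0.71), 2) == 0.81

    def test_undefined_ratios_are_none_not_zero(self):
        labels = [EvidenceLabel("c", "AD", INDIRECT, truth=INDIRECT)]
        report = evaluate(labels)
        assert report.precision is None and report.recall is None
        assert report.accuracy == 1.0

    def test_missing_truth_lists_cuis(self):
        labels = [EvidenceLabel("cX", "AD", DIRECT)]
        with pytest.raises(EvaluationError, match="cX"):
            evaluate(labels)

    def test_empty_input_is_error(self):
        with pytest.raises(EvaluationError):
            evaluate([])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=30))
    def test_f_between_precision_and_recall_and_class_swap(self, outcomes):
        labels = [
            EvidenceLabel(
                f"c{i}",
                "AD",
                DIRECT if predicted else INDIRECT,
                truth=DIRECT if actual else INDIRECT,
            )
            for i, (predicted, actual) in enumerate(outcomes)
        ]
        report = evaluate(labels)
        if report.precision is not None and report.recall is not None and report.f_measure is not None:
            assert (
                min(report.precision, report.recall) - 1e-12
                <= report.f_measure
                <= max(report.precision, report.recall) + 1e-12
            )
        swapped = evaluate(labels, positive_class=INDIRECT)
        assert swapped.accuracy == pytest.approx(report.accuracy)
        assert (swapped.tp, swapped.fp, swapped.fn, swapped.tn) == (
            report.tn,
            report.fn,
            report.fp,
            report.tp,
        )


class TestDegenerateFixtures:
    @pytest.mark.parametrize("prob, positive", [(1.0, DIRECT), (0.0, INDIRECT)])
    def test_extreme_direct_probability_gives_perfect_metrics(self, prob, positive):
        config = GeneratorConfig(n_aapp=50, direct_edge_prob=prob, seed=13)
        graph, truth = generate_graph(config)
        labels = []
        for cui, flags in truth.direct_flag.items():
            for disease, flag in flags.items():
                predicted = classify_evidence(graph, cui, [DISEASES[disease][0]])
                labels.append(
                    EvidenceLabel(
                        cui, disease, predicted, truth=DIRECT if flag else INDIRECT
                    )
                )
        report = evaluate(labels, positive_class=positive)
        assert report.rounded() == {
            "precision": 1.0,
            "recall": 1.0,
            "f_measure": 1.0,
            "accuracy": 1.0,
        }


def test_label_csv_round_trip(tmp_path):
    labels = [
        EvidenceLabel("c1", "AD", DIRECT, "graph", DIRECT),
        EvidenceLabel("c2", "ALS", INDIRECT, "external", None),
    ]
    path = tmp_path / "labels.csv"
    write_labels(labels, path)
    assert read_labels(path) == labels
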