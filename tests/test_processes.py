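import warnings

import numpy as np
import pandas as pd
import pytest

from litkg.exceptions import ConfigurationError
from litkg.processes import (
    CATEGORIES,
    ProcessTaxonomy,
    default_taxonomy,
    intersection_profile,
    map_nodes,
    normalize_profile,
    overall_percentages,
    process_zscores,
)
from litkg.synthetic import GeneratorConfig, generate_graph


class TestTaxonomy:
    def test_default_taxonomy_has_eight_nonempty_categories(self):
        taxonomy = default_taxonomy()
        assert taxonomy.categories == CATEGORIES
        assert all(taxonomy.lexicon[c] for c in CATEGORIES)

    def test_rejects_wrong_category_set(self):
        with pytest.raises(ConfigurationError):
            ProcessTaxonomy({"only one": ("kw",)})

    def test_rejects_uppercase_keywords(self):
        lexicon = {c: ("kw",) for c in CATEGORIES}
        lexicon["membrane regulation"] = ("Membrane",)
        with pytest.raises(ConfigurationError):
            ProcessTaxonomy(lexicon)


class TestMapNodes:
    def test_direct_keyword_hit(self):
        mapping = map_nodes([("C1", "synaptic vesicle protein X")])
        assert mapping["C1"] == {"synapse and neurotransmission"}

    def test_multi_label_assignment(self):
        mapping = map_nodes([("C1", "cytokine-driven cell cycle kinase")])
        assert mapping["C1"] == {
            "inflammation and immune response",
            "cell cycle regulation",
        }

    def test_word_boundary_not_substring(self):
        # "taurine" must not hit the "tau" keyword.
        with pytest.warns(UserWarning, match="no process keyword"):
            mapping = map_nodes([("C1", "taurine transport factor")])
        assert mapping["C1"] == set()

    def test_fixture_recovery_with_full_keyword_rate(self):
        config = GeneratorConfig(n_aapp=120, keyword_rate=1.0, seed=21)
        graph, truth = generate_graph(config)
        pairs = sorted((c, graph.node(c).name) for c in truth.process_labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mapping = map_nodes(pairs)
        for cui, planted in truth.process_labels.items():
            assert mapping[cui] == set(planted)


def toy_counts():
    counts = pd.DataFrame(
        0, index=list(CATEGORIES), columns=["AD∩ALS", "AD∩FTD", "ALS∩FTD"]
    )
    counts.loc["inflammation and immune response"] = [4, 1, 1]
    counts.loc["synapse and neurotransmission"] = [2, 2, 0]
    counts.loc["protein aggregation"] = [0, 0, 3]
    return counts


class TestProfiles:
    def test_single_shared_node_single_label(self):
        top_sets = {"AD": {"n1", "n2"}, "ALS": {"n1"}, "FTD": set()}
        mapping = {"n1": {"inflammation and immune response"}, "n2": {"protein aggregation"}}
        with pytest.warns(UserWarning, match="empty intersection"):
            counts = intersection_profile(top_sets, mapping)
        assert counts.loc["inflammation and immune response", "AD∩ALS"] == 1
        assert counts.drop(index="inflammation and immune response")["AD∩ALS"].sum() == 0
        assert counts["AD∩FTD"].sum() == 0

    def test_matrix_equals_hand_tally(self, small_fixture):
        _, graph, truth = small_fixture
        sets = truth.region_sets()
        mapping = {c: set(labels) for c, labels in truth.process_labels.items()}
        counts = intersection_profile(sets, mapping)
        for x, y in (("AD", "ALS"), ("AD", "FTD"), ("ALS", "FTD")):
            for category in CATEGORIES:
                tally = sum(
                    category in mapping[c] for c in sets[x] & sets[y]
                )
                assert counts.loc[category, f"{x}∩{y}"] == tally

    def test_multilabel_conservation(self, small_fixture):
        _, _, truth = small_fixture
        sets = truth.region_sets()
        mapping = {c: set(labels) for c, labels in truth.process_labels.items()}
        counts = intersection_profile(sets, mapping)
        for x, y in (("AD", "ALS"), ("AD", "FTD"), ("ALS", "FTD")):
            assignments = sum(len(mapping[c]) for c in sets[x] & sets[y])
            assert counts[f"{x}∩{y}"].sum() == assignments

    def test_unlabeled_node_changes_nothing(self):
        top_sets = {"AD": {"n1", "n9"}, "ALS": {"n1", "n9"}}
        with_labels = intersection_profile(top_sets, {"n1": {"protein aggregation"}, "n9": set()})
        without = intersection_profile(
            {"AD": {"n1"}, "ALS": {"n1"}}, {"n1": {"protein aggregation"}}
        )
        pd.testing.assert_frame_equal(with_labels, without)


class TestNormalization:
    def test_single_nonzero_cell_is_100(self):
        counts = toy_counts()
        normalized = normalize_profile(counts)
        assert normalized.loc["protein aggregation", "ALS∩FTD"] == pytest.approx(75.0)
        assert normalized["AD∩ALS"].sum() == pytest.approx(100.0)

    def test_uniform_counts_are_12_5_each(self):
        counts = pd.DataFrame(3, index=list(CATEGORIES), columns=["AD∩ALS", "AD∩FTD"])
        normalized = normalize_profile(counts)
        assert np.allclose(normalized.to_numpy(), 12.5)

    def test_zero_column_stays_zero_with_warning(self):
        counts = toy_counts()
        counts["ALS∩FTD"] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            normalized = normalize_profile(counts)
        assert (normalized["ALS∩FTD"] == 0).all()

    def test_random_counts_columns_sum_to_100(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(1, 30, size=(8, 3)),
            index=list(CATEGORIES),
            columns=["a", "b", "c"],
        )
        sums = normalize_profile(counts).sum(axis=0)
        assert np.allclose(sums, 100.0, atol=1e-9)


class TestZScores:
    def test_zero_variance_category(self):
        profile = pd.DataFrame(
            [[10.0, 10.0, 10.0]], index=["protein aggregation"], columns=list("abc")
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            z = process_zscores(profile)
        assert (z.to_numpy() == 0).all()

    def test_closed_form_population_sd(self):
        profile = pd.DataFrame(
            [[0.0, 0.0, 30.0]], index=["protein aggregation"], columns=list("abc")
        )
        z = process_zscores(profile).to_numpy().ravel()
        assert z == pytest.approx([-0.7071, -0.7071, 1.4142], abs=1e-4)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(4)
        profile = pd.DataFrame(
            rng.random((8, 3)) * 40, index=list(CATEGORIES), columns=list("abc")
        )
        z = process_zscores(profile)
        assert np.allclose(z.sum(axis=1), 0.0, atol=1e-9)

    def test_single_intersection_is_error(self):
        with pytest.raises(ValueError):
            process_zscores(toy_counts()[["AD∩ALS"]])


class TestOverallPercentages:
    def test_single_category_holds_all(self):
        counts = pd.DataFrame(0, index=list(CATEGORIES), columns=["a", "b"])
        counts.loc["membrane regulation"] = [2, 3]
        shares = overall_percentages(counts)
        assert shares["membrane regulation"] == pytest.approx(100.0)

    def test_two_equal_categories_split_evenly(self):
        counts = pd.DataFrame(0, index=list(CATEGORIES), columns=["a"])
        counts.loc["membrane regulation"] = 4
        counts.loc["protein aggregation"] = 4
        shares = overall_percentages(counts)
        assert shares["membrane regulation"] == pytest.approx(50.0)

    def test_matches_exhaustive_tally(self):
        counts = toy_counts()
        shares = overall_percentages(counts)
        total = counts.to_numpy().sum()
        for category in CATEGORIES:
            assert shares[category] == pytest.approx(100 * counts.loc[category].sum() / total)

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValueError):
            overall_percentages(pd.DataFrame(0, index=list(CATEGORIES), columns=["a"]))

    def test_planted_label_distribution_recovered(self):
        """Overall shares track the planted category distribution at keyword_rate 1."""
        from litkg.synthetic import DEFAULT_LABEL_WEIGHTS

        config = GeneratorConfig(n_aapp=400, keyword_rate=1.0, seed=31)
        graph, truth = generate_graph(config)
        sets = truth.region_sets()
        pairs = sorted((c, graph.node(c).name) for c in truth.process_labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mapping = map_nodes(pairs)
            counts = intersection_profile(sets, mapping)
            shares = overall_percentages(counts)
        total_assignments = counts.to_numpy().sum()
        for category in CATEGORIES:
            expected = 100.0 * DEFAULT_LABEL_WEIGHTS[category]
            # Binomial 99% bound on the share at the realized assignment count.
            p = DEFAULT_LABEL_WEIGHTS[category]
            bound = 100.0 * 2.58 * np.sqrt(p * (1 - p) / total_assignments)
            # Second labels are drawn without replacement, which slightly
            # flattens the distribution; allow that shift on top of noise.
            assert abs(shares[category] - expected) < bound + 6.0
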