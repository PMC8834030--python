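"""Portrait-level analyses: PCM, similarity net, supporting maps, hourglass."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from agesom.portraits import (
    group_mean_portraits,
    pairwise_correlation_map,
    sample_summary_stats,
    shannon_entropy,
    similarity_net,
    supporting_maps,
)
from agesom.preprocess import centralize
from agesom.schemes import EXPRESSION_SCHEME
from agesom.simulate import generate_cohort, hourglass_fixture_spec


def _portraits(vals, samples):
    return pd.DataFrame(vals, columns=samples)


class TestGroupMeanPortraits:
    def test_hand_checked_node_wise_means(self, exp_cohort):
        vals = np.array([[1.0, 3.0, 10.0], [2.0, 4.0, 20.0]])
        portraits = _portraits(vals, ["a", "b", "c"])
        groups = {"a": "newborn", "b": "newborn", "c": "baby"}

        class TwoGroups:
            labels = ("newborn", "baby")

        out = group_mean_portraits(portraits, groups, TwoGroups())
        assert out["newborn"].tolist() == [2.0, 3.0]
        assert out["baby"].tolist() == [10.0, 20.0]

    def test_single_sample_group_equals_that_portrait(self, exp_model, exp_groups, exp_cohort):
        gp = group_mean_portraits(exp_model.portraits(), exp_groups, exp_cohort.scheme)
        assert list(gp.columns) == list(exp_cohort.scheme.labels)

    def test_empty_group_rejected_with_label(self):
        portraits = _portraits(np.ones((2, 1)), ["a"])

        class S:
            labels = ("newborn", "baby")

        with pytest.raises(ValueError, match="baby"):
            group_mean_portraits(portraits, {"a": "newborn"}, S())


class TestPairwiseCorrelationMap:
    def test_diagonal_unity_and_negation_minus_one(self, rng):
        v = rng.normal(size=20)
        portraits = _portraits(np.column_stack([v, -v]), ["a", "b"])
        pcm = pairwise_correlation_map(portraits).matrix
        assert pcm.loc["a", "a"] == pytest.approx(1.0)
        assert pcm.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self, rng):
        vals = rng.normal(size=(30, 3))
        portraits = _portraits(vals, ["a", "b", "c"])
        pcm = pairwise_correlation_map(portraits).matrix
        for i, x in enumerate("abc"):
            for j, y in enumerate("abc"):
                direct = np.corrcoef(vals[:, i], vals[:, j])[0, 1]
                assert pcm.iloc[i, j] == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_portrait_reported_missing(self, rng):
        vals = np.column_stack([rng.normal(size=10), np.full(10, 2.0)])
        pcm = pairwise_correlation_map(_portraits(vals, ["a", "b"])).matrix
        assert np.isnan(pcm.loc["a", "b"]) and np.isnan(pcm.loc["b", "b"])

    def test_samples_ordered_by_age_when_requested(self, rng):
        vals = rng.normal(size=(10, 3))
        pcm = pairwise_correlation_map(
            _portraits(vals, ["a", "b", "c"]), ages={"a": 50, "b": 1, "c": 20}
        )
        assert pcm.samples == ["b", "c", "a"]

    def test_age_band_structure_on_planted_gradient(self, exp_model, exp_cohort):
        """Group-mean portrait correlations decay with age-group distance."""
        gp = group_mean_portraits(
            exp_model.portraits(),
            exp_cohort.metadata["group"].to_dict(),
            exp_cohort.scheme,
        )
        corr = np.corrcoef(gp.to_numpy().T)
        n = corr.shape[0]
        lags = {
            d: np.mean([corr[i, i + d] for i in range(n - d)]) for d in range(1, n)
        }
        # adjacent age groups are the most similar; distant ones decorrelate
        # (and partly anti-correlate through antagonistic switching)
        assert all(lags[1] > lags[d] for d in range(2, n))


class TestSimilarityNet:
    def test_threshold_above_max_yields_spanning_tree_only(self, rng):
        vals = rng.normal(size=(25, 5))
        g = similarity_net(_portraits(vals, list("abcde")), threshold=1.01)
        assert nx.is_connected(g) and g.number_of_edges() == 4

    def test_threshold_minus_one_yields_complete_graph(self, rng):
        vals = rng.normal(size=(25, 5))
        g = similarity_net(_portraits(vals, list("abcde")), threshold=-1.0)
        assert g.number_of_edges() == 10

    def test_tree_diameter_path_orders_samples_by_age(self, exp_model, exp_cohort):
        g = similarity_net(exp_model.portraits(), threshold=1.01)  # MST only
        ends = nx.periphery(g)
        path = nx.shortest_path(g, ends[0], ends[-1])
        ages = exp_cohort.metadata["age_years"]
        rho = sstats.spearmanr(range(len(path)), [ages[s] for s in path]).statistic
        assert abs(rho) >= 0.9


class TestSupportingMaps:
    def test_population_conserves_gene_count(self, exp_model, exp_cohort):
        maps = supporting_maps(exp_model)
        assert maps.population.sum() == len(exp_cohort.truth)

    def test_significance_in_unit_interval(self, exp_model):
        maps = supporting_maps(exp_model)
        p = maps.significance[np.isfinite(maps.significance)]
        assert (p > 0).all() and (p <= 1).all()

    def test_entropy_bounds(self):
        concentrated = np.zeros(100)
        assert shannon_entropy(concentrated) == 0.0
        uniform = np.repeat(np.arange(25), 4) + 0.5  # exactly one value per bin
        assert shannon_entropy(uniform, bins=25) == pytest.approx(np.log2(25))

    def test_wto_symmetric_in_unit_interval(self, exp_model, exp_group_portraits, exp_cohort):
        from agesom.spots import detect_spots

        ss = detect_spots(exp_model, exp_group_portraits, exp_cohort.scheme)
        maps = supporting_maps(exp_model, spots=ss)
        w = maps.wto.to_numpy()
        np.testing.assert_allclose(w, w.T, atol=1e-12)
        off = w[~np.eye(len(w), dtype=bool)]
        assert (off >= 0).all() and (off <= 1 + 1e-12).all()

    def test_invariant_region_has_low_variance(self, exp_model):
        maps = supporting_maps(exp_model)
        var = maps.variance.ravel()
        assert var[maps.invariant_region].mean() < np.median(var)


class TestSampleSummaryStats:
    def test_zero_column_gives_zero_mean_and_variance(self):
        x = np.random.default_rng(1).normal(size=50)
        df = pd.DataFrame({"a": np.zeros(50), "b": x, "c": -x})  # rows centered
        mat = centralize(df)
        per_sample, _ = sample_summary_stats(
            mat, {"a": "newborn", "b": "newborn", "c": "newborn"}, EXPRESSION_SCHEME
        )
        assert per_sample.loc["a", "mean"] == 0.0
        assert per_sample.loc["a", "variance"] == 0.0

    def test_doubling_values_quadruples_variance(self, small_matrix):
        groups = {s: "adult" for s in small_matrix.samples}
        base, _ = sample_summary_stats(small_matrix, groups, EXPRESSION_SCHEME)
        doubled = centralize(small_matrix.values * 2.0)
        twice, _ = sample_summary_stats(doubled, groups, EXPRESSION_SCHEME)
        np.testing.assert_allclose(
            twice["variance"], 4.0 * base["variance"], rtol=1e-12
        )

    def test_hourglass_variance_minimum_at_middle_groups(self):
        cohort = generate_cohort(hourglass_fixture_spec(seed=3))
        mat = centralize(cohort.expression)
        _, per_group = sample_summary_stats(
            mat, cohort.metadata["group"].to_dict(), cohort.scheme
        )
        var = per_group[per_group["statistic"] == "variance"].set_index("group")["median"]
        order = list(cohort.scheme.labels)
        assert var.idxmin() in {order[2], order[3]}
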