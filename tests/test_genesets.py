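"""Gene-set analysis: enrichment, GSZ, density maps, melting, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from agesom.genesets import (
    GeneSetCollection,
    coupling_classify,
    enrich_spots,
    gene_density_map,
    gsz_profile,
    melting_score,
    overrepresentation,
    read_gmt,
    write_gmt,
)
from agesom.som import SOMPortrayal


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection({"s1": ["a", "b"], "s2": ["c"]}, provenance="test")
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert dict(back.items()) == dict(coll.items())

    def test_short_lines_skipped_and_duplicates_deduplicated(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("ok\tdesc\tg1\tg2\tg1\nbad_line\tonly_two\n")
        coll = read_gmt(path)
        assert len(coll) == 1
        assert coll["ok"] == ["g1", "g2"]

    def test_empty_sets_dropped(self):
        coll = GeneSetCollection({"a": ["g"], "b": []})
        assert len(coll) == 1


class TestOverrepresentation:
    def test_matches_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:10]
        spot = universe[5:15]  # overlap 5
        ov, p = overrepresentation(gene_set, spot, universe)
        assert ov == 5
        expected = sstats.hypergeom.sf(4, 100, 10, 10)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_degenerate_full_overlap_reports_one(self):
        genes = ["a", "b", "c"]
        ov, p = overrepresentation(genes, genes, genes)
        assert ov == 3 and p == 1.0

    def test_no_overlap_tiny_set_p_near_one(self):
        universe = [f"g{i}" for i in range(50)]
        _, p = overrepresentation(universe[:2], universe[40:45], universe)
        assert p > 0.9

    def test_universe_must_cover_inputs(self):
        with pytest.raises(ValueError):
            overrepresentation(["a"], ["b"], ["a"])

    def test_bh_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        coll = GeneSetCollection(
            {f"s{k}": list(rng.choice(universe, 20, replace=False)) for k in range(5)}
        )
        spots = {
            "A": list(rng.choice(universe, 30, replace=False)),
            "B": universe[:25],
        }
        out = enrich_spots(coll, spots, universe)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()
        # BH preserves the significance ordering of the raw p-values
        ranked = out.sort_values("p")["p_adj"].to_numpy()
        assert (np.diff(ranked) >= -1e-15).all()


class TestGsz:
    def test_whole_universe_set_scores_zero(self, small_matrix):
        per_sample, _ = gsz_profile(list(small_matrix.genes), small_matrix)
        np.testing.assert_allclose(per_sample, 0.0, atol=1e-9)

    def test_matches_loop_based_reimplementation(self, small_matrix, rng):
        genes = list(rng.choice(small_matrix.genes, 12, replace=False))
        per_sample, _ = gsz_profile(genes, small_matrix)
        vals = small_matrix.values
        for s in vals.columns:
            col = vals[s]
            set_mean = np.mean([col[g] for g in genes])
            all_mean = col.mean()
            all_sd = np.sqrt(np.mean((col - all_mean) ** 2))
            expected = (set_mean - all_mean) / (all_sd / np.sqrt(len(genes)))
            assert per_sample[s] == pytest.approx(expected, abs=1e-9)

    def test_shifted_set_closed_form(self, small_matrix):
        genes = list(small_matrix.genes[:10])
        delta = 1.7
        shifted = small_matrix.values.copy()
        shifted.loc[genes, shifted.columns[0]] += delta
        from agesom.preprocess import OmicsMatrix

        mat = OmicsMatrix(values=shifted, layer="expression", centralized=False)
        per_sample, _ = gsz_profile(genes, mat)
        col = shifted[shifted.columns[0]]
        base = small_matrix.values[small_matrix.values.columns[0]]
        sd = np.sqrt(np.mean((col - col.mean()) ** 2))
        n, N = len(genes), len(shifted.index)
        # the set-vs-background mean gap grows by delta * (1 - n/N);
        # the baseline gap and the new overall sd carry through linearly
        gap = (base[genes].mean() - base.mean()) + delta * (1 - n / N)
        expected = gap * np.sqrt(n) / sd
        assert per_sample.iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_random_sets_are_standard_normal_under_permutation(self, small_matrix, rng):
        zs = []
        for _ in range(300):
            genes = list(rng.choice(small_matrix.genes, 10, replace=False))
            per_sample, _ = gsz_profile(genes, small_matrix)
            zs.append(per_sample.iloc[0])
        assert abs(np.mean(zs)) < 0.15
        assert 0.8 < np.std(zs) < 1.25

    def test_too_few_genes_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            gsz_profile(["g0"], small_matrix)


class TestGeneDensityMap:
    def test_mass_conserved_and_single_gene_peak(self, exp_model, exp_cohort):
        gene = exp_cohort.truth.index[0]
        density = gene_density_map([gene], exp_model, bandwidth=1.5)
        assert density.sum() == pytest.approx(1.0, abs=1e-6)
        node = exp_model.assignment_[gene]
        assert density.ravel().argmax() == node

    def test_two_corner_genes_make_two_maxima(self):
        model = SOMPortrayal(rows=9, cols=9, epochs=1)
        model.codebook_ = np.zeros((81, 2))
        model.sample_ids_ = ["a", "b"]
        model.gene_ids_ = ["g1", "g2"]
        model.assignment_ = pd.Series([0, 80], index=["g1", "g2"])
        density = gene_density_map(["g1", "g2"], model, bandwidth=1.0)
        assert density[0, 0] > density[0, 1] and density[8, 8] > density[8, 7]
        assert density.sum() == pytest.approx(2.0, abs=1e-6)

    def test_absent_set_rejected(self, exp_model):
        with pytest.raises(ValueError):
            gene_density_map(["nope"], exp_model)


def _fake_model(assignments, n_nodes=16, rows=4, cols=4):
    m = SOMPortrayal(rows=rows, cols=cols, epochs=1)
    m.codebook_ = np.zeros((n_nodes, 2))
    m.sample_ids_ = ["a", "b"]
    genes = list(assignments)
    m.gene_ids_ = genes
    m.assignment_ = pd.Series(assignments)
    return m


class TestMeltingScore:
    def test_identical_models_give_ratio_one(self):
        assign = {f"g{i}": i % 4 for i in range(12)}
        a = _fake_model(assign)
        h1, h2, ratio = melting_score(list(assign), a, _fake_model(assign))
        assert ratio == pytest.approx(1.0)

    def test_single_node_both_maps_ratio_one(self):
        assign = {f"g{i}": 3 for i in range(8)}
        h1, h2, ratio = melting_score(list(assign), _fake_model(assign), _fake_model(assign))
        assert h1 == 0.0 and h2 == 0.0 and ratio == 1.0

    def test_concentrated_to_scattered_ratio_exceeds_one(self):
        src = {f"g{i}": 0 if i < 6 else 1 for i in range(12)}
        dst = {f"g{i}": i for i in range(12)}
        h1, h2, ratio = melting_score(list(src), _fake_model(src), _fake_model(dst))
        assert h2 == pytest.approx(1.0)  # uniform over 12 nodes
        assert ratio > 1.0

    def test_source_only_concentrated_is_capped(self):
        src = {f"g{i}": 0 for i in range(8)}
        dst = {f"g{i}": i for i in range(8)}
        _, _, ratio = melting_score(list(src), _fake_model(src), _fake_model(dst))
        assert ratio == 100.0

    def test_small_sets_rejected(self):
        assign = {f"g{i}": 0 for i in range(4)}
        with pytest.raises(ValueError):
            melting_score(list(assign), _fake_model(assign), _fake_model(assign))

    def test_decoupled_set_melts_more_than_coupled_set(
        self, exp_model, exp_cohort, meth_model_on_exp_cohort
    ):
        truth = exp_cohort.truth
        dec = truth[truth["coupling"] == "decoupled"].index
        coup = truth[truth["coupling"] == "antagonistic"].index
        r_dec = melting_score(dec, exp_model, meth_model_on_exp_cohort)[2]
        r_coup = melting_score(coup, exp_model, meth_model_on_exp_cohort)[2]
        assert r_dec >= 1.0
        assert r_dec > r_coup

    def test_antagonistic_genes_anticorrelate_across_layers(
        self, exp_cohort, exp_matrix
    ):
        from agesom.preprocess import (
            MethylationInput,
            aggregate_promoter,
            beta_to_mratio,
            centralize,
        )

        agg, _ = aggregate_promoter(
            MethylationInput(exp_cohort.beta, exp_cohort.cpg_annotation)
        )
        m = centralize(beta_to_mratio(agg), layer="methylation_log_ratio")
        glab = exp_cohort.metadata["group"]
        genes = exp_cohort.truth[exp_cohort.truth["coupling"] == "antagonistic"].index[:100]
        rs = []
        for g in genes:
            e_means = exp_matrix.values.loc[g].groupby(glab).mean()
            m_means = m.values.loc[g].groupby(glab).mean().loc[e_means.index]
            rs.append(np.corrcoef(e_means, m_means)[0, 1])
        assert np.median(rs) <= -0.5


class TestCouplingClassify:
    def test_exact_anticorrelation_is_repressed(self):
        e = [1.0, 0.5, 0.0, -0.5, -1.0]
        call = coupling_classify(e, [-x for x in e])
        assert call.category == "repressed" and call.r == pytest.approx(-1.0)

    def test_exact_correlation_is_de_repressed(self):
        e = [1.0, 0.5, 0.0, -0.5, -1.0]
        call = coupling_classify(e, e)
        assert call.category == "de_repressed_RC" and call.r == pytest.approx(1.0)

    def test_constant_series_flagged_degenerate_decoupled(self):
        call = coupling_classify([1.0, 1.0, 1.0], [0.2, 0.5, 0.9])
        assert call.category == "decoupled" and call.degenerate

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            coupling_classify([1.0, 2.0], [1.0, 2.0])
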