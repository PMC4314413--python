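import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hubnet import signature_scoring as ss


def make_study(case, control, study_id="S1", genes=None):
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    genes = genes or [f"g{i}" for i in range(case.shape[0])]
    values = pd.DataFrame(
        np.hstack([case, control]),
        index=genes,
        columns=[f"c{i}" for i in range(case.shape[1])]
        + [f"n{i}" for i in range(control.shape[1])],
    )
    groups = ["case"] * case.shape[1] + ["control"] * control.shape[1]
    return ss.ExpressionStudy(study_id, values, groups)


class TestExpressionStudy:
    def test_rejects_single_sample_group(self):
        with pytest.raises(ValueError, match="case"):
            make_study([[1.0]], [[2.0, 3.0]])

    def test_rejects_unknown_labels(self):
        values = pd.DataFrame(np.zeros((1, 4)), index=["g"],
                              columns=list("abcd"))
        with pytest.raises(ValueError, match="group labels"):
            ss.ExpressionStudy("S1", values, ["case", "case", "tumor", "tumor"])


class TestCollapseProbes:
    def test_elementwise_max(self):
        probes = pd.DataFrame([[3, 7], [5, 4]], index=["p1", "p2"],
                              columns=["s1", "s2"])
        out = ss.collapse_probes(probes, {"p1": "geneA", "p2": "geneA"})
        assert out.loc["geneA"].tolist() == [5, 7]

    def test_one_probe_per_gene_is_identity(self):
        probes = pd.DataFrame([[1, 2], [3, 4]], index=["p1", "p2"],
                              columns=["s1", "s2"])
        out = ss.collapse_probes(probes, {"p1": "a", "p2": "b"})
        assert out.loc["a"].tolist() == [1, 2]
        assert out.loc["b"].tolist() == [3, 4]

    def test_unmapped_probes_dropped_and_multimap_duplicates(self):
        probes = pd.DataFrame([[1.0, 2.0], [9.0, 0.0]], index=["p1", "p2"],
                              columns=["s1", "s2"])
        out = ss.collapse_probes(probes, {"p1": ["a", "b"]})
        assert set(out.index) == {"a", "b"}
        assert out.loc["a"].tolist() == out.loc["b"].tolist() == [1.0, 2.0]

    def test_empty_map_rejected(self):
        probes = pd.DataFrame([[1.0]], index=["p1"], columns=["s1"])
        with pytest.raises(ValueError):
            ss.collapse_probes(probes, {})

    def test_matches_bruteforce_on_random_probes(self):
        rng = np.random.default_rng(0)
        probes = pd.DataFrame(
            rng.normal(size=(100, 6)),
            index=[f"p{i:03d}" for i in range(100)],
            columns=[f"s{i}" for i in range(6)],
        )
        mapping = {
            f"p{i:03d}": f"gene{rng.integers(40):02d}" for i in range(100)
        }
        out = ss.collapse_probes(probes, mapping)
        for gene in out.index:
            members = [p for p, g in mapping.items() if g == gene]
            expected = probes.loc[members].to_numpy().max(axis=0)
            np.testing.assert_allclose(out.loc[gene].to_numpy(), expected)


class TestCommonGenes:
    def test_intersection(self):
        s1 = make_study(np.zeros((3, 2)), np.zeros((3, 2)), "S1",
                        genes=["A", "B", "C"])
        s2 = make_study(np.zeros((3, 2)), np.zeros((3, 2)), "S2",
                        genes=["B", "C", "D"])
        s3 = make_study(np.zeros((2, 2)), np.zeros((2, 2)), "S3",
                        genes=["C", "B"])
        genes, restricted = ss.filter_common_genes([s1, s2, s3])
        assert genes == ["B", "C"]
        for study in restricted:
            assert list(study.values.index) == ["B", "C"]

    def test_identical_sets_unchanged(self):
        s1 = make_study(np.zeros((2, 2)), np.zeros((2, 2)), "S1", ["A", "B"])
        s2 = make_study(np.zeros((2, 2)), np.zeros((2, 2)), "S2", ["B", "A"])
        genes, _ = ss.filter_common_genes([s1, s2])
        assert genes == ["A", "B"]

    def test_empty_intersection_rejected(self):
        s1 = make_study(np.zeros((1, 2)), np.zeros((1, 2)), "S1", ["A"])
        s2 = make_study(np.zeros((1, 2)), np.zeros((1, 2)), "S2", ["B"])
        with pytest.raises(ValueError, match="no genes"):
            ss.filter_common_genes([s1, s2])

    def test_single_study_rejected(self):
        s1 = make_study(np.zeros((1, 2)), np.zeros((1, 2)), "S1", ["A"])
        with pytest.raises(ValueError):
            ss.filter_common_genes([s1])


class TestFoldChange:
    def test_definition(self):
        study = make_study([[6, 6]], [[4, 4]])
        assert ss.fold_change(study).iloc[0] == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        study = make_study([[5, 5, 5]], [[5, 5, 5]])
        assert ss.fold_change(study).iloc[0] == pytest.approx(0.0)

    def test_planted_effect_within_sampling_error(self, sim_bundle):
        truth = sim_bundle["truth"]
        config = sim_bundle["config"]
        bound = 3 * config.noise_sd * np.sqrt(2 / config.samples_per_group)
        for study in sim_bundle["studies"]:
            fc = ss.fold_change(study)
            for gene, sign in truth.de_genes.items():
                assert abs(fc[gene] - sign * config.effect_size) < bound


class TestPerStudyPvalue:
    def test_identical_groups_give_one(self):
        study = make_study([[5.0, 5.0]], [[5.0, 5.0]])
        assert ss.per_study_pvalue(study).iloc[0] == 1.0

    def test_clear_separation(self):
        rng = np.random.default_rng(1)
        case = 8 + rng.normal(0, 1e-6, size=(1, 4))
        control = 4 + rng.normal(0, 1e-6, size=(1, 4))
        assert ss.per_study_pvalue(make_study(case, control)).iloc[0] < 1e-6

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(2)
        study = make_study(rng.normal(size=(1000, 10)),
                           rng.normal(size=(1000, 10)))
        p = ss.per_study_pvalue(study)
        rate = float((p < 0.05).mean())
        assert 0.035 <= rate <= 0.065


class TestRankGenes:
    def test_absolute_fold_change_ordering(self):
        fc = pd.Series([5.0, 1.0, 3.0], index=["a", "b", "c"])
        assert ss.rank_genes(fc).tolist() == [1, 3, 2]

    def test_negative_values_ranked_by_magnitude(self):
        fc = pd.Series([-5.0, 1.0, 3.0], index=["a", "b", "c"])
        assert ss.rank_genes(fc).tolist() == [1, 3, 2]

    def test_tie_break_by_pvalue_then_id(self):
        fc = pd.Series([2.0, 2.0, 2.0], index=["c", "a", "b"])
        p = pd.Series([0.5, 0.5, 0.01], index=["c", "a", "b"])
        ranks = ss.rank_genes(fc, p)
        assert ranks["b"] == 1  # smallest p wins
        assert ranks["a"] == 2  # then lexicographic id
        assert ranks["c"] == 3
        assert sorted(ranks) == [1, 2, 3]

    def test_matches_argsort_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=1000)
        fc = pd.Series(values, index=[f"g{i:04d}" for i in range(1000)])
        ranks = ss.rank_genes(fc)
        order = np.argsort(-np.abs(values), kind="stable")
        expected = np.empty(1000, dtype=int)
        expected[order] = np.arange(1, 1001)
        np.testing.assert_array_equal(ranks.to_numpy(), expected)


class TestGwrs:
    def test_bottom_rank_is_zero(self):
        assert ss.gwrs(20, 20) == pytest.approx(0.0)

    def test_top_rank_value(self):
        assert ss.gwrs(1, 20109) == pytest.approx(19.818, abs=1e-3)

    def test_midpoint_value(self):
        assert ss.gwrs(10, 20) == pytest.approx(1.3863, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.gwrs(0, 10)
        with pytest.raises(ValueError):
            ss.gwrs(11, 10)

    @given(st.integers(1, 9999), st.integers(1, 9999))
    def test_monotone_decreasing_in_rank(self, r, r2):
        m = 10_000
        lo, hi = sorted((r, r2))
        if lo != hi:
            assert ss.gwrs(lo, m) > ss.gwrs(hi, m)


class TestGwgs:
    def test_identical_scores_identity(self):
        assert ss.gwgs([3.0, 3.0, 3.0], [1, 1, 1]) == pytest.approx(3.0)

    def test_degenerate_weights(self):
        assert ss.gwgs([19.8, 1.0, 2.0], [1, 0, 0]) == pytest.approx(19.8)

    def test_equal_weight_mean(self):
        s = [19.82, 10, 5, 8, 12]
        assert ss.gwgs(s, [0.2] * 5) == pytest.approx(10.964)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ss.gwgs([1.0, 2.0], [0.5, -0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ss.gwgs([1.0, 2.0], [1.0])

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            s = rng.uniform(0, 20, size=5)
            w = rng.uniform(0, 1, size=5)
            value = ss.gwgs(s, w)
            assert s.min() - 1e-12 <= value <= s.max() + 1e-12


class TestMaxP:
    def test_simple_max(self):
        assert ss.maxp_combine([0.001, 0.5, 0.02]) == 0.5

    def test_all_equal(self):
        assert ss.maxp_combine([0.3, 0.3]) == 0.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ss.maxp_combine([])

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=8))
    @settings(max_examples=200)
    def test_dominates_every_input(self, pvalues):
        combined = ss.maxp_combine(pvalues)
        assert all(combined >= p for p in pvalues)


class TestScoreTableAndSelection:
    def test_boundary_fold_change_excluded(self):
        table = pd.DataFrame(
            {"mean_log2fc": [2.0, 2.1], "maxp": [1e-5, 1e-5]},
            index=["exact", "above"],
        )
        up, down = ss.select_signatures(table)
        assert "exact" not in up | down
        assert "above" in up

    def test_degenerate_thresholds_select_everything_nonzero(self):
        table = pd.DataFrame(
            {"mean_log2fc": [0.5, -0.5, 0.0], "maxp": [0.9, 0.2, 0.3]},
            index=["a", "b", "c"],
        )
        up, down = ss.select_signatures(table, fc_threshold=0, p_threshold=1)
        assert up == {"a"} and down == {"b"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            ss.select_signatures(pd.DataFrame({"mean_log2fc": []}))

    def test_ranks_are_permutations(self, sim_bundle):
        table = ss.score_table(sim_bundle["studies"])
        m = len(table)
        for study in sim_bundle["studies"]:
            ranks = table[f"rank_{study.study_id}"]
            assert sorted(ranks) == list(range(1, m + 1))

    def test_planted_genes_selected_and_top_ranked(self, sim_bundle):
        table = ss.score_table(sim_bundle["studies"])
        truth = sim_bundle["truth"]
        up, down = ss.select_signatures(table)
        assert set(truth.de_genes) <= up | down
        top = set(table.index[: len(truth.de_genes)])
        assert top == set(truth.de_genes)

    def test_maxp_column_dominates_per_study(self, sim_bundle):
        table = ss.score_table(sim_bundle["studies"])
        p_cols = [c for c in table.columns if c.startswith("p_")]
        assert (table[p_cols].max(axis=1) <= table["maxp"] + 1e-15).all()

    def test_direction_matches_planted_sign(self, sim_bundle):
        table = ss.score_table(sim_bundle["studies"])
        for gene, sign in sim_bundle["truth"].de_genes.items():
            expected = "up" if sign > 0 else "down"
            assert table.loc[gene, "direction"] == expected


class TestRoundTrip:
    def test_expression_tsv_round_trip(self, tmp_path, sim_bundle):
        from hubnet import synthetic_data as sd

        study = sim_bundle["studies"][0]
        sd.write_expression_tsv(study, tmp_path / "v.tsv")
        sd.write_labels_tsv(study, tmp_path / "l.tsv")
        back = ss.read_expression_tsv(tmp_path / "v.tsv", tmp_path / "l.tsv",
                                      study.study_id)
        assert list(back.values.index) == list(study.values.index)
        assert list(back.groups) == list(study.groups)
        np.testing.assert_allclose(
            back.values.to_numpy(), study.values.to_numpy(), atol=1e-6
        )
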