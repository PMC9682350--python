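import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_ks
from sapor.descriptors import FeatureTable
from sapor.feature_selection import (
    KSClusterSelector,
    build_correlation_structure,
    choose_k,
    intra_cluster_mean_abs_corr,
    ks_statistic,
    rank_features,
    select_representatives,
    sequential_sweep,
    spearman_matrix,
    ward_clusters,
)
from sapor.modeling import CVSpec, ModelSpec, run_cv


class TestKSStatistic:
    def test_worked_example(self):
        # ECDFs of {1,2,3} and {2,3,4} differ by at most 1/3
        d, _ = ks_statistic([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_identical_samples(self):
        d, p = ks_statistic([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, p = ks_statistic([0, 1, 2], [10, 11, 12])
        assert d == 1.0 and p < 0.05

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.choice(np.linspace(0, 1, 9), size=rng.integers(5, 60))
            y = rng.choice(np.linspace(0, 1, 9), size=rng.integers(5, 60))
            d, _ = ks_statistic(x, y)
            assert d == pytest.approx(brute_force_ks(x, y), abs=1e-12)

    def test_missing_values_dropped(self):
        d1, _ = ks_statistic([1, 2, 3, np.nan], [2, 3, 4])
        d2, _ = ks_statistic([1, 2, 3], [2, 3, 4])
        assert d1 == d2

    def test_empty_after_dropping_raises(self):
        with pytest.raises(ValueError):
            ks_statistic([np.nan, np.nan], [1, 2])


class TestRankFeatures:
    def test_separating_feature_outranks_noise(self, tiny_table):
        r = rank_features(tiny_table)
        assert r.statistic("a") > r.statistic("d")
        assert r.best() in ("a", "b")

    def test_all_columns_present(self, tiny_table):
        r = rank_features(tiny_table)
        assert set(r.table.index) == set(tiny_table.X.columns)

    def test_degenerate_column_scored_zero_with_warning(self):
        X = pd.DataFrame({"g": [np.nan, np.nan, 1.0, 2.0], "ok": [1.0, 2.0, 3.0, 4.0]})
        t = FeatureTable(X, pd.Series([0, 0, 1, 1]))
        with pytest.warns(UserWarning, match="no observed values"):
            r = rank_features(t)
        assert r.statistic("g") == 0.0

    def test_best_breaks_ties_lexicographically(self):
        X = pd.DataFrame({"zz": [0.0, 0, 1, 1], "aa": [0.0, 0, 1, 1]})
        t = FeatureTable(X, pd.Series([0, 0, 1, 1]))
        assert rank_features(t).best() == "aa"


class TestSpearmanMatrix:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        b = a + rng.normal(0, 0.5, 40)
        X1 = pd.DataFrame({"a": a, "b": b})
        X2 = pd.DataFrame({"a": np.exp(a), "b": b**3})  # strictly increasing maps
        r1 = spearman_matrix(X1)
        r2 = spearman_matrix(X2)
        assert r1.loc["a", "b"] == pytest.approx(r2.loc["a", "b"], abs=1e-12)

    def test_perfect_monotone_pair(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [10.0, 20, 21, 100]})
        assert spearman_matrix(X).loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1]})
        assert spearman_matrix(X).loc["a", "b"] == pytest.approx(-1.0)

    def test_pairwise_complete_missing_handling(self):
        # the missing cell in 'a' is dropped only for pairs involving 'a'
        X = pd.DataFrame(
            {"a": [1.0, 2, np.nan, 4], "b": [1.0, 2, 3, 4], "c": [2.0, 4, 6, 8]}
        )
        r = spearman_matrix(X)
        assert r.loc["b", "c"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(1.0)  # computed on the 3 complete rows

    def test_undefined_pair_set_to_zero_with_warning(self):
        X = pd.DataFrame({"const": [1.0, 1, 1, 1], "v": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="undefined correlation"):
            r = spearman_matrix(X)
        assert r.loc["const", "v"] == 0.0
        assert r.loc["const", "const"] == 1.0


class TestClustering:
    def test_planted_blocks_recovered(self, small_block_table):
        table, truth = small_block_table
        structure = build_correlation_structure(table)
        labels = ward_clusters(structure, n_clusters=5)
        # features of the same planted block always share a label
        for name, lab in labels.items():
            block_members = [f for f, b in truth["block_of"].items()
                             if b == truth["block_of"][name]]
            assert (labels[block_members] == lab).all()
        assert labels.nunique() == 5

    def test_cuts_are_nested(self, small_block_table):
        table, _ = small_block_table
        structure = build_correlation_structure(table)
        fine = ward_clusters(structure, 10)
        coarse = ward_clusters(structure, 4)
        # every fine cluster lies inside exactly one coarse cluster
        for _, members in fine.groupby(fine):
            assert coarse[members.index].nunique() == 1

    def test_k_equal_n_features_all_singletons(self, tiny_table):
        structure = build_correlation_structure(tiny_table)
        labels = ward_clusters(structure, tiny_table.n_cols)
        assert labels.nunique() == tiny_table.n_cols

    def test_invalid_k_rejected(self, tiny_table):
        structure = build_correlation_structure(tiny_table)
        for bad in (0, tiny_table.n_cols + 1):
            with pytest.raises(ValueError):
                ward_clusters(structure, bad)

    def test_signed_distance_separates_anticorrelated(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=60)
        X = pd.DataFrame({"a": a, "neg": -a + rng.normal(0, 0.1, 60),
                          "z": rng.normal(size=60)})
        abs_s = build_correlation_structure(X, sign="abs")
        signed_s = build_correlation_structure(X, sign="signed")
        lab_abs = ward_clusters(abs_s, 2)
        lab_signed = ward_clusters(signed_s, 2)
        assert lab_abs["a"] == lab_abs["neg"]  # |rho| distance merges them
        assert lab_signed["a"] != lab_signed["neg"]  # signed distance keeps apart


class TestRepresentatives:
    def test_max_ks_member_per_cluster(self):
        assignment = pd.Series({"a": 1, "b": 1, "c": 2})
        ranking = rank_features(
            FeatureTable(
                pd.DataFrame({"a": [0.0, 0, 1, 1], "b": [0.0, 1, 0, 1],
                              "c": [5.0, 6, 7, 8]}),
                pd.Series([0, 0, 1, 1]),
            )
        )
        reps = select_representatives(assignment, ranking)
        assert reps == ["a", "c"]  # 'a' separates perfectly, 'b' not at all

    def test_tie_broken_lexicographically(self):
        assignment = pd.Series({"zz": 1, "aa": 1})
        ranking = rank_features(
            FeatureTable(
                pd.DataFrame({"zz": [0.0, 0, 1, 1], "aa": [0.0, 0, 1, 1]}),
                pd.Series([0, 0, 1, 1]),
            )
        )
        assert select_representatives(assignment, ranking) == ["aa"]

    def test_missing_ranking_entry_raises(self):
        assignment = pd.Series({"a": 1, "ghost": 1})
        ranking = rank_features(
            FeatureTable(pd.DataFrame({"a": [0.0, 0, 1, 1]}), pd.Series([0, 0, 1, 1]))
        )
        with pytest.raises(KeyError):
            select_representatives(assignment, ranking)


class TestIntraClusterCorr:
    def test_all_singletons_is_zero(self, tiny_table):
        structure = build_correlation_structure(tiny_table)
        assignment = ward_clusters(structure, tiny_table.n_cols)
        assert intra_cluster_mean_abs_corr(assignment, structure) == 0.0

    def test_hand_computed_example(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 4, 3],
                          "c": [9.0, 1, 5, 2]})
        structure = build_correlation_structure(X)
        assignment = pd.Series({"a": 1, "b": 1, "c": 2})
        expected = abs(structure.matrix.loc["a", "b"])  # the only intra pair
        assert intra_cluster_mean_abs_corr(assignment, structure) == pytest.approx(expected)

    def test_matches_planted_level(self, small_block_table):
        table, truth = small_block_table
        structure = build_correlation_structure(table)
        assignment = ward_clusters(structure, 5)
        got = intra_cluster_mean_abs_corr(assignment, structure)
        assert got == pytest.approx(truth["planted_within_spearman"], abs=0.05)


class TestKSClusterSelector:
    def test_fit_transform_shape_and_names(self, small_block_table):
        table, _ = small_block_table
        sel = KSClusterSelector(n_clusters=5).fit(table.X, table.y)
        out = sel.transform(table.X)
        assert out.shape == (table.n_rows, 5)
        assert list(out.columns) == sel.selected_features_

    def test_transform_before_fit_raises(self, tiny_table):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            KSClusterSelector(n_clusters=2).transform(tiny_table.X)

    def test_selection_uses_training_data_only(self, small_block_table):
        table, _ = small_block_table
        sel = KSClusterSelector(n_clusters=3).fit(table.X, table.y)
        # transforming unseen rows keeps the fitted feature set
        new = table.X.iloc[:5] * 100.0
        assert list(sel.transform(new).columns) == sel.selected_features_

    def test_k1_picks_global_ks_argmax(self, small_block_table):
        table, _ = small_block_table
        sel = KSClusterSelector(n_clusters=1).fit(table.X, table.y)
        assert sel.selected_features_ == [rank_features(table).best()]


@pytest.fixture(scope="module")
def sweep(small_block_table):
    table, _ = small_block_table
    trace = sequential_sweep(
        table,
        model=ModelSpec("gradient_boosting", {"min_child_samples": 10}),
        cv=CVSpec(k=5, repeats=1, seed=0),
        k_grid=[1, 3, 5, table.n_cols],
    )
    return table, trace


class TestSequentialSweep:
    def test_entry_sizes_match_k(self, sweep):
        _, trace = sweep
        for e in trace.entries:
            assert len(e["selected_features"]) == e["k"]

    def test_k1_is_global_ks_argmax(self, sweep):
        table, trace = sweep
        assert trace.entry(1)["selected_features"] == [rank_features(table).best()]

    def test_full_k_equals_all_features_and_full_cv(self, sweep):
        table, trace = sweep
        e = trace.entry(table.n_cols)
        assert sorted(e["selected_features"]) == sorted(table.X.columns)
        full = run_cv(
            table,
            ModelSpec("gradient_boosting", {"min_child_samples": 10}),
            CVSpec(k=5, repeats=1, seed=0),
        )
        assert e["cv_auroc"] == pytest.approx(full.per_fold["auroc"].mean())

    def test_representatives_hit_planted_blocks(self, sweep):
        table, trace = sweep
        # at k = number of planted blocks each block contributes one feature
        e = trace.entry(5)
        blocks = {f.split("_")[0] for f in e["selected_features"]}
        assert len(blocks) == 5

    def test_trace_frame_roundtrip(self, sweep, tmp_path):
        _, trace = sweep
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        df = pd.read_csv(path)
        assert list(df["k"]) == trace.ks()
        assert df.loc[0, "selected_features"] == ";".join(
            trace.entries[0]["selected_features"]
        )

    def test_invalid_k_grid_rejected(self, small_block_table):
        table, _ = small_block_table
        with pytest.raises(ValueError):
            sequential_sweep(table, k_grid=[0, 3])


class TestChooseK:
    def make_trace(self, aurocs):
        from sapor.feature_selection import SelectionTrace

        t = SelectionTrace()
        for k, a in enumerate(aurocs, start=1):
            t.add(k, [f"f{i}" for i in range(k)], a, 0.0)
        return t

    def test_fixed_k(self):
        t = self.make_trace([0.6, 0.7, 0.8])
        assert choose_k(t, strategy="fixed_k", k=2) == ["f0", "f1"]

    def test_knee_smallest_within_tolerance(self):
        t = self.make_trace([0.60, 0.79, 0.795, 0.80])
        assert len(choose_k(t, strategy="knee", tolerance=0.01)) == 2

    def test_knee_reference_is_largest_k(self):
        t = self.make_trace([0.9, 0.6, 0.7])  # non-monotone: reference is k=3
        assert len(choose_k(t, strategy="knee", tolerance=0.01)) == 1

    def test_empty_trace_raises(self):
        from sapor.feature_selection import SelectionTrace

        with pytest.raises(ValueError):
            choose_k(SelectionTrace())

    def test_unknown_strategy(self):
        t = self.make_trace([0.5])
        with pytest.raises(ValueError):
            choose_k(t, strategy="elbow")
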