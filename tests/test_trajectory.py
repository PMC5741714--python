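import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devtraj import trajectory as tj
from tests.conftest import make_de_result


def _zmat(arr, genes=None, cols=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cols = cols or [f"c{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=cols)


class TestSelection:
    def _results(self, z_rows):
        """z_rows: gene -> list of 10 z values."""
        labels = tj.canonical_comparisons()
        return {
            lab: make_de_result({g: z_rows[g][i] for g in z_rows}, comparison=lab)
            for i, lab in enumerate(labels)
        }

    def test_two_hits_selected(self):
        rows = {"a": [5.2, 5.1] + [0.0] * 8}
        assert tj.select_developmental(self._results(rows)) == ["a"]

    def test_single_hit_not_selected(self):
        rows = {"a": [9.0] + [0.0] * 9}
        assert tj.select_developmental(self._results(rows)) == []

    def test_all_zero_not_selected(self):
        rows = {"a": [0.0] * 10}
        assert tj.select_developmental(self._results(rows)) == []

    def test_direction_agnostic(self):
        rows = {"a": [5.5, -6.0] + [0.0] * 8}
        assert tj.select_developmental(self._results(rows)) == ["a"]


class TestBuildZMatrix:
    def test_five_stages_give_ten_columns(self):
        labels = tj.canonical_comparisons()
        assert len(labels) == 10
        results = {lab: make_de_result({"a": 1.0, "b": 2.0}, comparison=lab)
                   for lab in labels}
        z = tj.build_z_matrix(results, ["a", "b"])
        assert list(z.columns) == labels
        assert z.columns[0] == "E15_vs_P1" and z.columns[-1] == "P15_vs_P30"

    def test_missing_comparison_raises_with_name(self):
        labels = tj.canonical_comparisons()
        results = {lab: make_de_result({"a": 1.0}, comparison=lab)
                   for lab in labels[:-1]}
        with pytest.raises(ValueError, match="P15_vs_P30"):
            tj.build_z_matrix(results, ["a"])

    def test_absent_transcript_raises(self):
        labels = tj.canonical_comparisons()
        results = {lab: make_de_result({"a": 1.0}, comparison=lab) for lab in labels}
        results[labels[3]] = make_de_result({"b": 1.0}, comparison=labels[3])
        with pytest.raises(ValueError, match="absent"):
            tj.build_z_matrix(results, ["a"])

    def test_three_stage_toy(self):
        stages = ("E15", "P1", "P7")
        labels = tj.canonical_comparisons(stages)
        assert len(labels) == 3
        results = {lab: make_de_result({"a": 0.0}, comparison=lab) for lab in labels}
        z = tj.build_z_matrix(results, ["a"], stages=stages)
        assert z.shape == (1, 3)


class TestDiscretize:
    def test_explicit_percentile_oracle_1_to_100(self):
        # np.percentile of 1..100 at (10,30,70,90) = (10.9, 30.7, 70.3, 90.1)
        z = _zmat(np.arange(1, 101).reshape(-1, 1))
        d = tj.discretize(z)
        assert np.allclose(d.cutpoints["c0"], [10.9, 30.7, 70.3, 90.1])
        levels = d.levels["c0"]
        assert levels.loc["g4"] == -2    # value 5
        assert levels.loc["g49"] == 0    # value 50
        assert levels.loc["g94"] == 2    # value 95

    def test_level_mass_on_continuous_data(self):
        rng = np.random.default_rng(0)
        z = _zmat(rng.standard_normal((5000, 2)))
        d = tj.discretize(z)
        for col in d.levels:
            frac = d.levels[col].value_counts(normalize=True)
            expected = {-2: 0.10, -1: 0.20, 0: 0.40, 1: 0.20, 2: 0.10}
            for lv, p in expected.items():
                bound = 2.58 * np.sqrt(p * (1 - p) / 5000)
                assert abs(frac.get(lv, 0.0) - p) <= bound + 1 / 5000

    def test_constant_column_all_zero_with_warning(self):
        arr = np.column_stack([np.arange(20.0), np.full(20, 3.0)])
        with pytest.warns(RuntimeWarning, match="constant column"):
            d = tj.discretize(_zmat(arr))
        assert (d.levels["c1"] == 0).all()
        assert not (d.levels["c0"] == 0).all()

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError, match=">= 10 rows"):
            tj.discretize(_zmat(np.zeros((5, 2))))

    def test_global_mode_shares_cutpoints(self):
        rng = np.random.default_rng(1)
        z = _zmat(rng.standard_normal((200, 3)))
        d = tj.discretize(z, per_column=False)
        assert np.allclose(d.cutpoints.iloc[:, 0], d.cutpoints.iloc[:, 1])

    @given(st.sampled_from(["cubic", "exp", "arsinh"]))
    @settings(max_examples=9, deadline=None)
    def test_census_invariant_under_monotone_column_transform(self, kind):
        rng = np.random.default_rng(2)
        z = _zmat(rng.standard_normal((80, 4)))
        fn = {"cubic": lambda x: x**3, "exp": np.exp, "arsinh": np.arcsinh}[kind]
        base = tj.count_real_trajectories(tj.discretize(z), min_el=0.02)
        trans = tj.count_real_trajectories(tj.discretize(fn(z)), min_el=0.02)
        assert base.k == trans.k
        assert sorted(base.table["count"]) == sorted(trans.table["count"])


class TestTrajectoryCensus:
    def _levels(self, rows):
        return pd.DataFrame(rows, columns=["c0", "c1"])

    def test_threshold_arithmetic_at_default_min_el(self):
        rows = [(0, 0)] * 50 + [(1, 0)] * 49 + [(2, 2)] * 1
        census = tj.count_real_trajectories(self._levels(rows), min_el=0.01)
        assert census.k == 3

    def test_higher_min_el_drops_singleton(self):
        rows = [(0, 0)] * 50 + [(1, 0)] * 49 + [(2, 2)] * 1
        census = tj.count_real_trajectories(self._levels(rows), min_el=0.02)
        assert census.k == 2

    def test_all_identical_rows(self):
        census = tj.count_real_trajectories(self._levels([(1, 1)] * 30), min_el=0.01)
        assert census.k == 1

    def test_no_real_trajectory_raises(self):
        rows = [(i, i) for i in range(10)]
        with pytest.raises(ValueError, match="lower min_el"):
            tj.count_real_trajectories(self._levels(rows), min_el=0.5)

    def test_invalid_min_el(self):
        with pytest.raises(ValueError):
            tj.count_real_trajectories(self._levels([(0, 0)] * 10), min_el=1.5)

    @given(st.integers(min_value=2, max_value=20))
    @settings(max_examples=20, deadline=None)
    def test_k_bounded_by_inverse_min_el(self, denom):
        min_el = 1.0 / denom
        rng = np.random.default_rng(denom)
        rows = [tuple(rng.integers(-2, 3, size=2)) for _ in range(200)]
        try:
            census = tj.count_real_trajectories(self._levels(rows), min_el=min_el)
        except ValueError:
            return
        assert census.k <= int(np.floor(1.0 / min_el))


class TestKMeans:
    def test_duplicated_points_give_zero_wcss(self):
        pts = np.array([[0.0, 0.0], [5.0, 5.0], [-4.0, 2.0]])
        z = _zmat(np.repeat(pts, 10, axis=0))
        assign = tj.kmeans_partition(z, k=3, seed=0, n_restarts=5)
        assert assign.inertia == pytest.approx(0.0, abs=1e-9)
        assert assign.assignments.nunique() == 3
        # all duplicates co-assigned
        for i in range(3):
            block = assign.assignments.iloc[i * 10:(i + 1) * 10]
            assert block.nunique() == 1

    def test_two_blobs_recover_labels(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.2, size=(30, 4))
        b = rng.normal(6, 0.2, size=(30, 4))
        z = _zmat(np.vstack([a, b]))
        assign = tj.kmeans_partition(z, k=2, seed=1, n_restarts=10)
        left = set(assign.assignments.iloc[:30])
        right = set(assign.assignments.iloc[30:])
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_k_one_centroid_is_column_mean(self):
        rng = np.random.default_rng(1)
        z = _zmat(rng.normal(size=(25, 3)))
        assign = tj.kmeans_partition(z, k=1, seed=0, n_restarts=3)
        assert np.allclose(assign.centroids.iloc[0], z.mean(axis=0))

    def test_k_exceeding_distinct_rows_raises(self):
        z = _zmat(np.zeros((20, 2)))
        with pytest.raises(ValueError, match="distinct rows"):
            tj.kmeans_partition(z, k=2, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        z = _zmat(rng.normal(size=(60, 5)))
        a1 = tj.kmeans_partition(z, k=4, seed=9, n_restarts=8)
        a2 = tj.kmeans_partition(z, k=4, seed=9, n_restarts=8)
        assert a1.assignments.equals(a2.assignments)


class TestDirection:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((1.0, 0.8, 0.5, 0.3, 0.2), "decreasing"),
            ((1.0, 1.2, 2.0, 4.0, 6.0), "increasing"),
            ((1.0, 3.0, 3.0, 1.1, 1.0), "transient"),
        ],
    )
    def test_pattern_classes(self, profile, expected):
        assert tj.classify_direction(profile) == expected

    def test_nonpositive_profile_raises(self):
        with pytest.raises(ValueError):
            tj.classify_direction((1.0, 0.5, 0.0, 0.5, 1.0))

    def test_threshold_is_configurable(self):
        profile = (1.0, 1.0, 1.0, 1.0, 1.6)
        assert tj.classify_direction(profile, threshold=1.0) == "transient"
        assert tj.classify_direction(profile, threshold=0.5) == "increasing"


class TestPartitionTotality:
    def test_every_selected_in_exactly_one_cluster(self, bulk_de_results):
        selected = tj.select_developmental(bulk_de_results)
        z = tj.build_z_matrix(bulk_de_results, selected)
        census = tj.count_real_trajectories(tj.discretize(z))
        assign = tj.kmeans_partition(z, census.k, seed=0, n_restarts=10)
        assert sorted(assign.assignments.index) == sorted(selected)
        sizes = assign.assignments.value_counts()
        assert sizes.sum() == len(selected)
        assert set(sizes.index) == set(range(1, census.k + 1))
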