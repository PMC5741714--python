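import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devtraj import enrich
from devtraj.trajectory import ClusterAssignment


def hypergeom_oracle(N, K, n, k, tail="over"):
    """Direct PMF summation with exact integer arithmetic."""
    def pmf(i):
        return math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)

    lo, hi = max(0, n + K - N), min(n, K)
    if tail == "over":
        return sum(pmf(i) for i in range(k, hi + 1))
    return sum(pmf(i) for i in range(lo, k + 1))


def make_sets(N, K, n, k):
    universe = [f"g{i}" for i in range(N)]
    target = universe[:K]
    query = universe[:k] + universe[K:K + (n - k)]
    return query, target, universe


def make_assignment(clusters, directions=None):
    """clusters: {cluster_id: [genes]}."""
    rows = {g: c for c, genes in clusters.items() for g in genes}
    assignments = pd.Series(rows, name="cluster")
    centroids = pd.DataFrame(
        np.zeros((len(clusters), 2)), index=sorted(clusters), columns=["a", "b"]
    )
    centroids.index.name = "cluster"
    return ClusterAssignment(
        assignments=assignments, centroids=centroids, k=len(clusters),
        inertia=0.0, directions=dict(directions or {}),
    )


class TestHypergeomTest:
    def test_pmf_summation_oracle_example(self):
        query, target, universe = make_sets(100, 10, 10, 5)
        overlap, expected, fold, p = enrich.hypergeom_test(query, target, universe)
        assert overlap == 5
        assert expected == pytest.approx(1.0)
        assert fold == pytest.approx(5.0)
        assert abs(p - hypergeom_oracle(100, 10, 10, 5)) < 1e-12

    def test_query_equals_target_minimal_p(self):
        query, target, universe = make_sets(60, 8, 8, 8)
        _, _, _, p = enrich.hypergeom_test(query, target, universe)
        # the smallest achievable over-tail p for these sizes
        others = [hypergeom_oracle(60, 8, 8, k) for k in range(9)]
        assert p == pytest.approx(min(others), rel=1e-12)

    def test_overlap_at_expectation_not_enriched(self):
        # universe 100, target 50, query 10 -> expected overlap 5
        query, target, universe = make_sets(100, 50, 10, 5)
        _, expected, _, p = enrich.hypergeom_test(query, target, universe)
        assert expected == pytest.approx(5.0)
        assert p > 0.3

    def test_under_tail(self):
        query, target, universe = make_sets(100, 50, 10, 1)
        _, _, _, p = enrich.hypergeom_test(query, target, universe, tail="under")
        assert abs(p - hypergeom_oracle(100, 50, 10, 1, tail="under")) < 1e-12
        assert p < 0.05

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            enrich.hypergeom_test([], [], [])

    def test_non_subset_raises(self):
        with pytest.raises(ValueError):
            enrich.hypergeom_test(["x"], ["g0"], ["g0", "g1"])

    @given(
        N=st.integers(min_value=2, max_value=40),
        data=st.data(),
    )
    @settings(max_examples=40, deadline=None)
    def test_tails_share_boundary_mass(self, N, data):
        K = data.draw(st.integers(min_value=0, max_value=N))
        n = data.draw(st.integers(min_value=0, max_value=N))
        k_lo, k_hi = max(0, n + K - N), min(n, K)
        k = data.draw(st.integers(min_value=k_lo, max_value=k_hi))
        query, target, universe = make_sets(N, K, n, k)
        _, _, _, p_over = enrich.hypergeom_test(query, target, universe, tail="over")
        _, _, _, p_under = enrich.hypergeom_test(query, target, universe, tail="under")
        assert p_over + p_under >= 1.0 - 1e-9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(50)]
        perm = dict(zip(universe, rng.permutation(universe)))
        query = universe[:12]
        target = universe[5:20]
        base = enrich.hypergeom_test(query, target, universe)
        mapped = enrich.hypergeom_test(
            [perm[g] for g in query], [perm[g] for g in target], universe
        )
        assert base == mapped


class TestCorrect:
    def test_single_test_unchanged(self):
        assert enrich.correct([0.03], "bonferroni")[0] == pytest.approx(0.03)
        assert enrich.correct([0.03], "benjamini")[0] == pytest.approx(0.03)

    def test_bonferroni_arithmetic(self):
        out = enrich.correct([0.01, 0.02, 0.03], "bonferroni")
        assert np.allclose(out, [0.03, 0.06, 0.09])

    def test_bonferroni_capped(self):
        assert enrich.correct([0.9, 0.9], "bonferroni").max() == 1.0

    def test_bh_matches_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(size=10)
        assert np.allclose(enrich.correct(p, "benjamini"),
                           multipletests(p, method="fdr_bh")[1])

    def test_invalid_method(self):
        with pytest.raises(ValueError):
            enrich.correct([0.5], "holm")


class TestClusterMarkerEnrichment:
    def test_planted_markers_rank_their_cluster_first(self):
        universe = [f"g{i}" for i in range(300)]
        clusters = {1: universe[:100], 2: universe[100:200], 3: universe[200:]}
        assignment = make_assignment(clusters)
        markers = {"typeA": universe[:30], "typeB": universe[120:150]}
        table, top = enrich.cluster_marker_enrichment(assignment, markers, universe)
        assert top["typeA"][0] == 1
        assert top["typeB"][0] == 2

    def test_markers_outside_universe_warn(self):
        universe = [f"g{i}" for i in range(100)]
        assignment = make_assignment({1: universe[:50], 2: universe[50:]})
        markers = {"typeA": ["nope1", "nope2"]}
        with pytest.warns(RuntimeWarning, match="absent from the universe"):
            table, top = enrich.cluster_marker_enrichment(assignment, markers, universe)
        assert top["typeA"] == []
        assert (table["p"] == 1.0).all()

    def test_random_markers_not_significant(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(1000)]
        order = rng.permutation(universe)
        clusters = {c + 1: list(order[c * 100:(c + 1) * 100]) for c in range(10)}
        assignment = make_assignment(clusters)
        markers = {"rand": list(rng.choice(universe, size=50, replace=False))}
        _, top = enrich.cluster_marker_enrichment(
            assignment, markers, universe, alpha=0.01
        )
        assert top["rand"] == []


class TestInteractionMatrix:
    def _setup(self):
        universe = [f"g{i}" for i in range(400)]
        cluster = universe[:200]
        lists = {"A": set(universe[:60]), "B": set(universe[60:120])}
        non_markers = set(universe[120:])
        return universe, cluster, lists, non_markers

    def test_term_inside_one_type_enriched_there_only(self):
        universe, cluster, lists, non_markers = self._setup()
        sets = {"termA": frozenset(universe[:40])}  # subset of A and of cluster
        coll = enrich.GeneSetCollection(sets=sets, universe=frozenset(universe))
        table = enrich.go_celltype_interaction(cluster, coll, lists, non_markers)
        byg = table[table["tail"] == "over"].set_index("group")
        assert byg.loc["A", "p_corrected"] < 0.01
        assert byg.loc["B", "p_corrected"] > 0.05
        sgn = table.drop_duplicates(["term", "group"]).set_index("group")["signed_log10_q"]
        assert sgn["A"] > 0

    def test_non_marker_column_depleted(self):
        universe, cluster, lists, non_markers = self._setup()
        sets = {"termA": frozenset(universe[:40])}  # avoids non-markers entirely
        coll = enrich.GeneSetCollection(sets=sets, universe=frozenset(universe))
        table = enrich.go_celltype_interaction(cluster, coll, lists, non_markers)
        under = table[(table["group"] == "non_marker") & (table["tail"] == "under")]
        assert float(under["p_corrected"].iloc[0]) < 0.01
        sgn = table[table["group"] == "non_marker"]["signed_log10_q"].iloc[0]
        assert sgn < 0

    def test_uniform_term_no_significant_cell(self):
        universe, cluster, lists, non_markers = self._setup()
        rng = np.random.default_rng(1)
        # uniform over the cluster but still enriched in the cluster itself
        spread = frozenset(rng.choice(cluster, size=120, replace=False))
        coll = enrich.GeneSetCollection(
            sets={"spread": spread}, universe=frozenset(universe)
        )
        table = enrich.go_celltype_interaction(cluster, coll, lists, non_markers)
        marker_cells = table[table["group"].isin(["A", "B"])]
        assert (marker_cells["p_corrected"] > 0.05).all()

    def test_unenriched_terms_filtered_out(self):
        universe, cluster, lists, non_markers = self._setup()
        sets = {"outside": frozenset(universe[200:260])}  # disjoint from cluster
        coll = enrich.GeneSetCollection(sets=sets, universe=frozenset(universe))
        table = enrich.go_celltype_interaction(cluster, coll, lists, non_markers)
        assert len(table) == 0


class TestSplitByDirection:
    def test_partition_by_cluster_direction(self):
        clusters = {1: ["a", "b"], 2: ["c"], 3: ["d", "e"]}
        directions = {1: "decreasing", 2: "increasing", 3: "transient"}
        assignment = make_assignment(clusters, directions)
        annotated = {"a", "c", "d", "zzz"}
        out = enrich.split_by_direction(annotated, assignment)
        assert out["decreasing"] == {"a"}
        assert out["increasing"] == {"c"}
        assert out["transient"] == {"d"}
        total = set().union(*out.values())
        assert "zzz" not in total
        assert len(total) == sum(len(v) for v in out.values())  # disjoint

    def test_requires_directions(self):
        assignment = make_assignment({1: ["a"]})
        with pytest.raises(ValueError, match="directions"):
            enrich.split_by_direction({"a"}, assignment)
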