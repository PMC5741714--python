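"""Hypergeometric gene-set enrichment machinery.

Provides the plain hypergeometric test (over/under), Bonferroni and
Benjamini-Hochberg correction, marker-set enrichment per developmental
cluster with top-3 reporting, the term x cell-type interaction matrix with
its non-marker depletion column, and splitting of an annotated gene set by
cluster direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de import benjamini_hochberg
from .trajectory import ClusterAssignment, DIRECTIONS


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a fixed gene universe."""

    sets: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self):
        for name, genes in self.sets.items():
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(
                    f"set {name!r} has {len(extra)} genes outside the universe"
                )

    def restricted(self, genes: Collection[str]) -> "GeneSetCollection":
        """Intersect every set (and the universe) with ``genes``."""
        keep = frozenset(genes) & self.universe
        return GeneSetCollection(
            sets={n: s & keep for n, s in self.sets.items()}, universe=keep
        )


def hypergeom_test(
    query: Collection[str],
    target: Collection[str],
    universe: Collection[str],
    tail: str = "over",
) -> tuple[int, float, float, float]:
    """Hypergeometric over/under-representation test.

    Returns (overlap, expected, fold, p) where p is P(X >= overlap) for
    ``tail='over'`` and P(X <= overlap) for ``tail='under'``, with
    X ~ Hypergeom(|universe|, |target|, |query|).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    target = frozenset(target)
    if not query <= universe or not target <= universe:
        raise ValueError("query and target must be subsets of the universe")
    if tail not in ("over", "under"):
        raise ValueError(f"tail must be 'over' or 'under', got {tail!r}")
    overlap = len(query & target)
    m, n, q = len(universe), len(target), len(query)
    expected = q * n / m
    fold = overlap / expected if expected > 0 else float("nan")
    dist = stats.hypergeom(m, n, q)
    if tail == "over":
        p = float(dist.sf(overlap - 1))
    else:
        p = float(dist.cdf(overlap))
    return overlap, expected, fold, min(p, 1.0)


def correct(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing correction: Bonferroni or Benjamini-Hochberg."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method in ("benjamini", "bh"):
        return benjamini_hochberg(p)
    raise ValueError(f"unknown correction method {method!r}")


def _as_table(rows: list[dict]) -> pd.DataFrame:
    cols = ["term", "group", "overlap", "expected", "fold", "p", "p_corrected", "tail"]
    return pd.DataFrame(rows, columns=cols)


def cluster_marker_enrichment(
    assignment: ClusterAssignment,
    marker_lists: Mapping[str, Collection[str]],
    universe: Collection[str],
    top_n: int = 3,
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Over-representation of each cell type's markers in each cluster.

    Marker genes absent from the universe are dropped with a warning.  The
    corrected p-value (Bonferroni over all type x cluster tests by default)
    ranks, per cell type, the ``top_n`` most enriched clusters; types with
    no test below ``alpha`` get an empty top list.
    """
    universe = frozenset(universe)
    clusters = sorted(int(c) for c in assignment.centroids.index)
    rows = []
    for cell_type, markers in marker_lists.items():
        markers = frozenset(markers)
        inside = markers & universe
        if len(inside) < len(markers):
            warnings.warn(
                f"{len(markers) - len(inside)} markers of {cell_type!r} "
                "are absent from the universe and were dropped",
                RuntimeWarning,
                stacklevel=2,
            )
        for cid in clusters:
            members = frozenset(assignment.members(cid)) & universe
            if inside:
                overlap, expected, fold, p = hypergeom_test(
                    members, inside, universe, tail="over"
                )
            else:
                overlap, expected, fold, p = 0, 0.0, float("nan"), 1.0
            rows.append(
                {
                    "term": cell_type,
                    "group": cid,
                    "overlap": overlap,
                    "expected": expected,
                    "fold": fold,
                    "p": p,
                    "p_corrected": np.nan,
                    "tail": "over",
                }
            )
    table = _as_table(rows)
    table["p_corrected"] = correct(table["p"].to_numpy(), method=method)
    top: dict[str, list[int]] = {}
    for cell_type in marker_lists:
        sub = table[(table["term"] == cell_type) & (table["p_corrected"] < alpha)]
        ranked = sub.sort_values(["p_corrected", "p", "group"]).head(top_n)
        top[cell_type] = [int(c) for c in ranked["group"]]
    return table, top


def go_celltype_interaction(
    cluster_genes: Collection[str],
    collection: GeneSetCollection,
    marker_lists: Mapping[str, Collection[str]],
    non_markers: Collection[str],
    term_alpha: float = 0.01,
    term_method: str = "benjamini",
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Term x cell-type interaction matrix restricted to one cluster.

    Terms are first filtered to those over-represented in the cluster
    (``term_method``-corrected p < ``term_alpha`` against the collection's
    universe).  For every retained term and every marker list (plus the
    non-marker set), both over- and under-representation of term-in-cluster
    genes within the list-in-cluster genes are tested against the cluster as
    universe; corrections run over the whole matrix.  ``signed_log10_q`` is
    -log10 of the better corrected tail, positive for enrichment and
    negative for depletion.
    """
    cluster_genes = frozenset(cluster_genes) & collection.universe
    if not cluster_genes:
        raise ValueError("cluster has no genes inside the gene-set universe")

    term_rows = []
    for name, genes in collection.sets.items():
        overlap, expected, fold, p = hypergeom_test(
            cluster_genes, genes, collection.universe, tail="over"
        )
        term_rows.append((name, overlap, p))
    term_df = pd.DataFrame(term_rows, columns=["term", "overlap", "p"])
    term_df["p_corrected"] = correct(term_df["p"].to_numpy(), method=term_method)
    kept = term_df.loc[term_df["p_corrected"] < term_alpha, "term"].tolist()

    lists = {**{k: frozenset(v) for k, v in marker_lists.items()},
             "non_marker": frozenset(non_markers)}
    rows = []
    skipped = []
    for term in kept:
        term_in_cluster = collection.sets[term] & cluster_genes
        if not term_in_cluster:
            skipped.append(term)
            continue
        for list_name, genes in lists.items():
            list_in_cluster = genes & cluster_genes
            for tail in ("over", "under"):
                overlap, expected, fold, p = hypergeom_test(
                    term_in_cluster, list_in_cluster, cluster_genes, tail=tail
                )
                rows.append(
                    {
                        "term": term,
                        "group": list_name,
                        "overlap": overlap,
                        "expected": expected,
                        "fold": fold,
                        "p": p,
                        "p_corrected": np.nan,
                        "tail": tail,
                    }
                )
    if skipped:
        warnings.warn(
            f"{len(skipped)} enriched terms have no genes in the cluster "
            "and were skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    table = _as_table(rows)
    if len(table):
        for tail in ("over", "under"):
            mask = table["tail"] == tail
            table.loc[mask, "p_corrected"] = correct(
                table.loc[mask, "p"].to_numpy(), method=method
            )
        signed = []
        for (term, group), pair in table.groupby(["term", "group"], sort=False):
            po = float(pair.loc[pair["tail"] == "over", "p_corrected"].iloc[0])
            pu = float(pair.loc[pair["tail"] == "under", "p_corrected"].iloc[0])
            sign = 1.0 if po <= pu else -1.0
            q = max(min(po, pu), 1e-300)
            signed.append((term, group, sign * -np.log10(q)))
        signed_df = pd.DataFrame(signed, columns=["term", "group", "signed_log10_q"])
        table = table.merge(signed_df, on=["term", "group"], how="left")
    else:
        table["signed_log10_q"] = pd.Series(dtype=float)
    return table


def split_by_direction(
    annotated: Collection[str], assignment: ClusterAssignment
) -> dict[str, set[str]]:
    """Partition (annotated AND clustered) genes by their cluster's direction."""
    if not assignment.directions:
        raise ValueError("cluster directions have not been classified")
    annotated = frozenset(annotated)
    out: dict[str, set[str]] = {d: set() for d in DIRECTIONS}
    for direction in DIRECTIONS:
        out[direction] = set(assignment.genes_with_direction(direction)) & annotated
    return out
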