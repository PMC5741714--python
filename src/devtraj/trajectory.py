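"""Trajectory clustering of a developmental time course.

The composite algorithm works on the signed Z-scores of all pairwise
stage comparisons:

1. select developmentally regulated transcripts (|Z| above a threshold in a
   minimum number of comparisons);
2. assemble their signed Z-scores into an m x n matrix (n = stage pairs);
3. discretize every value into 5 levels delimited by the 10th/30th/70th/90th
   percentiles;
4. call each distinct discretized row a *trajectory* and count the "real"
   trajectories, those collecting at least a fraction ``min_el`` of the rows
   -- this count is the estimated number of clusters k;
5. run k-means (squared Euclidean) on the *original* Z values with that k;
6. classify every cluster's mean stage profile as decreasing, increasing or
   transient.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .de import DEResult, comparison_label

#: The five developmental stages, in temporal order.
STAGES: tuple[str, ...] = ("E15", "P1", "P7", "P15", "P30")

DIRECTIONS = ("decreasing", "increasing", "transient")


def stage_pairs(stages: Sequence[str] = STAGES) -> list[tuple[str, str]]:
    """All unordered stage pairs in canonical (temporal) order."""
    return list(itertools.combinations(stages, 2))


def canonical_comparisons(stages: Sequence[str] = STAGES) -> list[str]:
    return [comparison_label(a, b) for a, b in stage_pairs(stages)]


def select_developmental(
    de_results: Mapping[str, DEResult],
    z_threshold: float = 5.0,
    min_comparisons: int = 2,
) -> list[str]:
    """Transcripts with |Z| >= ``z_threshold`` in >= ``min_comparisons`` comparisons.

    Direction-agnostic: up- and down-regulation both count.  Returns a
    sorted list of transcript identifiers.
    """
    if not de_results:
        raise ValueError("no DE results supplied")
    zs = pd.DataFrame({label: res.table["z"] for label, res in de_results.items()})
    if zs.isna().any().any():
        raise ValueError("DE results do not share a common transcript set")
    hits = (zs.abs() >= z_threshold).sum(axis=1)
    return sorted(zs.index[hits >= min_comparisons])


def build_z_matrix(
    de_results: Mapping[str, DEResult],
    selected: Sequence[str],
    stages: Sequence[str] = STAGES,
) -> pd.DataFrame:
    """Assemble the m x n signed Z matrix (rows = selected transcripts,
    columns = stage-pair comparisons in canonical order)."""
    columns = canonical_comparisons(stages)
    missing = [c for c in columns if c not in de_results]
    if missing:
        raise ValueError(f"missing DE comparison(s): {', '.join(missing)}")
    selected = list(selected)
    data = {}
    for label in columns:
        z = de_results[label].table["z"]
        absent = [t for t in selected if t not in z.index]
        if absent:
            raise ValueError(
                f"transcript(s) absent from comparison {label}: {absent[:5]}"
            )
        data[label] = z.loc[selected]
    return pd.DataFrame(data, index=selected, columns=columns)


@dataclass(frozen=True)
class DiscretizedMatrix:
    """5-level discretization of a signed Z matrix plus the cutpoints used."""

    levels: pd.DataFrame  # values in {-2, -1, 0, +1, +2}
    cutpoints: pd.DataFrame  # rows q10, q30, q70, q90; one column per comparison
    per_column: bool


def _levels_from_cuts(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    # Half-open intervals, closed on the left at each cutpoint:
    # (-inf, q10) -> -2, [q10, q30) -> -1, [q30, q70) -> 0,
    # [q70, q90) -> +1, [q90, inf) -> +2.
    return np.searchsorted(cuts, values, side="right") - 2


def discretize(
    z: pd.DataFrame,
    percentiles: Sequence[float] = (10, 30, 70, 90),
    per_column: bool = True,
) -> DiscretizedMatrix:
    """Reduce each Z value to one of 5 levels delimited by the given percentiles.

    Percentiles use the linear-interpolation definition and are computed per
    column by default (``per_column=False`` computes a single set of
    cutpoints over the whole matrix).  A constant column is mapped entirely
    to level 0 with a warning.
    """
    if len(percentiles) != 4 or list(percentiles) != sorted(percentiles):
        raise ValueError("percentiles must be 4 increasing values")
    if z.shape[0] < 10:
        raise ValueError(f"need >= 10 rows to discretize, got {z.shape[0]}")
    x = z.to_numpy(dtype=float)
    out = np.empty_like(x, dtype=np.int8)
    if per_column:
        cuts = np.percentile(x, percentiles, axis=0, method="linear")
        for j in range(x.shape[1]):
            col = x[:, j]
            if col.max() == col.min():
                warnings.warn(
                    f"constant column {z.columns[j]!r}: all levels set to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
                out[:, j] = 0
            else:
                out[:, j] = _levels_from_cuts(col, cuts[:, j])
    else:
        flat = x.ravel()
        global_cuts = np.percentile(flat, percentiles, method="linear")
        cuts = np.tile(global_cuts[:, None], (1, x.shape[1]))
        if flat.max() == flat.min():
            warnings.warn(
                "constant matrix: all levels set to 0", RuntimeWarning, stacklevel=2
            )
            out[:] = 0
        else:
            for j in range(x.shape[1]):
                out[:, j] = _levels_from_cuts(x[:, j], global_cuts)
    levels = pd.DataFrame(out, index=z.index, columns=z.columns)
    cutpoints = pd.DataFrame(
        cuts, index=[f"q{p:g}" for p in percentiles], columns=z.columns
    )
    return DiscretizedMatrix(levels=levels, cutpoints=cutpoints, per_column=per_column)


@dataclass(frozen=True)
class TrajectoryCensus:
    """Distinct discretized trajectories with their abundances."""

    table: pd.DataFrame  # columns: trajectory (str), count, is_real
    k: int  # number of real trajectories
    min_el: float
    threshold: int  # minimal count for a real trajectory


def count_real_trajectories(
    discretized: DiscretizedMatrix | pd.DataFrame, min_el: float = 0.01
) -> TrajectoryCensus:
    """Count distinct trajectories; those collecting >= ceil(min_el * m)
    elements are "real" and their number is the estimated cluster count k."""
    if not 0 < min_el < 1:
        raise ValueError(f"min_el must be in (0, 1), got {min_el}")
    levels = discretized.levels if isinstance(discretized, DiscretizedMatrix) else discretized
    m = levels.shape[0]
    threshold = int(np.ceil(min_el * m))
    tuples = levels.apply(lambda row: ",".join(map(str, row)), axis=1)
    counts = tuples.value_counts()
    table = pd.DataFrame(
        {
            "trajectory": counts.index,
            "count": counts.to_numpy(),
            "is_real": counts.to_numpy() >= threshold,
        }
    ).reset_index(drop=True)
    k = int(table["is_real"].sum())
    if k == 0:
        raise ValueError(
            f"no trajectory collects {threshold} elements (min_el={min_el}); "
            "lower min_el"
        )
    return TrajectoryCensus(table=table, k=k, min_el=min_el, threshold=threshold)


@dataclass
class ClusterAssignment:
    """k-means partition of the selected transcripts.

    ``assignments`` maps transcript -> cluster id (1..k, largest cluster
    first); ``centroids`` holds the per-cluster mean Z vector; ``directions``
    maps cluster id -> decreasing/increasing/transient once classified.
    """

    assignments: pd.Series
    centroids: pd.DataFrame
    k: int
    inertia: float
    directions: dict[int, str] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])

    def genes_with_direction(self, direction: str) -> set[str]:
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        ids = [c for c, d in self.directions.items() if d == direction]
        return {g for c in ids for g in self.members(c)}


def kmeans_partition(
    z: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 50
) -> ClusterAssignment:
    """k-means (squared Euclidean, k-means++ init) on the original Z values.

    Best of ``n_restarts`` by within-cluster sum of squares; deterministic
    given ``seed``.  Cluster ids are 1..k ordered by decreasing size.
    """
    x = z.to_numpy(dtype=float)
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(x)
    # Relabel 1..k by decreasing size (ties broken by original label) so the
    # output is stable and the biggest pattern is always cluster 1.
    sizes = pd.Series(raw_labels).value_counts()
    order = sorted(range(k), key=lambda c: (-int(sizes.get(c, 0)), c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw_labels])
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=z.columns
    )
    centroids.index.name = "cluster"
    return ClusterAssignment(
        assignments=pd.Series(labels, index=z.index, name="cluster"),
        centroids=centroids,
        k=k,
        inertia=float(km.inertia_),
    )


def classify_direction(profile: Sequence[float], threshold: float = 1.0) -> str:
    """Classify a 5-stage mean expression profile (normalized to E15).

    decreasing if log2(P30/E15) <= -threshold, increasing if >= +threshold,
    transient otherwise.
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (len(STAGES),):
        raise ValueError(f"profile must have {len(STAGES)} values")
    if np.any(p <= 0):
        raise ValueError("profile values must be positive")
    ratio = np.log2(p[-1] / p[0])
    if ratio <= -threshold:
        return "decreasing"
    if ratio >= threshold:
        return "increasing"
    return "transient"


def cluster_stage_profiles(
    normalized_counts: pd.DataFrame,
    sample_stages: pd.Series,
    assignment: ClusterAssignment,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-cluster mean stage profile, each gene normalized to its E15 level.

    ``normalized_counts`` is the size-factor normalized bulk matrix;
    ``sample_stages`` maps sample id -> stage.  Returns a k x 5 table whose
    E15 column is 1 by construction.
    """
    stage_means = pd.DataFrame(
        {
            stage: normalized_counts[
                sample_stages.index[sample_stages == stage]
            ].mean(axis=1)
            for stage in STAGES
        }
    )
    rel = stage_means.add(pseudocount).div(
        stage_means[STAGES[0]] + pseudocount, axis=0
    )
    profiles = {}
    for cid in assignment.centroids.index:
        members = assignment.members(cid)
        profiles[cid] = rel.loc[members].mean(axis=0)
    out = pd.DataFrame(profiles).T
    out.index.name = "cluster"
    return out[list(STAGES)]


def classify_clusters(
    assignment: ClusterAssignment,
    stage_profiles: pd.DataFrame,
    threshold: float = 1.0,
) -> ClusterAssignment:
    """Fill ``assignment.directions`` from per-cluster stage profiles."""
    for cid in assignment.centroids.index:
        assignment.directions[int(cid)] = classify_direction(
            stage_profiles.loc[cid].to_numpy(), threshold=threshold
        )
    return assignment
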