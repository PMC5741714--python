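"""Differentiation-driver prediction.

A driver of cell type T is a gene that (i) belongs to T's combined marker
list (exclusive owner) and (ii) is a member of a decreasing-direction
developmental cluster.  The prediction is an exact set intersection with no
additional heuristics.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

from .de import rpkm
from .markers import MarkerCatalog
from .trajectory import STAGES, ClusterAssignment


def predict_drivers(
    catalog: MarkerCatalog, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Drivers(T) = combined markers of T intersected with decreasing clusters.

    Returns a table indexed by gene with columns ``cell_type``, ``level``,
    ``cluster`` and ``direction`` ('decreasing' for every row).  Marker
    genes absent from the clustering are logged and skipped.
    """
    if not assignment.directions:
        raise ValueError("cluster directions have not been classified")
    decreasing = assignment.genes_with_direction("decreasing")
    if not decreasing:
        warnings.warn(
            "no decreasing cluster: driver table is empty", RuntimeWarning, stacklevel=2
        )
    clustered = set(assignment.assignments.index)
    unmatched = [g for g in catalog.table.index if g not in clustered]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} marker gene(s) absent from the clustering",
            RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for cell_type, markers in sorted(catalog.combined_lists().items()):
        for gene in sorted(markers & decreasing):
            cid = int(assignment.assignments.loc[gene])
            rows.append(
                (
                    gene,
                    cell_type,
                    catalog.table.at[gene, "level"],
                    cid,
                    assignment.directions[cid],
                )
            )
    return pd.DataFrame(
        rows, columns=["gene", "cell_type", "level", "cluster", "direction"]
    ).set_index("gene")


def profile_table(
    drivers: pd.DataFrame,
    bulk_counts: pd.DataFrame,
    gene_lengths: pd.Series,
    sample_stages: pd.Series,
    sc_mean_expr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate drivers with their max-normalized 5-stage RPKM profile.

    Per driver, the per-stage RPKM means are scaled to max = 1.  Drivers
    without a gene length are flagged (``has_profile = False``) with NaN
    profile columns instead of being dropped.  When ``sc_mean_expr``
    (genes x cell types, normalized) is given, the mean expression in the
    owning type is appended.
    """
    out = drivers.copy()
    lengths = gene_lengths.reindex(drivers.index)
    missing = lengths.isna() | (lengths <= 0)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} driver(s) lack a gene length; "
            "profile omitted for them",
            RuntimeWarning,
            stacklevel=2,
        )
    usable = drivers.index[~missing]
    profile_cols = [f"rpkm_rel_{s}" for s in STAGES]
    for col in profile_cols:
        out[col] = np.nan
    out["has_profile"] = ~missing
    if len(usable):
        counts = bulk_counts.loc[:, sample_stages.index]
        expr = rpkm(counts, gene_lengths.reindex(bulk_counts.index))
        stage_means = pd.DataFrame(
            {
                s: expr.loc[usable, sample_stages.index[sample_stages == s]].mean(axis=1)
                for s in STAGES
            }
        )
        peak = stage_means.max(axis=1)
        flat = peak <= 0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} driver(s) have an all-zero RPKM profile",
                RuntimeWarning,
                stacklevel=2,
            )
            out.loc[stage_means.index[flat], "has_profile"] = False
        ok = stage_means.index[~flat]
        scaled = stage_means.loc[ok].div(peak.loc[ok], axis=0)
        for s, col in zip(STAGES, profile_cols):
            out.loc[ok, col] = scaled[s]
    if sc_mean_expr is not None:
        out["sc_mean_expr_owner"] = [
            float(sc_mean_expr.at[g, t]) if g in sc_mean_expr.index else np.nan
            for g, t in zip(out.index, out["cell_type"])
        ]
    return out


def drivers_as_gmt(drivers: pd.DataFrame) -> dict[str, set[str]]:
    """One gene set per cell type, GMT-writable."""
    return {
        str(t): set(sub.index)
        for t, sub in drivers.groupby("cell_type", sort=True)
    }
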