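"""Cell-type and subtype marker discovery from labeled single-cell data.

Subtype markers are found by pairwise-win voting: a gene is a candidate
marker of a subtype when it is significantly up-regulated against almost
all the other subtypes (all but ``allowed_losses`` of them).  Genes that
qualify for several subtypes are assigned to the one with the highest mean
normalized expression.  Type-level markers must be homogeneously expressed
across the subtypes of their type and up-regulated against every other
type.  The combined list of a type is its type-level markers plus the
subtype-level markers of its nested subtypes; everything else is the
non-marker set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .de import DEResult, nb_wald_test, umi_normalize

#: Losses tolerated in the pairwise voting (44-of-46 wins at 47 subtypes).
ALLOWED_LOSSES = 2


@dataclass(frozen=True)
class MarkerCatalog:
    """Exclusive gene -> owner assignments with their voting evidence.

    ``table`` is indexed by gene with columns ``level`` ('type' or
    'subtype'), ``owner_type``, ``owner_subtype`` (empty for type-level
    markers), ``wins`` and ``mean_expr_owner``.
    """

    table: pd.DataFrame
    subtype_to_type: dict[str, str]

    def combined_lists(self) -> dict[str, set[str]]:
        """Per-type marker lists: type markers plus nested subtype markers."""
        out: dict[str, set[str]] = {t: set() for t in sorted(set(self.subtype_to_type.values()))}
        for gene, row in self.table.iterrows():
            out[row["owner_type"]].add(gene)
        return out

    def non_markers(self, universe) -> set[str]:
        return set(universe) - set(self.table.index)


def pairwise_subtype_de(
    sc,
    size_factors: pd.Series | None = None,
    min_cells: int = 2,
) -> dict[tuple[str, str], DEResult]:
    """One NB Wald DE table per unordered subtype pair (s*(s-1)/2 tables).

    Pair keys and comparison labels put the lexicographically smaller
    subtype first; ``log2fc > 0`` means higher in the second subtype.
    Cell size factors default to library-size factors from
    :func:`devtraj.de.umi_normalize`.
    """
    subtypes = sc.subtypes
    too_small = [s for s in subtypes if len(sc.cells_of_subtype(s)) < min_cells]
    if too_small:
        raise ValueError(f"subtype(s) with < {min_cells} cells: {too_small}")
    if size_factors is None:
        _, size_factors = umi_normalize(sc.counts)
    results = {}
    for s1, s2 in itertools.combinations(subtypes, 2):
        results[(s1, s2)] = nb_wald_test(
            sc.counts,
            sc.cells_of_subtype(s1),
            sc.cells_of_subtype(s2),
            size_factors=size_factors,
            group_a=s1,
            group_b=s2,
        )
    return results


def _win_matrix(
    pairwise: Mapping[tuple[str, str], DEResult], subtypes: list[str], alpha: float
) -> dict[str, pd.DataFrame]:
    """Per-subtype boolean gene x opponent win table (significant AND up)."""
    wins = {s: {} for s in subtypes}
    for (s1, s2), res in pairwise.items():
        sig = res.table["padj"] < alpha
        up_in_b = res.table["log2fc"] > 0
        wins[s2][s1] = sig & up_in_b
        wins[s1][s2] = sig & ~up_in_b & (res.table["log2fc"] < 0)
    return {s: pd.DataFrame(w) for s, w in wins.items()}


def call_subtype_markers(
    pairwise: Mapping[tuple[str, str], DEResult],
    alpha: float = 0.05,
    allowed_losses: int = ALLOWED_LOSSES,
) -> dict[str, pd.Series]:
    """Candidate subtype markers by pairwise-win voting.

    A gene is a candidate of subtype S when it is significantly
    up-regulated (adjusted p < ``alpha``) in at least (s-1) -
    ``allowed_losses`` of S's s-1 pairwise comparisons (44 of 46 under the
    defaults at 47 subtypes).  Returns, per subtype, a Series mapping each
    candidate gene to its win count.
    """
    subtypes = sorted({s for pair in pairwise for s in pair})
    n_opponents = len(subtypes) - 1
    min_wins = max(1, n_opponents - allowed_losses)
    win_tables = _win_matrix(pairwise, subtypes, alpha)
    candidates = {}
    for s in subtypes:
        wins = win_tables[s].sum(axis=1)
        passed = wins[wins >= min_wins]
        candidates[s] = passed.astype(int)
    return candidates


def mean_subtype_expression(sc, normalized: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean library-size-normalized expression per gene per subtype."""
    if normalized is None:
        normalized, _ = umi_normalize(sc.counts)
    cols = {}
    for s in sc.subtypes:
        cells = [c for c in sc.cells_of_subtype(s) if c in normalized.columns]
        cols[s] = normalized[cells].mean(axis=1)
    return pd.DataFrame(cols)


def resolve_multiple_markers(
    candidates: Mapping[str, pd.Series], mean_expr: pd.DataFrame
) -> pd.DataFrame:
    """Assign each multi-subtype candidate to its highest-expressing subtype.

    Ties are broken by subtype label order with a warning.  Returns a table
    indexed by gene with columns ``owner_subtype``, ``wins``,
    ``mean_expr_owner``.
    """
    by_gene: dict[str, list[tuple[str, int]]] = {}
    for subtype, series in candidates.items():
        for gene, wins in series.items():
            by_gene.setdefault(gene, []).append((subtype, int(wins)))
    rows = []
    for gene, owners in sorted(by_gene.items()):
        exprs = {s: float(mean_expr.at[gene, s]) for s, _ in owners}
        best = max(exprs.values())
        top = sorted(s for s, e in exprs.items() if e == best)
        if len(top) > 1:
            warnings.warn(
                f"gene {gene!r}: tie between subtypes {top}; "
                f"assigned to {top[0]!r}",
                RuntimeWarning,
                stacklevel=2,
            )
        owner = top[0]
        wins = dict(owners)[owner]
        rows.append((gene, owner, wins, exprs[owner]))
    return pd.DataFrame(
        rows, columns=["gene", "owner_subtype", "wins", "mean_expr_owner"]
    ).set_index("gene")


def pairwise_type_de(
    sc, size_factors: pd.Series | None = None
) -> dict[tuple[str, str], DEResult]:
    """Pooled type-versus-type NB Wald comparisons (one per unordered pair)."""
    if size_factors is None:
        _, size_factors = umi_normalize(sc.counts)
    results = {}
    for t1, t2 in itertools.combinations(sc.types, 2):
        results[(t1, t2)] = nb_wald_test(
            sc.counts,
            sc.cells_of_type(t1),
            sc.cells_of_type(t2),
            size_factors=size_factors,
            group_a=t1,
            group_b=t2,
        )
    return results


def call_type_markers(
    sc,
    pairwise_sub: Mapping[tuple[str, str], DEResult],
    pairwise_type: Mapping[tuple[str, str], DEResult] | None = None,
    alpha: float = 0.05,
    size_factors: pd.Series | None = None,
    mode: str = "each",
) -> pd.DataFrame:
    """Type-level markers: within-type homogeneity plus cross-type up-regulation.

    A gene is a marker of type T iff (i) every subtype-pair comparison
    internal to T has adjusted p > ``alpha`` (vacuous for single-subtype
    types) and (ii) it is significantly up-regulated in the pooled T cells
    against every other type (``mode='each'``) or against all other cells
    pooled (``mode='rest'``).  Returns a table indexed by gene with columns
    ``owner_type``, ``wins`` (number of cross-type wins).
    """
    if mode not in ("each", "rest"):
        raise ValueError(f"mode must be 'each' or 'rest', got {mode!r}")
    if size_factors is None:
        _, size_factors = umi_normalize(sc.counts)
    types = sc.types
    by_type_subtypes = {
        t: sorted(s for s, tt in sc.subtype_to_type.items() if tt == t) for t in types
    }

    homogeneous = {}
    for t in types:
        subs = by_type_subtypes[t]
        internal = list(itertools.combinations(subs, 2))
        if not internal:
            homogeneous[t] = pd.Series(True, index=sc.counts.index)
            continue
        ok = pd.Series(True, index=sc.counts.index)
        for pair in internal:
            ok &= pairwise_sub[pair].table["padj"] > alpha
        homogeneous[t] = ok

    if mode == "each":
        if pairwise_type is None:
            pairwise_type = pairwise_type_de(sc, size_factors=size_factors)
        up_counts = {t: pd.Series(0, index=sc.counts.index) for t in types}
        for (t1, t2), res in pairwise_type.items():
            sig = res.table["padj"] < alpha
            up_counts[t2] += (sig & (res.table["log2fc"] > 0)).astype(int)
            up_counts[t1] += (sig & (res.table["log2fc"] < 0)).astype(int)
        need = len(types) - 1
        up_ok = {t: up_counts[t] >= need for t in types}
        wins = up_counts
    else:
        up_ok, wins = {}, {}
        for t in types:
            inside = sc.cells_of_type(t)
            outside = [c for c in sc.counts.columns if c not in set(inside)]
            res = nb_wald_test(
                sc.counts, outside, inside, size_factors=size_factors,
                group_a="rest", group_b=t,
            )
            ok = (res.table["padj"] < alpha) & (res.table["log2fc"] > 0)
            up_ok[t] = ok
            wins[t] = ok.astype(int)

    rows = []
    for t in types:
        hit = homogeneous[t] & up_ok[t]
        for gene in sc.counts.index[hit]:
            rows.append((gene, t, int(wins[t].loc[gene])))
    table = pd.DataFrame(rows, columns=["gene", "owner_type", "wins"])
    dup = table["gene"].duplicated(keep=False)
    if dup.any():
        # A gene passing for two types is not exclusive; drop it entirely.
        dropped = sorted(table.loc[dup, "gene"].unique())
        warnings.warn(
            f"{len(dropped)} gene(s) qualified as type markers of several "
            "types and were discarded",
            RuntimeWarning,
            stacklevel=2,
        )
        table = table[~dup]
    return table.set_index("gene")


def build_marker_catalog(
    sc,
    alpha: float = 0.05,
    allowed_losses: int = ALLOWED_LOSSES,
    type_mode: str = "each",
    pairwise_sub: Mapping[tuple[str, str], DEResult] | None = None,
) -> MarkerCatalog:
    """Full marker catalog: type-level first, then subtype-level voting.

    Genes claimed at the type level are removed from subtype candidacy so
    every gene has at most one owner.
    """
    normalized, size_factors = umi_normalize(sc.counts)
    if pairwise_sub is None:
        pairwise_sub = pairwise_subtype_de(sc, size_factors=size_factors)
    mean_expr = mean_subtype_expression(sc, normalized)
    mean_expr_type = pd.DataFrame(
        {
            t: normalized[[c for c in sc.cells_of_type(t) if c in normalized.columns]].mean(axis=1)
            for t in sc.types
        }
    )

    type_table = call_type_markers(
        sc, pairwise_sub, alpha=alpha, size_factors=size_factors, mode=type_mode
    )
    candidates = call_subtype_markers(
        pairwise_sub, alpha=alpha, allowed_losses=allowed_losses
    )
    claimed = set(type_table.index)
    candidates = {
        s: series[~series.index.isin(claimed)] for s, series in candidates.items()
    }
    sub_table = resolve_multiple_markers(candidates, mean_expr)

    rows = []
    for gene, row in type_table.iterrows():
        rows.append(
            (
                gene,
                "type",
                row["owner_type"],
                "",
                int(row["wins"]),
                float(mean_expr_type.at[gene, row["owner_type"]]),
            )
        )
    for gene, row in sub_table.iterrows():
        owner_sub = row["owner_subtype"]
        rows.append(
            (
                gene,
                "subtype",
                sc.subtype_to_type[owner_sub],
                owner_sub,
                int(row["wins"]),
                float(row["mean_expr_owner"]),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "level", "owner_type", "owner_subtype", "wins", "mean_expr_owner"],
    ).set_index("gene")
    return MarkerCatalog(table=table.sort_index(), subtype_to_type=dict(sc.subtype_to_type))


def combined_type_marker_lists(
    catalog: MarkerCatalog, universe
) -> tuple[dict[str, set[str]], set[str]]:
    """Combined per-type lists and the complementary non-marker set."""
    return catalog.combined_lists(), catalog.non_markers(universe)
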