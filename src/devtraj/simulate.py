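"""Synthetic bulk time-course, labeled single-cell UMI data and gene sets.

Every simulator returns the generated data together with a ground-truth
table, so downstream stages (selection, clustering, marker voting,
enrichment, driver prediction) can be tested for recovery of a planted
signal.  All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .trajectory import STAGES


@dataclass(frozen=True)
class TrajectoryArchetype:
    """A planted temporal pattern: 5 positive multipliers of the baseline
    mean (one per stage) and the fraction of simulated genes following it."""

    archetype_id: str
    profile: tuple[float, float, float, float, float]
    proportion: float

    def __post_init__(self):
        if len(self.profile) != len(STAGES):
            raise ValueError("profile must have one value per stage")
        if any(v <= 0 for v in self.profile):
            raise ValueError("profile values must be positive")
        if not 0 < self.proportion < 1:
            raise ValueError("proportion must be in (0, 1)")


def _ladder(*exponents: int, step: float = 20.0) -> tuple[float, ...]:
    return tuple(step**e for e in exponents)


def default_archetypes() -> list[TrajectoryArchetype]:
    """Thirteen well-separated temporal archetypes.

    Stage levels sit on a geometric ladder (factor 20 per step) so that any
    planted between-stage change is far above the selection threshold while
    equal stages stay null.  Five archetypes decrease over development, four
    increase, four are transient, mirroring the green/red/gray split of the
    reference analysis.  The proportions (20% of genes regulated in total,
    each archetype 5-10% of the regulated set) were tuned so that the
    10/30/70/90 discretization cutpoints fall well inside the saturated or
    null masses of every comparison column, making cluster-number recovery
    stable across seeds.  Pairwise, the stage-pair sign patterns of any two
    archetypes differ in at least four comparisons, so single-comparison
    discretization noise cannot collapse two planted patterns.
    """
    spec = [
        ("D1", (1, 0, 0, 1, 0), 0.0181),
        ("D2", (1, 1, 0, 2, 0), 0.0151),
        ("D3", (1, 1, 1, 1, 0), 0.0120),
        ("D4", (1, 1, 2, 2, 0), 0.0198),
        ("D5", (2, 1, 2, 0, 0), 0.0198),
        ("I1", (0, 1, 1, 0, 1), 0.0153),
        ("I2", (0, 1, 0, 0, 1), 0.0189),
        ("I3", (1, 1, 1, 0, 2), 0.0106),
        ("I4", (0, 0, 1, 2, 2), 0.0183),
        ("T1", (1, 2, 0, 0, 1), 0.0106),
        ("T2", (1, 0, 0, 2, 1), 0.0181),
        ("T3", (0, 2, 1, 0, 0), 0.0113),
        ("T4", (1, 1, 2, 0, 1), 0.0122),
    ]
    return [
        TrajectoryArchetype(name, _ladder(*exps), prop) for name, exps, prop in spec
    ]


@dataclass
class BulkData:
    """Bulk count matrix with its sample design and transcript lengths."""

    counts: pd.DataFrame  # genes x samples, integer
    samples: pd.DataFrame  # columns: sample, stage, replicate
    gene_lengths: pd.Series  # base pairs

    @property
    def stage_of(self) -> pd.Series:
        return self.samples.set_index("sample")["stage"]


def _draw_baseline(rng: np.random.Generator, n: int, law: Mapping | None) -> np.ndarray:
    law = dict(law or {"type": "lognormal", "median": 800.0, "sigma": 0.3})
    kind = law.get("type", "lognormal")
    if kind == "lognormal":
        median = float(law.get("median", 800.0))
        sigma = float(law.get("sigma", 0.3))
        return median * np.exp(rng.normal(0.0, sigma, size=n))
    if kind == "fixed":
        return np.full(n, float(law["value"]))
    raise ValueError(f"unknown baseline law {kind!r}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    # NB as gamma-Poisson keeps large means numerically safe.
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def simulate_bulk(
    archetypes: Sequence[TrajectoryArchetype] | None = None,
    n_genes: int = 10_000,
    reps_per_stage: int = 3,
    baseline_law: Mapping | None = None,
    dispersion: float = 0.002,
    seed: int = 0,
    size_factor_sigma: float = 0.2,
    length_law: Mapping | None = None,
) -> tuple[BulkData, pd.DataFrame]:
    """Simulate NB bulk counts over the 5 stages with planted archetypes.

    Each gene is assigned to an archetype (or to the flat null pattern)
    according to the archetype proportions; its per-sample mean is
    baseline * profile[stage] * size-factor jitter and counts are drawn
    NB(mean, dispersion) with variance mu + dispersion * mu^2.

    Returns the data and a truth table (gene, archetype_id, baseline,
    dispersion) where archetype_id is empty for null genes.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if reps_per_stage < 2:
        raise ValueError("reps_per_stage must be >= 2 for DE to be testable")
    total = sum(a.proportion for a in archetypes)
    if total > 1.0 + 1e-9:
        raise ValueError(
            f"archetype proportions sum to {total:.4f} > 1 (null archetype "
            "must keep a nonnegative share)"
        )
    ids = [a.archetype_id for a in archetypes]
    if len(set(ids)) != len(ids):
        raise ValueError("archetype ids must be unique")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    probs = [a.proportion for a in archetypes] + [max(0.0, 1.0 - total)]
    assign = rng.choice(len(archetypes) + 1, size=n_genes, p=np.array(probs) / sum(probs))

    baseline = _draw_baseline(rng, n_genes, baseline_law)
    profiles = np.vstack(
        [np.asarray(a.profile, dtype=float) for a in archetypes]
        + [np.ones(len(STAGES))]
    )
    gene_profiles = profiles[assign]  # n_genes x 5

    samples = []
    for stage in STAGES:
        for rep in range(1, reps_per_stage + 1):
            samples.append((f"{stage}_r{rep}", stage, rep))
    sample_df = pd.DataFrame(samples, columns=["sample", "stage", "replicate"])
    if size_factor_sigma > 0:
        jitter = np.exp(rng.normal(0.0, size_factor_sigma, size=len(samples)))
    else:
        jitter = np.ones(len(samples))

    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, (_, stage, _) in enumerate(samples):
        mu = baseline * gene_profiles[:, STAGES.index(stage)] * jitter[j]
        counts[:, j] = _nb_draw(rng, mu, dispersion)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_df["sample"])
    counts_df.index.name = "gene"
    law = dict(length_law or {"type": "lognormal", "median": 2000.0, "sigma": 0.5})
    lengths = pd.Series(
        np.maximum(200, _draw_baseline(rng, n_genes, law)).round().astype(int),
        index=genes,
        name="length",
    )
    truth = pd.DataFrame(
        {
            "archetype_id": [ids[a] if a < len(archetypes) else "" for a in assign],
            "baseline": baseline,
            "dispersion": dispersion,
        },
        index=genes,
    )
    truth.index.name = "gene"
    return BulkData(counts=counts_df, samples=sample_df, gene_lengths=lengths), truth


# ---------------------------------------------------------------------------
# single-cell simulation


#: Subtype counts per cell type used by default: 11 types, 47 subtypes.
DEFAULT_SUBTYPE_COUNTS: tuple[int, ...] = (7, 6, 6, 5, 4, 4, 4, 4, 3, 2, 2)


@dataclass
class SCSimConfig:
    """Configuration of the single-cell UMI simulator.

    ``subtype_counts`` gives the number of subtypes nested in each type; the
    defaults reproduce the 11-type / 47-subtype structure.  Each type gets
    ``n_type_markers`` planted type-level markers (elevated ``fold_change``-
    fold in every cell of the type) and each subtype ``n_subtype_markers``
    subtype-level markers (elevated only in that subtype).
    """

    n_genes: int = 1000
    subtype_counts: Sequence[int] = DEFAULT_SUBTYPE_COUNTS
    cells_per_subtype: int = 10
    n_type_markers: int = 5
    n_subtype_markers: int = 3
    fold_change: float = 8.0
    depth: float = 5000.0  # mean UMIs per cell
    depth_sigma: float = 0.3
    dispersion: float = 0.05
    base_expr_sigma: float = 1.0

    def type_names(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(len(self.subtype_counts))]

    def subtype_map(self) -> dict[str, str]:
        """subtype -> type nesting map."""
        out: dict[str, str] = {}
        for t, n_sub in zip(self.type_names(), self.subtype_counts):
            for s in range(1, n_sub + 1):
                out[f"{t}.{s}"] = t
        return out


@dataclass
class SingleCellData:
    counts: pd.DataFrame  # genes x cells, integer UMIs
    cells: pd.DataFrame  # columns: cell, type, subtype
    subtype_to_type: dict[str, str]

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.subtype_to_type)

    @property
    def types(self) -> list[str]:
        return sorted(set(self.subtype_to_type.values()))

    def cells_of_subtype(self, subtype: str) -> list[str]:
        mask = self.cells["subtype"] == subtype
        return list(self.cells.loc[mask, "cell"])

    def cells_of_type(self, cell_type: str) -> list[str]:
        mask = self.cells["type"] == cell_type
        return list(self.cells.loc[mask, "cell"])


def simulate_sc(
    config: SCSimConfig | None = None,
    seed: int = 0,
    gene_names: Sequence[str] | None = None,
) -> tuple[SingleCellData, pd.DataFrame]:
    """Simulate labeled single-cell UMI counts with planted markers.

    Counts are NB draws around lib_size * relative_expression, where the
    relative expression of a planted marker is multiplied by
    ``fold_change`` inside its owning population.  ``gene_names`` lets the
    caller reuse an existing namespace (e.g. the bulk genes) so that both
    datasets can be integrated downstream; it overrides ``config.n_genes``.
    Returns the data and a truth table (gene, role in {none, type,
    subtype}, owner, fold_change).
    """
    config = config or SCSimConfig()
    if gene_names is not None:
        gene_names = list(gene_names)
        if len(set(gene_names)) != len(gene_names):
            raise ValueError("gene_names must be unique")
        config = SCSimConfig(**{**config.__dict__, "n_genes": len(gene_names)})
    if any(n <= 0 for n in config.subtype_counts):
        raise ValueError("every type needs at least one subtype")
    if config.cells_per_subtype < 2:
        raise ValueError("need >= 2 cells per subtype")
    has_markers = config.n_type_markers > 0 or config.n_subtype_markers > 0
    if has_markers and config.fold_change <= 1.0:
        raise ValueError(
            "fold_change must be > 1 for planted markers to be recoverable"
        )
    sub_map = config.subtype_map()
    types = config.type_names()
    subtypes = sorted(sub_map)
    n_markers = config.n_type_markers * len(types) + config.n_subtype_markers * len(
        subtypes
    )
    if n_markers > config.n_genes:
        raise ValueError("more planted markers than genes")

    rng = np.random.default_rng(seed)
    if gene_names is not None:
        genes = gene_names
    else:
        genes = [f"sg{i:05d}" for i in range(config.n_genes)]

    role = np.array(["none"] * config.n_genes, dtype=object)
    owner = np.array([""] * config.n_genes, dtype=object)
    marker_genes = rng.choice(config.n_genes, size=n_markers, replace=False)
    cursor = 0
    for t in types:
        for _ in range(config.n_type_markers):
            g = marker_genes[cursor]
            role[g], owner[g] = "type", t
            cursor += 1
    for s in subtypes:
        for _ in range(config.n_subtype_markers):
            g = marker_genes[cursor]
            role[g], owner[g] = "subtype", s
            cursor += 1

    base = np.exp(rng.normal(0.0, config.base_expr_sigma, size=config.n_genes))

    cell_rows = []
    for s in subtypes:
        for i in range(1, config.cells_per_subtype + 1):
            cell_rows.append((f"{s}.c{i:03d}", sub_map[s], s))
    cells = pd.DataFrame(cell_rows, columns=["cell", "type", "subtype"])
    n_cells = len(cells)
    lib = config.depth * np.exp(rng.normal(0.0, config.depth_sigma, size=n_cells))

    # Per-subtype expression weights: base, with markers boosted in their
    # owning population; renormalized so every cell spends its depth budget.
    weights = {}
    for s in subtypes:
        w = base.copy()
        boost = (role == "type") & (owner == sub_map[s])
        boost |= (role == "subtype") & (owner == s)
        w[boost] *= config.fold_change
        weights[s] = w / w.sum()

    counts = np.empty((config.n_genes, n_cells), dtype=np.int64)
    for j, (_, _, s) in enumerate(cells.itertuples(index=False)):
        mu = lib[j] * weights[s]
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    counts_df = pd.DataFrame(counts, index=genes, columns=cells["cell"])
    counts_df.index.name = "gene"
    truth = pd.DataFrame(
        {"role": role, "owner": owner, "fold_change": config.fold_change},
        index=genes,
    )
    truth.index.name = "gene"
    return SingleCellData(counts=counts_df, cells=cells, subtype_to_type=sub_map), truth


# ---------------------------------------------------------------------------
# gene-set simulation


def simulate_genesets(
    truth_groups: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    n_terms: int = 50,
    size_law: Mapping | None = None,
    planted_overlap: float = 0.75,
    seed: int = 0,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """GMT-writable gene-set collection with controlled planted overlap.

    One term is planted per truth group: a fraction ``planted_overlap`` of
    its members is drawn from the group, the rest uniformly from the
    remaining universe.  Additional terms up to ``n_terms`` are uniform
    random draws.  Returns the collection and a truth table mapping each
    term to its source group ('' for random terms).
    """
    if not 0 <= planted_overlap <= 1:
        raise ValueError("planted_overlap must be in [0, 1]")
    universe = sorted(set(universe))
    n_universe = len(universe)
    if n_universe == 0:
        raise ValueError("empty universe")
    law = dict(size_law or {"type": "uniform", "min": 10, "max": 100})
    rng = np.random.default_rng(seed)

    def draw_size() -> int:
        if law.get("type", "uniform") == "uniform":
            size = int(rng.integers(int(law["min"]), int(law["max"]) + 1))
        elif law["type"] == "fixed":
            size = int(law["value"])
        else:
            raise ValueError(f"unknown size law {law['type']!r}")
        if size > n_universe:
            raise ValueError(f"term size {size} exceeds universe size {n_universe}")
        return size

    uni_arr = np.array(universe, dtype=object)
    sets: dict[str, frozenset] = {}
    sources = []
    for group_name, members in truth_groups.items():
        members = sorted(set(members) & set(universe))
        if not members:
            continue
        size = draw_size()
        n_in = min(len(members), int(round(planted_overlap * size)))
        inside = rng.choice(members, size=n_in, replace=False) if n_in else []
        pool = sorted(set(universe) - set(members))
        n_out = min(size - n_in, len(pool))
        outside = rng.choice(pool, size=n_out, replace=False) if n_out else []
        name = f"term_{group_name}"
        sets[name] = frozenset(inside) | frozenset(outside)
        sources.append((name, group_name))
    i = 0
    while len(sets) < n_terms:
        size = draw_size()
        name = f"term_random_{i:03d}"
        sets[name] = frozenset(rng.choice(uni_arr, size=size, replace=False))
        sources.append((name, ""))
        i += 1
    truth = pd.DataFrame(sources, columns=["term", "source_group"]).set_index("term")
    return GeneSetCollection(sets=sets, universe=frozenset(universe)), truth
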