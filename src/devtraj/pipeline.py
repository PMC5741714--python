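"""End-to-end orchestration: simulate/load -> DE -> clustering -> markers ->
enrichment -> drivers, with TSV/GMT artifacts and a reproducible manifest.

All randomness flows from a single root seed; rerunning an unchanged
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, de, drivers as drv, enrich, io, markers as mk, simulate as sim
from .trajectory import (
    STAGES,
    build_z_matrix,
    canonical_comparisons,
    classify_clusters,
    cluster_stage_profiles,
    count_real_trajectories,
    discretize,
    kmeans_partition,
    select_developmental,
    stage_pairs,
)

log = logging.getLogger("devtraj")

ALL_STAGE_NAMES = ("simulate", "de", "cluster", "markers", "enrich", "drivers")


@dataclass
class RunConfig:
    """Validated run configuration (YAML-compatible)."""

    seed: int = 0
    outdir: str = "devtraj_out"
    stages: tuple[str, ...] = ALL_STAGE_NAMES
    # thresholds
    z_threshold: float = 5.0
    min_comparisons: int = 2
    min_el: float = 0.01
    alpha: float = 0.05
    allowed_losses: int = 2
    direction_threshold: float = 1.0
    term_alpha: float = 0.01
    n_restarts: int = 50
    # simulation blocks (None -> module defaults); ignored when inputs given
    sim_bulk: dict = field(default_factory=dict)
    sim_sc: dict = field(default_factory=dict)
    sim_genesets: dict = field(default_factory=dict)
    # external inputs (paths); when set, the simulate stage is skipped
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        thresholds = raw.pop("thresholds", {}) or {}
        simblock = raw.pop("simulate", {}) or {}
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "devtraj_out")),
            stages=tuple(raw.get("stages", ALL_STAGE_NAMES)),
            sim_bulk=dict(simblock.get("bulk", {}) or {}),
            sim_sc=dict(simblock.get("sc", {}) or {}),
            sim_genesets=dict(simblock.get("genesets", {}) or {}),
            inputs=dict(raw.get("inputs", {}) or {}),
        )
        for key, value in thresholds.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown threshold {key!r}")
            setattr(cfg, key, type(getattr(cfg, key))(value))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.min_el < 1:
            raise ValueError(f"min_el must be in (0, 1), got {self.min_el}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.term_alpha < 1:
            raise ValueError(f"term_alpha must be in (0, 1), got {self.term_alpha}")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.min_comparisons < 1:
            raise ValueError("min_comparisons must be >= 1")
        if self.allowed_losses < 0:
            raise ValueError("allowed_losses must be >= 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        needs_sc = {"markers", "drivers"} & set(self.stages)
        if needs_sc and "simulate" not in self.stages:
            for key in ("sc_counts", "cell_sheet"):
                if key not in self.inputs:
                    raise ValueError(
                        f"stage 'markers' requested but input {key!r} missing"
                    )
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ValueError(f"input file for {key!r} does not exist: {path}")

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "stages": list(self.stages),
            "thresholds": {
                k: getattr(self, k)
                for k in (
                    "z_threshold",
                    "min_comparisons",
                    "min_el",
                    "alpha",
                    "allowed_losses",
                    "direction_threshold",
                    "term_alpha",
                    "n_restarts",
                )
            },
            "simulate": {
                "bulk": self.sim_bulk,
                "sc": self.sim_sc,
                "genesets": self.sim_genesets,
            },
            "inputs": self.inputs,
        }


def _load_bulk(inputs: Mapping[str, str]) -> sim.BulkData:
    counts = io.read_tsv(inputs["bulk_counts"])
    samples = io.read_tsv(inputs["sample_sheet"], index_col=None)
    lengths = None
    if "gene_lengths" in inputs:
        lengths = io.read_tsv(inputs["gene_lengths"]).iloc[:, 0]
    else:
        lengths = pd.Series(1000, index=counts.index, name="length")
    return sim.BulkData(counts=counts, samples=samples, gene_lengths=lengths)


def _load_sc(inputs: Mapping[str, str]) -> sim.SingleCellData:
    counts = io.read_tsv(inputs["sc_counts"])
    cells = io.read_tsv(inputs["cell_sheet"], index_col=None)
    sub_map = dict(
        cells.drop_duplicates("subtype")[["subtype", "type"]].itertuples(index=False)
    )
    return sim.SingleCellData(counts=counts, cells=cells, subtype_to_type=sub_map)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig | Mapping[str, Any], outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the run manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_jsonable(),
        "outputs": {},
        "warnings": [],
    }
    produced: list[Path] = []
    caught: list[str] = []

    def emit(path: Path):
        produced.append(path)

    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            state = _execute(config, out, emit)
            caught.extend(f"{w.category.__name__}: {w.message}" for w in wrec)
    except Exception as exc:  # annotate failure and keep partial outputs
        stage = getattr(exc, "stage", stage)
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise
    manifest["warnings"] = caught
    manifest["summary"] = state.get("summary", {})
    for path in produced:
        manifest["outputs"][str(path.relative_to(out))] = io.sha256_file(path)
    io.write_json_atomic(manifest, out / "manifest.json")
    return manifest


def _execute(config: RunConfig, out: Path, emit) -> dict:
    rng_seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_bulk, seed_sc, seed_sets, seed_kmeans = (
        int(s.generate_state(1)[0]) % (2**31) for s in rng_seeds
    )
    state: dict[str, Any] = {"summary": {}}
    stages = set(config.stages)

    def run_stage(name, fn):
        if name not in stages:
            return
        log.info("stage %s", name)
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    # ---- simulate ---------------------------------------------------------
    def do_simulate():
        bulk_kw = dict(config.sim_bulk)
        bulk, bulk_truth = sim.simulate_bulk(seed=bulk_kw.pop("seed", seed_bulk), **bulk_kw)
        sc_kw = dict(config.sim_sc)
        sc_seed = sc_kw.pop("seed", seed_sc)
        sc_cfg = sim.SCSimConfig(**sc_kw)
        # Share the bulk gene namespace so markers/clusters can be
        # intersected downstream (drivers stage).
        rng = np.random.default_rng(seed_sc)
        n_sc = min(sc_cfg.n_genes, bulk.counts.shape[0])
        shared = sorted(rng.choice(bulk.counts.index, size=n_sc, replace=False))
        sc, sc_truth = sim.simulate_sc(sc_cfg, seed=sc_seed, gene_names=shared)
        state.update(bulk=bulk, bulk_truth=bulk_truth, sc=sc, sc_truth=sc_truth)
        emit(io.write_tsv(bulk.counts, out / "bulk_counts.tsv"))
        emit(io.write_tsv(bulk.samples, out / "sample_sheet.tsv", index=False))
        emit(io.write_tsv(bulk.gene_lengths.to_frame(), out / "gene_lengths.tsv"))
        emit(io.write_tsv(bulk_truth, out / "bulk_truth.tsv"))
        emit(io.write_tsv(sc.counts, out / "sc_counts.tsv"))
        emit(io.write_tsv(sc.cells, out / "cell_sheet.tsv", index=False))
        emit(io.write_tsv(sc_truth, out / "sc_truth.tsv"))

        # gene sets planted on the type-level marker truth groups
        groups = {
            owner: list(g.index)
            for owner, g in sc_truth[sc_truth["role"] == "type"].groupby("owner")
        }
        sets_kw = dict(config.sim_genesets)
        collection, set_truth = sim.simulate_genesets(
            groups,
            universe=list(sc_truth.index),
            seed=sets_kw.pop("seed", seed_sets),
            **sets_kw,
        )
        state["genesets"] = collection
        emit(io.write_gmt(collection.sets, out / "genesets.gmt"))
        emit(io.write_tsv(set_truth, out / "geneset_truth.tsv"))

    run_stage("simulate", do_simulate)

    if "bulk" not in state and stages & {"de", "cluster", "enrich", "drivers"}:
        state["bulk"] = _load_bulk(config.inputs)
    if "sc" not in state and stages & {"markers", "drivers"}:
        state["sc"] = _load_sc(config.inputs)
    if "genesets" not in state and "gmt" in config.inputs:
        sets = io.read_gmt(config.inputs["gmt"])
        universe = frozenset().union(*sets.values()) if sets else frozenset()
        state["genesets"] = enrich.GeneSetCollection(sets=sets, universe=universe)

    # ---- bulk DE ----------------------------------------------------------
    def do_de():
        bulk: sim.BulkData = state["bulk"]
        stage_of = bulk.stage_of
        reps = stage_of.value_counts()
        thin = reps[reps < 2]
        if len(thin):
            raise ValueError(f"stage(s) with < 2 replicates: {list(thin.index)}")
        sf = pd.Series(
            de.estimate_size_factors(bulk.counts), index=bulk.counts.columns
        )
        results = {}
        frames = []
        for a, b in stage_pairs():
            label = de.comparison_label(a, b)
            res = de.nb_wald_test(
                bulk.counts,
                list(stage_of.index[stage_of == a]),
                list(stage_of.index[stage_of == b]),
                size_factors=sf,
                group_a=a,
                group_b=b,
            )
            results[label] = res
            frame = res.table[["log2fc", "pvalue", "padj", "z"]].copy()
            frame.insert(0, "comparison", label)
            frames.append(frame)
        state["de_results"] = results
        state["size_factors"] = sf
        emit(io.write_tsv(pd.concat(frames), out / "de_bulk.tsv"))
        state["summary"]["n_bulk_comparisons"] = len(results)

    run_stage("de", do_de)

    # ---- trajectory clustering -------------------------------------------
    def do_cluster():
        bulk: sim.BulkData = state["bulk"]
        results = state["de_results"]
        selected = select_developmental(
            results, z_threshold=config.z_threshold, min_comparisons=config.min_comparisons
        )
        zmat = build_z_matrix(results, selected)
        disc = discretize(zmat)
        census = count_real_trajectories(disc, min_el=config.min_el)
        assignment = kmeans_partition(
            zmat, census.k, seed=seed_kmeans, n_restarts=config.n_restarts
        )
        normalized = bulk.counts / state["size_factors"]
        profiles = cluster_stage_profiles(normalized, bulk.stage_of, assignment)
        classify_clusters(assignment, profiles, threshold=config.direction_threshold)
        state.update(zmat=zmat, census=census, assignment=assignment, profiles=profiles)
        state["summary"].update(
            m_selected=len(selected),
            k=census.k,
            directions={str(c): d for c, d in assignment.directions.items()},
        )
        emit(io.write_tsv(zmat.rename_axis("transcript"), out / "z_matrix.tsv"))
        emit(io.write_tsv(census.table, out / "trajectory_census.tsv", index=False))
        assign_df = assignment.assignments.to_frame("cluster_id")
        assign_df["direction"] = [
            assignment.directions[int(c)] for c in assign_df["cluster_id"]
        ]
        emit(io.write_tsv(assign_df.rename_axis("transcript"), out / "clusters.tsv"))
        emit(io.write_tsv(assignment.centroids, out / "centroids.tsv"))
        emit(io.write_tsv(profiles, out / "cluster_stage_profiles.tsv"))

    run_stage("cluster", do_cluster)

    # ---- markers ----------------------------------------------------------
    def do_markers():
        sc: sim.SingleCellData = state["sc"]
        catalog = mk.build_marker_catalog(
            sc, alpha=config.alpha, allowed_losses=config.allowed_losses
        )
        lists, non_markers = mk.combined_type_marker_lists(catalog, sc.counts.index)
        state.update(catalog=catalog, marker_lists=lists, non_markers=non_markers)
        state["summary"].update(
            n_type_markers=int((catalog.table["level"] == "type").sum()),
            n_subtype_markers=int((catalog.table["level"] == "subtype").sum()),
        )
        emit(io.write_tsv(catalog.table.rename_axis("gene"), out / "marker_catalog.tsv"))
        emit(
            io.write_gmt(
                {**{f"markers_{t}": s for t, s in lists.items()},
                 "non_markers": non_markers},
                out / "marker_lists.gmt",
            )
        )

    run_stage("markers", do_markers)

    # ---- enrichment -------------------------------------------------------
    def do_enrich():
        assignment = state["assignment"]
        # Universe: genes expressed in the bulk dataset (nonzero in >= 2
        # samples); marker genes outside it are dropped with a warning.
        universe = set(state["bulk"].counts.index[
            (state["bulk"].counts > 0).sum(axis=1) >= 2
        ])
        lists = state.get("marker_lists", {})
        table, top = enrich.cluster_marker_enrichment(
            assignment, lists, universe, alpha=config.alpha,
        )
        emit(io.write_tsv(table, out / "marker_cluster_enrichment.tsv", index=False))
        emit(
            io.write_json_atomic(
                {t: c for t, c in top.items()}, out / "top_clusters_per_type.json"
            )
        )
        if "genesets" in state:
            collection = state["genesets"]
            largest = assignment.assignments.value_counts().idxmax()
            cluster_genes = set(assignment.members(int(largest))) & collection.universe
            if cluster_genes and lists:
                interaction = enrich.go_celltype_interaction(
                    cluster_genes,
                    collection,
                    lists,
                    state.get("non_markers", set()),
                    term_alpha=config.term_alpha,
                )
                emit(io.write_tsv(interaction, out / "go_type_interaction.tsv", index=False))
        state["summary"]["top_clusters"] = {t: c for t, c in top.items()}

    run_stage("enrich", do_enrich)

    # ---- drivers ----------------------------------------------------------
    def do_drivers():
        catalog: mk.MarkerCatalog = state["catalog"]
        assignment = state["assignment"]
        table = drv.predict_drivers(catalog, assignment)
        bulk: sim.BulkData = state["bulk"]
        annotated = drv.profile_table(
            table, bulk.counts, bulk.gene_lengths, bulk.stage_of
        )
        emit(io.write_tsv(annotated.rename_axis("gene"), out / "drivers.tsv"))
        emit(io.write_gmt(drv.drivers_as_gmt(table), out / "drivers.gmt"))
        state["summary"]["n_drivers"] = int(len(table))

    run_stage("drivers", do_drivers)
    return state
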