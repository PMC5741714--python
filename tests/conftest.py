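import numpy as np
import pandas as pd
import pytest

from devtraj import de, simulate as sim
from devtraj.trajectory import stage_pairs


def make_de_result(z_by_gene, comparison="A_vs_B", group_a="A", group_b="B"):
    """Fabricate a DEResult carrying only the columns downstream code reads."""
    genes = list(z_by_gene)
    z = np.array([z_by_gene[g] for g in genes], dtype=float)
    table = pd.DataFrame(
        {
            "base_mean_a": 1.0,
            "base_mean_b": 1.0,
            "log2fc": np.sign(z),
            "pvalue": 1.0,
            "padj": 1.0,
            "z": z,
            "tested": True,
        },
        index=genes,
    )
    return de.DEResult(comparison=comparison, group_a=group_a, group_b=group_b, table=table)


@pytest.fixture(scope="session")
def small_bulk():
    """Small planted bulk simulation shared across tests (read-only)."""
    return sim.simulate_bulk(n_genes=4000, seed=11)


@pytest.fixture(scope="session")
def bulk_de_results(small_bulk):
    bulk, _ = small_bulk
    sf = pd.Series(de.estimate_size_factors(bulk.counts), index=bulk.counts.columns)
    stage_of = bulk.stage_of
    results = {}
    for a, b in stage_pairs():
        label = de.comparison_label(a, b)
        results[label] = de.nb_wald_test(
            bulk.counts,
            list(stage_of.index[stage_of == a]),
            list(stage_of.index[stage_of == b]),
            size_factors=sf,
            group_a=a,
            group_b=b,
        )
    return results


@pytest.fixture(scope="session")
def small_sc():
    """4 types x 2 subtypes, 20 cells each, fold 8 (read-only)."""
    cfg = sim.SCSimConfig(
        n_genes=400,
        subtype_counts=(2, 2, 2, 2),
        cells_per_subtype=20,
        n_type_markers=6,
        n_subtype_markers=3,
        fold_change=8.0,
    )
    return sim.simulate_sc(cfg, seed=7)
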