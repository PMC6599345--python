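"""Shared fixtures: one default synthetic study reused across test modules."""

import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", message=".*Identity link.*")

import dcfate as dc


@pytest.fixture(scope="session")
def default_cfg():
    return dc.SimConfig(seed=0)


@pytest.fixture(scope="session")
def sim(default_cfg):
    matrix, truth = dc.simulate_dataset(default_cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def filtered(sim):
    matrix, truth = sim
    report = dc.compute_cell_qc(matrix)
    return dc.filter_cells(matrix, report), truth


@pytest.fixture(scope="session")
def norm(filtered):
    matrix, truth = filtered
    factors = dc.size_factors(matrix)
    return dc.normalize_log2(matrix, factors), truth


@pytest.fixture(scope="session")
def norm_pre(norm):
    """Normalized matrix restricted to healthy precursor cells."""
    normalized, truth = norm
    pops = truth.populations.loc[normalized.cell_ids]
    pre = normalized.cell_ids[(pops == "pre-cDC").to_numpy()]
    return normalized.subset_cells(pre), truth


@pytest.fixture(scope="session")
def bulk_pipeline(default_cfg, sim):
    """Bulk DE between cDC1 and cDC2 plus target enrichment and MR selection."""
    _, truth = sim
    bulk = dc.simulate_bulk(default_cfg, n_replicates=3)
    cdc = bulk.subset_cells((bulk.cell_meta["known_type"] != "pre-cDC").to_numpy())
    bnorm = dc.normalize_log2(cdc, dc.size_factors(cdc))
    de = dc.bulk_de(bnorm, cdc.cell_meta["known_type"])
    de_genes = de.significant(fdr=0.05, fc_cut=1.0)
    db = dc.make_tf_gmt(truth, default_cfg)
    universe = list(de.table.index)
    enr = dc.tf_target_enrichment(de_genes, universe, db)
    selected = dc.select_master_regulators(de, enr, truth.mr_tfs + truth.decoy_tfs)
    return {"bulk": bulk, "norm": bnorm, "de": de, "de_genes": de_genes,
            "db": db, "enr": enr, "selected": selected, "truth": truth}


def tiny_matrix(counts, gene_ids=None, cell_ids=None, **flags):
    """Small ExpressionMatrix builder for hand-crafted examples."""
    counts = np.asarray(counts)
    g, c = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    cell_ids = cell_ids or [f"c{j}" for j in range(c)]
    gene_flags = pd.DataFrame(False, index=gene_ids,
                              columns=["is_spikein", "is_mito", "is_tf"])
    for name, genes in flags.items():
        col = name if name.startswith("is_") else f"is_{name}"
        gene_flags.loc[list(genes), col] = True
    return dc.ExpressionMatrix(counts=counts, gene_ids=np.array(gene_ids, dtype=object),
                               cell_ids=np.array(cell_ids, dtype=object),
                               gene_flags=gene_flags, cell_meta=None)
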