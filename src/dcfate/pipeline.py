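"""Composed end-to-end workflows over the module-level operations.

These helpers wire the stages together the way the full study runs them:
simulate (or load) -> QC -> normalize -> per-stage inference.  They keep
scripts and tests free of repeated glue; each step remains the module
function it wraps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import commitment, diffexpr, embed, hvg, mrtf, qc
from .simulate import SimConfig, make_tf_gmt, simulate_bulk, simulate_dataset


def prepare_study(cfg: SimConfig) -> dict:
    """Simulate, QC-filter and normalize one single-cell study."""
    matrix, truth = simulate_dataset(cfg)
    filtered = qc.filter_cells(matrix, qc.compute_cell_qc(matrix))
    norm = qc.normalize_log2(filtered, qc.size_factors(filtered))
    pops = truth.populations.loc[norm.cell_ids]
    is_pre = (pops == "pre-cDC").to_numpy()
    pre_cells = norm.cell_ids[is_pre]
    return {
        "cfg": cfg,
        "matrix": matrix,
        "truth": truth,
        "filtered": filtered,
        "norm": norm,
        "norm_pre": norm.subset_cells(pre_cells),
        "pops": pops,
        "pre_cells": pre_cells,
        "mature_labels": pops[~is_pre],
        "fates": truth.fates.loc[pre_cells],
    }


def select_mrtfs_from_bulk(cfg: SimConfig, truth, n_replicates: int = 3) -> dict:
    """Bulk cDC1-vs-cDC2 DE -> regulon enrichment -> MR-TF selection."""
    bulk = simulate_bulk(cfg, n_replicates=n_replicates)
    cdc = bulk.subset_cells((bulk.cell_meta["known_type"] != "pre-cDC").to_numpy())
    bnorm = qc.normalize_log2(cdc, qc.size_factors(cdc))
    de = diffexpr.bulk_de(bnorm, cdc.cell_meta["known_type"])
    de_genes = de.significant(fdr=0.05, fc_cut=1.0)
    db = make_tf_gmt(truth, cfg)
    enr = mrtf.tf_target_enrichment(de_genes, list(de.table.index), db)
    selected = mrtf.select_master_regulators(
        de, enr, truth.mr_tfs + truth.decoy_tfs)
    return {"bulk": bulk, "de": de, "de_genes": de_genes, "db": db,
            "enr": enr, "selected": selected}


def global_cluster_ari(norm, labels, seed: int = 0) -> float:
    """Dropout-weighted distance -> 2-D MDS -> k-means, ARI vs given labels."""
    model = embed.fit_dropout_model(norm)
    dist = embed.dropout_weighted_distance(norm, model)
    emb = embed.classical_mds(dist, k=2)
    k = len(set(labels))
    km = embed.kmeans_cluster(emb, k=k, seed=seed)
    return embed.adjusted_rand_index(km.labels, pd.Categorical(labels).codes)


def assignment_ari(study: dict, genes, seed: int = 0) -> float:
    """ARI of MR-TF (or any gene set) subpopulation assignment vs truth."""
    asn = commitment.assign_subpopulations(
        study["norm"], genes, study["pre_cells"], study["mature_labels"],
        seed=seed)
    return embed.adjusted_rand_index(
        pd.Categorical(asn.labels).codes,
        pd.Categorical(study["fates"]).codes)


def nonconstant_transcriptome(norm) -> np.ndarray:
    """Endogenous genes usable as a 'global transcriptome' feature set."""
    keep = (np.ptp(norm.values, axis=1) > 0) & ~norm.flag("is_spikein")
    return norm.gene_ids[keep]


def hvg_genes(norm_pre, fdr: float = 0.1, min_cells: int = 10) -> list:
    fit = hvg.fit_technical_noise(norm_pre)
    table = hvg.variable_gene_test(norm_pre, fit)
    return hvg.select_hvg(table, fdr=fdr, min_cells=min_cells)
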