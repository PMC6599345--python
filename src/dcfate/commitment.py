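"""Precursor fate analysis: subpopulation assignment from MR-TF expression,
the anchor-TF dose-ratio statistic, bimodality scoring, the weighted-sum
signature score, and the random-gene-set Rand-index null.

The central statistic is the per-cell log2 expression ratio of the two
anchor transcription factors (IRF8-like over IRF4-like).  The package's
combinatorial-dose analysis asks whether this ratio separates the two
precursor subpopulations better than either TF's level alone: the ratio
cancels activity shared by both factors, so a fate signal carried by the
balance of the two doses survives while each marginal level stays noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .core import NormalizedMatrix, log
from .diffexpr import rank_auc, ranksum_z
from .embed import (adjusted_rand_index, classical_mds, kmeans_cluster,
                    spearman_distance, tsne_embed)


@dataclass
class SubpopAssignment:
    """Per-precursor-cell fate labels anchored to the mature populations."""

    labels: pd.Series              # precursor cell -> "pre-1" | "pre-2"
    anchor_map: dict               # k-means cluster id -> mature type
    anchor_distances: pd.DataFrame # cluster centroid vs mature median distances
    embedding: object              # joint Embedding used


@dataclass
class RatioStat:
    """Dose-ratio statistic for one anchor pair and a two-group labeling."""

    ratios: pd.Series              # per-cell log2((a + pc) / (b + pc))
    gene_a: str
    gene_b: str
    wilcoxon_z: float
    wilcoxon_p: float
    auc_ratio: float
    auc_gene_a: float
    auc_gene_b: float
    z_gene_a: float
    p_gene_a: float
    z_gene_b: float
    p_gene_b: float


@dataclass
class NullDistribution:
    """Resampled-gene-set ARI null with an observed value and empirical p."""

    null_ari: np.ndarray
    observed_ari: float
    rounds: int
    pool_size: int
    empirical_p: float


# ---------------------------------------------------------------------------
# subpopulation assignment
# ---------------------------------------------------------------------------

def assign_subpopulations(norm: NormalizedMatrix, mr_tfs, precursor_cells,
                          mature_labels: pd.Series, seed: int = 0,
                          perplexity: float = 20.0, theta: float = 0.1,
                          restarts: int = 50) -> SubpopAssignment:
    """Split precursors into two fate groups using MR-TF expression.

    Pipeline: 1 - Spearman distance on the MR-TF expression of ALL cells
    -> 2-D t-SNE -> k-means (k=2) on the precursor cells' embedded
    coordinates.  Each precursor cluster is named after the mature type
    whose cells' median embedded coordinate lies nearest its centroid;
    the mapping must be a bijection.
    """
    mr_tfs = sorted(set(mr_tfs))
    if len(mr_tfs) < 2:
        raise ValueError("need at least 2 MR TFs")
    mature_labels = pd.Series(mature_labels)
    mature_types = sorted(pd.unique(mature_labels.dropna()))
    if len(mature_types) != 2:
        raise ValueError(f"expected 2 mature types, got {mature_types}")
    dist = spearman_distance(norm, mr_tfs)
    emb = tsne_embed(dist, perplexity=perplexity, theta=theta, seed=seed)
    cell_pos = {c: i for i, c in enumerate(norm.cell_ids)}
    pre_idx = np.array([cell_pos[c] for c in precursor_cells], dtype=int)
    pre_coords = emb.coordinates[pre_idx]
    pre_emb_labels = kmeans_cluster(
        _coords_as_embedding(pre_coords, np.asarray(precursor_cells, dtype=object)),
        k=2, seed=seed, restarts=restarts)

    centroids = np.vstack([
        pre_coords[pre_emb_labels.labels == c].mean(axis=0) for c in range(2)
    ])
    medians = {}
    for t in mature_types:
        cells_t = [c for c in mature_labels.index[mature_labels == t]
                   if c in cell_pos]
        if not cells_t:
            raise ValueError(f"no cells carry mature label {t!r}")
        medians[t] = np.median(
            emb.coordinates[[cell_pos[c] for c in cells_t]], axis=0)
    dist_table = pd.DataFrame(
        {t: np.linalg.norm(centroids - medians[t][None, :], axis=1)
         for t in mature_types},
        index=[0, 1],
    )
    # bijective anchoring: pick the cluster->type pairing with the smaller
    # total centroid-to-median distance (a greedy nearest-type rule can map
    # both clusters to the same mature type when precursors sit between the
    # two mature blobs)
    t1, t2 = mature_types
    cost_direct = dist_table.loc[0, t1] + dist_table.loc[1, t2]
    cost_swapped = dist_table.loc[0, t2] + dist_table.loc[1, t1]
    if np.isclose(cost_direct, cost_swapped):
        raise ValueError(
            "anchor mapping is ambiguous; both pairings have equal total "
            f"centroid distance (distances:\n{dist_table})")
    nearest = ({0: t1, 1: t2} if cost_direct < cost_swapped else {0: t2, 1: t1})
    greedy = {c: dist_table.loc[c].idxmin() for c in (0, 1)}
    if greedy != nearest:
        log.warning("subpopulation anchoring: nearest-type rule was not a "
                    "bijection; used optimal pairing instead")
    # pre-1 = cluster anchored to the first mature type (sorted order)
    name_of = {c: ("pre-1" if nearest[c] == mature_types[0] else "pre-2")
               for c in (0, 1)}
    labels = pd.Series([name_of[c] for c in pre_emb_labels.labels],
                       index=list(precursor_cells), name="subpopulation")
    return SubpopAssignment(labels=labels, anchor_map=nearest,
                            anchor_distances=dist_table, embedding=emb)


def _coords_as_embedding(coords: np.ndarray, ids: np.ndarray):
    from .embed import Embedding

    return Embedding(coordinates=coords, cell_ids=ids, method="t-SNE")


# ---------------------------------------------------------------------------
# dose ratio
# ---------------------------------------------------------------------------

def dose_ratio_statistic(norm: NormalizedMatrix, gene_a: str, gene_b: str,
                         group_labels: pd.Series,
                         pseudocount: float = 1.0) -> RatioStat:
    """log2 anchor dose ratio per cell plus rank-sum tests and AUCs.

    The ratio is computed on the linear normalized scale with a
    pseudocount: log2((a + pc) / (b + pc)).  Wilcoxon rank-sum compares
    the two groups for the ratio and for each gene alone; AUCs come from
    the rank statistic (first group label in sorted order = positive).
    """
    for g in (gene_a, gene_b):
        if g not in set(norm.gene_ids):
            raise ValueError(f"gene {g!r} not present in the matrix")
    group_labels = pd.Series(group_labels)
    groups = sorted(pd.unique(group_labels.dropna()))
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    cell_pos = {c: i for i, c in enumerate(norm.cell_ids)}
    idx = {g: [cell_pos[c] for c in group_labels.index[group_labels == g]
               if c in cell_pos] for g in groups}
    if min(len(v) for v in idx.values()) < 5:
        raise ValueError("each group needs at least 5 cells")
    linear = norm.linear()
    ia, ib = norm.gene_index([gene_a]), norm.gene_index([gene_b])
    a_expr = linear[ia[0]]
    b_expr = linear[ib[0]]
    ratio = np.log2((a_expr + pseudocount) / (b_expr + pseudocount))
    cells_used = idx[groups[0]] + idx[groups[1]]
    ratios = pd.Series(ratio[cells_used],
                       index=[norm.cell_ids[i] for i in cells_used],
                       name=f"log2({gene_a}/{gene_b})")
    g1, g2 = idx[groups[0]], idx[groups[1]]
    z_r, p_r = ranksum_z(ratio[g2], ratio[g1])
    z_a, p_a = ranksum_z(a_expr[g2], a_expr[g1])
    z_b, p_b = ranksum_z(b_expr[g2], b_expr[g1])
    return RatioStat(
        ratios=ratios, gene_a=gene_a, gene_b=gene_b,
        wilcoxon_z=z_r, wilcoxon_p=p_r,
        auc_ratio=rank_auc(ratio[g1], ratio[g2]),
        auc_gene_a=rank_auc(a_expr[g1], a_expr[g2]),
        auc_gene_b=rank_auc(b_expr[g1], b_expr[g2]),
        z_gene_a=z_a, p_gene_a=p_a, z_gene_b=z_b, p_gene_b=p_b,
    )


# ---------------------------------------------------------------------------
# bimodality
# ---------------------------------------------------------------------------

def bimodality_score(values, seed: int = 0,
                     min_weight: float = 0.1) -> tuple[float, int]:
    """Gaussian-mixture model comparison: (delta_BIC, modes called).

    delta_BIC = BIC(1 component) - BIC(2 components); two modes are
    called iff delta_BIC > 0 and the minor component carries >= 10% of
    the mass.  Constant input returns (NaN, 1).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 finite values")
    if np.ptp(x) == 0:
        return float("nan"), 1
    X = x[:, None]
    gm1 = GaussianMixture(n_components=1, random_state=int(seed)).fit(X)
    gm2 = GaussianMixture(n_components=2, n_init=10,
                          random_state=int(seed)).fit(X)
    delta = float(gm1.bic(X) - gm2.bic(X))
    two_modes = delta > 0 and gm2.weights_.min() >= min_weight
    return delta, 2 if two_modes else 1


# ---------------------------------------------------------------------------
# weighted-sum signature score
# ---------------------------------------------------------------------------

def weighted_sum_score(binary_expression, weights) -> np.ndarray:
    """Sum over signature genes of weight_i * x_i with x_i in {0, 1}.

    `binary_expression` is a genes x cells 0/1 DataFrame (1 iff the raw
    count is positive); `weights` a per-gene Series of bulk log2 fold
    changes (positive = cDC1-like by convention).  Returns one score per
    cell.
    """
    expr = pd.DataFrame(binary_expression)
    weights = pd.Series(weights)
    if set(expr.index) != set(weights.index):
        raise ValueError("gene lists of expression and weights differ")
    expr = expr.loc[weights.index]
    if not expr.isin([0, 1]).all().all():
        raise ValueError("binary_expression must be 0/1")
    return weights.to_numpy() @ expr.to_numpy()


def binary_detection(matrix, genes) -> pd.DataFrame:
    """0/1 detection (raw count > 0) for the given genes of an ExpressionMatrix."""
    idx = matrix.gene_index(list(genes))
    return pd.DataFrame((matrix.counts[idx] > 0).astype(int),
                        index=list(genes), columns=matrix.cell_ids)


# ---------------------------------------------------------------------------
# resampling null
# ---------------------------------------------------------------------------

def random_geneset_null(norm: NormalizedMatrix, reference_labels: pd.Series,
                        observed_genes=None, n_genes: int = 842,
                        rounds: int = 3000, mean_floor: float = 100.0,
                        seed: int = 0, restarts: int = 10) -> NullDistribution:
    """ARI null from random high-mean gene sets, with add-one empirical p.

    Each round samples `n_genes` without replacement from the endogenous
    genes whose mean normalized count exceeds `mean_floor`, computes
    1 - Spearman distances over the sampled genes for the reference
    cells, embeds with classical MDS (2-D), k-means with k = number of
    reference classes, and records the ARI against `reference_labels`.
    The observed ARI runs the same procedure on `observed_genes`.
    """
    reference_labels = pd.Series(reference_labels).dropna()
    classes = sorted(pd.unique(reference_labels))
    if len(classes) < 2:
        raise ValueError("reference labels need at least 2 classes")
    cells = [c for c in reference_labels.index if c in set(norm.cell_ids)]
    sub = norm.subset_cells(np.array(cells, dtype=object))
    ref = reference_labels.loc[cells]
    ref_codes = pd.Categorical(ref).codes

    linear = norm.linear()
    bio = ~norm.flag("is_spikein")
    pool_mask = bio & (linear.mean(axis=1) > mean_floor)
    pool = norm.gene_ids[pool_mask]
    if pool.size < n_genes:
        raise ValueError(
            f"high-mean gene pool has {pool.size} members (< {n_genes})")
    rng = np.random.default_rng(int(seed))

    def _ari_for(genes) -> float:
        dist = spearman_distance(sub, genes)
        emb = classical_mds(dist, k=2)
        labels = kmeans_cluster(emb, k=len(classes), seed=int(seed),
                                restarts=restarts)
        return adjusted_rand_index(labels.labels, ref_codes)

    null = np.empty(rounds)
    for r in range(rounds):
        genes = rng.choice(pool, size=n_genes, replace=False)
        null[r] = _ari_for(genes)
    observed = float("nan")
    emp_p = float("nan")
    if observed_genes is not None:
        observed = _ari_for(np.asarray(observed_genes, dtype=object))
        emp_p = (1.0 + np.sum(null >= observed)) / (rounds + 1.0)
    return NullDistribution(null_ari=null, observed_ari=observed,
                            rounds=rounds, pool_size=int(pool.size),
                            empirical_p=emp_p)
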