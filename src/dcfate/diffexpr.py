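"""Differential expression: bulk two-group, single-cell rank-sum, three-group
ANOVA + Tukey signatures, and Ward / 1 - Spearman gene clustering.

Bulk two-group DE is a per-gene Welch t-test on log2 normalized values;
single-cell two-group DE is a Wilcoxon rank-sum test reported as a signed
Z-score (tie-corrected normal approximation, exact enumeration when both
groups have at most 10 observations and the data are tie-free).  The
three-population signature combines a one-way ANOVA F-test (BH-adjusted)
with Tukey HSD to identify which population pairs differ and a
fold-change condition on at least one pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .core import NormalizedMatrix, bh_adjust


@dataclass
class DEResult:
    """Per-gene two-group differential-expression table.

    log2 fold change is the group2 - group1 mean difference on the log2
    scale; the statistic is a Welch t or a signed rank-sum Z depending on
    the method tag.
    """

    table: pd.DataFrame          # log2fc, statistic, p, q, mean1, mean2
    group1: str
    group2: str
    method: str                  # "bulk-t" | "sc-ranksum"

    def significant(self, fdr: float = 0.05, fc_cut: float = 1.0) -> list:
        t = self.table
        sel = t[(t["q"] < fdr) & (t["log2fc"].abs() > fc_cut)]
        return list(sel.index)

    def top_by_z(self, k: int = 20) -> list:
        """Top-k genes by |statistic|, ties broken by gene id."""
        t = self.table.assign(_absz=self.table["statistic"].abs(),
                              _gene=self.table.index.astype(str))
        t = t.sort_values(["_absz", "_gene"], ascending=[False, True])
        return list(t.index[:k])


@dataclass
class AnovaResult:
    table: pd.DataFrame          # F, p, q, per-pair tukey p and log2 diffs, selected
    groups: tuple

    def selected_genes(self) -> list:
        return list(self.table.index[self.table["selected"]])


@dataclass
class GeneClusterResult:
    assignments: pd.Series       # gene -> cluster id (1..n_clusters)
    n_clusters: int
    linkage_method: str = "ward on 1 - Spearman"


# ---------------------------------------------------------------------------
# rank-sum machinery (shared with the commitment module)
# ---------------------------------------------------------------------------

def ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum: signed Z (direction of y vs x) and two-sided p.

    Normal approximation with tie correction; exact enumeration (via the
    Mann-Whitney U null distribution) when both groups have <= 10
    observations and no ties are present.  Degenerate all-tied input
    yields Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r2 = ranks[n1:].sum()
    u2 = r2 - n2 * (n2 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    diff = u2 - mu
    # continuity correction: U is discrete on a unit lattice
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    no_ties = tie_counts.size == n
    if n1 <= 10 and n2 <= 10 and no_ties:
        res = stats.mannwhitneyu(y, x, alternative="two-sided", method="exact")
        return float(z), float(res.pvalue)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(value in `pos` > value in `neg`), ties counted half."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _group_columns(norm: NormalizedMatrix, groups: pd.Series):
    groups = pd.Series(groups)
    labels = sorted(pd.unique(groups.dropna()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {labels}")
    cells = list(norm.cell_ids)
    idx = {c: i for i, c in enumerate(cells)}
    cols = {lab: [idx[c] for c in groups.index[groups == lab] if c in idx]
            for lab in labels}
    return labels, cols


def bulk_de(bulk_norm: NormalizedMatrix, groups: pd.Series) -> DEResult:
    """Welch two-sample t-test per gene on log2 normalized values."""
    labels, cols = _group_columns(bulk_norm, groups)
    g1, g2 = labels
    if len(cols[g1]) < 2 or len(cols[g2]) < 2:
        raise ValueError("each group needs at least 2 replicates")
    a = bulk_norm.values[:, cols[g1]]
    b = bulk_norm.values[:, cols[g2]]
    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    table = pd.DataFrame(
        {
            "log2fc": mean2 - mean1,
            "statistic": t,
            "p": p,
            "q": bh_adjust(p),
            "mean1": mean1,
            "mean2": mean2,
        },
        index=bulk_norm.gene_ids,
    )
    return DEResult(table=table, group1=g1, group2=g2, method="bulk-t")


def sc_de_ranksum(norm: NormalizedMatrix, groups: pd.Series) -> DEResult:
    """Wilcoxon rank-sum per gene between two cell sets, signed Z reported."""
    labels, cols = _group_columns(norm, groups)
    g1, g2 = labels
    if len(cols[g1]) < 5 or len(cols[g2]) < 5:
        raise ValueError("each group needs at least 5 cells")
    a = norm.values[:, cols[g1]]
    b = norm.values[:, cols[g2]]
    n_genes = norm.n_genes
    z = np.empty(n_genes)
    p = np.empty(n_genes)
    for i in range(n_genes):
        z[i], p[i] = ranksum_z(a[i], b[i])
    table = pd.DataFrame(
        {
            "log2fc": b.mean(axis=1) - a.mean(axis=1),
            "statistic": z,
            "p": p,
            "q": bh_adjust(p),
            "mean1": a.mean(axis=1),
            "mean2": b.mean(axis=1),
        },
        index=norm.gene_ids,
    )
    return DEResult(table=table, group1=g1, group2=g2, method="sc-ranksum")


def anova_signature(norm: NormalizedMatrix, groups: pd.Series,
                    fc_cut: float = 1.0, fdr: float = 0.05) -> AnovaResult:
    """One-way ANOVA + Tukey HSD signature genes across three populations.

    A gene is selected iff its BH-adjusted ANOVA p < fdr and at least one
    population pair has |log2 mean difference| > fc_cut.
    """
    groups = pd.Series(groups)
    labels = sorted(pd.unique(groups.dropna()))
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 group labels, got {labels}")
    idx = {c: i for i, c in enumerate(norm.cell_ids)}
    cols = {lab: [idx[c] for c in groups.index[groups == lab] if c in idx]
            for lab in labels}
    sizes = {lab: len(cols[lab]) for lab in labels}
    if min(sizes.values()) < 3:
        raise ValueError("each population needs at least 3 cells")
    mats = [norm.values[:, cols[lab]] for lab in labels]
    N = sum(sizes.values())
    k = 3
    means = np.column_stack([m.mean(axis=1) for m in mats])
    grand = np.concatenate(mats, axis=1).mean(axis=1)
    ss_between = sum(sizes[lab] * (means[:, j] - grand) ** 2
                     for j, lab in enumerate(labels))
    ss_within = sum(((m - means[:, j][:, None]) ** 2).sum(axis=1)
                    for j, m in enumerate(mats))
    df_b, df_w = k - 1, N - k
    msw = ss_within / df_w
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / df_b) / msw
    degenerate = ~np.isfinite(F)
    p = np.where(degenerate, 1.0, stats.f.sf(np.where(degenerate, 1.0, F), df_b, df_w))
    F = np.where(degenerate, 0.0, F)
    q = bh_adjust(p)

    pairs = [(0, 1), (0, 2), (1, 2)]
    table = pd.DataFrame({"F": F, "p": p, "q": q}, index=norm.gene_ids)
    any_fc = np.zeros(norm.n_genes, dtype=bool)
    for i, j in pairs:
        li, lj = labels[i], labels[j]
        diff = means[:, j] - means[:, i]
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[li] + 1.0 / sizes[lj]))
        with np.errstate(invalid="ignore", divide="ignore"):
            qstat = np.where(se > 0, np.abs(diff) / se, 0.0)
        tp = stats.studentized_range.sf(qstat, k, df_w)
        tp = np.where(np.isfinite(tp), tp, 1.0)
        table[f"log2diff_{lj}_vs_{li}"] = diff
        table[f"tukey_p_{lj}_vs_{li}"] = np.clip(tp, 0.0, 1.0)
        any_fc |= np.abs(diff) > fc_cut
    table["selected"] = (q < fdr) & any_fc
    return AnovaResult(table=table, groups=tuple(labels))


def cluster_genes_ward(norm: NormalizedMatrix, genes,
                       n_clusters: int = 4) -> GeneClusterResult:
    """Agglomerative (Ward) clustering of genes on 1 - Spearman distance."""
    sub = norm.subset_genes(genes)
    if sub.n_genes < n_clusters:
        raise ValueError(
            f"{sub.n_genes} genes is fewer than n_clusters={n_clusters}")
    ranks = np.apply_along_axis(rankdata, 1, sub.values)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    rho = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    Z = linkage(condensed, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return GeneClusterResult(
        assignments=pd.Series(labels, index=sub.gene_ids, name="cluster"),
        n_clusters=int(np.unique(labels).size),
    )
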