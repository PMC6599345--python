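"""Dropout-aware cell-cell distances, MDS, t-SNE, k-means and Rand indices.

The dropout-weighted distance down-weights zeros that are likely
amplification failures: each cell gets a logistic detection model
P(detected | log2 pooled mean expression), and for a cell pair the
per-gene weight is v_x(g) * v_y(g) where v_c(g) = 1 for a detected gene
and 1 - P_c(detect | g) for a zero -- a zero at a magnitude where the
cell usually detects transcripts is a credible biological zero and keeps
weight, a zero where dropout is expected contributes almost nothing.
The distance is then 1 minus the weighted Pearson correlation of log2
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from .core import NormalizedMatrix, log

_PROB_CLIP = (0.01, 0.99)


@dataclass
class DropoutModel:
    """Per-cell logistic detection models.

    intercepts/slopes -- logistic coefficients per cell (slope clipped >= 0)
    covariate         -- per-gene log2 pooled mean expression (magnitude axis)
    gene_mask         -- genes with a positive pooled mean (the fitted subset)
    degenerate        -- cells whose detection vector was constant
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    covariate: np.ndarray
    gene_mask: np.ndarray
    cell_ids: np.ndarray
    degenerate: np.ndarray

    def detect_probability(self) -> np.ndarray:
        """P(detect) per (gene-in-mask, cell), clipped to (0, 1)."""
        z = self.intercepts[None, :] + self.slopes[None, :] * self.covariate[:, None]
        p = 1.0 / (1.0 + np.exp(-z))
        return np.clip(p, *_PROB_CLIP)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    cell_ids: np.ndarray
    provenance: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < 0:
            raise ValueError("distances must be nonnegative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    coordinates: np.ndarray
    cell_ids: np.ndarray
    method: str
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")
        if self.coordinates.shape[0] != len(self.cell_ids):
            raise ValueError("one coordinate row per cell required")


@dataclass
class ClusterLabels:
    labels: np.ndarray
    k: int
    cell_ids: np.ndarray
    inertia: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.min() < 0 or labels.max() >= self.k:
            raise ValueError("labels must lie in 0..k-1")
        if np.unique(labels).size != self.k:
            raise ValueError("every cluster must be nonempty")
        self.labels = labels


# ---------------------------------------------------------------------------
# dropout model and distances
# ---------------------------------------------------------------------------

def fit_dropout_model(norm: NormalizedMatrix, min_genes: int = 50) -> DropoutModel:
    """Per-cell logistic regression of detection on pooled log2 mean expression.

    The magnitude covariate is the log2 mean of normalized counts over the
    cells that detected the gene, which is robust to the dropout process
    itself (dropout removes whole observations, it does not shrink them).
    """
    if norm.n_cells < 2:
        raise ValueError("need at least 2 cells")
    linear = norm.linear()
    detected = linear > 0
    n_det = detected.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(n_det > 0, linear.sum(axis=1) / np.maximum(n_det, 1), 0.0)
    gene_mask = pooled > 0
    if gene_mask.sum() < min_genes:
        raise ValueError(
            f"insufficient genes with nonzero pooled mean "
            f"({int(gene_mask.sum())} < {min_genes})")
    x = np.log2(pooled[gene_mask])
    y_all = detected[gene_mask]
    n_cells = norm.n_cells
    intercepts = np.zeros(n_cells)
    slopes = np.zeros(n_cells)
    degenerate = np.zeros(n_cells, dtype=bool)
    X = x[:, None]
    for j in range(n_cells):
        y = y_all[:, j]
        if y.all() or not y.any():
            degenerate[j] = True
            # constant detection: clamp P(detect) at the probability bound
            intercepts[j] = np.inf if y.all() else -np.inf
            slopes[j] = 0.0
            continue
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
        clf.fit(X, y)
        b0, b1 = float(clf.intercept_[0]), float(clf.coef_[0, 0])
        if b1 < 0:
            log.warning("dropout model: negative detection slope for cell %s "
                        "clipped to 0", norm.cell_ids[j])
            b1 = 0.0
            # refit the intercept as the logit of the mean detection rate
            rate = np.clip(y.mean(), *_PROB_CLIP)
            b0 = float(np.log(rate / (1 - rate)))
        intercepts[j] = b0
        slopes[j] = b1
    if degenerate.any():
        log.info("dropout model: %d degenerate cell(s), probabilities clamped",
                 int(degenerate.sum()))
    return DropoutModel(intercepts=intercepts, slopes=slopes, covariate=x,
                        gene_mask=gene_mask, cell_ids=norm.cell_ids.copy(),
                        degenerate=degenerate)


def dropout_weighted_distance(norm: NormalizedMatrix,
                              model: DropoutModel) -> DistanceMatrix:
    """1 - detection-probability-weighted Pearson correlation per cell pair."""
    if not np.array_equal(model.cell_ids, norm.cell_ids):
        raise ValueError("dropout model was fitted on different cells")
    values = norm.values[model.gene_mask]
    detected = values > 0
    p = model.detect_probability()
    # v_c(g): detected -> 1, zero -> 1 - P_c(detect | magnitude of g)
    v = np.where(detected, 1.0, 1.0 - p)
    n = norm.n_cells
    dist = np.zeros((n, n))
    for i in range(n):
        w = v[:, i, None] * v[:, i + 1:]          # genes x (n - i - 1)
        wsum = w.sum(axis=0)
        if np.any(wsum <= 0):
            j = i + 1 + int(np.argmax(wsum <= 0))
            raise ValueError(
                f"all gene weights zero for cell pair "
                f"({norm.cell_ids[i]!r}, {norm.cell_ids[j]!r})")
        xi = values[:, i, None]
        xj = values[:, i + 1:]
        mi = (w * xi).sum(axis=0) / wsum
        mj = (w * xj).sum(axis=0) / wsum
        di = xi - mi
        dj = xj - mj
        cov = (w * di * dj).sum(axis=0)
        var_i = (w * di * di).sum(axis=0)
        var_j = (w * dj * dj).sum(axis=0)
        denom = np.sqrt(var_i * var_j)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, cov / denom, 0.0)
        dist[i, i + 1:] = 1.0 - r
    dist = np.clip(dist + dist.T, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(values=dist, cell_ids=norm.cell_ids.copy(),
                          provenance="dropout-weighted")


def spearman_distance(norm: NormalizedMatrix, gene_subset) -> DistanceMatrix:
    """1 - Spearman rank correlation over a gene subset, average ranks for ties."""
    sub = norm.subset_genes(gene_subset)
    if sub.n_genes < 3:
        raise ValueError("gene subset must contain at least 3 genes")
    vals = sub.values
    constant = np.ptp(vals, axis=0) == 0
    if constant.any():
        cell = sub.cell_ids[int(np.argmax(constant))]
        raise ValueError(f"constant expression over the subset in cell {cell!r}; "
                         "Spearman correlation undefined")
    ranks = np.apply_along_axis(rankdata, 0, vals)
    rho = np.corrcoef(ranks.T)
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(values=dist, cell_ids=sub.cell_ids.copy(),
                          provenance="spearman")


# ---------------------------------------------------------------------------
# embeddings and clustering
# ---------------------------------------------------------------------------

def classical_mds(dist: DistanceMatrix, k: int = 2,
                  tol: float = 1e-9) -> Embedding:
    """Torgerson classical MDS: double-center -D^2/2, take top-k eigenpairs.

    Dimensions with eigenvalue ~0 yield zero coordinates (degenerate but
    exact); requesting more dimensions than the positive spectrum supports
    while negative eigenvalues remain is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = dist.values
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > tol * scale
    n_pos = int(pos.sum())
    if n_pos < k:
        rest = eigval[n_pos:k]
        if np.any(rest < -tol * scale):
            raise ValueError(
                f"only {n_pos} positive eigenvalue(s); maximum usable k is {n_pos}")
    n_neg = int((eigval < -tol * scale).sum())
    if n_neg:
        log.info("classical MDS: truncated %d negative eigenvalue(s)", n_neg)
    coords = np.zeros((n, k))
    use = min(k, n_pos)
    if use:
        coords[:, :use] = eigvec[:, :use] * np.sqrt(eigval[:use])
    return Embedding(coordinates=coords, cell_ids=dist.cell_ids.copy(),
                     method="MDS", eigenvalues=eigval[:k])


def tsne_embed(dist: DistanceMatrix, perplexity: float = 20.0,
               theta: float = 0.1, seed: int = 0) -> Embedding:
    """2-D Barnes-Hut t-SNE on a precomputed distance matrix (deterministic)."""
    n = dist.n_cells
    if n <= 3 * perplexity:
        raise ValueError(
            f"{n} cells is too few for perplexity {perplexity}; "
            f"use perplexity < {n / 3:.1f}")
    tsne = TSNE(n_components=2, metric="precomputed", perplexity=perplexity,
                angle=theta, init="random", random_state=int(seed),
                method="barnes_hut")
    coords = tsne.fit_transform(dist.values)
    return Embedding(coordinates=np.asarray(coords, dtype=float),
                     cell_ids=dist.cell_ids.copy(), method="t-SNE")


def kmeans_cluster(emb: Embedding, k: int, seed: int = 0,
                   restarts: int = 50) -> ClusterLabels:
    """k-means++ / Lloyd, best of `restarts` by inertia, deterministic per seed."""
    n = emb.coordinates.shape[0]
    if k < 2 or k > n:
        raise ValueError("k must be in [2, number of cells]")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed))
    labels = km.fit_predict(emb.coordinates)
    if np.unique(labels).size != k:
        raise ValueError("empty cluster after convergence")
    return ClusterLabels(labels=labels, k=k, cell_ids=emb.cell_ids.copy(),
                         inertia=float(km.inertia_), seed=int(seed))


def _as_labels(x) -> np.ndarray:
    if isinstance(x, ClusterLabels):
        return np.asarray(x.labels)
    return np.asarray(x)


def adjusted_rand_index(a, b, adjusted: bool = True) -> float:
    """Chance-corrected (adjusted) Rand index; plain Rand behind a flag."""
    la, lb = _as_labels(a), _as_labels(b)
    if isinstance(a, ClusterLabels) and isinstance(b, ClusterLabels):
        if not np.array_equal(a.cell_ids, b.cell_ids):
            raise ValueError("clusterings are over different cell sets")
    if la.shape != lb.shape:
        raise ValueError("label vectors differ in length")
    if adjusted:
        return float(adjusted_rand_score(la, lb))
    # plain Rand: fraction of concordant pairs
    n = la.size
    same_a = la[:, None] == la[None, :]
    same_b = lb[:, None] == lb[None, :]
    iu = np.triu_indices(n, 1)
    return float((same_a[iu] == same_b[iu]).mean())
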