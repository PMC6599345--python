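"""Distances, dropout model, MDS/t-SNE, k-means, Rand indices."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

import dcfate as dc
from conftest import tiny_matrix


def _norm_of(counts, factors=None):
    m = tiny_matrix(counts)
    f = np.ones(m.n_cells) if factors is None else np.asarray(factors, float)
    return dc.normalize_log2(m, f)


# ---------------------------------------------------------------------------
# dropout model
# ---------------------------------------------------------------------------

def test_dropout_model_all_detected_is_degenerate():
    rng = np.random.default_rng(0)
    norm = _norm_of(rng.integers(1, 100, size=(80, 5)))
    model = dc.fit_dropout_model(norm)
    assert model.degenerate.all()
    assert np.allclose(model.detect_probability(), 0.99)


def test_dropout_model_recovers_planted_slope():
    slopes = []
    for seed in range(10):
        cfg = dc.SimConfig(seed=seed, n_precdc=0, n_cdc1=60, n_cdc2=0,
                           n_dead_cells=0, dropout_intercept=-4.0,
                           dropout_slope=1.5, base_log2_mean_loc=4.0,
                           base_log2_mean_scale=2.0, n_variable_genes=0,
                           n_cdc_signature=0, n_precdc_signature=0,
                           n_state_genes=0, dispersion=0.05,
                           capture_sd_log2=0.0, content_sd_log2=0.0,
                           batch_multipliers=(1, 1, 1))
        matrix, _ = dc.simulate_dataset(cfg)
        norm = dc.normalize_log2(matrix, dc.size_factors(matrix))
        model = dc.fit_dropout_model(norm)
        slopes.append(np.median(model.slopes))
    assert abs(np.median(slopes) - 1.5) / 1.5 < 0.2


def test_dropout_model_needs_enough_genes():
    norm = _norm_of([[1, 2], [0, 3]])
    with pytest.raises(ValueError, match="insufficient genes"):
        dc.fit_dropout_model(norm)


# ---------------------------------------------------------------------------
# dropout-weighted distance
# ---------------------------------------------------------------------------

def test_weighted_distance_identical_cells_is_zero():
    rng = np.random.default_rng(1)
    col = rng.integers(1, 50, size=60)
    norm = _norm_of(np.column_stack([col, col, col + 1]))
    model = dc.fit_dropout_model(norm)
    d = dc.dropout_weighted_distance(norm, model)
    assert d.values[0, 1] < 1e-12
    assert np.all(np.diag(d.values) == 0)


def test_weighted_distance_reduces_to_pearson_without_zeros():
    rng = np.random.default_rng(2)
    norm = _norm_of(rng.integers(1, 500, size=(120, 6)))
    model = dc.fit_dropout_model(norm)
    d = dc.dropout_weighted_distance(norm, model)
    oracle = 1 - np.corrcoef(norm.values.T)
    np.fill_diagonal(oracle, 0.0)
    assert np.allclose(d.values, oracle, atol=1e-12)


def test_distance_matrix_invariants_enforced():
    with pytest.raises(ValueError, match="symmetric"):
        dc.DistanceMatrix(values=np.array([[0, 1.0], [2.0, 0]]),
                          cell_ids=np.array(["a", "b"]))
    with pytest.raises(ValueError, match="diagonal"):
        dc.DistanceMatrix(values=np.array([[1.0, 0], [0, 0]]),
                          cell_ids=np.array(["a", "b"]))
    with pytest.raises(ValueError, match="nonnegative"):
        dc.DistanceMatrix(values=np.array([[0, -0.5], [-0.5, 0]]),
                          cell_ids=np.array(["a", "b"]))


# ---------------------------------------------------------------------------
# Spearman distance
# ---------------------------------------------------------------------------

def test_spearman_distance_hand_computed():
    # rank vectors (1,2,3,4) vs (1,3,2,4): rho = 0.8 -> distance 0.2
    norm = _norm_of([[1, 1], [3, 10], [7, 4], [15, 30]])
    d = dc.spearman_distance(norm, norm.gene_ids)
    assert np.isclose(d.values[0, 1], 0.2)


def test_spearman_distance_extremes():
    norm = _norm_of([[1, 1, 30], [3, 3, 7], [7, 7, 3], [30, 30, 1]])
    d = dc.spearman_distance(norm, norm.gene_ids)
    assert np.isclose(d.values[0, 1], 0.0)    # identical ranks
    assert np.isclose(d.values[0, 2], 2.0)    # exactly reversed


def test_spearman_distance_constant_cell_errors():
    norm = _norm_of([[1, 5], [1, 9], [1, 2]])
    with pytest.raises(ValueError, match="constant expression.*c0"):
        dc.spearman_distance(norm, norm.gene_ids)
    with pytest.raises(ValueError, match="at least 3"):
        dc.spearman_distance(norm, norm.gene_ids[:2])


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

def test_classical_mds_exact_for_plane_points():
    pts = np.array([[0.0, 0.0], [3.0, 0.5], [1.0, 4.0], [-2.0, 1.5]])
    d = dc.DistanceMatrix(values=squareform(pdist(pts)),
                          cell_ids=np.array(list("abcd")))
    emb = dc.classical_mds(d, k=2)
    x = emb.coordinates - emb.coordinates.mean(axis=0)
    y = pts - pts.mean(axis=0)
    R, _ = orthogonal_procrustes(x, y)
    assert np.sqrt(((x @ R - y) ** 2).mean()) < 1e-8


def test_classical_mds_zero_distances_give_zero_coords():
    d = dc.DistanceMatrix(values=np.zeros((4, 4)),
                          cell_ids=np.array(list("abcd")))
    emb = dc.classical_mds(d, k=2)
    assert np.allclose(emb.coordinates, 0.0)
    assert emb.coordinates.shape == (4, 2)


def test_classical_mds_k_exceeding_cells_errors():
    d = dc.DistanceMatrix(values=np.zeros((3, 3)), cell_ids=np.array(list("abc")))
    with pytest.raises(ValueError):
        dc.classical_mds(d, k=5)


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def blob_distance():
    rng = np.random.default_rng(3)
    centers = np.array([[0, 0], [10, 0], [0, 10]])
    pts = np.vstack([rng.normal(c, 0.5, size=(30, 2)) for c in centers])
    ids = np.array([f"c{i}" for i in range(90)], dtype=object)
    labels = np.repeat([0, 1, 2], 30)
    return dc.DistanceMatrix(values=squareform(pdist(pts)), cell_ids=ids), labels


def test_tsne_deterministic_for_fixed_seed(blob_distance):
    d, _ = blob_distance
    e1 = dc.tsne_embed(d, seed=7)
    e2 = dc.tsne_embed(d, seed=7)
    assert np.array_equal(e1.coordinates, e2.coordinates)


def test_tsne_preserves_planted_clusters(blob_distance):
    from sklearn.metrics import silhouette_score

    d, labels = blob_distance
    emb = dc.tsne_embed(d, seed=0)
    assert silhouette_score(emb.coordinates, labels) > 0.5


def test_tsne_perplexity_guard():
    d = dc.DistanceMatrix(values=np.zeros((50, 50)),
                          cell_ids=np.array([f"c{i}" for i in range(50)]))
    with pytest.raises(ValueError, match="perplexity"):
        dc.tsne_embed(d, perplexity=20)


# ---------------------------------------------------------------------------
# k-means and Rand indices
# ---------------------------------------------------------------------------

def test_kmeans_separated_blobs_and_determinism():
    rng = np.random.default_rng(4)
    pts = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(40, 1, (40, 2))])
    ids = np.array([f"c{i}" for i in range(80)], dtype=object)
    emb = dc.Embedding(coordinates=pts, cell_ids=ids, method="MDS")
    l1 = dc.kmeans_cluster(emb, k=2, seed=1)
    l2 = dc.kmeans_cluster(emb, k=2, seed=1)
    truth = np.repeat([0, 1], 40)
    assert dc.adjusted_rand_index(l1.labels, truth) == 1.0
    assert np.array_equal(l1.labels, l2.labels)


def test_kmeans_k_equals_cell_count():
    pts = np.arange(10, dtype=float).reshape(5, 2)
    emb = dc.Embedding(coordinates=pts,
                       cell_ids=np.array([f"c{i}" for i in range(5)]),
                       method="MDS")
    labels = dc.kmeans_cluster(emb, k=5, seed=0)
    assert labels.inertia == pytest.approx(0.0)
    assert sorted(labels.labels) == list(range(5))


def ari_bruteforce(a, b):
    """Pair-counting oracle: ARI from explicit enumeration of all pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            ss += sa and sb
            sd += sa and not sb
            ds += not sa and sb
            dd += not sa and not sb
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = ((ss + sd) + (ss + ds)) / 2
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


def test_ari_identical_and_relabeled_partitions():
    a = np.array([0, 0, 1, 1, 2])
    assert dc.adjusted_rand_index(a, a) == 1.0
    assert dc.adjusted_rand_index(a, np.array([5, 5, 3, 3, 9])) == 1.0


def test_ari_matches_bruteforce_on_random_cases():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = rng.integers(3, 11)
        a = rng.integers(0, 4, size=n)
        b = rng.integers(0, 4, size=n)
        if len(set(a)) == 1 and len(set(b)) == 1:
            continue  # degenerate: both single-cluster
        assert dc.adjusted_rand_index(a, b) == pytest.approx(
            ari_bruteforce(a, b), abs=1e-12)


def test_plain_rand_index_flag():
    a = np.array([0, 0, 1, 1])
    b = np.array([0, 1, 1, 1])
    # concordant pairs: (0,1) same-diff, ... brute force: 3 of 6 concordant
    assert dc.adjusted_rand_index(a, b, adjusted=False) == pytest.approx(0.5)


def test_ari_mismatched_lengths_error():
    with pytest.raises(ValueError):
        dc.adjusted_rand_index(np.array([0, 1]), np.array([0, 1, 1]))
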