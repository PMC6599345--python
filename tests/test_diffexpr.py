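"""Bulk t-test DE, rank-sum single-cell DE, ANOVA+Tukey signatures, Ward."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dcfate as dc
from conftest import tiny_matrix


def _norm_from_values(values, cell_ids=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    cell_ids = cell_ids or [f"c{j}" for j in range(c)]
    flags = pd.DataFrame(False, index=gene_ids,
                         columns=["is_spikein", "is_mito", "is_tf"])
    return dc.NormalizedMatrix(values=values, size_factors=np.ones(c),
                               gene_ids=np.array(gene_ids, dtype=object),
                               cell_ids=np.array(cell_ids, dtype=object),
                               gene_flags=flags,
                               cell_meta=pd.DataFrame(index=cell_ids))


def _groups(cells, labels):
    return pd.Series(labels, index=cells)


# ---------------------------------------------------------------------------
# rank-sum machinery
# ---------------------------------------------------------------------------

def test_ranksum_exact_on_fully_separated_groups():
    z, p = dc.ranksum_z(np.array([1, 2, 3, 4, 5]), np.array([6, 7, 8, 9, 10]))
    assert p == pytest.approx(2 / 252)
    assert z > 0


def test_ranksum_constant_input_degenerates_cleanly():
    z, p = dc.ranksum_z(np.zeros(6), np.zeros(6))
    assert (z, p) == (0.0, 1.0)


def test_ranksum_normal_approx_close_to_exact():
    rng = np.random.default_rng(6)
    rel_errs = []
    for _ in range(100):
        x = rng.normal(size=8)
        y = rng.normal(loc=rng.uniform(0, 2), size=8)
        _, p_exact = dc.ranksum_z(x, y)
        # recompute the asymptotic p from the reported Z
        z, _ = dc.ranksum_z(x, y)
        p_norm = 2 * stats.norm.sf(abs(z))
        if p_exact < 1e-4:
            continue
        rel_errs.append(abs(p_norm - p_exact) / p_exact)
    assert np.median(rel_errs) < 0.10


def test_rank_auc_extremes_and_ties():
    assert dc.rank_auc(np.array([5, 6]), np.array([1, 2])) == 1.0
    assert dc.rank_auc(np.array([1, 2]), np.array([5, 6])) == 0.0
    assert dc.rank_auc(np.array([3, 3]), np.array([3, 3])) == 0.5


# ---------------------------------------------------------------------------
# single-cell rank-sum DE
# ---------------------------------------------------------------------------

def test_sc_de_null_z_scores_standard_normal():
    rng = np.random.default_rng(7)
    values = rng.gamma(2, 2, size=(2000, 40))
    norm = _norm_from_values(values)
    groups = _groups(norm.cell_ids, ["A"] * 20 + ["B"] * 20)
    res = dc.sc_de_ranksum(norm, groups)
    z = res.table["statistic"]
    assert -0.1 < z.mean() < 0.1
    assert 0.9 < z.std() < 1.1


def test_sc_de_small_group_rejected():
    norm = _norm_from_values(np.random.default_rng(0).random((10, 8)))
    groups = _groups(norm.cell_ids, ["A"] * 4 + ["B"] * 4)
    with pytest.raises(ValueError, match="at least 5"):
        dc.sc_de_ranksum(norm, groups)


def test_sc_de_top_by_z_deterministic_tiebreak():
    values = np.vstack([
        np.r_[np.ones(5), np.zeros(5) + 10],     # strong, z > 0
        np.r_[np.ones(5) * 10, np.zeros(5)],     # strong, z < 0 (same |z|)
        np.r_[np.ones(5), np.ones(5)],           # null
    ])
    norm = _norm_from_values(values, gene_ids=["gB", "gA", "gC"])
    res = dc.sc_de_ranksum(norm, _groups(norm.cell_ids, list("AAAAABBBBB")))
    assert res.top_by_z(2) == ["gA", "gB"]      # |Z| tie broken by gene id


# ---------------------------------------------------------------------------
# bulk DE
# ---------------------------------------------------------------------------

def test_bulk_de_identical_groups_flat():
    rng = np.random.default_rng(8)
    half = rng.random((50, 3))
    norm = _norm_from_values(np.hstack([half, half]))
    res = dc.bulk_de(norm, _groups(norm.cell_ids, list("AAABBB")))
    assert np.allclose(res.table["log2fc"], 0.0)
    assert (res.table["q"] > 0.9).all()


def test_bulk_de_constant_gene_p_one():
    values = np.vstack([np.full(6, 3.0), np.random.default_rng(1).random(6)])
    norm = _norm_from_values(values)
    res = dc.bulk_de(norm, _groups(norm.cell_ids, list("AAABBB")))
    assert res.table.iloc[0]["p"] == 1.0
    assert res.table.iloc[0]["log2fc"] == 0.0


def test_bulk_de_recovers_planted_signature(bulk_pipeline):
    truth = bulk_pipeline["truth"]
    de_genes = set(bulk_pipeline["de_genes"])
    sig = set(truth.de_genes["cDC1_vs_cDC2"])
    assert len(sig & de_genes) / len(sig) >= 0.75
    # planted-null background: few false calls
    null_genes = de_genes - sig - set(truth.mr_tfs)
    universe = len(bulk_pipeline["de"].table) - len(sig) - len(truth.mr_tfs)
    assert len(null_genes) / universe < 0.01


def test_bulk_de_replicate_guard():
    norm = _norm_from_values(np.random.default_rng(2).random((5, 3)))
    with pytest.raises(ValueError, match="2 replicates"):
        dc.bulk_de(norm, _groups(norm.cell_ids, ["A", "A", "B"]))


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

def test_anova_identical_populations_selects_nothing():
    rng = np.random.default_rng(9)
    block = rng.random((40, 5))
    norm = _norm_from_values(np.hstack([block, block, block]))
    groups = _groups(norm.cell_ids, ["A"] * 5 + ["B"] * 5 + ["C"] * 5)
    res = dc.anova_signature(norm, groups)
    assert res.selected_genes() == []


def test_anova_forced_separation_and_tukey_pairs():
    rng = np.random.default_rng(10)
    n = 30
    gene = np.r_[rng.normal(0, 0.5, n), rng.normal(0, 0.5, n),
                 rng.normal(3, 0.5, n)]
    filler = rng.normal(2, 0.5, size=(30, 3 * n))
    norm = _norm_from_values(np.vstack([np.abs(gene), np.abs(filler)]))
    groups = _groups(norm.cell_ids, ["A"] * n + ["B"] * n + ["C"] * n)
    res = dc.anova_signature(norm, groups)
    row = res.table.iloc[0]
    assert "g0" in res.selected_genes()
    assert row["tukey_p_C_vs_A"] < 0.01
    assert row["tukey_p_C_vs_B"] < 0.01
    assert row["tukey_p_B_vs_A"] > 0.05


def test_anova_tukey_matches_statsmodels():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(11)
    values = rng.normal(2, 1, size=(5, 24))
    values[0, 8:16] += 1.5
    norm = _norm_from_values(np.abs(values))
    labels = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
    res = dc.anova_signature(norm, _groups(norm.cell_ids, labels))
    for gi in range(5):
        sm_res = pairwise_tukeyhsd(norm.values[gi], labels)
        ours = res.table.iloc[gi][["tukey_p_B_vs_A", "tukey_p_C_vs_A",
                                   "tukey_p_C_vs_B"]].to_numpy(dtype=float)
        assert np.allclose(ours, sm_res.pvalues, atol=1e-6)


def test_anova_fold_change_cut_respected():
    rng = np.random.default_rng(12)
    n = 40
    gene = np.r_[rng.normal(2.0, 0.05, n), rng.normal(2.8, 0.05, n),
                 rng.normal(2.0, 0.05, n)]
    norm = _norm_from_values(gene[None, :])
    groups = _groups(norm.cell_ids, ["A"] * n + ["B"] * n + ["C"] * n)
    res = dc.anova_signature(norm, groups, fc_cut=1.0)
    assert res.table.iloc[0]["q"] < 0.05          # highly significant
    assert res.selected_genes() == []             # |log2FC| = 0.8 < 1
    res2 = dc.anova_signature(norm, groups, fc_cut=0.5)
    assert res2.selected_genes() == ["g0"]


def test_anova_ordering_matches_ttest_when_two_groups_merged():
    rng = np.random.default_rng(13)
    values = np.abs(rng.normal(4, 1, size=(300, 120)))
    values[:250, 80:] += rng.uniform(0.3, 2.0, size=(250, 1))
    norm = _norm_from_values(values)
    labels3 = _groups(norm.cell_ids, ["A"] * 40 + ["B"] * 40 + ["C"] * 40)
    labels2 = _groups(norm.cell_ids, ["AB"] * 80 + ["C"] * 40)
    # merge A and B generatively: they are drawn identically above
    res3 = dc.anova_signature(norm, labels3)
    res2 = dc.bulk_de(norm, labels2)
    rho = stats.spearmanr(res3.table["p"], res2.table["p"]).statistic
    assert rho > 0.95


def test_anova_small_population_guard():
    norm = _norm_from_values(np.random.default_rng(3).random((5, 7)))
    groups = _groups(norm.cell_ids, ["A"] * 3 + ["B"] * 2 + ["C"] * 2)
    with pytest.raises(ValueError, match="at least 3"):
        dc.anova_signature(norm, groups)


# ---------------------------------------------------------------------------
# Ward gene clustering
# ---------------------------------------------------------------------------

def test_ward_recovers_planted_gene_blocks():
    rng = np.random.default_rng(14)
    t = np.linspace(0, 1, 40)
    block1 = np.vstack([5 * t + rng.normal(0, 0.3, 40) for _ in range(10)])
    block2 = np.vstack([5 * (1 - t) + rng.normal(0, 0.3, 40) for _ in range(10)])
    norm = _norm_from_values(np.abs(np.vstack([block1, block2])))
    res = dc.cluster_genes_ward(norm, norm.gene_ids, n_clusters=2)
    labels = res.assignments.to_numpy()
    assert len(set(labels[:10])) == 1
    assert len(set(labels[10:])) == 1
    assert labels[0] != labels[10]


def test_ward_singletons_and_duplicates():
    rng = np.random.default_rng(15)
    values = np.abs(rng.normal(2, 1, size=(6, 20)))
    values[5] = values[0]          # duplicate gene row
    norm = _norm_from_values(values)
    singles = dc.cluster_genes_ward(norm, norm.gene_ids, n_clusters=6)
    assert singles.assignments.nunique() == 6
    paired = dc.cluster_genes_ward(norm, norm.gene_ids, n_clusters=3)
    assert paired.assignments["g0"] == paired.assignments["g5"]
    with pytest.raises(ValueError, match="fewer than"):
        dc.cluster_genes_ward(norm, norm.gene_ids[:2], n_clusters=4)
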