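"""Master-regulator transcription-factor inference.

A TF qualifies as a candidate master regulator of the cDC1/cDC2 fate
split through either of two routes:

(a) strict differential expression between bulk cDC1 and cDC2
    (BH q below threshold AND |log2 fold change| above the cut); or
(b) its target regulon is over-represented among the bulk DE genes
    (hypergeometric, BH-adjusted) AND the TF itself shows marginal
    differential expression (raw p below threshold, same fold-change cut).

The over-representation test is a one-sided hypergeometric upper tail
within the universe of genes actually tested for DE; the combined score
-ln(p) * log2(odds ratio) (Haldane-corrected) carries the direction:
positive for enrichment, negative for depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetDB, bh_adjust, log
from .diffexpr import DEResult


@dataclass
class EnrichmentResult:
    """Per-TF over-representation statistics against one DE gene set."""

    table: pd.DataFrame    # set_size, overlap, universe, p, q, odds_ratio, combined_score
    n_de: int
    n_universe: int


@dataclass
class MRTFSet:
    """Selected master regulators with the evidence backing each call.

    `reason` is "a" (strict DE) or "b" (target enrichment + marginal DE);
    a TF satisfying both is reported as "a".
    """

    table: pd.DataFrame    # reason, log2fc, p, q, enrichment_p, enrichment_q

    def names(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def tf_target_enrichment(de_genes, universe, db: GeneSetDB) -> EnrichmentResult:
    """Hypergeometric over-representation of each TF's targets in `de_genes`.

    Target sets are intersected with the universe first; TFs with no
    in-universe targets are skipped with a warning.
    """
    universe = set(universe)
    de = set(de_genes)
    if not universe:
        raise ValueError("empty universe")
    if not de:
        raise ValueError("empty DE gene set")
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    N = len(universe)
    n = len(de)
    rows = []
    for tf in db.names():
        targets = set(db[tf]) & universe
        K = len(targets)
        if K == 0:
            log.warning("enrichment: TF %s has no in-universe targets; skipped", tf)
            continue
        k = len(targets & de)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        # Haldane-corrected odds ratio of the 2x2 overlap table
        a, b = k, K - k
        c, d = n - k, N - K - (n - k)
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        combined = -np.log(max(p, np.finfo(float).tiny)) * np.log2(odds)
        rows.append((tf, K, k, p, odds, combined))
    if not rows:
        raise ValueError("no TF with in-universe targets")
    table = pd.DataFrame(
        rows, columns=["tf", "set_size", "overlap", "p", "odds_ratio",
                       "combined_score"],
    ).set_index("tf")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["universe"] = N
    return EnrichmentResult(table=table, n_de=n, n_universe=N)


def select_master_regulators(bulk_de: DEResult, enr: EnrichmentResult,
                             tf_list, fc_cut: float = 1.0,
                             strict_q: float = 0.05,
                             marginal_p: float = 0.05,
                             enr_q: float = 0.05) -> MRTFSet:
    """Union of the strict-DE (a) and enrichment + marginal-DE (b) criteria."""
    de = bulk_de.table
    rows = []
    for tf in sorted(set(tf_list)):
        if tf not in de.index:
            log.warning("MR selection: TF %s absent from the DE table; skipped", tf)
            continue
        log2fc = float(de.loc[tf, "log2fc"])
        p = float(de.loc[tf, "p"])
        q = float(de.loc[tf, "q"])
        e_p = e_q = np.nan
        if tf in enr.table.index:
            e_p = float(enr.table.loc[tf, "p"])
            e_q = float(enr.table.loc[tf, "q"])
        fc_ok = abs(log2fc) > fc_cut
        reason_a = fc_ok and q < strict_q
        reason_b = (fc_ok and p < marginal_p
                    and np.isfinite(e_q) and e_q < enr_q)
        if not (reason_a or reason_b):
            continue
        rows.append((tf, "a" if reason_a else "b", log2fc, p, q, e_p, e_q))
    table = pd.DataFrame(
        rows, columns=["tf", "reason", "log2fc", "p", "q",
                       "enrichment_p", "enrichment_q"],
    ).set_index("tf")
    return MRTFSet(table=table)


def predict_cluster_regulators(cluster_de: DEResult, enr: EnrichmentResult,
                               detection_counts: pd.Series,
                               q_cut: float = 0.05, fc_cut: float = 2.0,
                               min_cells: int = 10) -> list:
    """Regulators predicted for one gene cluster's population contrast.

    A TF is reported iff all four conditions hold: BH q < q_cut,
    log2FC > fc_cut (strictly, signed toward the cluster's population),
    combined enrichment score > 0, and detection in >= min_cells cells.
    """
    detection_counts = pd.Series(detection_counts)
    de = cluster_de.table
    out = []
    for tf in sorted(enr.table.index):
        if tf not in de.index or tf not in detection_counts.index:
            continue
        if float(de.loc[tf, "q"]) >= q_cut:
            continue
        if float(de.loc[tf, "log2fc"]) <= fc_cut:
            continue
        if float(enr.table.loc[tf, "combined_score"]) <= 0:
            continue
        if int(detection_counts[tf]) < min_cells:
            continue
        out.append(tf)
    return out
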