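"""Per-cell quality control and depth normalization.

Filters: total reads assigned to genes >= 100,000; mitochondrial read
fraction < 30%; number of detected genes strictly > 1000.  Spike-in rows
are excluded from all three statistics (they are exogenous and their
yield says nothing about cell quality).  Housekeeping and cell-cycle
detection fractions are reported descriptively, never used as filters.

Size factors use the median-of-ratios estimator (each cell's median
ratio of counts to the per-gene geometric mean over reference genes);
normalized values are log2(count / size_factor + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, NormalizedMatrix, log


@dataclass
class QCThresholds:
    min_mapped_reads: int = 100_000
    max_mito_fraction: float = 0.30
    min_genes_detected: int = 1000          # strict: pass requires count > this
    housekeeping_genes: list = field(default_factory=list)   # report-only
    cell_cycle_genes: list = field(default_factory=list)     # report-only

    def __post_init__(self) -> None:
        if self.min_mapped_reads < 0:
            raise ValueError("min_mapped_reads must be >= 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Per-cell QC metrics and pass/fail decisions (one row per cell)."""

    table: pd.DataFrame
    thresholds: QCThresholds

    def passing_cells(self) -> np.ndarray:
        return self.table.index[self.table["pass_all"]].to_numpy(dtype=object)


def compute_cell_qc(matrix: ExpressionMatrix,
                    thresholds: QCThresholds | None = None) -> QCReport:
    """Depth, mitochondrial fraction and gene-detection QC for every cell."""
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("empty matrix")
    thresholds = thresholds or QCThresholds()
    bio = ~matrix.flag("is_spikein")
    counts = matrix.counts[bio]
    mito = matrix.flag("is_mito")[bio]
    total = counts.sum(axis=0)
    mito_frac = np.divide(counts[mito].sum(axis=0), total,
                          out=np.zeros(matrix.n_cells), where=total > 0)
    detected = (counts > 0).sum(axis=0)

    table = pd.DataFrame(
        {
            "total_reads": total,
            "mito_fraction": mito_frac,
            "genes_detected": detected,
        },
        index=matrix.cell_ids,
    )
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids[bio])}
    for name, glist in (("housekeeping_detected_fraction", thresholds.housekeeping_genes),
                        ("cell_cycle_detected_fraction", thresholds.cell_cycle_genes)):
        present = [gene_pos[g] for g in glist if g in gene_pos]
        if present:
            table[name] = (counts[present] > 0).mean(axis=0)
        else:
            table[name] = np.nan
    table["pass_depth"] = table["total_reads"] >= thresholds.min_mapped_reads
    table["pass_mito"] = table["mito_fraction"] < thresholds.max_mito_fraction
    table["pass_genes"] = table["genes_detected"] > thresholds.min_genes_detected
    table["pass_all"] = (table["pass_depth"] & table["pass_mito"]
                         & table["pass_genes"])
    return QCReport(table=table, thresholds=thresholds)


def filter_cells(matrix: ExpressionMatrix, report: QCReport) -> ExpressionMatrix:
    """Drop failing cells; the gene set is left intact."""
    if not np.array_equal(report.table.index.to_numpy(dtype=object),
                          matrix.cell_ids):
        raise ValueError("QC report does not match this matrix")
    t = report.table
    for crit in ("pass_depth", "pass_mito", "pass_genes"):
        removed = int((~t[crit]).sum())
        if removed:
            log.info("QC: %d cell(s) fail %s", removed, crit)
    keep = t["pass_all"].to_numpy()
    if not keep.any():
        raise ValueError("all cells filtered")
    return matrix.subset_cells(keep)


def size_factors(matrix: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size factors; spike-ins excluded.

    Reference genes are those with a nonzero count in every cell (positive
    geometric mean).  If none exists the estimator falls back to total
    counts scaled to geometric mean one (logged).
    """
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    counts = matrix.counts[~matrix.flag("is_spikein")].astype(float)
    if counts.sum() == 0:
        raise ValueError("matrix of all zeros")
    expressed_everywhere = (counts > 0).all(axis=1)
    if not expressed_everywhere.any():
        log.warning("size_factors: no gene expressed in all cells; "
                    "falling back to total-count factors")
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("cell with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return factors
    ref = counts[expressed_everywhere]
    log_geo = np.mean(np.log(ref), axis=1)
    ratios = ref / np.exp(log_geo)[:, None]
    return np.median(ratios, axis=0)


def normalize_log2(matrix: ExpressionMatrix, factors: np.ndarray) -> NormalizedMatrix:
    """log2(count / size_factor + 1); zeros map to zero."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (matrix.n_cells,):
        raise ValueError("one size factor per cell required")
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    values = np.log2(matrix.counts / factors[None, :] + 1.0)
    return NormalizedMatrix(
        values=values,
        size_factors=factors,
        gene_ids=matrix.gene_ids.copy(),
        cell_ids=matrix.cell_ids.copy(),
        gene_flags=matrix.gene_flags.copy(),
        cell_meta=matrix.cell_meta.copy(),
    )
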