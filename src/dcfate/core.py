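"""Shared domain types, file I/O and generic statistical utilities.

The central container is :class:`ExpressionMatrix`: a genes x cells (or
genes x samples) raw count matrix with per-gene flags (spike-in,
mitochondrial, transcription factor) and per-cell metadata.  Counts are
kept genes-as-rows throughout the package because every statistic the
pipeline computes (CV^2, fold change, detection counts) is per gene.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("dcfate")
if not log.handlers:  # stage timings / warnings go to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[dcfate] %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

GENE_FLAG_COLUMNS = ("is_spikein", "is_mito", "is_tf")

DEFAULT_SPIKEIN_PREFIX = "ERCC-"
DEFAULT_MITO_PREFIX = "MT-"


def _check_unique(ids: np.ndarray, what: str) -> None:
    values, counts = np.unique(ids, return_counts=True)
    dup = values[counts > 1]
    if dup.size:
        raise ValueError(f"duplicate {what} id: {dup[0]!r}")


@dataclass
class ExpressionMatrix:
    """Raw counts, genes x cells, with gene flags and cell metadata.

    counts      -- nonnegative integer array, shape (n_genes, n_cells)
    gene_ids    -- unique gene identifiers (rows)
    cell_ids    -- unique cell/sample identifiers (columns)
    gene_flags  -- boolean DataFrame indexed by gene id with columns
                   is_spikein / is_mito / is_tf
    cell_meta   -- DataFrame indexed by cell id; carries at least 'batch',
                   optionally 'known_type'
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    gene_flags: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                bad = np.argwhere(as_int != counts)[0]
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"cell {self.cell_ids[bad[1]]!r}"
                )
            counts = as_int
        if counts.min(initial=0) < 0:
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)
        if self.counts.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValueError("counts shape does not match gene/cell ids")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.gene_flags is None:
            self.gene_flags = pd.DataFrame(
                False, index=self.gene_ids, columns=list(GENE_FLAG_COLUMNS)
            )
        for col in GENE_FLAG_COLUMNS:
            if col not in self.gene_flags.columns:
                self.gene_flags[col] = False
        if len(self.gene_flags) != self.gene_ids.size:
            raise ValueError("gene_flags length does not match gene_ids")
        self.gene_flags = self.gene_flags.loc[self.gene_ids].astype(bool)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        if "batch" not in self.cell_meta.columns:
            self.cell_meta = self.cell_meta.assign(batch="batch1")
        if len(self.cell_meta) != self.cell_ids.size:
            raise ValueError("cell_meta length does not match cell_ids")
        self.cell_meta = self.cell_meta.loc[self.cell_ids]

    # -- convenience ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return int(self.gene_ids.size)

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    def flag(self, name: str) -> np.ndarray:
        return self.gene_flags[name].to_numpy()

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"gene not in matrix: {missing[0]!r}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, mask_or_genes) -> "ExpressionMatrix":
        idx = self._as_gene_idx(mask_or_genes)
        return ExpressionMatrix(
            counts=self.counts[idx],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids.copy(),
            gene_flags=self.gene_flags.iloc[idx].copy(),
            cell_meta=self.cell_meta.copy(),
        )

    def subset_cells(self, mask_or_cells) -> "ExpressionMatrix":
        idx = self._as_cell_idx(mask_or_cells)
        return ExpressionMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            gene_flags=self.gene_flags.copy(),
            cell_meta=self.cell_meta.iloc[idx].copy(),
        )

    def _as_gene_idx(self, sel) -> np.ndarray:
        sel = np.asarray(sel)
        if sel.dtype == bool:
            return np.flatnonzero(sel)
        if np.issubdtype(sel.dtype, np.integer):
            return sel
        return self.gene_index(sel)

    def _as_cell_idx(self, sel) -> np.ndarray:
        sel = np.asarray(sel)
        if sel.dtype == bool:
            return np.flatnonzero(sel)
        if np.issubdtype(sel.dtype, np.integer):
            return sel
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in sel if c not in lookup]
        if missing:
            raise KeyError(f"cell not in matrix: {missing[0]!r}")
        return np.array([lookup[c] for c in sel], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class NormalizedMatrix:
    """log2(count / size_factor + 1) values plus the size factors used.

    ``linear()`` recovers count/size_factor exactly (2**value - 1), which is
    the scale the spike-in noise model and the CV^2 statistics operate on.
    """

    values: np.ndarray
    size_factors: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    gene_flags: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if self.values.min(initial=0.0) < 0:
            raise ValueError("normalized values must be nonnegative")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match gene/cell ids")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)

    @property
    def n_genes(self) -> int:
        return int(self.gene_ids.size)

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    def flag(self, name: str) -> np.ndarray:
        return self.gene_flags[name].to_numpy()

    def linear(self) -> np.ndarray:
        """Size-factor-normalized counts on the linear scale."""
        return np.exp2(self.values) - 1.0

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"gene not in matrix: {missing[0]!r}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes) -> "NormalizedMatrix":
        sel = np.asarray(genes)
        idx = np.flatnonzero(sel) if sel.dtype == bool else self.gene_index(sel)
        return NormalizedMatrix(
            values=self.values[idx],
            size_factors=self.size_factors,
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids,
            gene_flags=self.gene_flags.iloc[idx],
            cell_meta=self.cell_meta,
        )

    def subset_cells(self, cells) -> "NormalizedMatrix":
        sel = np.asarray(cells)
        if sel.dtype == bool:
            idx = np.flatnonzero(sel)
        else:
            lookup = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([lookup[c] for c in sel], dtype=int)
        return NormalizedMatrix(
            values=self.values[:, idx],
            size_factors=self.size_factors[idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            gene_flags=self.gene_flags,
            cell_meta=self.cell_meta.iloc[idx],
        )


@dataclass
class GeneSetDB:
    """TF name -> set of target gene symbols, e.g. parsed from a GMT file."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            members = frozenset(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = members

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def names(self) -> list:
        return sorted(self.sets)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _apply_prefix_flags(matrix: ExpressionMatrix, spikein_prefix: str,
                        mito_prefix: str, tf_genes=None) -> ExpressionMatrix:
    genes = matrix.gene_ids
    matrix.gene_flags["is_spikein"] = [str(g).startswith(spikein_prefix) for g in genes]
    matrix.gene_flags["is_mito"] = [str(g).startswith(mito_prefix) for g in genes]
    if tf_genes is not None:
        tf_genes = set(tf_genes)
        matrix.gene_flags["is_tf"] = [g in tf_genes for g in genes]
    return matrix


def read_counts(path, format: str = "tsv-dense", *,
                spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
                mito_prefix: str = DEFAULT_MITO_PREFIX,
                tf_genes: Iterable[str] | None = None,
                genes_file=None, cells_file=None) -> ExpressionMatrix:
    """Read a genes x cells count matrix.

    format "tsv-dense": header row of cell ids, first column gene ids.
    format "mtx-triplet": MatrixMarket coordinate file; row (gene) and
    column (cell) names are read from `genes.txt` / `cells.txt` next to
    the matrix file unless explicit paths are given.

    Spike-in and mitochondrial rows are flagged by identifier prefix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "tsv-dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = df.index.to_numpy(dtype=object)
        cell_ids = df.columns.to_numpy(dtype=object)
        counts = df.to_numpy()
    elif format == "mtx-triplet":
        from scipy.io import mmread

        genes_file = Path(genes_file) if genes_file else path.parent / "genes.txt"
        cells_file = Path(cells_file) if cells_file else path.parent / "cells.txt"
        for f in (genes_file, cells_file):
            if not f.exists():
                raise FileNotFoundError(f"companion name file missing: {f}")
        gene_ids = np.loadtxt(genes_file, dtype=str, ndmin=1).astype(object)
        cell_ids = np.loadtxt(cells_file, dtype=str, ndmin=1).astype(object)
        counts = np.asarray(mmread(str(path)).todense())
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_unique(gene_ids, "gene")
    _check_unique(cell_ids, "cell")
    mat = ExpressionMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids,
                           gene_flags=None, cell_meta=None)
    return _apply_prefix_flags(mat, spikein_prefix, mito_prefix, tf_genes)


def write_counts(matrix: ExpressionMatrix, path, format: str = "tsv-dense") -> None:
    """Write counts in either supported format (lossless round trip)."""
    path = Path(path)
    if format == "tsv-dense":
        matrix.to_frame().to_csv(path, sep="\t")
    elif format == "mtx-triplet":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(matrix.counts))
        np.savetxt(path.parent / "genes.txt", matrix.gene_ids, fmt="%s")
        np.savetxt(path.parent / "cells.txt", matrix.cell_ids, fmt="%s")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gmt(path) -> GeneSetDB:
    """Parse a GMT file: name TAB description TAB member [TAB member ...]."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: too few fields (need >= 3)")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate TF name {name!r}")
            sets[name] = frozenset(fields[2:])
            descriptions[name] = desc
    return GeneSetDB(sets=sets, descriptions=descriptions)


def write_gmt(db: GeneSetDB, path) -> None:
    with open(path, "w") as fh:
        for name in db.names():
            desc = db.descriptions.get(name, "")
            members = "\t".join(sorted(db.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_table(result, path) -> None:
    """Write any tabular pipeline output as TSV, floats to 6 significant digits.

    Row order is whatever deterministic order the producing operation
    documents; this function preserves it.
    """
    df = result if isinstance(result, pd.DataFrame) else pd.DataFrame(result)
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    NaN entries propagate as NaN and do not count toward the number of
    tests m, so genes skipped by prefilters do not dilute the correction.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ps = p[finite]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    scaled = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[finite] = out
    return q


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every threshold and seed the pipeline uses, in one place.

    Defaults follow the analysis protocol: 100k-read depth filter, <30%
    mitochondrial fraction, >1000 detected genes, 10% FDR / 50% biological
    CV for variable genes, |log2FC|>1 & 5% FDR for signatures, t-SNE
    perplexity 20 / theta 0.1, 3000 resampling rounds.
    """

    # QC
    min_mapped_reads: int = 100_000
    max_mito_fraction: float = 0.30
    min_genes_detected: int = 1000
    # HVG
    hvg_fdr: float = 0.10
    min_bio_cv: float = 0.5
    hvg_min_cells: int = 10
    spikein_fit_quantile: float = 0.4
    # DE / signatures
    de_fdr: float = 0.05
    fc_cut: float = 1.0
    # MR-TF selection
    mr_strict_q: float = 0.05
    mr_marginal_p: float = 0.05
    mr_enrichment_q: float = 0.05
    # embedding / clustering
    tsne_perplexity: float = 20.0
    tsne_theta: float = 0.1
    kmeans_restarts: int = 50
    # resampling null
    null_rounds: int = 3000
    null_n_genes: int = 842
    null_mean_floor: float = 100.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_mapped_reads < 0:
            raise ValueError("min_mapped_reads must be >= 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        for name in ("hvg_fdr", "de_fdr", "mr_strict_q", "mr_marginal_p",
                     "mr_enrichment_q", "spikein_fit_quantile"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_bio_cv < 0 or self.fc_cut < 0:
            raise ValueError("min_bio_cv and fc_cut must be >= 0")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a nonnegative integer")
        if self.null_rounds < 1 or self.null_n_genes < 1:
            raise ValueError("resampling parameters must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
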