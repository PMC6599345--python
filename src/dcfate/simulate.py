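"""Synthetic single-cell and bulk RNA-seq generator with planted ground truth.

The generator emulates the study design the downstream analysis assumes:

* three cell populations -- pre-cDC precursors plus the two mature
  conventional dendritic-cell subsets (cDC1, cDC2) -- mixed 2:1:1;
* pre-cDCs split into two latent fates (future cDC1 vs future cDC2);
* negative-binomial (Gamma-Poisson) counts with an additional
  logit-linear dropout process (low-abundance transcripts fail to
  amplify more often);
* ERCC-like spike-ins at cell-constant true abundance whose normalized
  counts obey the technical-noise law CV^2 = a1/mu + alpha0;
* planted highly variable genes, population signature genes, and master
  regulator (MR) transcription factors whose *log dose ratio* -- not
  either marginal level -- encodes the precursor fate;
* mild batch depth effects and a handful of dead-cell outliers
  (20x lower depth, ~50% mitochondrial reads) to exercise the QC stage.

The fate encoding is the generative counterpart of the combinatorial-dose
hypothesis: a shared activity u ~ N(0, sigma_u^2) moves BOTH anchor-TF
log2 doses together while the fate shifts their difference by +/- delta/2,
so the log ratio separates the fates cleanly although each marginal level
overlaps whenever sigma_u >> delta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ExpressionMatrix, GeneSetDB, log

POPULATIONS = ("pre-cDC", "cDC1", "cDC2")
FATES = ("pre-cDC1", "pre-cDC2")
LN2 = float(np.log(2.0))


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the package's study conditions."""

    # gene universe
    n_genes: int = 2000            # biological genes incl. mito + TFs
    n_spikeins: int = 92
    n_mito: int = 10
    # cells (pre-cDC : cDC1 : cDC2 = 2 : 1 : 1)
    n_precdc: int = 100
    n_cdc1: int = 50
    n_cdc2: int = 50
    fate1_fraction: float = 0.5
    n_dead_cells: int = 6
    # baseline expression (log2 mean of regular genes)
    base_log2_mean_loc: float = 4.0
    base_log2_mean_scale: float = 2.8
    mito_log2_mean: float = 7.0
    # count noise
    dispersion: float = 0.10       # extra-Poisson gamma variance, biological genes
    # dropout (detection probability logistic in per-cell log2 mean)
    dropout: bool = True
    dropout_intercept: float = -10.0
    dropout_slope: float = 3.0
    # spike-in technical law CV^2 = a1/mu + alpha0 (a1 >= 1: Poisson floor)
    a1: float = 1.0
    alpha0: float = 0.05
    spikein_log2_min: float = -1.0
    spikein_log2_max: float = 9.0
    # planted structure
    n_variable_genes: int = 350    # >= n_cdc_signature; surplus is pure noise genes
    variable_bio_cv: float = 1.3
    n_cdc_signature: int = 150     # DE cDC1 vs cDC2, also variable within pre-cDCs
    cdc_effect: float = 2.0        # log2 fold change between cDC1 and cDC2
    # fate-program genes are moderately expressed (below the housekeeping-
    # dominated high-mean pool the resampling null draws from)
    sig_log2_mean_loc: float = 3.2
    sig_log2_mean_scale: float = 0.8
    n_precdc_signature: int = 300  # DE pre-cDC vs both cDCs
    precdc_effect: float = 2.0
    # structured fate-independent heterogeneity: a latent per-cell state
    # factor loading on a program of background genes (activation/maturation
    # continuum shared by all populations)
    n_state_genes: int = 300
    state_sd_log2: float = 0.8
    # master-regulator TFs
    n_mr_tfs: int = 16
    n_decoy_tfs: int = 24
    anchor_genes: tuple = ("IRF8", "IRF4")
    delta: float = 2.0             # fate-linked shift of the anchor log2 ratio
    sigma_u: float = 3.0           # spread of the shared anchor activity
    anchor_base_log2: float = 6.0
    anchor_noise: float = 0.3      # independent per-cell anchor dose noise (log2)
    anchor_mature_effect: float = 3.0
    mr_effect_min: float = 1.2     # |log2FC| range of non-anchor MR TFs
    mr_effect_max: float = 2.5
    mr_precdc_noise: float = 0.5  # per-cell dose noise of non-anchor MRs in pre-cDCs
    mr_precdc_attenuation: float = 0.8  # precursor fate effect as fraction of mature
    # cell-level multipliers
    capture_sd_log2: float = 0.25  # capture efficiency, shared by genes and spike-ins
    content_sd_log2: float = 0.10  # RNA content, biological genes only
    batch_multipliers: tuple = (1.0, 1.15, 0.85)
    # dead-cell outliers
    dead_depth_factor: float = 0.05   # 20x lower depth
    dead_mito_fraction: float = 0.5
    # bulk
    bulk_depth_factor: float = 20.0
    bulk_dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0 or self.bulk_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.a1 < 1.0:
            raise ValueError("a1 must be >= 1 (Poisson counting noise floor)")
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be >= 0")
        if not 0 <= self.fate1_fraction <= 1:
            raise ValueError("fate1_fraction must be in [0, 1]")
        if self.delta < 0 or self.sigma_u < 0:
            raise ValueError("delta and sigma_u must be >= 0")
        if self.n_variable_genes < self.n_cdc_signature:
            raise ValueError("n_variable_genes must be >= n_cdc_signature")
        if self.n_mr_tfs < 2:
            raise ValueError("need at least the two anchor MR TFs")
        n_special = (self.n_mito + self.n_mr_tfs + self.n_decoy_tfs
                     + self.n_variable_genes + self.n_precdc_signature
                     + self.n_state_genes)
        if self.n_genes < n_special + 50:
            raise ValueError("n_genes too small for the planted structure")
        for m in self.batch_multipliers:
            if m <= 0:
                raise ValueError("batch multipliers must be positive")
        if not 0 < self.dead_depth_factor <= 1:
            raise ValueError("dead_depth_factor must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("batch_multipliers", "anchor_genes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["batch_multipliers"] = list(self.batch_multipliers)
        data["anchor_genes"] = list(self.anchor_genes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests."""

    populations: pd.Series            # per cell: pre-cDC / cDC1 / cDC2
    fates: pd.Series                  # per pre-cDC cell: pre-cDC1 / pre-cDC2
    dead_cells: list
    variable_genes: list
    mr_tfs: list
    decoy_tfs: list
    anchors: tuple
    mr_doses: pd.DataFrame            # true log2 doses, MR TFs x cells
    de_genes: dict                    # contrast -> planted gene list
    state_genes: list                 # latent cell-state program members
    spikein_abundance: pd.Series      # true mean normalized count per spike-in
    expected_mean: pd.DataFrame       # linear-scale expected mean, genes x populations

    def __eq__(self, other) -> bool:
        if not isinstance(other, SimTruth):
            return NotImplemented
        return (
            self.populations.equals(other.populations)
            and self.fates.equals(other.fates)
            and self.dead_cells == other.dead_cells
            and self.variable_genes == other.variable_genes
            and self.mr_tfs == other.mr_tfs
            and self.decoy_tfs == other.decoy_tfs
            and tuple(self.anchors) == tuple(other.anchors)
            and np.allclose(self.mr_doses.to_numpy(), other.mr_doses.to_numpy())
            and list(self.mr_doses.index) == list(other.mr_doses.index)
            and self.de_genes == other.de_genes
            and self.state_genes == other.state_genes
            and np.allclose(self.spikein_abundance.to_numpy(),
                            other.spikein_abundance.to_numpy())
            and np.allclose(self.expected_mean.to_numpy(),
                            other.expected_mean.to_numpy())
        )


# ---------------------------------------------------------------------------
# gene / cell layout
# ---------------------------------------------------------------------------

def _gene_layout(cfg: SimConfig):
    mito = [f"MT-{i + 1}" for i in range(cfg.n_mito)]
    anchors = list(cfg.anchor_genes)
    other_mr = [f"TF{i + 3:02d}" for i in range(cfg.n_mr_tfs - 2)]
    decoys = [f"TFD{i + 1:02d}" for i in range(cfg.n_decoy_tfs)]
    n_regular = cfg.n_genes - cfg.n_mito - cfg.n_mr_tfs - cfg.n_decoy_tfs
    regular = [f"G{i + 1:05d}" for i in range(n_regular)]
    genes = mito + anchors + other_mr + decoys + regular
    spikes = [f"ERCC-{i + 1:05d}" for i in range(cfg.n_spikeins)]
    return genes, mito, anchors, other_mr, decoys, regular, spikes


def _cell_layout(cfg: SimConfig, rng: np.random.Generator):
    n_total = cfg.n_precdc + cfg.n_cdc1 + cfg.n_cdc2 + cfg.n_dead_cells
    cells = [f"C{i + 1:04d}" for i in range(n_total)]
    pops = (["pre-cDC"] * cfg.n_precdc + ["cDC1"] * cfg.n_cdc1
            + ["cDC2"] * cfg.n_cdc2 + ["pre-cDC"] * cfg.n_dead_cells)
    dead = [False] * (n_total - cfg.n_dead_cells) + [True] * cfg.n_dead_cells
    n_fate1 = int(round(cfg.fate1_fraction * cfg.n_precdc))
    fate_pool = np.array([FATES[0]] * n_fate1
                         + [FATES[1]] * (cfg.n_precdc - n_fate1), dtype=object)
    rng.shuffle(fate_pool)
    # batch design: batch1 = cDCs only, batch2 = pre-cDCs only, batch3 = mixture
    batches = []
    counters = {"pre-cDC": 0, "cDC1": 0, "cDC2": 0}
    halves = {"pre-cDC": cfg.n_precdc // 2, "cDC1": cfg.n_cdc1 // 2,
              "cDC2": cfg.n_cdc2 // 2}
    for pop, is_dead in zip(pops, dead):
        if is_dead:
            batches.append("batch3")
            continue
        first_half = counters[pop] < halves[pop]
        counters[pop] += 1
        if pop == "pre-cDC":
            batches.append("batch2" if first_half else "batch3")
        else:
            batches.append("batch1" if first_half else "batch3")
    return cells, np.array(pops, dtype=object), np.array(dead), fate_pool, batches


def _lognormal_correction(sd_log2: float) -> float:
    """log2 shift that keeps the linear-scale mean at the planted value."""
    return -0.5 * sd_log2 ** 2 * LN2


def _e2x(sd_log2: float) -> float:
    """E[2^X] for X ~ N(0, sd_log2^2)."""
    return float(np.exp(0.5 * (sd_log2 * LN2) ** 2))


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw one single-cell dataset; bit-identical for identical config."""
    rng = np.random.default_rng(cfg.seed)
    genes, mito, anchors, other_mr, decoys, regular, spikes = _gene_layout(cfg)
    cells, pops, dead, fates_pool, batches = _cell_layout(cfg, rng)
    n_cells = len(cells)
    n_genes = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}

    # --- baseline log2 means per gene -------------------------------------
    base = np.empty(n_genes)
    base[:] = np.nan
    for g in mito:
        base[gidx[g]] = cfg.mito_log2_mean
    base[gidx[anchors[0]]] = cfg.anchor_base_log2
    base[gidx[anchors[1]]] = cfg.anchor_base_log2
    for g in other_mr:
        base[gidx[g]] = rng.normal(3.5, 0.8)
    for g in decoys:
        base[gidx[g]] = rng.normal(3.5, 1.0)
    reg_idx = np.array([gidx[g] for g in regular], dtype=int)
    base[reg_idx] = rng.normal(cfg.base_log2_mean_loc, cfg.base_log2_mean_scale,
                               size=reg_idx.size)

    # --- planted gene roles (drawn from regular genes) ---------------------
    perm = rng.permutation(regular)
    cdc_sig = list(perm[:cfg.n_cdc_signature])
    n_extra_var = cfg.n_variable_genes - cfg.n_cdc_signature
    extra_var = list(perm[cfg.n_cdc_signature:cfg.n_cdc_signature + n_extra_var])
    n_used = cfg.n_cdc_signature + n_extra_var
    pre_sig = list(perm[n_used:n_used + cfg.n_precdc_signature])
    n_used += cfg.n_precdc_signature
    state_genes = list(perm[n_used:n_used + cfg.n_state_genes])
    variable_genes = cdc_sig + extra_var
    cdc_sig_idx = np.array([gidx[g] for g in cdc_sig], dtype=int)
    base[cdc_sig_idx] = rng.normal(cfg.sig_log2_mean_loc,
                                   cfg.sig_log2_mean_scale,
                                   size=cdc_sig_idx.size)

    # population offsets (log2), genes x 3 populations
    offs = pd.DataFrame(0.0, index=genes, columns=list(POPULATIONS))
    half = len(cdc_sig) // 2
    offs.loc[cdc_sig[:half], "cDC1"] += cfg.cdc_effect / 2
    offs.loc[cdc_sig[:half], "cDC2"] -= cfg.cdc_effect / 2
    offs.loc[cdc_sig[half:], "cDC1"] -= cfg.cdc_effect / 2
    offs.loc[cdc_sig[half:], "cDC2"] += cfg.cdc_effect / 2
    halfp = len(pre_sig) // 2
    offs.loc[pre_sig[:halfp], "pre-cDC"] += cfg.precdc_effect / 2
    offs.loc[pre_sig[:halfp], ["cDC1", "cDC2"]] -= cfg.precdc_effect / 2
    offs.loc[pre_sig[halfp:], "pre-cDC"] -= cfg.precdc_effect / 2
    offs.loc[pre_sig[halfp:], ["cDC1", "cDC2"]] += cfg.precdc_effect / 2

    # non-anchor MR TFs: fate-correlated dose, random sign and magnitude
    mr_all = anchors + other_mr
    mr_sign = {}
    mr_mag = {}
    for g in other_mr:
        mr_sign[g] = int(rng.choice([-1, 1]))
        mr_mag[g] = float(rng.uniform(cfg.mr_effect_min, cfg.mr_effect_max))
        offs.loc[g, "cDC1"] += mr_sign[g] * mr_mag[g] / 2
        offs.loc[g, "cDC2"] -= mr_sign[g] * mr_mag[g] / 2
    offs.loc[anchors[0], "cDC1"] += cfg.anchor_mature_effect / 2
    offs.loc[anchors[0], "cDC2"] -= cfg.anchor_mature_effect / 2
    offs.loc[anchors[1], "cDC1"] -= cfg.anchor_mature_effect / 2
    offs.loc[anchors[1], "cDC2"] += cfg.anchor_mature_effect / 2

    # --- per-cell log2 mean matrix -----------------------------------------
    # latent cell-state program: per-gene loadings, per-cell factor
    state_idx = np.array([gidx[g] for g in state_genes], dtype=int)
    state_loading = rng.normal(0.0, cfg.state_sd_log2, size=state_idx.size)
    state_corr = np.array([_lognormal_correction(abs(l)) for l in state_loading])

    pop_col = {p: offs[p].to_numpy() for p in POPULATIONS}
    logmean = np.empty((n_genes, n_cells))
    fates = np.array([""] * n_cells, dtype=object)
    pre_counter = 0
    var_idx = np.array([gidx[g] for g in variable_genes], dtype=int)
    var_corr = _lognormal_correction(np.sqrt(np.log1p(cfg.variable_bio_cv ** 2)) / LN2)
    var_sd_log2 = np.sqrt(np.log1p(cfg.variable_bio_cv ** 2)) / LN2
    mr_doses = np.zeros((len(mr_all), n_cells))
    mr_rows = {g: r for r, g in enumerate(mr_all)}

    for j in range(n_cells):
        pop = pops[j]
        col = (base + pop_col[pop]).copy()
        if pop == "pre-cDC":
            if dead[j]:
                fate = ""
            else:
                fate = fates_pool[pre_counter]
                pre_counter += 1
                fates[j] = fate
            s = 1.0 if fate == FATES[0] else -1.0
            # planted variable genes fluctuate fate-independently
            col[var_idx] += (rng.normal(0.0, var_sd_log2, size=var_idx.size)
                             + var_corr)
            # anchor doses: shared activity u moves both, fate moves the ratio
            u = rng.normal(0.0, cfg.sigma_u)
            eps = rng.normal(0.0, cfg.anchor_noise, size=2)
            dose_a = cfg.anchor_base_log2 + u + s * cfg.delta / 4 + eps[0]
            dose_b = cfg.anchor_base_log2 + u - s * cfg.delta / 4 + eps[1]
            col[gidx[anchors[0]]] = dose_a
            col[gidx[anchors[1]]] = dose_b
            mr_doses[mr_rows[anchors[0]], j] = dose_a
            mr_doses[mr_rows[anchors[1]], j] = dose_b
            for g in other_mr:
                dose = (base[gidx[g]]
                        + mr_sign[g] * s * cfg.mr_precdc_attenuation
                        * mr_mag[g] / 2
                        + rng.normal(0.0, cfg.mr_precdc_noise))
                col[gidx[g]] = dose
                mr_doses[mr_rows[g], j] = dose
        else:
            for g in mr_all:
                mr_doses[mr_rows[g], j] = col[gidx[g]]
        h = rng.normal(0.0, 1.0)
        col[state_idx] = col[state_idx] + state_loading * h + state_corr
        logmean[:, j] = col

    # --- dead cells: depth / 20, mitochondrial fraction ~ 50% --------------
    mito_idx = np.array([gidx[g] for g in mito], dtype=int)
    is_mito = np.zeros(n_genes, dtype=bool)
    is_mito[mito_idx] = True
    for j in np.flatnonzero(dead):
        lin = np.exp2(logmean[:, j])
        total = lin.sum()
        m_tot = lin[is_mito].sum()
        scale_non = (1 - cfg.dead_mito_fraction) * total / (total - m_tot)
        scale_mito = cfg.dead_mito_fraction * total / m_tot
        logmean[~is_mito, j] += np.log2(scale_non)
        logmean[is_mito, j] += np.log2(scale_mito)

    # --- cell multipliers ---------------------------------------------------
    capture = np.exp2(rng.normal(0.0, cfg.capture_sd_log2, size=n_cells)
                      + _lognormal_correction(cfg.capture_sd_log2))
    content = np.exp2(rng.normal(0.0, cfg.content_sd_log2, size=n_cells)
                      + _lognormal_correction(cfg.content_sd_log2))
    bmult = {f"batch{i + 1}": m for i, m in enumerate(cfg.batch_multipliers)}
    batch_f = np.array([bmult[b] for b in batches])
    depth = capture * batch_f
    depth[dead] *= cfg.dead_depth_factor

    # --- biological counts: Gamma-Poisson + logistic dropout ----------------
    lam = np.exp2(logmean) * (depth * content)[None, :]
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        lam = lam * rng.gamma(shape, cfg.dispersion, size=lam.shape)
    counts = rng.poisson(lam)
    if cfg.dropout:
        p_det = 1.0 / (1.0 + np.exp(-(cfg.dropout_intercept
                                      + cfg.dropout_slope * logmean)))
        detected = rng.random(size=counts.shape) < p_det
        counts = counts * detected

    # --- spike-ins: cell-constant abundance, CV^2 = a1/mu + alpha0 ----------
    mu_s = np.exp2(rng.uniform(cfg.spikein_log2_min, cfg.spikein_log2_max,
                               size=cfg.n_spikeins))
    mu_s.sort()
    lam_s = mu_s[:, None] * depth[None, :]
    v = np.broadcast_to((cfg.a1 - 1.0) / mu_s[:, None] + cfg.alpha0, lam_s.shape)
    if np.any(v > 0):
        gshape = 1.0 / np.maximum(v, 1e-12)
        noise = np.where(v > 0, rng.gamma(gshape, 1.0 / gshape), 1.0)
        lam_s = lam_s * noise
    spike_counts = rng.poisson(lam_s)

    all_counts = np.vstack([counts, spike_counts]).astype(np.int64)
    all_genes = np.array(genes + spikes, dtype=object)
    flags = pd.DataFrame(
        {
            "is_spikein": [g.startswith("ERCC-") for g in all_genes],
            "is_mito": [g.startswith("MT-") for g in all_genes],
            "is_tf": [g in set(mr_all + decoys) for g in all_genes],
        },
        index=all_genes,
    )
    meta = pd.DataFrame({"batch": batches, "known_type": pops}, index=cells)
    matrix = ExpressionMatrix(counts=all_counts, gene_ids=all_genes,
                              cell_ids=np.array(cells, dtype=object),
                              gene_flags=flags, cell_meta=meta)

    # --- expected linear means per population (healthy cells) ---------------
    expected = pd.DataFrame(index=genes, columns=list(POPULATIONS), dtype=float)
    for p in POPULATIONS:
        expected[p] = np.exp2(base + pop_col[p])
    # variable genes were mean-corrected; anchors and MRs need their own law
    a_mean = (np.exp2(cfg.anchor_base_log2) * _e2x(cfg.sigma_u)
              * _e2x(cfg.anchor_noise) * np.cosh(cfg.delta / 4 * LN2))
    expected.loc[anchors[0], "pre-cDC"] = a_mean
    expected.loc[anchors[1], "pre-cDC"] = a_mean
    for g in other_mr:
        expected.loc[g, "pre-cDC"] = (
            np.exp2(base[gidx[g]]) * _e2x(cfg.mr_precdc_noise)
            * np.cosh(cfg.mr_precdc_attenuation * mr_mag[g] / 2 * LN2))

    truth = SimTruth(
        populations=pd.Series(pops, index=cells, name="population"),
        fates=pd.Series(fates, index=cells, name="fate"),
        dead_cells=[c for c, d in zip(cells, dead) if d],
        variable_genes=sorted(variable_genes),
        mr_tfs=list(mr_all),
        decoy_tfs=list(decoys),
        anchors=tuple(anchors),
        mr_doses=pd.DataFrame(mr_doses, index=mr_all, columns=cells),
        de_genes={
            "cDC1_vs_cDC2": sorted(cdc_sig),
            "pre_vs_cDC": sorted(pre_sig),
        },
        state_genes=sorted(state_genes),
        spikein_abundance=pd.Series(mu_s, index=spikes, name="true_mean"),
        expected_mean=expected,
    )
    return matrix, truth


def simulate_bulk(cfg: SimConfig, n_replicates: int = 3) -> ExpressionMatrix:
    """Bulk replicates per population, NB around the population mean profile."""
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (DE needs replication)")
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    # the expected profile is deterministic given the config
    _, truth = simulate_dataset(cfg)
    profiles = truth.expected_mean
    genes = profiles.index.to_numpy(dtype=object)
    cols, counts = [], []
    for pop in POPULATIONS:
        mean = profiles[pop].to_numpy() * cfg.bulk_depth_factor
        for r in range(n_replicates):
            lam = mean
            if cfg.bulk_dispersion > 0:
                shape = 1.0 / cfg.bulk_dispersion
                lam = mean * rng.gamma(shape, cfg.bulk_dispersion, size=mean.size)
            counts.append(rng.poisson(lam))
            cols.append(f"{pop}_rep{r + 1}")
    counts = np.column_stack(counts).astype(np.int64)
    flags = pd.DataFrame(
        {
            "is_spikein": False,
            "is_mito": [g.startswith("MT-") for g in genes],
            "is_tf": [g in set(truth.mr_tfs + truth.decoy_tfs) for g in genes],
        },
        index=genes,
    )
    meta = pd.DataFrame(
        {"batch": "bulk", "known_type": [c.rsplit("_", 1)[0] for c in cols]},
        index=cols,
    )
    return ExpressionMatrix(counts=counts, gene_ids=genes,
                            cell_ids=np.array(cols, dtype=object),
                            gene_flags=flags, cell_meta=meta)


def make_tf_gmt(truth: SimTruth, cfg: SimConfig, target_fraction: float = 0.4,
                n_background_targets: int = 5) -> GeneSetDB:
    """TF->target gene sets consistent with the planted regulation.

    Each planted MR TF's target set is a random subset of the planted
    cDC1-vs-cDC2 DE genes (its regulon drives the fate signature) plus a
    few background genes; decoy TFs get size-matched random target sets.
    """
    rng = np.random.default_rng(cfg.seed + 7_777_777)
    de = list(truth.de_genes["cDC1_vs_cDC2"])
    pool = [g for g in truth.expected_mean.index
            if g not in set(de) and not g.startswith("MT-")]
    n_de_targets = max(2, int(round(target_fraction * len(de))))
    sets, descriptions = {}, {}
    for tf in truth.mr_tfs:
        targets = list(rng.choice(de, size=n_de_targets, replace=False))
        targets += list(rng.choice(pool, size=n_background_targets, replace=False))
        sets[tf] = frozenset(targets)
        descriptions[tf] = "planted master regulator"
    for tf in truth.decoy_tfs:
        targets = list(rng.choice(pool, size=n_de_targets + n_background_targets,
                                  replace=False))
        sets[tf] = frozenset(targets)
        descriptions[tf] = "decoy regulator (synthetic random targets)"
    return GeneSetDB(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def truth_report(truth: SimTruth, path) -> None:
    """Serialize a SimTruth to JSON; read_truth() round-trips it losslessly."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    payload = {
        "populations": {"index": list(truth.populations.index),
                        "values": list(truth.populations)},
        "fates": {"index": list(truth.fates.index), "values": list(truth.fates)},
        "dead_cells": truth.dead_cells,
        "variable_genes": truth.variable_genes,
        "mr_tfs": truth.mr_tfs,
        "decoy_tfs": truth.decoy_tfs,
        "anchors": list(truth.anchors),
        "mr_doses": {"index": list(truth.mr_doses.index),
                     "columns": list(truth.mr_doses.columns),
                     "values": truth.mr_doses.to_numpy().tolist()},
        "de_genes": truth.de_genes,
        "state_genes": truth.state_genes,
        "spikein_abundance": {"index": list(truth.spikein_abundance.index),
                              "values": truth.spikein_abundance.to_numpy().tolist()},
        "expected_mean": {"index": list(truth.expected_mean.index),
                          "columns": list(truth.expected_mean.columns),
                          "values": truth.expected_mean.to_numpy().tolist()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SimTruth(
        populations=pd.Series(d["populations"]["values"],
                              index=d["populations"]["index"], name="population"),
        fates=pd.Series(d["fates"]["values"], index=d["fates"]["index"],
                        name="fate"),
        dead_cells=d["dead_cells"],
        variable_genes=d["variable_genes"],
        mr_tfs=d["mr_tfs"],
        decoy_tfs=d["decoy_tfs"],
        anchors=tuple(d["anchors"]),
        mr_doses=pd.DataFrame(d["mr_doses"]["values"],
                              index=d["mr_doses"]["index"],
                              columns=d["mr_doses"]["columns"]),
        de_genes={k: list(v) for k, v in d["de_genes"].items()},
        state_genes=d["state_genes"],
        spikein_abundance=pd.Series(d["spikein_abundance"]["values"],
                                    index=d["spikein_abundance"]["index"],
                                    name="true_mean"),
        expected_mean=pd.DataFrame(d["expected_mean"]["values"],
                                   index=d["expected_mean"]["index"],
                                   columns=d["expected_mean"]["columns"]),
    )
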