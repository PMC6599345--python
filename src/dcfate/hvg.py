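"""Spike-in-calibrated detection of biologically variable genes.

Technical noise is modeled on the spike-ins as CV^2 = a1/mu + alpha0,
where mu is the mean of size-factor-normalized counts across cells (the
linear scale, not log).  Each endogenous gene is then tested against the
null hypothesis that its biological coefficient of variation is below a
floor (default 50%): the null CV^2 at the gene's mean is

    CV^2_0(mu) = a1/mu + alpha0 + min_bio_cv^2

and (m - 1) * CV^2_g / CV^2_0 is referred to a chi-squared distribution
with m - 1 degrees of freedom (m = number of cells), upper tail.
Benjamini-Hochberg controls the FDR over the tested genes; the final
selection additionally requires detection in a minimum number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import NormalizedMatrix, bh_adjust, log


@dataclass
class NoiseFit:
    """Coefficients of the technical-noise law CV^2 = a1/mu + alpha0."""

    a1: float
    alpha0: float
    min_mean_quantile: float
    n_spikeins_used: int
    clipped: bool = False
    residual_sd: float = float("nan")

    def technical_cv2(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return self.a1 / mu + self.alpha0


def _cv2_stats(linear: np.ndarray):
    mu = linear.mean(axis=1)
    var = linear.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv2 = np.where(mu > 0, var / mu ** 2, np.nan)
    return mu, cv2


def fit_technical_noise(norm: NormalizedMatrix,
                        min_mean_quantile: float = 0.4,
                        min_spikeins: int = 20) -> NoiseFit:
    """Fit CV^2 = a1/mu + alpha0 on spike-in rows.

    Uses a gamma-family GLM with identity link (CV^2 estimates scale with
    their mean), restricted to spike-ins above the given mean quantile so
    the high-abundance noise floor does not dominate the fit.  If the
    matrix carries no spike-in flags all rows are treated as spike-ins.
    """
    spike = norm.flag("is_spikein")
    sub = norm.subset_genes(spike) if spike.any() else norm
    linear = sub.linear()
    mu, cv2 = _cv2_stats(linear)
    usable = (mu > 0) & np.isfinite(cv2) & (cv2 > 0)
    if usable.sum() < min_spikeins:
        raise ValueError(
            f"only {int(usable.sum())} usable spike-ins (< {min_spikeins})")
    mu_u, cv2_u = mu[usable], cv2[usable]
    if np.ptp(np.log(mu_u)) < 0.7:   # < ~2x spread: 1/mu and 1 collinear
        raise ValueError("spike-in means span too narrow a range; "
                         "fit unidentifiable")
    floor = np.quantile(mu_u, min_mean_quantile)
    keep = mu_u >= floor
    mu_f, cv2_f = mu_u[keep], cv2_u[keep]

    X = np.column_stack([np.ones_like(mu_f), 1.0 / mu_f])
    ols = np.linalg.lstsq(X, cv2_f, rcond=None)[0]
    start = np.clip(ols, 1e-6, None)
    try:
        import warnings

        with warnings.catch_warnings():
            # identity link on a Gamma family is intentional: the noise law
            # is linear in 1/mu with strictly positive fitted values here
            warnings.simplefilter("ignore")
            glm = sm.GLM(cv2_f, X,
                         family=sm.families.Gamma(sm.families.links.Identity()))
            res = glm.fit(start_params=start, maxiter=200)
        alpha0, a1 = float(res.params[0]), float(res.params[1])
        if not np.isfinite([a1, alpha0]).all():
            raise ValueError("non-finite GLM coefficients")
    except Exception as exc:   # fall back to least squares on failure
        log.warning("gamma GLM failed (%s); using least-squares fit", exc)
        alpha0, a1 = float(ols[0]), float(ols[1])
    clipped = a1 < 0 or alpha0 < 0
    if clipped:
        log.warning("noise fit clipped at zero (a1=%.4g, alpha0=%.4g)", a1, alpha0)
    a1, alpha0 = max(a1, 0.0), max(alpha0, 0.0)
    resid = cv2_f - (a1 / mu_f + alpha0)
    return NoiseFit(a1=a1, alpha0=alpha0, min_mean_quantile=min_mean_quantile,
                    n_spikeins_used=int(keep.sum()), clipped=clipped,
                    residual_sd=float(np.std(resid)))


def variable_gene_test(norm: NormalizedMatrix, fit: NoiseFit,
                       min_bio_cv: float = 0.5) -> pd.DataFrame:
    """Per-gene chi-squared test of CV^2 against the technical + floor null.

    Returns one row per endogenous gene: mean, cv2, null_cv2, statistic,
    p, q (BH over tested genes), n_cells_detected and flags.  Genes with
    zero mean are not tested (NaN p, excluded from the BH m).
    """
    m = norm.n_cells
    if m < 10:
        raise ValueError("need at least 10 cells")
    bio = ~norm.flag("is_spikein")
    sub = norm.subset_genes(bio)
    linear = sub.linear()
    mu, cv2 = _cv2_stats(linear)
    detected = (linear > 0).sum(axis=1)
    tested = (mu > 0) & np.isfinite(cv2)
    null_cv2 = np.full(mu.shape, np.nan)
    null_cv2[tested] = fit.technical_cv2(mu[tested]) + min_bio_cv ** 2
    stat = np.full(mu.shape, np.nan)
    stat[tested] = (m - 1) * cv2[tested] / null_cv2[tested]
    p = np.full(mu.shape, np.nan)
    p[tested] = stats.chi2.sf(stat[tested], df=m - 1)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "mean": mu,
            "cv2": cv2,
            "null_cv2": null_cv2,
            "statistic": stat,
            "p": p,
            "q": q,
            "n_cells_detected": detected,
            "tested": tested,
        },
        index=sub.gene_ids,
    )


def select_hvg(table: pd.DataFrame, fdr: float = 0.1,
               min_cells: int = 10) -> list:
    """Significant genes detected in >= min_cells cells, ordered by (q, id)."""
    sel = table[(table["q"] < fdr) & (table["n_cells_detected"] >= min_cells)]
    order = sel.assign(_gene=sel.index.astype(str)).sort_values(["q", "_gene"])
    return list(order.index)
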