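"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

The global test asks whether the observed scatter of outcome effects about
the per-SNP leave-one-out IVW predictions exceeds what sampling error alone
would produce; the null distribution is built by parametric simulation.  The
outlier test localizes the excess to individual SNPs, and the distortion test
asks whether removing the flagged SNPs meaningfully shifts the causal
estimate.

Conventions: empirical p-values use the add-one rule (1+count)/(n_sim+1), so
the smallest attainable p is 1/(n_sim+1); residuals are weighted by
1/sigma_Y^2 so the observed RSS reduces to a Cochran-type scale; one seed
governs the full run with sub-streams split deterministically.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .estimators import MRResult, ivw
from .sumstats import HarmonizedSet


@dataclasses.dataclass
class PressoResult:
    """Global/outlier/distortion outputs plus the outlier-corrected IVW."""

    rss_obs: float
    global_pval: float
    outlier_pvals: np.ndarray
    outlier_ids: list[str]
    distortion_coefficient: float | None
    distortion_pval: float | None
    raw_estimate: MRResult
    corrected_estimate: MRResult | None
    n_sim: int
    seed: int

    @property
    def pval_floor(self) -> float:
        return 1.0 / (self.n_sim + 1)


def _loo_betas(gamma: np.ndarray, Gamma: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for every SNP, closed form.

    Works on 1-D arrays or (n_sim, k) matrices (row-wise)."""
    num = np.sum(w * gamma * Gamma, axis=-1, keepdims=True)
    den = np.sum(w * gamma**2, axis=-1, keepdims=True)
    return (num - w * gamma * Gamma) / (den - w * gamma**2)


def _weighted_sq_resid(gamma, Gamma, w) -> np.ndarray:
    """Per-SNP weighted squared residual about the leave-one-out prediction."""
    b_loo = _loo_betas(gamma, Gamma, w)
    d = Gamma - b_loo * gamma
    return w * d**2


def presso_global(
    h: HarmonizedSet, n_sim: int = 1000, seed: int = 0
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Global pleiotropy test.

    Returns ``(rss_obs, global_pval, obs_sq_resid, sim_sq_resid)`` where
    ``obs_sq_resid`` is the per-SNP weighted squared residual (length k) and
    ``sim_sq_resid`` the (n_sim, k) matrix of simulated counterparts, reused
    by the outlier test so the two are mutually consistent.
    """
    if h.k < 4:
        raise ValueError("PRESSO requires >=4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    w = 1.0 / h.se_y**2
    obs_sq = _weighted_sq_resid(h.gamma, h.Gamma, w)
    rss_obs = float(np.sum(obs_sq))

    b_loo = _loo_betas(h.gamma, h.Gamma, w)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    g_star = rng.normal(h.gamma, h.se_x, size=(n_sim, h.k))
    G_star = rng.normal(b_loo * h.gamma, h.se_y, size=(n_sim, h.k))
    sim_sq = _weighted_sq_resid(g_star, G_star, w)
    rss_star = np.sum(sim_sq, axis=1)
    global_pval = (1 + int(np.sum(rss_star >= rss_obs))) / (n_sim + 1)
    return rss_obs, float(global_pval), obs_sq, sim_sq


def presso_outliers(
    h: HarmonizedSet,
    obs_sq_resid: np.ndarray,
    sim_sq_resid: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Per-SNP outlier test on the residual distributions from the global run.

    Empirical p per SNP, Bonferroni-adjusted over k; SNPs with adjusted
    p < ``alpha`` are flagged, returned in input order.
    """
    n_sim = sim_sq_resid.shape[0]
    counts = np.sum(sim_sq_resid >= obs_sq_resid[None, :], axis=0)
    pvals = (1 + counts) / (n_sim + 1)
    adj = np.minimum(1.0, pvals * h.k)
    outliers = [s for s, p in zip(h.snp_ids, adj) if p < alpha]
    return pvals, outliers


def presso_distortion(
    h: HarmonizedSet,
    outlier_ids: list[str],
    n_sim: int = 1000,
    seed: int = 0,
) -> tuple[float, float, MRResult]:
    """Distortion test and outlier-corrected estimate.

    Corrected estimate: fixed-effect IVW on the non-outliers.  Distortion
    coefficient: 100*(beta_raw - beta_corrected)/|beta_corrected|.  The null
    removes |outliers| SNPs uniformly at random and recomputes the
    coefficient; the p-value is the two-sided empirical tail.
    """
    if not outlier_ids:
        raise ValueError("no outliers to correct for")
    if h.k - len(outlier_ids) < 2:
        raise ValueError("no instruments remain")
    raw, _ = ivw(h, model="fixed")
    corrected, _ = ivw(h.drop(outlier_ids), model="fixed")
    coef = 100.0 * (raw.beta - corrected.beta) / abs(corrected.beta)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    m = len(outlier_ids)
    coefs = np.empty(n_sim)
    for i in range(n_sim):
        drop = rng.choice(h.snp_ids, size=m, replace=False)
        b_rand, _ = ivw(h.drop(drop), model="fixed")
        coefs[i] = 100.0 * (raw.beta - b_rand.beta) / abs(b_rand.beta)
    pval = (1 + int(np.sum(np.abs(coefs) >= abs(coef)))) / (n_sim + 1)
    return float(coef), float(pval), corrected


def run_presso(
    h: HarmonizedSet, n_sim: int = 1000, seed: int = 0, alpha: float = 0.05
) -> PressoResult:
    """Full PRESSO pipeline: global test, outlier test, distortion test."""
    rss_obs, global_pval, obs_sq, sim_sq = presso_global(h, n_sim, seed)
    outlier_pvals, outlier_ids = presso_outliers(h, obs_sq, sim_sq, alpha)
    raw, _ = ivw(h, model="fixed")
    coef = dist_p = corrected = None
    if outlier_ids and h.k - len(outlier_ids) >= 2:
        coef, dist_p, corrected = presso_distortion(h, outlier_ids, n_sim, seed)
    return PressoResult(
        rss_obs, global_pval, outlier_pvals, outlier_ids,
        coef, dist_p, raw, corrected, n_sim, seed,
    )
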