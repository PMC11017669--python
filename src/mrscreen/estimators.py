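"""Causal estimators and diagnostics for two-sample summary-data MR.

Given harmonized per-SNP effects (gamma_j on the exposure, Gamma_j on the
outcome, with SEs sigma_Xj, sigma_Yj), the suite computes:

* per-SNP Wald ratios Gamma_j / gamma_j with first-order SEs;
* inverse-variance-weighted (IVW) estimate — the zero-intercept weighted
  regression slope of Gamma on gamma with weights 1/sigma_Y^2 — under a
  fixed-effect or multiplicative random-effects model, chosen automatically
  from Cochran's Q and I^2 (heterogeneity when Q-p < 0.05 and I^2 > 25%);
* MR-Egger weighted regression with intercept (directional-pleiotropy test);
* the weighted median of Wald ratios with parametric-bootstrap SE, consistent
  when valid instruments carry a majority of the weight;
* leave-one-out IVW influence analysis;
* the Steiger directionality test comparing instrument variance explained in
  exposure versus outcome.

Normal reference distributions are used for IVW and weighted-median p-values;
Egger uses t with k-2 df, with multiplicative residual dispersion floored
at 1 — the conventions of the originating method literature.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import variance_explained
from .sumstats import HarmonizedSet

#: two-sided 95% normal multiplier
Z95 = 1.959964


@dataclasses.dataclass
class MRResult:
    """One estimator's causal estimate with uncertainty."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    model_note: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI does not bracket the estimate")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclasses.dataclass
class HeterogeneityStats:
    """Cochran's Q across Wald ratios and its I^2 percentage form."""

    Q: float
    df: int
    pval: float
    i2: float


@dataclasses.dataclass
class PleiotropyStats:
    """Egger intercept: a nonzero value signals directional pleiotropy."""

    intercept: float
    se: float
    pval: float


@dataclasses.dataclass
class SteigerResult:
    """Directionality check: does the instrument explain more variance in the
    exposure than in the outcome?"""

    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    pval: float


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP causal ratios Gamma_j/gamma_j and first-order SEs sigma_Yj/|gamma_j|."""
    zero = np.flatnonzero(h.gamma == 0)
    if zero.size:
        raise ValueError(f"zero exposure effect for SNP(s): {[h.snp_ids[i] for i in zero]}")
    return h.Gamma / h.gamma, h.se_y / np.abs(h.gamma)


def cochran_q(h: HarmonizedSet, beta: float) -> HeterogeneityStats:
    """Cochran's Q of the Wald ratios about ``beta`` with IVW weights."""
    ratios, _ = wald_ratios(h)
    w = h.gamma**2 / h.se_y**2
    Q = float(np.sum(w * (ratios - beta) ** 2))
    df = h.k - 1
    pval = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    i2 = max(0.0, (Q - df) / Q) * 100 if Q > 0 else 0.0
    return HeterogeneityStats(Q, df, pval, i2)


def ivw(h: HarmonizedSet, model: str = "auto") -> tuple[MRResult, HeterogeneityStats]:
    """Inverse-variance-weighted estimate.

    Fixed-effect: beta = sum(gamma*Gamma/sigma_Y^2) / sum(gamma^2/sigma_Y^2),
    SE = 1/sqrt(sum(gamma^2/sigma_Y^2)).  Under ``model='auto'`` the SE is
    inflated by max(1, sqrt(Q/df)) (multiplicative random effects) when the
    heterogeneity rule fires (Q-p < 0.05 and I^2 > 25%); ``model='random'``
    always inflates, ``model='fixed'`` never.  k = 1 degrades to the single
    Wald ratio.
    """
    if model not in ("auto", "fixed", "random"):
        raise ValueError("model must be auto, fixed or random")
    if h.k == 0:
        raise ValueError("no instruments")
    if h.k == 1:
        ratios, ses = wald_ratios(h)
        beta, se = float(ratios[0]), float(ses[0])
        res = MRResult(
            "wald_ratio", beta, se, beta - Z95 * se, beta + Z95 * se,
            _normal_p(beta / se), 1, "single instrument",
        )
        return res, HeterogeneityStats(0.0, 0, 1.0, 0.0)

    w = h.gamma**2 / h.se_y**2
    beta = float(np.sum(h.gamma * h.Gamma / h.se_y**2) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    het = cochran_q(h, beta)

    heterogeneous = het.pval < 0.05 and het.i2 > 25.0
    if model == "random" or (model == "auto" and heterogeneous):
        se = se_fixed * max(1.0, np.sqrt(het.Q / het.df))
        method, note = "ivw_random", "random-effects (heterogeneity detected)" \
            if heterogeneous else "random-effects (forced)"
    else:
        se = se_fixed
        method, note = "ivw_fixed", "fixed-effect"
    res = MRResult(
        method, beta, se, beta - Z95 * se, beta + Z95 * se,
        _normal_p(beta / se), h.k, note,
    )
    return res, het


def egger(h: HarmonizedSet) -> tuple[MRResult, PleiotropyStats]:
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    Each SNP is oriented so gamma_j >= 0 before fitting (the intercept's sign
    is otherwise coding-dependent).  Weights 1/sigma_Y^2; slope and intercept
    SEs carry multiplicative residual dispersion floored at 1 and are tested
    against t with k-2 df.
    """
    if h.k < 3:
        raise ValueError("Egger requires >=3 instruments")
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    x = h.gamma * sign
    y = h.Gamma * sign
    w = 1.0 / h.se_y**2

    # weighted normal equations for [intercept, slope]
    sw, swx, swx2 = np.sum(w), np.sum(w * x), np.sum(w * x**2)
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    det = sw * swx2 - swx**2
    intercept = (swx2 * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det

    resid = y - intercept - slope * x
    df = h.k - 2
    disp = max(1.0, float(np.sum(w * resid**2) / df))
    se_slope = float(np.sqrt(disp * sw / det))
    se_int = float(np.sqrt(disp * swx2 / det))

    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), df))
    res = MRResult(
        "egger", float(slope), se_slope,
        float(slope - Z95 * se_slope), float(slope + Z95 * se_slope),
        p_slope, h.k, f"dispersion={disp:.3g}",
    )
    return res, PleiotropyStats(float(intercept), se_int, p_int)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by the standard percentile convention: cumulative
    weight minus half the step, linear interpolation at 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(v[0])
    if s[-1] < 0.5:
        return float(v[-1])
    below = int(np.max(np.flatnonzero(s < 0.5)))
    if below == len(v) - 1:
        return float(v[-1])
    frac = (0.5 - s[below]) / (s[below + 1] - s[below])
    return float(v[below] + (v[below + 1] - v[below]) * frac)


def weighted_median_point(h: HarmonizedSet) -> float:
    """Point estimate only: weighted median of the Wald ratios with inverse-
    variance weights gamma^2/sigma_Y^2."""
    ratios, _ = wald_ratios(h)
    w = h.gamma**2 / h.se_y**2
    return _weighted_median(ratios, w)


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted median estimator with parametric-bootstrap SE.

    The estimate is robust to invalid instruments carrying up to half of the
    total weight.  SE: resample gamma*_j ~ N(gamma_j, sigma_Xj) and
    Gamma*_j ~ N(Gamma_j, sigma_Yj) ``n_boot`` times, recompute the weighted
    median of the resampled ratios (weights held fixed), and take the SD.
    """
    if h.k < 3:
        raise ValueError("weighted median requires >=3 instruments")
    beta = weighted_median_point(h)
    w = h.gamma**2 / h.se_y**2
    rng = np.random.default_rng(seed)
    g_star = rng.normal(h.gamma, h.se_x, size=(n_boot, h.k))
    G_star = rng.normal(h.Gamma, h.se_y, size=(n_boot, h.k))
    boots = np.array(
        [_weighted_median(G_star[b] / g_star[b], w) for b in range(n_boot)]
    )
    se = float(np.std(boots, ddof=1))
    return MRResult(
        "weighted_median", beta, se, beta - Z95 * se, beta + Z95 * se,
        _normal_p(beta / se) if se > 0 else 1.0, h.k, f"n_boot={n_boot}",
    )


def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """IVW (model=auto) recomputed with each SNP dropped in turn.

    Returns one row per dropped SNP with the remaining-set estimate, plus a
    ``sign_consistent`` flag: whether the row's CI excludes zero on the same
    side as the full-set estimate.
    """
    if h.k < 3:
        raise ValueError("leave-one-out requires >=3 instruments")
    full, _ = ivw(h, model="auto")
    rows = []
    for snp in list(h.snp_ids):
        sub = h.drop([snp])
        res, _ = ivw(sub, model="auto")
        sign_ok = (res.ci_low > 0) if full.beta > 0 else (res.ci_high < 0)
        rows.append(
            {
                "dropped_snp": snp,
                "method": res.method,
                "beta": res.beta,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "pval": res.pval,
                "k": res.k,
                "delta_beta": res.beta - full.beta,
                "sign_consistent": bool(sign_ok),
            }
        )
    return pd.DataFrame(rows)


def steiger(h: HarmonizedSet) -> SteigerResult:
    """Directionality test: summed instrument r^2 in exposure vs outcome.

    The two summed correlations are compared on the Fisher-z scale,
    z = atanh(sqrt(r^2)), with variance 1/(n_exp-3) + 1/(n_out-3); a small p
    with r2_exposure > r2_outcome supports the exposure -> outcome direction.
    """
    if h.n_exp <= 3 or h.n_out <= 3:
        raise ValueError("Steiger requires sample sizes > 3")
    r2_exp = float(np.sum(variance_explained(h.gamma, h.se_x, h.n_exp)))
    r2_out = float(np.sum(variance_explained(h.Gamma, h.se_y, h.n_out)))
    if r2_exp >= 1 or r2_out >= 1:
        raise ValueError("summed variance explained >= 1")
    z = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
    var = 1.0 / (h.n_exp - 3) + 1.0 / (h.n_out - 3)
    pval = _normal_p(z / np.sqrt(var))
    return SteigerResult(r2_exp, r2_out, r2_exp > r2_out, pval)
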