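"""Causal-effect estimators for a harmonized instrument set.

Five methods: per-SNP Wald ratio, inverse-variance-weighted (IVW) meta-
analysis, MR-Egger regression, weighted median, and weighted mode. All report
the effect on the outcome's beta scale (log odds for binary outcomes) plus
the odds-ratio transform exp(beta) with a 95% Wald interval.

Conventions: IVW defaults to multiplicative random effects (the fixed-effect
SE scaled by the residual standard deviation, floored at 1) with a normal
p-value. MR-Egger uses weighted least squares with a free intercept, gammas
oriented non-negative, the same multiplicative SE floor, and t-distributed
p-values on nsnp-2 degrees of freedom — the usual small-sample treatment for
the regression-based estimator. Weighted median and mode standard errors come
from a seeded parametric bootstrap (resampling gamma-hat and Gamma-hat from
their normal sampling distributions).

Minimum instrument counts: Wald 1, IVW 2, Egger 3, median/mode 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedSet
from .instruments import InsufficientInstrumentsError

#: z for a two-sided 95% interval
Z95 = 1.959964

MIN_SNPS = {"wald": 1, "ivw": 2, "egger": 3, "weighted_median": 3, "weighted_mode": 3}


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with OR-scale confidence interval."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    or_value: float
    ci_low: float
    ci_high: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None


def beta_to_or(beta: float, se: float, z: float = Z95) -> tuple[float, float, float]:
    """exp-transform a log-scale estimate to (OR, CI low, CI high)."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _estimate(method: str, beta: float, se: float, pval: float, nsnp: int,
              **extra) -> MREstimate:
    or_value, lo, hi = beta_to_or(beta, se)
    return MREstimate(method=method, beta=float(beta), se=float(se), pval=float(pval),
                      nsnp=int(nsnp), or_value=or_value, ci_low=lo, ci_high=hi, **extra)


def _require(hset: HarmonizedSet, method: str) -> None:
    need = MIN_SNPS[method]
    if hset.nsnp < need:
        hint = "; use wald_ratio for a single instrument" if method == "ivw" else ""
        raise InsufficientInstrumentsError(
            f"{method} needs >= {need} instruments, got {hset.nsnp}{hint}"
        )


def wald_ratio(gamma: float, Gamma: float, se_Gamma: float) -> MREstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order delta SE."""
    if gamma == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return _estimate("wald", beta, se, p, 1)


def ivw(hset: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of Gamma on
    gamma through the origin with weights 1/se_Gamma^2."""
    if mode not in {"fixed", "multiplicative_random"}:
        raise ValueError(f"unknown IVW mode {mode!r}")
    _require(hset, "ivw")
    g, G, sG = hset.gamma, hset.Gamma, hset.se_Gamma
    w = 1.0 / sG**2
    denom = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / denom
    se = np.sqrt(1.0 / denom)
    if mode == "multiplicative_random":
        resid_sd = np.sqrt(np.sum(w * (G - beta * g) ** 2) / (hset.nsnp - 1))
        se *= max(1.0, resid_sd)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return _estimate("ivw", beta, se, p, hset.nsnp)


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger: WLS of Gamma on gamma with a free intercept estimating the
    average directional pleiotropy; gammas oriented non-negative first."""
    _require(hset, "egger")
    flip = np.sign(hset.gamma)
    flip[flip == 0] = 1.0
    g = hset.gamma * flip
    G = hset.Gamma * flip
    w = 1.0 / hset.se_Gamma**2
    fit = sm.WLS(G, sm.add_constant(g), weights=w).fit()
    scale = float(fit.scale)  # weighted residual variance, df = nsnp - 2
    infl = max(1.0, np.sqrt(scale))
    # unscaled (fixed-effect) SEs; robust to an exact fit where scale == 0
    base_se = np.sqrt(np.diag(fit.normalized_cov_params))
    se = base_se * infl
    df = hset.nsnp - 2
    alpha_hat, beta_hat = float(fit.params[0]), float(fit.params[1])
    p_slope = 2 * stats.t.sf(abs(beta_hat) / se[1], df)
    p_int = 2 * stats.t.sf(abs(alpha_hat) / se[0], df)
    return _estimate(
        "egger", beta_hat, float(se[1]), p_slope, hset.nsnp,
        egger_intercept=alpha_hat,
        egger_intercept_se=float(se[0]),
        egger_intercept_pval=float(p_int),
    )


def _weighted_median(betas: np.ndarray, weights: np.ndarray) -> float:
    # secondary sort on weight makes tied ratios order-independent
    order = np.lexsort((weights, betas))
    b = betas[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, b))


def _bootstrap_se(hset: HarmonizedSet, point_fn, reps: int, seed: int) -> float:
    """Parametric bootstrap SD of a ratio-based point estimator."""
    if reps < 2:
        raise ValueError("bootstrap needs at least 2 replicates")
    rng = np.random.default_rng(seed)
    n = hset.nsnp
    g = hset.gamma + rng.standard_normal((reps, n)) * hset.se_gamma
    G = hset.Gamma + rng.standard_normal((reps, n)) * hset.se_Gamma
    w = g**2 / hset.se_Gamma**2
    with np.errstate(divide="ignore", invalid="ignore"):
        ests = np.array([point_fn(G[k] / g[k], w[k]) for k in range(reps)])
    ests = ests[np.isfinite(ests)]  # a resampled gamma can land on 0
    return float(ests.std(ddof=1))


def weighted_median(hset: HarmonizedSet, bootstrap_reps: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimator: consistent when instruments carrying up to
    half the weight are invalid. SE from a seeded parametric bootstrap."""
    _require(hset, "weighted_median")
    ratios = hset.Gamma / hset.gamma
    w = hset.gamma**2 / hset.se_Gamma**2
    beta = _weighted_median(ratios, w)
    se = _bootstrap_se(hset, _weighted_median, bootstrap_reps, seed)
    p = 2 * stats.norm.sf(abs(beta) / max(se, np.finfo(float).tiny))
    return _estimate("weighted_median", beta, se, p, hset.nsnp)


def _mode_bandwidth(betas: np.ndarray, factor: float) -> float:
    n = len(betas)
    sd = betas.std(ddof=1)
    mad = 1.4826 * np.median(np.abs(betas - np.median(betas)))
    s = 0.9 * min(sd, mad if mad > 0 else sd) * n ** (-0.2)
    return factor * s


def _weighted_mode_point(betas: np.ndarray, weights: np.ndarray,
                         factor: float = 1.0) -> float:
    bw = _mode_bandwidth(betas, factor)
    if not np.isfinite(bw) or bw <= 0:
        return float(np.median(betas))
    grid = np.linspace(betas.min() - 3 * bw, betas.max() + 3 * bw, 512)
    dens = (weights[:, None] * np.exp(-0.5 * ((grid - betas[:, None]) / bw) ** 2)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(hset: HarmonizedSet, bandwidth_factor: float = 1.0,
                  bootstrap_reps: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimator: mode of the weighted Gaussian-kernel density
    of the per-SNP ratios (modified-Silverman bandwidth scaled by
    ``bandwidth_factor``); consistent when the largest weight-share of
    instruments with a common ratio are valid."""
    _require(hset, "weighted_mode")
    ratios = hset.Gamma / hset.gamma
    w = hset.gamma**2 / hset.se_Gamma**2
    beta = _weighted_mode_point(ratios, w, bandwidth_factor)
    se = _bootstrap_se(
        hset, lambda b, ww: _weighted_mode_point(b, ww, bandwidth_factor),
        bootstrap_reps, seed,
    )
    p = 2 * stats.norm.sf(abs(beta) / max(se, np.finfo(float).tiny))
    return _estimate("weighted_mode", beta, se, p, hset.nsnp)


def all_estimates(hset: HarmonizedSet, seed: int = 0) -> list[MREstimate]:
    """Every estimator whose minimum instrument count is met, IVW first."""
    out: list[MREstimate] = []
    if hset.nsnp >= 2:
        out.append(ivw(hset))
    elif hset.nsnp == 1:
        out.append(wald_ratio(hset.gamma[0], hset.Gamma[0], hset.se_Gamma[0]))
    if hset.nsnp >= 3:
        out.append(egger(hset))
        out.append(weighted_median(hset, seed=seed))
        out.append(weighted_mode(hset, seed=seed))
    return out
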