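"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Implements Cochran's Q on the Wald ratios, the MR-Egger intercept test, the
MR-PRESSO residual-sum simulation battery (global test, per-SNP outlier test,
optional distortion test, and IVW re-analysis after outlier removal), and
leave-one-out IVW.

MR-PRESSO works on the leave-one-out residual sum of squares
``RSS = sum_j (Gamma_j - b_(-j) * gamma_j)^2`` where ``b_(-j)`` is the IVW
slope fitted without SNP j. Its null distribution is built by parametric
simulation: draw gamma* and Gamma* from the observed sampling distributions
around the leave-one-out fit, recompute RSS, and compare. All simulation is
seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MREstimate, egger, ivw
from .harmonize import HarmonizedSet
from .instruments import InsufficientInstrumentsError


@dataclass(frozen=True)
class PressoParams:
    n_simulations: int = 1000
    outlier_alpha: float = 0.05
    seed: int = 0
    run_distortion: bool = True

    def __post_init__(self) -> None:
        if self.n_simulations < 100:
            raise ValueError("n_simulations must be >= 100")
        if not (0 < self.outlier_alpha < 1):
            raise ValueError("outlier_alpha must lie in (0,1)")


@dataclass
class PressoResult:
    rss_observed: float
    global_pval: float
    outlier_table: list[tuple[str, float]]  # (variant_id, Bonferroni-adjusted p)
    outliers: list[str]
    distortion_pval: float | None
    ivw_after_removal: MREstimate | None


@dataclass
class SensitivityReport:
    """Per exposure-outcome diagnostics backing the P_Q / Egger intercept /
    P_intercept / MR-PRESSO report columns. Fields are None when the set is
    too small for the corresponding test."""

    nsnp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_pval: float | None = None
    ivw_after_removal: MREstimate | None = None
    loo_table: list[tuple[str, MREstimate]] = field(default_factory=list)
    loo_flag: bool | None = None


def cochran_q(hset: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over the Wald ratios with weights gamma^2/se_Gamma^2;
    upper chi-square tail on nsnp-1 df."""
    if hset.nsnp < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 instruments, got {hset.nsnp}")
    ratios = hset.Gamma / hset.gamma
    w = hset.gamma**2 / hset.se_Gamma**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = hset.nsnp - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept, its SE and two-sided p; p > 0.05 is read as no
    evidence of directional horizontal pleiotropy."""
    est = egger(hset)
    return est.egger_intercept, est.egger_intercept_se, est.egger_intercept_pval


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope excluding each SNP in turn (vectorized over the last axis)."""
    num = (w * g * G).sum(axis=-1, keepdims=True) - w * g * G
    den = (w * g * g).sum(axis=-1, keepdims=True) - w * g * g
    return num / den


def run_presso(hset: HarmonizedSet, params: PressoParams | None = None) -> PressoResult:
    """Full MR-PRESSO battery with one shared simulation stream, so the
    global and outlier tests are mutually consistent for a given seed."""
    params = params or PressoParams()
    n = hset.nsnp
    if n < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {n}")
    g, G = hset.gamma, hset.Gamma
    sg, sG = hset.se_gamma, hset.se_Gamma
    w = 1.0 / sG**2

    b_loo = _loo_slopes(g, G, w)
    resid2_obs = (G - b_loo * g) ** 2
    rss_obs = float(resid2_obs.sum())

    rng = np.random.default_rng(params.seed)
    k = params.n_simulations
    g_star = g + rng.standard_normal((k, n)) * sg
    G_star = b_loo * g + rng.standard_normal((k, n)) * sG
    b_loo_star = _loo_slopes(g_star, G_star, w)
    resid2_star = (G_star - b_loo_star * g_star) ** 2
    rss_star = resid2_star.sum(axis=1)

    global_p = (1 + int((rss_star >= rss_obs).sum())) / (1 + k)

    per_snp_p = (1 + (resid2_star >= resid2_obs).sum(axis=0)) / (1 + k)
    adj = np.minimum(per_snp_p * n, 1.0)
    ids = hset.variant_ids
    table = list(zip(ids.tolist(), adj.tolist()))
    outliers = [vid for vid, p in table if p < params.outlier_alpha]

    ivw_after = None
    distortion_p = None
    if outliers:
        keep = ~np.isin(ids, outliers)
        if keep.sum() >= 2:
            ivw_after = ivw(hset.subset(keep))
            if params.run_distortion and keep.sum() < n:
                distortion_p = _distortion_test(hset, keep, rng)
    return PressoResult(rss_obs, float(global_p), table, outliers, distortion_p, ivw_after)


def _distortion_test(hset: HarmonizedSet, keep: np.ndarray,
                     rng: np.random.Generator, n_draws: int = 1000) -> float:
    """Distortion test: is the shift in IVW beta after outlier removal larger
    than expected from removing the same number of SNPs at random?"""
    beta_all = ivw(hset).beta
    beta_no_out = ivw(hset.subset(keep)).beta
    obs = abs(beta_no_out - beta_all)
    n = hset.nsnp
    n_remove = int(n - keep.sum())
    g, G, sG = hset.gamma, hset.Gamma, hset.se_Gamma
    w = 1.0 / sG**2
    draws = np.empty(n_draws)
    for i in range(n_draws):
        drop = rng.choice(n, size=n_remove, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[drop] = False
        draws[i] = (w[mask] * g[mask] * G[mask]).sum() / (w[mask] * g[mask] ** 2).sum()
    null = np.abs(draws - beta_all)
    return float((1 + (null >= obs).sum()) / (1 + n_draws))


def presso_global(hset: HarmonizedSet, params: PressoParams | None = None) -> tuple[float, float]:
    """(observed RSS, global p) from the MR-PRESSO simulation test."""
    res = run_presso(hset, params)
    return res.rss_observed, res.global_pval


def presso_outliers(hset: HarmonizedSet, params: PressoParams | None = None) -> list[tuple[str, float]]:
    """Per-SNP Bonferroni-adjusted outlier p-values (all SNPs, flagged or not)."""
    return run_presso(hset, params).outlier_table


def presso_rerun_ivw(hset: HarmonizedSet, outliers: list[str]) -> MREstimate:
    """IVW on the set with the flagged outliers removed."""
    keep = ~np.isin(hset.variant_ids, list(outliers))
    if keep.sum() < 2:
        raise InsufficientInstrumentsError("fewer than 2 instruments remain after outlier removal")
    return ivw(hset.subset(keep))


def leave_one_out(hset: HarmonizedSet, alpha: float = 0.05
                  ) -> tuple[list[tuple[str, MREstimate]], bool]:
    """IVW omitting each SNP in turn. The flag is raised when any single
    omission flips the sign of beta or moves p across ``alpha`` relative to
    the full-set estimate — i.e. the association is driven by one variant."""
    if hset.nsnp < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 3 instruments, got {hset.nsnp}")
    full = ivw(hset)
    table = []
    flag = False
    mask = np.ones(hset.nsnp, dtype=bool)
    for j in range(hset.nsnp):
        mask[j] = False
        est = ivw(hset.subset(mask))
        mask[j] = True
        table.append((str(hset.variant_ids[j]), est))
        if np.sign(est.beta) != np.sign(full.beta):
            flag = True
        if (est.pval < alpha) != (full.pval < alpha):
            flag = True
    return table, flag


def sensitivity_report(hset: HarmonizedSet,
                       presso_params: PressoParams | None = None) -> SensitivityReport:
    """Run every diagnostic the instrument count allows."""
    rep = SensitivityReport(nsnp=hset.nsnp)
    if hset.nsnp >= 2:
        rep.q_stat, rep.q_df, rep.q_pval = cochran_q(hset)
    if hset.nsnp >= 3:
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_pval = \
            egger_intercept_test(hset)
        rep.loo_table, rep.loo_flag = leave_one_out(hset)
    if hset.nsnp >= 4:
        res = run_presso(hset, presso_params)
        rep.presso_global_pval = res.global_pval
        rep.presso_outliers = res.outliers
        rep.presso_distortion_pval = res.distortion_pval
        rep.ivw_after_removal = res.ivw_after_removal
    return rep
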