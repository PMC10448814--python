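"""Synthetic two-sample (and three-trait mediation) GWAS summary statistics.

The generator instantiates the linear instrumental-variable model that
two-sample MR assumes: per-variant exposure effects gamma_j, outcome effects
``beta * gamma_j + alpha_j`` where alpha_j is a direct (horizontally
pleiotropic) effect, and sampling noise with the standard unit-variance-trait
approximation ``var = 1 / (2 f (1-f) n)`` so standard errors carry the
allele-frequency and sample-size dependence of real summary statistics.

Instrument effects are drawn half-normal (|N(0, sd^2)|): summary statistics
enter MR with the effect allele oriented to increase the exposure, and a
directional pleiotropy scenario is only meaningful against oriented
instruments. Pleiotropy modes:

``none``
    alpha_j = 0 everywhere (all instruments valid).
``balanced``
    alpha_j ~ N(0, pleiotropy_sd^2) on the invalid subset.
``directional``
    alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2) on the invalid subset;
    InSIDE still holds (alpha independent of gamma).
``inside_violation``
    alpha_j = inside_rho * gamma_j + N(0, pleiotropy_sd^2), correlating
    instrument strength with the direct effect.

The reference panel uses a latent multivariate-normal threshold model:
within blocks of ``ld_block_size`` variants the latent haplotype values are
exchangeable-correlated at ``ld_rho``, then dichotomized at the quantile of
each variant's allele frequency; dosage = sum of two haplotypes. Blocks are
independent, giving near-zero cross-block LD.

A single seed drives everything; per-trait child streams are derived
deterministically so adding a mediator never perturbs the exposure draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import GwasConfigError, GwasTable, ReferencePanel

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: child-stream order is part of the on-disk contract: exposure draws are
#: identical whether or not a mediator is requested
_STREAMS = ("structure", "exposure", "outcome", "mediator", "panel", "encoding")


@dataclass(frozen=True)
class MediatorSpec:
    """Effects defining the causal path exposure -> mediator -> outcome."""

    beta2_true: float  # exposure -> mediator
    beta3_true: float  # mediator -> outcome
    mediator_n: int = 100_000


@dataclass(frozen=True)
class SimulationConfig:
    n_variants: int = 200
    n_instruments: int = 20
    causal_effect: float = 0.0  # direct effect of exposure on outcome
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violation
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_rho: float = 0.5
    invalid_fraction: float = 1.0
    exposure_n: int = 20_000
    outcome_n: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_effect_sd: float = 0.1
    ld_block_size: int = 1
    ld_rho: float = 0.0
    n_panel: int = 500
    palindromic_fraction: float = 0.15
    allele_swap_fraction: float = 0.5
    strand_flip_fraction: float = 0.0
    mediator_spec: MediatorSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments > self.n_variants:
            raise GwasConfigError("n_instruments exceeds n_variants")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise GwasConfigError(f"degenerate maf_range {self.maf_range}")
        if self.pleiotropy_mode not in {"none", "balanced", "directional", "inside_violation"}:
            raise GwasConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        for name in ("invalid_fraction", "palindromic_fraction",
                     "allele_swap_fraction", "strand_flip_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise GwasConfigError(f"{name} must lie in [0,1], got {v}")
        if not (0 <= self.ld_rho < 1):
            raise GwasConfigError("ld_rho must lie in [0,1)")
        if self.ld_block_size < 1 or self.pleiotropy_sd < 0:
            raise GwasConfigError("ld_block_size >= 1 and pleiotropy_sd >= 0 required")


@dataclass(frozen=True)
class TruthRecord:
    variant_id: str
    gamma_true: float
    alpha_true: float
    is_invalid: bool


@dataclass(frozen=True)
class MediationTruth:
    beta1_true: float  # total effect = direct + beta2*beta3
    beta2_true: float
    beta3_true: float
    direct_effect: float


class TwoSampleData(NamedTuple):
    exposure: GwasTable
    outcome: GwasTable
    truth: list[TruthRecord]
    panel: ReferencePanel


class MediationTriplet(NamedTuple):
    exposure: GwasTable
    mediator: GwasTable
    outcome: GwasTable
    truth: MediationTruth
    panel: ReferencePanel


def sampling_se(maf: np.ndarray, n: float) -> np.ndarray:
    """SE of a per-allele effect on a unit-variance trait: sqrt(1/(2 f (1-f) n))."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.nextafter(0.0, 1.0))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _structure(config: SimulationConfig, rng: np.random.Generator):
    """Variant ids, positions, MAFs, true gammas/alphas shared by all traits."""
    m = config.n_variants
    ids = np.array([f"rs{100000 + j}" for j in range(m)])
    block = np.arange(m) // config.ld_block_size
    within = np.arange(m) % config.ld_block_size
    # blocks separated far beyond any clumping window; 5 kb spacing inside
    pos = 1_000_000 + block * 20_000_000 + within * 5_000
    maf = rng.uniform(*config.maf_range, size=m)

    gamma = np.zeros(m)
    idx = np.sort(rng.choice(m, size=config.n_instruments, replace=False))
    gamma[idx] = np.abs(rng.normal(0.0, config.instrument_effect_sd, size=config.n_instruments))

    alpha = np.zeros(m)
    invalid = np.zeros(m, dtype=bool)
    if config.pleiotropy_mode != "none" and config.n_instruments:
        k = int(round(config.invalid_fraction * config.n_instruments))
        chosen = rng.choice(idx, size=k, replace=False) if k else np.array([], dtype=int)
        invalid[chosen] = True
        if config.pleiotropy_mode == "balanced":
            alpha[chosen] = rng.normal(0.0, config.pleiotropy_sd, size=k)
        elif config.pleiotropy_mode == "directional":
            alpha[chosen] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k)
        else:  # inside_violation
            alpha[chosen] = (config.inside_rho * gamma[chosen]
                             + rng.normal(0.0, config.pleiotropy_sd, size=k))
    return ids, pos, maf, gamma, alpha, invalid


def _alleles(m: int, palindromic_fraction: float, rng: np.random.Generator):
    pal = rng.random(m) < palindromic_fraction
    ea = np.empty(m, dtype="<U1")
    oa = np.empty(m, dtype="<U1")
    pick_pal = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    pick_non = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    for j in range(m):
        ea[j], oa[j] = (_PALINDROMIC_PAIRS[pick_pal[j]] if pal[j]
                        else _NONPALINDROMIC_PAIRS[pick_non[j]])
    return ea, oa


def _gwas_frame(ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se,
        "pval": _two_sided_p(beta, se), "n": float(n),
    })


def _recode(df: pd.DataFrame, swap_frac: float, flip_frac: float,
            rng: np.random.Generator) -> pd.DataFrame:
    """Re-encode a table with allele swaps and strand flips (harmonization fodder)."""
    df = df.copy()
    m = len(df)
    swap = rng.random(m) < swap_frac
    flip = rng.random(m) < flip_frac
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    beta = df["beta"].to_numpy().copy()
    eaf = df["eaf"].to_numpy().copy()
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    beta[swap] = -beta[swap]
    eaf[swap] = 1.0 - eaf[swap]
    comp = np.vectorize(_COMPLEMENT.get)
    if flip.any():
        ea[flip] = comp(ea[flip])
        oa[flip] = comp(oa[flip])
    df["effect_allele"], df["other_allele"] = ea, oa
    df["beta"], df["eaf"] = beta, eaf
    return df


def _panel(config: SimulationConfig, ids, pos, maf, ea, oa,
           rng: np.random.Generator) -> ReferencePanel:
    m = config.n_variants
    n = config.n_panel
    thresh = stats.norm.ppf(maf)
    if config.ld_block_size == 1 or config.ld_rho == 0.0:
        haps = rng.standard_normal((2, n, m))
    else:
        rho = config.ld_rho
        haps = np.empty((2, n, m))
        for start in range(0, m, config.ld_block_size):
            stop = min(start + config.ld_block_size, m)
            k = stop - start
            shared = rng.standard_normal((2, n, 1))
            own = rng.standard_normal((2, n, k))
            haps[:, :, start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    dosage = (haps[0] < thresh).astype(np.int8) + (haps[1] < thresh).astype(np.int8)
    # guard: keep every column polymorphic so LD stays defined
    mono = dosage.std(axis=0) == 0
    for j in np.flatnonzero(mono):
        dosage[0, j] = 1 if dosage[1, j] != 1 else 0
    vmap = pd.DataFrame({"variant_id": ids, "chrom": "1", "pos": pos,
                         "allele_a": ea, "allele_b": oa})
    return ReferencePanel(variant_map=vmap, dosages=dosage)


def simulate_two_sample(config: SimulationConfig) -> TwoSampleData:
    """Generate exposure/outcome summary statistics, ground truth, and an LD panel."""
    rngs = _streams(config.seed)
    ids, pos, maf, gamma, alpha, invalid = _structure(config, rngs["structure"])
    ea, oa = _alleles(config.n_variants, config.palindromic_fraction, rngs["encoding"])

    se_x = sampling_se(maf, config.exposure_n)
    gamma_hat = gamma + rngs["exposure"].normal(0.0, 1.0, config.n_variants) * se_x
    exp_df = _gwas_frame(ids, "1", pos, ea, oa, maf, gamma_hat, se_x, config.exposure_n)

    se_y = sampling_se(maf, config.outcome_n)
    theta = config.causal_effect * gamma + alpha
    Gamma_hat = theta + rngs["outcome"].normal(0.0, 1.0, config.n_variants) * se_y
    # the outcome study measures frequency in its own sample: small jitter
    enc = rngs["encoding"]
    eaf_y = np.clip(maf + enc.normal(0.0, 0.005, config.n_variants), 0.005, 0.995)
    out_df = _gwas_frame(ids, "1", pos, ea, oa, eaf_y, Gamma_hat, se_y, config.outcome_n)
    out_df = _recode(out_df, config.allele_swap_fraction, config.strand_flip_fraction, enc)

    panel = _panel(config, ids, pos, maf, ea, oa, rngs["panel"])
    truth = [TruthRecord(ids[j], float(gamma[j]), float(alpha[j]), bool(invalid[j]))
             for j in range(config.n_variants)]
    exposure = GwasTable("simulated exposure", "exposure", exp_df)
    outcome = GwasTable("simulated outcome", "outcome", out_df)
    return TwoSampleData(exposure, outcome, truth, panel)


def simulate_mediation_triplet(config: SimulationConfig) -> MediationTriplet:
    """Generate exposure, mediator and outcome tables sharing one instrument set.

    The outcome's per-variant effect is ``(direct + beta2*beta3) * gamma_j +
    alpha_j`` so the total effect beta1 equals direct + mediated by
    construction.
    """
    spec = config.mediator_spec
    if spec is None:
        raise GwasConfigError("mediator_spec must be set for a mediation triplet")
    if 2 * config.n_instruments > config.n_variants:
        raise GwasConfigError(
            "mediation needs disjoint exposure and mediator instrument sets: "
            "require 2 * n_instruments <= n_variants"
        )
    total = config.causal_effect + spec.beta2_true * spec.beta3_true
    rngs = _streams(config.seed)
    ids, pos, maf, gamma, alpha, invalid = _structure(config, rngs["structure"])
    ea, oa = _alleles(config.n_variants, config.palindromic_fraction, rngs["encoding"])

    se_x = sampling_se(maf, config.exposure_n)
    gamma_hat = gamma + rngs["exposure"].normal(0.0, 1.0, config.n_variants) * se_x
    exp_df = _gwas_frame(ids, "1", pos, ea, oa, maf, gamma_hat, se_x, config.exposure_n)

    # the mediator carries its own instruments (delta), disjoint from the
    # exposure's, so the mediator->outcome leg identifies beta3:
    #   m_j = beta2*gamma_j + delta_j
    #   y_j = direct*gamma_j + beta3*m_j + alpha_j
    med_rng = rngs["mediator"]
    delta = np.zeros(config.n_variants)
    free = np.flatnonzero(gamma == 0)
    own = med_rng.choice(free, size=config.n_instruments, replace=False)
    delta[own] = np.abs(med_rng.normal(0.0, config.instrument_effect_sd,
                                       size=config.n_instruments))
    m_true = spec.beta2_true * gamma + delta
    se_m = sampling_se(maf, spec.mediator_n)
    med_hat = m_true + med_rng.normal(0.0, 1.0, config.n_variants) * se_m
    med_df = _gwas_frame(ids, "1", pos, ea, oa, maf, med_hat, se_m, spec.mediator_n)

    se_y = sampling_se(maf, config.outcome_n)
    y_true = total * gamma + spec.beta3_true * delta + alpha
    Gamma_hat = y_true + rngs["outcome"].normal(0.0, 1.0, config.n_variants) * se_y
    enc = rngs["encoding"]
    eaf_y = np.clip(maf + enc.normal(0.0, 0.005, config.n_variants), 0.005, 0.995)
    out_df = _gwas_frame(ids, "1", pos, ea, oa, eaf_y, Gamma_hat, se_y, config.outcome_n)
    out_df = _recode(out_df, config.allele_swap_fraction, config.strand_flip_fraction, enc)

    panel = _panel(config, ids, pos, maf, ea, oa, rngs["panel"])
    truth = MediationTruth(beta1_true=total, beta2_true=spec.beta2_true,
                           beta3_true=spec.beta3_true, direct_effect=config.causal_effect)
    return MediationTriplet(
        GwasTable("simulated exposure", "exposure", exp_df),
        GwasTable("simulated mediator", "mediator", med_df),
        GwasTable("simulated outcome", "outcome", out_df),
        truth, panel,
    )
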