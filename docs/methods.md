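# Methods

`gutmr` implements a bidirectional two-sample Mendelian randomization (MR)
workflow for microbial-taxon exposures against disease outcomes, together
with a synthetic summary-statistics generator that makes every stage testable
without access to consortium data.

## The causal model

Two-sample MR treats genetic variants as instruments for an exposure. For
variant *j*, let γ_j be its effect on the exposure (estimated as γ̂_j with
standard error σ_γj in one GWAS) and Γ_j its effect on the outcome (Γ̂_j,
σ_Γj, from an independent GWAS). Under the instrumental-variable assumptions
(relevance, independence from confounders, exclusion restriction), each
variant yields a Wald ratio β_j = Γ_j/γ_j for the causal effect β of the
exposure on the outcome. The estimators combine these ratios:

- **IVW** — inverse-variance-weighted meta-analysis of the ratios,
  algebraically a weighted regression of Γ̂ on γ̂ through the origin with
  weights 1/σ²_Γj. Unbiased only if no instrument has a direct (horizontally
  pleiotropic) effect α_j on the outcome.
- **MR-Egger** — the same regression with a free intercept. Under InSIDE
  (instrument strength independent of direct effects) the intercept
  estimates the average directional pleiotropy and the slope remains a
  consistent causal estimate.
- **Weighted median** — the 50%-weight quantile of the ratio distribution;
  consistent while instruments carrying under half the weight are invalid.
- **Weighted mode** — the mode of a weighted Gaussian kernel density over
  the ratios; consistent when the largest group of instruments sharing a
  ratio is valid.

For binary outcomes β is a log odds ratio; reports carry exp(β) with a 95%
Wald interval (z = 1.959964).

## Pipeline stages and defaults

**Instrument selection** (`instruments`): p-value screen at the locus-wide
threshold p < 1e-5 (strict) for taxon exposures and genome-wide 5e-8 for
disease exposures in the reverse direction; greedy LD clumping against a
dosage reference panel keeping, among variants with r² ≥ 0.001 inside a
10,000 kb window on the same chromosome, only the smallest p-value (ties
broken by chromosome, position, then id, for determinism); removal of
variants with minor-allele frequency ≤ 0.01 (boundary removed, with a 1e-9
float tolerance); per-instrument strength F = β²/SE², with F > 10 read as
non-weak. Variants absent from the panel are dropped before clumping (their
LD is undefined) with a logged count; the panel's variant map is
authoritative for positions.

**Harmonization** (`harmonize`): shared variants are matched by id (an id
with conflicting positions across files is dropped rather than trusted);
allele-label swaps negate the outcome beta and mirror its frequency; strand
flips are resolved by base complement. Palindromic variants (A/T, C/G) carry
no strand information in their labels, so orientation comes from effect-
allele frequency: frequencies on the same side of 0.5 mean the encodings
agree, opposite sides mean the outcome effect is flipped. Palindromic
variants with either frequency inside the ambiguity window (0.42, 0.58) are
dropped by default (`drop_ambiguous=False` switches to frequency inference
regardless). The window is a convention adopted from common two-sample MR
tooling; it is configurable. Every decision is recorded in a per-variant
audit (action taken or drop reason).

**Estimators** (`estimators`): IVW defaults to multiplicative random
effects — the fixed-effect SE times the residual standard deviation, floored
at 1 — with a normal p-value; the fixed-effect variant is exposed via
`mode`. MR-Egger orients all γ̂ non-negative (the fit is invariant to
per-variant sign flips), uses the same multiplicative floor, and reports
t-distributed p-values on nsnp−2 degrees of freedom, the usual small-sample
treatment for the regression-based estimator. Weighted-median and
weighted-mode standard errors come from a seeded parametric bootstrap
(default 1000 replicates) resampling γ̂ and Γ̂ from their normal sampling
distributions. The mode bandwidth is a modified Silverman rule,
0.9·min(SD, 1.4826·MAD)·n^(−1/5), scaled by `bandwidth_factor` (default 1),
with the density evaluated on a 512-point grid. Minimum instrument counts:
Wald 1, IVW 2, Egger/median/mode 3.

**Sensitivity battery** (`sensitivity`): Cochran's Q on the Wald ratios
(weights γ²/σ²_Γ, chi-square on nsnp−1 df); the Egger intercept test (p >
0.05 read as no directional pleiotropy); MR-PRESSO with the global
residual-sum test, per-SNP outlier test (Bonferroni-adjusted empirical
p-values, outliers at adjusted p < 0.05), optional distortion test, and IVW
re-analysis after outlier removal (default 1000 simulations, seeded, with
the empirical p floored at 1/(1+n_sim)); leave-one-out IVW with a flag
raised when any single omission flips the sign of the estimate or moves its
p-value across 0.05. MR-PRESSO needs ≥ 4 instruments; report cells are
dashed when a test's minimum is not met.

**Classification and study orchestration** (`pipeline`): IVW is the primary
method for classification. The Bonferroni-corrected threshold is
0.05 divided by the number of taxa at the exposure's taxonomic level
(defaults 119 genera, 30 families, 20 orders, 16 classes, 9 phyla);
p < threshold is Bonferroni-significant, threshold ≤ p < 0.05 is nominal,
p ≥ 0.05 is null (strict boundaries, partitioning (0,1]). Thresholds are
kept at full precision internally and displayed at 3 significant figures.
Reverse MR is gated on nominal-or-better forward hits by default
(configurable to Bonferroni-only): the published reverse analyses cover all
nominally associated pairs. The reverse instrument screen defaults to
genome-wide significance, the convention for well-powered disease GWAS.

**Mediation** (`mediation`): two-step MR with β1 the total effect
(exposure→outcome), β2 the exposure→mediator effect and β3 the
mediator→outcome effect, each an IVW estimate from its own
select→harmonize→estimate run. The mediated effect is β2·β3 and the
proportion mediated is β2·β3/β1, reported as a percentage. Reporting
convention: the mediated effect is rounded half-away-from-zero to 3 decimals
*before* the division, and the percentage to 2 decimals — the only order
consistent with the published worked rows (0.014/0.11 → 12.73%, whereas the
unrounded 0.0135/0.11 would give 12.27%). Ties are resolved in decimal
arithmetic because binary floating point can land a product like
0.15 × 0.19 infinitesimally below the 0.0285 tie. No SE accompanies the
mediated effect by default; a delta-method SE is available via `with_se`.

## The synthetic generator

`simulate` instantiates the linear IV model directly on the summary-
statistic scale. Per variant: allele frequency f ~ Uniform(maf_range);
instrument effects γ_j drawn half-normal |N(0, instrument_effect_sd²)| —
summary statistics enter MR with the effect allele oriented to increase the
exposure, and a *directional* pleiotropy scenario is only meaningful against
oriented instruments (with sign-symmetric γ the pleiotropy term averages out
of the IVW numerator). Sampling noise uses the unit-variance-trait
approximation Var(β̂) = 1/(2f(1−f)n), reproducing the MAF and sample-size
dependence of real standard errors with one formula. Outcome effects are
β·γ_j + α_j with α_j = 0 (`none`), N(0, sd²) (`balanced`),
N(mean, sd²) (`directional`) on the configured invalid fraction of
instruments, or ρ·γ_j + noise (`inside_violation`). The mediation triplet
gives the mediator its own disjoint instrument set δ_j so that the
mediator→outcome leg is identified: m_j = β2·γ_j + δ_j and
y_j = direct·γ_j + β3·m_j + α_j, making the total effect
β1 = direct + β2·β3 by construction.

Defaults are sized to the study setting the package addresses: exposure
GWAS n = 20,000 (a 16S microbiome consortium scale), outcome n = 100,000 (an
intracranial-aneurysm-scale case-control meta-analysis), MAF in (0.05, 0.5),
instrument effect SD 0.1 (median F ≈ 35 at those sizes). The outcome table
is re-encoded with allele swaps (default rate 0.5 — arbitrary allele coding
across consortia), strand flips (default 0 — modern GWAS are forward-strand)
and palindromic pairs (default 0.15 of variants), and its allele frequency
carries a small jitter (SD 0.005) to mimic estimation in a different sample.
The reference panel is a latent multivariate-normal threshold model: within
blocks of `ld_block_size` variants the latent haplotype values share an
exchangeable correlation `ld_rho`, are dichotomized at each variant's
frequency quantile, and two haplotypes sum to a dosage in {0,1,2}; blocks
are independent, so cross-block LD is near zero. The latent correlation
attenuates through dichotomization, so `ld_rho` is an upper bound on the
dosage r, not its exact value. A guard flips one dosage in any column left
monomorphic by sampling so panel LD stays defined. One seed drives
everything through named child streams; the exposure draws are identical
whether or not a mediator is requested.

What the generator does **not** emulate: realistic human LD maps (block-
exchangeable correlation only), binary-trait liability-scale effects, allele
frequency differences between ancestries, overlapping GWAS samples,
winner's-curse in instrument discovery, or indels/multi-allelics (rejected
at I/O). Tests passing on these data show the pipeline implements its
contracts, not that any biological conclusion transfers to real cohorts.

## Validation study conditions

The repeat-simulation studies in `benchmarks` (also run by
`scripts/acceptance.py`) use these conditions:

- **IVW recovery / type-I error**: 50 instruments, defaults otherwise, true
  β = 0.2 (recovery, 500 replicates) or 0 (type I, 1000 replicates). Mean
  bias stays within ~0.003 of zero (a residual regression-dilution effect of
  measurement error in γ̂ at microbiome-GWAS instrument strength) and
  coverage/rejection sit near nominal.
- **Weighted median vs IVW under directional pleiotropy**: 40% invalid
  instruments, pleiotropy mean 0.05, 200 replicates, outcome GWAS sized like
  a large stroke meta-analysis (n = 450,000). The larger outcome keeps
  per-ratio sampling noise from dominating the contrast: the median's
  residual bias is noise-driven, while IVW's (≈ 0.16) is pleiotropy-driven
  and sample-size-invariant.
- **Egger intercept recovery**: all instruments pleiotropic with mean 0.05,
  200 replicates, near-exact instrument effects (exposure n = 10⁷). The
  intercept's estimand equals the injected mean only in the
  no-measurement-error (NOME) limit; at consortium scale the estimator's
  known weak-instrument attenuation appears (the same run at n = 20,000
  yields ≈ 0.04), which is a property of MR-Egger, not of this
  implementation — with near-exact γ the intercept is recovered within
  Monte-Carlo error.
- **MR-PRESSO**: 15-instrument sets, 1000 simulations, 100 runs; power
  measured on a single Γ̂ shifted by 10 standard errors, specificity on the
  unshifted sets.
- **Clumping oracle**: 100 random 20-variant, 4-per-block panels compared
  decision-by-decision against an exhaustive re-check of the greedy rule.

## Numerical and degenerate-input choices

Input p-values of exactly 0 are clamped to the smallest positive double
(with a warning) since downstream comparisons are log-scale; written files
round-trip at full double precision. An exact Egger fit (zero residual) uses
the unscaled covariance, avoiding 0/0 in the SE. Bootstrap draws that land a
resampled γ̂ on zero produce non-finite ratio estimates and are excluded
from the bootstrap SD. The weighted-median interpolation returns the exact
ratio when the cumulative weight midpoint hits 0.5. All stochastic
components (generator, bootstraps, MR-PRESSO, distortion test) are
bit-reproducible given a seed.

## Known limitations

Single-mediator, non-overlapping-samples design only; no multivariable MR,
Steiger filtering, radial diagnostics, or correlated-instrument IVW. The
LD panel model is exchangeable within blocks, so clumping behaviour on real
panels with long-range LD may differ. The weighted-mode grid search bounds
the mode to within the grid resolution (512 points across the ratio range
±3 bandwidths).
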