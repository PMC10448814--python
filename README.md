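# gutmr

Bidirectional two-sample Mendelian randomization (MR) of gut-microbiome taxa
against cerebrovascular outcomes — instrument selection, harmonization, five
MR estimators, a sensitivity battery, per-taxonomic-level Bonferroni
classification, reverse MR, and two-step mediation MR — plus a synthetic
GWAS summary-statistics generator so the whole workflow is testable
end-to-end without consortium downloads.

## Who this is for

Analysts asking whether genetically predicted abundance of a bacterial taxon
(exposure GWAS, e.g. a 16S consortium meta-analysis) causally affects a
disease such as intracranial aneurysm or stroke (outcome GWAS), using only
published summary statistics. Genetic variants serve as instruments: because
genotypes are randomized at conception, variant–outcome associations are not
confounded the way observational microbiome–disease associations are.

## The statistics

For variant *j* with exposure effect γ̂_j (SE σ_γj) and outcome effect Γ̂_j
(SE σ_Γj), each instrument gives a Wald ratio β_j = Γ̂_j/γ̂_j. The package
combines them with:

- **IVW** (primary): β̂ = Σ w_j γ̂_j Γ̂_j / Σ w_j γ̂_j², w_j = 1/σ²_Γj —
  a weighted regression of Γ̂ on γ̂ through the origin, multiplicative
  random effects by default;
- **MR-Egger**: the same regression with a free intercept estimating average
  directional pleiotropy (InSIDE assumption);
- **weighted median**: consistent with up to half the weight on invalid
  instruments;
- **weighted mode**: mode of the weighted kernel density of the ratios.

Sensitivity: Cochran's Q heterogeneity, the Egger intercept test, MR-PRESSO
(global residual-sum simulation test, per-SNP outlier detection, IVW
re-analysis after removal), leave-one-out, and per-instrument F = β²/SE²
(>10 = non-weak). Instruments are chosen at p < 1e-5 (locus-wide; 5e-8 for
disease exposures in reverse MR), LD-clumped at r² < 0.001 within 10,000 kb
against a dosage reference panel, and filtered at MAF > 0.01; palindromic
variants are oriented by allele frequency. Two-step mediation decomposes a
total effect β1 into a mediated part β2·β3 (exposure→mediator times
mediator→outcome) and its percentage β2·β3/β1. Estimates are classified per
taxonomic level: p below 0.05/(taxa at that level) is Bonferroni-significant,
between that and 0.05 is nominal.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate a study (one taxon with a true causal effect, log-OR 0.4) and run
the forward sweep:

```bash
cat > sim.yaml <<'YAML'
n_variants: 150
n_instruments: 15
causal_effect: 0.4
palindromic_fraction: 0.0
seed: 7
YAML
gutmr simulate --config sim.yaml --out demo

cat > study.yaml <<'YAML'
exposure_files:
  "genus Streptococcus": demo/exposure.tsv
outcome_files:
  IA: demo/outcome.tsv
panel_dosage: demo/panel_dosages.tsv
panel_map: demo/panel_variants.tsv
presso_simulations: 1000
seed: 7
YAML
gutmr forward --config study.yaml --out forward.tsv --hits-out hits.tsv
```

`forward.tsv` then contains (abridged):

```
Exposures            Outcomes  Method  OR(95%CI)        p         P_Q       Egger intercept  P_intercept  MR-PRESSO  nsnp  significance
genus Streptococcus  IA        IVW     1.47(1.41–1.53)  2.61E-73  3.20E-02  -8.95E-03        3.25E-01     2.21E-01   9     bonferroni_significant
genus Streptococcus  IA        egger   1.57(1.38–1.80)  2.83E-04  3.20E-02  -8.95E-03        3.25E-01     2.21E-01   9     bonferroni_significant
```

Reading it: 9 instruments survived selection and harmonization; the IVW odds
ratio 1.47 (95% CI 1.41–1.53) recovers the simulated exp(0.4) ≈ 1.49; the
Egger intercept is indistinguishable from zero (P_intercept 0.33, no
directional pleiotropy) and the MR-PRESSO global p of 0.22 flags no outliers,
so the IVW estimate stands; p = 2.6e-73 is far below the genus-level
Bonferroni threshold 0.05/119 = 4.20e-4, hence `bonferroni_significant`.
Reverse MR on the hit list and mediation triplets run the same way
(`gutmr reverse --config study.yaml --hits hits.tsv`,
`gutmr mediate --config study.yaml --triplets triplets.tsv`).

The mediation arithmetic is exposed directly:

```python
>>> from gutmr.mediation import mediation_effect, proportion_mediated
>>> _, med = mediation_effect(0.15, 0.09)   # beta2, beta3
>>> med, proportion_mediated(med, 0.11)     # beta1
(0.014, 12.73)
```

i.e. a mediated effect of 0.014 accounting for 12.73% of the total effect.

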