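"""Study orchestration: forward MR across exposures x outcomes, per-level
Bonferroni/nominal classification, reverse MR on hits, mediation triplets,
and table-style report writing.

Classification follows the per-taxonomic-level Bonferroni convention: the
corrected threshold is 0.05 divided by the number of taxa at the exposure's
level (119 genera, 30 families, 20 orders, 16 classes, 9 phyla by default);
p below the corrected threshold is Bonferroni-significant, p in
[threshold, 0.05) is a nominal association, and anything at or above 0.05 is
null. IVW is the primary method for classification; the other estimators are
reported for concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from .estimators import MREstimate, all_estimates
from .harmonize import build_instrument_set
from .instruments import GENOME_WIDE_P, SelectionParams, select_instruments
from .io import GwasConfigError, GwasTable, ReferencePanel, read_reference_panel, read_summary_stats
from .mediation import MediationResult, two_step_mediation
from .sensitivity import PressoParams, SensitivityReport, sensitivity_report

logger = logging.getLogger(__name__)

DEFAULT_BONFERRONI_COUNTS = {
    "genus": 119, "family": 30, "order": 20, "class": 16, "phylum": 9,
}

REPORT_COLUMNS = ["Exposures", "Outcomes", "Method", "OR(95%CI)", "p",
                  "P_Q", "Egger intercept", "P_intercept", "MR-PRESSO",
                  "nsnp", "significance"]

EN_DASH = "–"


@dataclass
class StudyConfig:
    exposure_files: dict[str, str]  # trait label -> summary-stat path
    outcome_files: dict[str, str]
    panel_dosage: str
    panel_map: str
    mediator_files: dict[str, str] = field(default_factory=dict)
    forward_params: SelectionParams = field(default_factory=SelectionParams)
    reverse_params: SelectionParams = field(
        default_factory=lambda: SelectionParams(p_threshold=GENOME_WIDE_P))
    bonferroni_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BONFERRONI_COUNTS))
    alpha: float = 0.05
    presso_simulations: int = 1000
    reverse_gate: str = "nominal"  # gate reverse MR on nominal-or-better hits
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.bonferroni_counts.values()):
            raise GwasConfigError("bonferroni counts must be positive")
        if self.reverse_gate not in {"nominal", "bonferroni"}:
            raise GwasConfigError("reverse_gate must be 'nominal' or 'bonferroni'")


@dataclass
class ClassifiedResult:
    exposure_label: str
    outcome_label: str
    estimates: list[MREstimate]
    sensitivity: SensitivityReport
    significance_class: str  # bonferroni_significant | nominal | null
    level: str
    audit: pd.DataFrame | None = None  # per-variant harmonization actions

    @property
    def primary(self) -> MREstimate:
        return self.estimates[0]


def load_study_config(path) -> StudyConfig:
    """Load a study config from YAML (flat mapping, documented template)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = dict(raw)
    for key in ("forward_params", "reverse_params"):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = SelectionParams(**kwargs[key])
    return StudyConfig(**kwargs)


def bonferroni_threshold(alpha: float, count: int) -> float:
    """Corrected significance threshold alpha/count at full precision."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return alpha / count


def format_threshold(threshold: float) -> str:
    """3-significant-figure scientific display, e.g. 4.20e-04."""
    d = Decimal(repr(threshold)).normalize()
    sign, digits, exp = d.as_tuple()
    magnitude = len(digits) + exp - 1
    mantissa = (Decimal(threshold) / Decimal(10) ** magnitude).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{mantissa}e{magnitude:+03d}"


def taxonomic_level(label: str) -> str:
    """First word of a taxon label ('genus Streptococcus' -> 'genus')."""
    return label.split()[0].lower() if label.split() else ""


def classify_significance(pval: float, level: str, config: StudyConfig) -> str:
    """bonferroni_significant iff p < alpha/count; nominal on
    [alpha/count, alpha); null otherwise. Partitions (0, 1]."""
    if level not in config.bonferroni_counts:
        raise GwasConfigError(f"no Bonferroni count configured for level {level!r}")
    corrected = bonferroni_threshold(config.alpha, config.bonferroni_counts[level])
    if pval < corrected:
        return "bonferroni_significant"
    if pval < config.alpha:
        return "nominal"
    return "null"


def _analyze_pair(exposure: GwasTable, outcome: GwasTable, panel: ReferencePanel,
                  params: SelectionParams, config: StudyConfig,
                  level: str | None = None) -> ClassifiedResult | None:
    selected = select_instruments(exposure, panel, params)
    if len(selected.df) == 0:
        logger.warning("no instruments for %s -> %s; pair skipped",
                       exposure.trait_label, outcome.trait_label)
        return None
    hset = build_instrument_set(selected, outcome, params)
    if hset.nsnp == 0:
        logger.warning("empty harmonized set for %s -> %s; pair skipped",
                       exposure.trait_label, outcome.trait_label)
        return None
    estimates = all_estimates(hset, seed=config.seed)
    presso = PressoParams(n_simulations=config.presso_simulations, seed=config.seed)
    sens = sensitivity_report(hset, presso)
    lvl = level or taxonomic_level(exposure.trait_label)
    if lvl in config.bonferroni_counts:
        cls = classify_significance(estimates[0].pval, lvl, config)
    else:
        cls = "bonferroni_significant" if estimates[0].pval < config.alpha else "null"
    logger.info("%s -> %s: nsnp=%d IVW beta=%.4f p=%.3g class=%s (drops: %d)",
                exposure.trait_label, outcome.trait_label, hset.nsnp,
                estimates[0].beta, estimates[0].pval, cls, len(hset.dropped))
    audit = hset.audit_frame()
    audit.insert(0, "exposure", exposure.trait_label)
    audit.insert(1, "outcome", outcome.trait_label)
    return ClassifiedResult(exposure.trait_label, outcome.trait_label,
                            estimates, sens, cls, lvl, audit)


def _load_tables(files: dict[str, str], trait_type: str) -> list[GwasTable]:
    return [read_summary_stats(path, trait_label=label, trait_type=trait_type)
            for label, path in files.items()]


def run_forward(config: StudyConfig) -> list[ClassifiedResult]:
    """Forward sweep: every exposure x outcome pair through selection,
    harmonization, all estimators and the sensitivity battery. Pairs without
    instruments are logged and skipped; per-pair failures never abort."""
    panel = read_reference_panel(config.panel_dosage, config.panel_map)
    outcomes = _load_tables(config.outcome_files, "outcome")
    results: list[ClassifiedResult] = []
    if not config.exposure_files:
        logger.warning("empty exposure set; nothing to analyse")
    for label, path in config.exposure_files.items():
        try:
            exposure = read_summary_stats(path, trait_label=label, trait_type="exposure")
        except Exception:
            logger.exception("failed to load exposure %s; skipped", label)
            continue
        for outcome in outcomes:
            try:
                res = _analyze_pair(exposure, outcome, panel, config.forward_params, config)
            except Exception:
                logger.exception("pair %s -> %s failed; skipped", label, outcome.trait_label)
                continue
            if res is not None:
                results.append(res)
    return results


def forward_hits(results: list[ClassifiedResult], gate: str = "nominal"
                 ) -> list[tuple[str, str]]:
    """(exposure, outcome) pairs that pass the gate for reverse analysis."""
    wanted = ({"bonferroni_significant"} if gate == "bonferroni"
              else {"bonferroni_significant", "nominal"})
    return [(r.exposure_label, r.outcome_label) for r in results
            if r.significance_class in wanted]


def run_reverse(config: StudyConfig,
                hits: list[tuple[str, str]]) -> list[ClassifiedResult]:
    """Reverse MR on forward hits: the disease becomes the exposure (screened
    at the reverse threshold, genome-wide by default) and the taxon the
    outcome. Sensitivity columns stay blank when instruments are too few."""
    if not hits:
        raise GwasConfigError("reverse MR requires a non-empty hit list")
    panel = read_reference_panel(config.panel_dosage, config.panel_map)
    results: list[ClassifiedResult] = []
    for taxon_label, disease_label in hits:
        try:
            disease = read_summary_stats(config.outcome_files[disease_label],
                                         trait_label=disease_label, trait_type="exposure")
            taxon = read_summary_stats(config.exposure_files[taxon_label],
                                       trait_label=taxon_label, trait_type="outcome")
            res = _analyze_pair(disease, taxon, panel, config.reverse_params, config,
                                level=taxonomic_level(taxon_label))
        except Exception:
            logger.exception("reverse pair %s -> %s failed; skipped",
                             disease_label, taxon_label)
            continue
        if res is not None:
            results.append(res)
    return results


def run_mediation(config: StudyConfig,
                  triplets: list[tuple[str, str, str]]) -> list[MediationResult]:
    """Two-step mediation MR for (exposure, mediator, outcome) label triplets."""
    panel = read_reference_panel(config.panel_dosage, config.panel_map)
    out: list[MediationResult] = []
    for exp_label, med_label, out_label in triplets:
        exposure = read_summary_stats(config.exposure_files[exp_label],
                                      trait_label=exp_label, trait_type="exposure")
        mediator = read_summary_stats(config.mediator_files[med_label],
                                      trait_label=med_label, trait_type="mediator")
        outcome = read_summary_stats(config.outcome_files[out_label],
                                     trait_label=out_label, trait_type="outcome")
        try:
            out.append(two_step_mediation(exposure, mediator, outcome, panel,
                                          config.forward_params))
        except Exception:
            logger.exception("mediation triplet %s / %s / %s failed; skipped",
                             exp_label, med_label, out_label)
    return out


def format_or_ci(beta: float, se: float) -> str:
    """Table-style OR cell, e.g. '0.60(0.43-0.83)' with an en dash."""
    from .estimators import beta_to_or

    or_value, lo, hi = beta_to_or(beta, se)
    return f"{or_value:.2f}({lo:.2f}{EN_DASH}{hi:.2f})"


def format_p(pval: float | None) -> str:
    """Scientific notation with 2 decimals, e.g. 1.67E-03; dash when missing."""
    if pval is None:
        return EN_DASH
    return f"{pval:.2E}"


def _fmt(value: float | None, spec: str = ".2E") -> str:
    return EN_DASH if value is None else f"{value:{spec}}"


def report_frame(results: list[ClassifiedResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for est in r.estimates:
            s = r.sensitivity
            rows.append({
                "Exposures": r.exposure_label,
                "Outcomes": r.outcome_label,
                "Method": est.method.upper() if est.method == "ivw" else est.method,
                "OR(95%CI)": format_or_ci(est.beta, est.se),
                "p": format_p(est.pval),
                "P_Q": format_p(s.q_pval),
                "Egger intercept": _fmt(s.egger_intercept),
                "P_intercept": format_p(s.egger_intercept_pval),
                "MR-PRESSO": format_p(s.presso_global_pval),
                "nsnp": est.nsnp,
                "significance": r.significance_class,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(results: list[ClassifiedResult], path, seed: int | None = None) -> None:
    """Write the results TSV in the forest-table column layout."""
    df = report_frame(results)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# gutmr report; seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_audit(results: list[ClassifiedResult], path) -> None:
    """Combined harmonization audit TSV: one row per matched variant and pair."""
    frames = [r.audit for r in results if r.audit is not None]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(columns=["exposure", "outcome", "variant_id",
                              "action_taken", "reason"]).to_csv(path, sep="\t", index=False)


def write_mediation_report(results: list[MediationResult], path) -> None:
    rows = [{
        "Exposure": r.exposure_label,
        "Mediation factors": r.mediator_label,
        "Outcome": r.outcome_label,
        "β1": round(r.beta1, 2),
        "β2": round(r.beta2, 2),
        "β3": round(r.beta3, 2),
        "Mediating effect": r.mediated_effect,
        "The percentage of the mediating effect": f"{r.proportion_mediated:.2f}%",
    } for r in results]
    cols = ["Exposure", "Mediation factors", "Outcome", "β1", "β2", "β3",
            "Mediating effect", "The percentage of the mediating effect"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
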