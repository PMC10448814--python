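"""Two-step mediation MR: decompose a total causal effect into a mediated
component and its proportion.

With beta1 the total effect of exposure on outcome, beta2 the effect of
exposure on mediator, and beta3 the effect of mediator on outcome (each an
IVW estimate from its own instrument set), the mediated effect is
``beta2 * beta3`` and the proportion mediated is ``beta2 * beta3 / beta1``.

Reporting convention: the mediated effect is rounded half-away-from-zero to
3 decimals *before* the proportion is taken, and the percentage is rounded
to 2 decimals. The proportion is reported as a percentage and carries the
sign convention of the inputs (a negative mediated effect over a negative
total effect gives a positive percentage).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .harmonize import build_instrument_set
from .instruments import InsufficientInstrumentsError, SelectionParams, select_instruments
from .io import GwasTable, ReferencePanel
from .estimators import ivw, MREstimate


def round_half_away(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MediationResult:
    exposure_label: str
    mediator_label: str
    outcome_label: str
    beta1: float  # total effect, exposure -> outcome
    beta2: float  # exposure -> mediator
    beta3: float  # mediator -> outcome
    mediated_effect: float  # rounded to 3 decimals for reporting
    mediated_effect_raw: float
    proportion_mediated: float  # percent, rounded to 2 decimals
    mediated_se: float | None = None  # optional delta-method SE


def mediation_effect(beta2: float, beta3: float) -> tuple[float, float]:
    """(raw, reported) mediated effect beta2*beta3; reported value rounded
    half-away-from-zero to 3 decimals.

    The product is formed in decimal arithmetic so that ties like
    0.15 * 0.19 = 0.0285 (slightly below the tie in binary floating point)
    round the way the printed inputs demand.
    """
    raw = beta2 * beta3
    q = Decimal("0.001")
    exact = Decimal(repr(float(beta2))) * Decimal(repr(float(beta3)))
    return raw, float(exact.quantize(q, rounding=ROUND_HALF_UP))


def proportion_mediated(mediated_rounded: float, beta1: float) -> float:
    """Percentage of the total effect that is mediated, to 2 decimals."""
    if beta1 == 0:
        raise ZeroDivisionError("proportion mediated undefined for beta1 = 0")
    ratio = 100 * Decimal(repr(float(mediated_rounded))) / Decimal(repr(float(beta1)))
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def combine(exposure_label: str, mediator_label: str, outcome_label: str,
            beta1: float, beta2: float, beta3: float,
            se2: float | None = None, se3: float | None = None,
            with_se: bool = False) -> MediationResult:
    """Assemble a MediationResult from the three leg estimates."""
    raw, rounded = mediation_effect(beta2, beta3)
    prop = proportion_mediated(rounded, beta1)
    se = None
    if with_se and se2 is not None and se3 is not None:
        se = float(np.sqrt(beta2**2 * se3**2 + beta3**2 * se2**2))
    return MediationResult(exposure_label, mediator_label, outcome_label,
                           beta1, beta2, beta3, rounded, raw, prop, se)


def _leg(name: str, exposure: GwasTable, outcome: GwasTable,
         panel: ReferencePanel, params: SelectionParams) -> MREstimate:
    selected = select_instruments(exposure, panel, params)
    hset = build_instrument_set(selected, outcome, params)
    if hset.nsnp < 2:
        raise InsufficientInstrumentsError(
            f"{name} leg ({exposure.trait_label} -> {outcome.trait_label}): "
            f"{hset.nsnp} instrument(s) after selection and harmonization"
        )
    return ivw(hset)


def two_step_mediation(
    exposure: GwasTable,
    mediator: GwasTable,
    outcome: GwasTable,
    panel: ReferencePanel,
    params: SelectionParams | None = None,
    mediator_params: SelectionParams | None = None,
    with_se: bool = False,
) -> MediationResult:
    """Estimate beta1/beta2/beta3 via the full select->harmonize->IVW pipeline
    on each leg and combine them.

    Mediator instruments are selected at the same threshold as the exposure's
    unless ``mediator_params`` overrides it.
    """
    params = params or SelectionParams()
    mediator_params = mediator_params or params
    est1 = _leg("total-effect", exposure, outcome, panel, params)
    est2 = _leg("exposure-to-mediator", exposure, mediator, panel, params)
    est3 = _leg("mediator-to-outcome", mediator, outcome, panel, mediator_params)
    return combine(exposure.trait_label, mediator.trait_label, outcome.trait_label,
                   est1.beta, est2.beta, est3.beta,
                   se2=est2.se, se3=est3.se, with_se=with_se)
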