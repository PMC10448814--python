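"""Align exposure and outcome summary statistics to a common effect allele.

Shared variants are matched by id; allele-label swaps negate the outcome beta
and mirror its frequency, strand flips are resolved by base complement, and
palindromic (A/T, C/G) variants — whose strand cannot be read off the allele
labels — are oriented from effect-allele frequency: if both studies' EAFs sit
on the same side of 0.5 the encodings agree, otherwise the outcome effect is
flipped. Palindromic variants whose frequency falls inside the ambiguity
window around 0.5 (default (0.42, 0.58)) are dropped when ``drop_ambiguous``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GwasTable
from .instruments import SelectionParams

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: retained-record actions
KEEP_ACTIONS = frozenset({
    "as_is", "swapped", "strand_flipped", "swapped_and_flipped", "palindromic_inferred",
})


def complement_alleles(allele: str) -> str:
    """Base complement (A<->T, C<->G); raises for anything else."""
    try:
        return COMPLEMENT[allele]
    except KeyError:
        raise ValueError(f"not a valid base: {allele!r}") from None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    return {effect_allele, other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Aligned exposure-outcome instrument table feeding every estimator.

    ``df`` columns: variant_id, gamma, se_gamma, Gamma, se_Gamma,
    eaf_exposure, eaf_outcome, action (plus f_stat when available).
    ``dropped`` lists (variant_id, reason) for everything excluded.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nsnp(self) -> int:
        return len(self.df)

    @property
    def gamma(self) -> np.ndarray:
        return self.df["gamma"].to_numpy(float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.df["se_gamma"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.df["Gamma"].to_numpy(float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.df["se_Gamma"].to_numpy(float)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    def subset(self, mask) -> "HarmonizedSet":
        return HarmonizedSet(
            self.exposure_label, self.outcome_label,
            self.df.loc[mask].reset_index(drop=True), list(self.dropped),
        )

    def audit_frame(self) -> pd.DataFrame:
        """Harmonization audit: one row per matched variant with its action."""
        kept = pd.DataFrame({
            "variant_id": self.df["variant_id"],
            "action_taken": self.df["action"],
            "reason": "",
        })
        dropped = pd.DataFrame(self.dropped, columns=["variant_id", "reason"])
        if len(dropped):
            dropped.insert(1, "action_taken", "dropped_" + dropped["reason"].where(
                dropped["reason"].isin(["ambiguous", "incompatible"]), "incompatible"))
        return pd.concat([kept, dropped], ignore_index=True)


def _orient_one(x_row, y_row, ambiguity_window, drop_ambiguous):
    """Return (sign, eaf_out, action) aligning one outcome row to the exposure
    effect allele, or (None, None, drop_reason)."""
    ea_x, oa_x = x_row.effect_allele, x_row.other_allele
    ea_y, oa_y = y_row.effect_allele, y_row.other_allele

    if is_palindromic(ea_x, oa_x):
        if not is_palindromic(ea_y, oa_y) or {ea_y, oa_y} != {ea_x, oa_x}:
            return None, None, "incompatible"
        eaf_x, eaf_y = x_row.eaf, y_row.eaf
        if not (np.isfinite(eaf_x) and np.isfinite(eaf_y)):
            return None, None, "ambiguous"
        lo, hi = ambiguity_window
        if drop_ambiguous and (lo < eaf_x < hi or lo < eaf_y < hi):
            return None, None, "ambiguous"
        # labels carry no strand information; frequency decides orientation
        same_side = (eaf_x - 0.5) * (eaf_y - 0.5) > 0
        if same_side:
            action = "as_is" if ea_y == ea_x else "palindromic_inferred"
            return 1.0, eaf_y, action
        action = "palindromic_inferred"
        return -1.0, 1.0 - eaf_y, action

    if {ea_y, oa_y} == {ea_x, oa_x}:
        if ea_y == ea_x:
            return 1.0, y_row.eaf, "as_is"
        return -1.0, 1.0 - y_row.eaf, "swapped"
    cea, coa = COMPLEMENT.get(ea_y), COMPLEMENT.get(oa_y)
    if {cea, coa} == {ea_x, oa_x}:
        if cea == ea_x:
            return 1.0, y_row.eaf, "strand_flipped"
        return -1.0, 1.0 - y_row.eaf, "swapped_and_flipped"
    return None, None, "incompatible"


def harmonize_pair(
    exposure: GwasTable,
    outcome: GwasTable,
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
    drop_ambiguous: bool = True,
) -> HarmonizedSet:
    """Harmonize two tables into an aligned instrument set.

    Exposure rows absent from the outcome are dropped with reason
    ``missing_in_outcome``; id-matched rows with conflicting positions are
    dropped as incompatible rather than trusted.
    """
    out_by_id = {r.variant_id: r for r in outcome.df.itertuples()}
    rows = []
    dropped: list[tuple[str, str]] = []
    for x in exposure.df.itertuples():
        y = out_by_id.get(x.variant_id)
        if y is None:
            dropped.append((x.variant_id, "missing_in_outcome"))
            continue
        if x.chrom == y.chrom and x.pos != y.pos:
            dropped.append((x.variant_id, "incompatible"))
            continue
        sign, eaf_out, action = _orient_one(x, y, ambiguity_window, drop_ambiguous)
        if sign is None:
            dropped.append((x.variant_id, action))
            continue
        row = {
            "variant_id": x.variant_id,
            "gamma": x.beta, "se_gamma": x.se,
            "Gamma": sign * y.beta, "se_Gamma": y.se,
            "eaf_exposure": x.eaf, "eaf_outcome": eaf_out,
            "action": action,
        }
        if hasattr(x, "f_stat"):
            row["f_stat"] = x.f_stat
        rows.append(row)
    cols = ["variant_id", "gamma", "se_gamma", "Gamma", "se_Gamma",
            "eaf_exposure", "eaf_outcome", "action"]
    if rows and "f_stat" in rows[0]:
        cols.append("f_stat")
    df = pd.DataFrame(rows, columns=cols)
    return HarmonizedSet(exposure.trait_label, outcome.trait_label, df, dropped)


def build_instrument_set(
    selected: GwasTable,
    outcome: GwasTable,
    params: SelectionParams | None = None,
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
    drop_ambiguous: bool = True,
) -> HarmonizedSet:
    """Harmonize an already-selected instrument table against an outcome,
    carrying F statistics through (computing them if absent)."""
    from .instruments import annotate_f

    if "f_stat" not in selected.df.columns:
        selected = annotate_f(selected)
    return harmonize_pair(selected, outcome, ambiguity_window, drop_ambiguous)
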