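"""Instrumental-variable selection: p-value screen, greedy LD clumping
against a reference panel, MAF filter, and instrument-strength (F) annotation.

The composition order is p-filter -> clump -> MAF filter -> F annotation.
Defaults follow the locus-wide convention for microbiome exposures:
p < 1e-5, clumping at r^2 < 0.001 within a 10,000 kb window, MAF <= 0.01
removed, and F = beta^2/se^2 with > 10 read as non-weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GwasTable, ReferencePanel

logger = logging.getLogger(__name__)

#: genome-wide significance, the default screen for disease exposures in reverse MR
GENOME_WIDE_P = 5e-8
#: locus-wide significance, the default screen for taxon exposures
LOCUS_WIDE_P = 1e-5


class InsufficientInstrumentsError(ValueError):
    """Too few instruments remain for the requested operation."""


class UndefinedLDError(ValueError):
    """LD requested for a monomorphic or absent panel variant."""


@dataclass(frozen=True)
class SelectionParams:
    p_threshold: float = LOCUS_WIDE_P
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    maf_min: float = 0.01
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in (0,1]")
        if not (0 <= self.clump_r2 < 1):
            raise ValueError("clump_r2 must lie in [0,1)")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0,0.5)")
        if self.clump_window_kb < 0:
            raise ValueError("clump_window_kb must be non-negative")


def f_statistic(beta: float, se: float) -> float:
    """Instrument strength F = (beta/se)^2; se must be positive."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def filter_pvalue(table: GwasTable, p_threshold: float) -> GwasTable:
    """Keep rows with pval strictly below the threshold, preserving order."""
    return table.subset(table.df["pval"] < p_threshold)


def filter_maf(table: GwasTable, maf_min: float) -> GwasTable:
    """Remove rows whose minor-allele frequency is <= maf_min (boundary removed)."""
    eaf = table.df["eaf"]
    maf = np.minimum(eaf, 1.0 - eaf)
    # tolerance so e.g. 1 - 0.99 (> 0.01 only in floating point) hits the boundary
    return table.subset(maf - maf_min > 1e-9)


def ld_r2(panel: ReferencePanel, id_a: str, id_b: str) -> float:
    """Squared Pearson correlation between two dosage columns of the panel."""
    a = panel.column(id_a).astype(float)
    b = panel.column(id_b).astype(float)
    if a.std() == 0 or b.std() == 0:
        raise UndefinedLDError(f"LD undefined: monomorphic variant in pair ({id_a}, {id_b})")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(table: GwasTable, panel: ReferencePanel, params: SelectionParams) -> GwasTable:
    """Greedy LD clumping: scan by ascending p-value, keep a variant iff it is
    below ``clump_r2`` with every kept same-chromosome variant inside the
    window. Ties broken by (chrom, pos, variant_id). Variants absent from the
    panel are dropped first (LD undefined for them). Result sorted by
    (chrom, pos).
    """
    df = table.df
    in_panel = df["variant_id"].map(lambda v: v in panel)
    n_absent = int((~in_panel).sum())
    if n_absent:
        logger.info("clump: dropping %d variant(s) absent from reference panel", n_absent)
    df = df.loc[in_panel]
    if df.empty:
        return table.subset(np.zeros(len(table.df), dtype=bool))

    # panel's variant map is authoritative for position/chromosome
    chroms, poss = zip(*(panel.position(v) for v in df["variant_id"]))
    work = df.assign(panel_chrom=chroms, panel_pos=poss).sort_values(
        ["pval", "panel_chrom", "panel_pos", "variant_id"], kind="mergesort"
    )
    window = params.clump_window_kb * 1000
    kept: list[tuple[str, str, int]] = []  # (variant_id, chrom, pos)
    for vid, chrom, pos in zip(work["variant_id"], work["panel_chrom"], work["panel_pos"]):
        ok = True
        for kid, kchrom, kpos in kept:
            if chrom == kchrom and abs(pos - kpos) <= window:
                if ld_r2(panel, vid, kid) >= params.clump_r2:
                    ok = False
                    break
        if ok:
            kept.append((vid, chrom, pos))
    kept_sorted = [vid for vid, _, _ in sorted(kept, key=lambda t: (t[1], t[2], t[0]))]
    order = {vid: i for i, vid in enumerate(kept_sorted)}
    out = table.df[table.df["variant_id"].isin(order)].copy()
    out = out.sort_values("variant_id", key=lambda s: s.map(order), kind="mergesort")
    result = table.subset(np.zeros(len(table.df), dtype=bool))
    result.df = out.reset_index(drop=True)
    return result


def annotate_f(table: GwasTable) -> GwasTable:
    """Attach the per-variant F statistic as an ``f_stat`` column."""
    out = table.subset(np.ones(len(table.df), dtype=bool))
    out.df["f_stat"] = (out.df["beta"] / out.df["se"]) ** 2
    return out


def select_instruments(
    table: GwasTable,
    panel: ReferencePanel,
    params: SelectionParams | None = None,
    filter_weak: bool = False,
) -> GwasTable:
    """Full selection pipeline: p-filter -> clump -> MAF filter -> F annotation.

    With ``filter_weak`` instruments at or below ``params.f_min`` are also
    removed; by default weak instruments are only annotated, not dropped.
    """
    params = params or SelectionParams()
    out = filter_pvalue(table, params.p_threshold)
    out = clump(out, panel, params)
    out = filter_maf(out, params.maf_min)
    out = annotate_f(out)
    if filter_weak:
        out = out.subset(out.df["f_stat"] > params.f_min)
    logger.info("selected %d instrument(s) for %s (min F=%s)",
                len(out.df), table.trait_label,
                f"{out.df['f_stat'].min():.1f}" if len(out.df) else "n/a")
    return out
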