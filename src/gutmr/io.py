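"""Reading, validation and writing of GWAS summary statistics and LD reference panels.

The canonical on-disk dialect is a tab-separated file with the fixed header
``variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n``.
Positions are 1-based. Written files carry a ``#`` comment header documenting
this; readers skip comment lines. Reference panels are a dosage matrix
(samples x variants, values in {0,1,2}, no header) plus a variant map TSV
(``variant_id  chrom  pos  allele_a  allele_b``).

Only biallelic SNPs with single-base alleles are accepted; indels and
multi-allelic records are rejected at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

VALID_BASES = frozenset("ACGT")

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_FLOAT_COLS = ["eaf", "beta", "se", "pval"]

#: smallest positive double; p-values of exactly 0 are clamped here
SMALLEST_PVAL = np.nextafter(0.0, 1.0)


class GwasConfigError(ValueError):
    """Bad column mapping or configuration."""


class GwasValidationError(ValueError):
    """Summary statistics or panel failed validation."""


@dataclass(frozen=True)
class GwasRecord:
    """One variant's summary statistics for a single trait.

    ``beta`` is the additive per-effect-allele association: a log odds ratio
    for binary traits, trait units otherwise.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float


@dataclass
class GwasTable:
    """One trait's per-variant summary statistics.

    Backed by a pandas DataFrame with the canonical columns; row order is
    preserved through read/write round trips.
    """

    trait_label: str
    trait_type: str  # exposure | outcome | mediator
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in {"exposure", "outcome", "mediator"}:
            raise GwasConfigError(f"unknown trait_type {self.trait_type!r}")
        self.df = validate_gwas_df(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def records(self) -> list[GwasRecord]:
        return [GwasRecord(**row) for row in self.df.to_dict("records")]

    def subset(self, mask) -> "GwasTable":
        out = GwasTable.__new__(GwasTable)
        out.trait_label = self.trait_label
        out.trait_type = self.trait_type
        out.df = self.df.loc[mask].reset_index(drop=True)
        return out


def validate_gwas_df(df: pd.DataFrame, check_pz: bool = False) -> pd.DataFrame:
    """Validate and normalize a canonical summary-statistics frame.

    Upper-cases alleles, clamps pval == 0 to the smallest positive double
    (with a warning), and raises :class:`GwasValidationError` listing the
    offending row indices for any hard failure. With ``check_pz`` the p-value
    is additionally checked against the two-sided normal tail of beta/se.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise GwasConfigError(f"missing canonical columns: {missing}")
    df = df[CANONICAL_COLUMNS].copy().reset_index(drop=True)

    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    bad_rows: dict[int, str] = {}

    def _numeric(col):
        coerced = pd.to_numeric(df[col], errors="coerce")
        for i in np.flatnonzero(coerced.isna().to_numpy()):
            bad_rows.setdefault(int(i), f"non-numeric {col}")
        return coerced.astype(float)

    df["pos"] = _numeric("pos")
    for col in _FLOAT_COLS + ["n"]:
        df[col] = _numeric(col)
    if bad_rows:
        raise GwasValidationError(f"rows failed numeric coercion: {bad_rows}")
    df["pos"] = df["pos"].astype(np.int64)

    zero_p = df["pval"] == 0
    if zero_p.any():
        warnings.warn(
            f"{int(zero_p.sum())} p-value(s) of 0 clamped to {SMALLEST_PVAL:g}",
            stacklevel=2,
        )
        df.loc[zero_p, "pval"] = SMALLEST_PVAL

    def _flag(mask: pd.Series, reason: str) -> None:
        for i in np.flatnonzero(mask.to_numpy()):
            bad_rows.setdefault(int(i), reason)

    _flag(~df["effect_allele"].isin(VALID_BASES), "effect_allele not a single base (indels rejected)")
    _flag(~df["other_allele"].isin(VALID_BASES), "other_allele not a single base (indels rejected)")
    _flag(df["effect_allele"] == df["other_allele"], "effect_allele equals other_allele")
    _flag(~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf outside (0,1)")
    _flag(~(df["se"] > 0), "se must be > 0")
    _flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0,1]")
    _flag(~(df["n"] > 0), "n must be > 0")
    _flag(df["pos"] < 1, "pos must be >= 1 (1-based)")
    if check_pz:
        z = np.abs(df["beta"] / df["se"])
        expected = 2 * stats.norm.sf(z)
        # tolerate rounding in published p-values: order-of-magnitude agreement
        with np.errstate(divide="ignore"):
            off = np.abs(np.log10(df["pval"]) - np.log10(np.maximum(expected, SMALLEST_PVAL))) > 1.0
        _flag(pd.Series(off), "pval inconsistent with beta/se under normal test")

    if bad_rows:
        raise GwasValidationError(f"invalid rows: {bad_rows}")

    dup = df["variant_id"][df["variant_id"].duplicated()].unique().tolist()
    if dup:
        raise GwasValidationError(f"duplicate variant_id values: {dup}")
    return df


def read_summary_stats(
    path,
    trait_label: str = "",
    trait_type: str = "exposure",
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    check_pz: bool = False,
) -> GwasTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's headers, e.g.
    ``{"variant_id": "SNP", "pval": "P"}``; unmapped canonical names are
    assumed to appear verbatim.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype={0: str})
    if column_map:
        rename = {}
        for canonical, header in column_map.items():
            if header not in df.columns:
                raise GwasConfigError(
                    f"mapped column {header!r} (for {canonical!r}) not in {path.name}"
                )
            rename[header] = canonical
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise GwasConfigError(f"{path.name}: missing columns {missing}")
    label = trait_label or path.stem
    return GwasTable(trait_label=label, trait_type=trait_type, df=df)


def write_summary_stats(table: GwasTable, path) -> None:
    """Write the canonical TSV; numeric fields keep full round-trip precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gutmr summary statistics; positions are 1-based; "
                 f"trait={table.trait_label}; type={table.trait_type}\n")
        table.df.to_csv(fh, sep="\t", index=False)


@dataclass
class ReferencePanel:
    """Genotype dosage reference panel used for LD computations.

    ``dosages`` is samples x variants with values in {0,1,2}; ``variant_map``
    has columns variant_id, chrom, pos, allele_a, allele_b in column order.
    """

    variant_map: pd.DataFrame
    dosages: np.ndarray
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        need = ["variant_id", "chrom", "pos", "allele_a", "allele_b"]
        missing = [c for c in need if c not in self.variant_map.columns]
        if missing:
            raise GwasValidationError(f"variant map missing columns {missing}")
        self.variant_map = self.variant_map.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.variant_map):
            raise GwasValidationError(
                f"dosage matrix has {self.dosages.shape[1] if self.dosages.ndim == 2 else '?'}"
                f" columns but variant map lists {len(self.variant_map)} variants"
            )
        if not np.isin(self.dosages, (0, 1, 2)).all():
            bad = np.unique(self.dosages[~np.isin(self.dosages, (0, 1, 2))])
            raise GwasValidationError(f"dosage values outside {{0,1,2}}: {bad.tolist()}")
        self.monomorphic = self.dosages.std(axis=0) == 0
        self._index = {v: i for i, v in enumerate(self.variant_map["variant_id"])}

    @property
    def sample_count(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def column_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in reference panel") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.column_index(variant_id)]

    def position(self, variant_id: str) -> tuple[str, int]:
        i = self.column_index(variant_id)
        row = self.variant_map.iloc[i]
        return str(row["chrom"]), int(row["pos"])


def read_reference_panel(dosage_path, map_path) -> ReferencePanel:
    """Load a dosage TSV (no header) and its variant map into a validated panel."""
    vmap = pd.read_csv(map_path, sep="\t", comment="#", dtype={"chrom": str})
    raw = pd.read_csv(dosage_path, sep="\t", header=None, comment="#")
    dosages = raw.to_numpy()
    if not np.issubdtype(dosages.dtype, np.number):
        raise GwasValidationError("dosage matrix contains non-numeric entries")
    return ReferencePanel(variant_map=vmap, dosages=dosages.astype(np.int8))


def write_reference_panel(panel: ReferencePanel, dosage_path, map_path) -> None:
    panel.variant_map.to_csv(map_path, sep="\t", index=False)
    pd.DataFrame(panel.dosages).to_csv(dosage_path, sep="\t", index=False, header=False)
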