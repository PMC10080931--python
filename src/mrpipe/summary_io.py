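"""Reading, validating and writing GWAS summary statistics.

Summary statistics are delimited tables with one row per SNP.  Column
headers vary across consortia, so a :class:`ColumnMap` translates source
headers to the canonical fields used throughout the package:

``snp_id, effect_allele, other_allele, eaf, beta, se, pval, n, n_case``

Betas are per effect-allele estimates: SD units for continuous traits,
log-odds for binary traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical column order for all summary-statistic tables the package writes
CANONICAL_FIELDS = (
    "snp_id", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_case",
)
REQUIRED_FIELDS = (
    "snp_id", "effect_allele", "other_allele", "beta", "se", "pval", "n",
)

#: genome-wide significance, the instrument-selection threshold
GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary for one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int
    n_case: int | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_BASES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if self.eaf is not None and not np.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}: pval outside (0, 1]")
        if not self.n > 0:
            raise ValueError(f"{self.snp_id}: n must be positive")
        if self.n_case is not None and not 0 < self.n_case <= self.n:
            raise ValueError(f"{self.snp_id}: n_case must be in (0, n]")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; None if EAF missing."""
        if self.eaf is None or np.isnan(self.eaf):
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class ColumnMap:
    """Maps canonical field names to source column headers.

    ``mapping`` entries are canonical -> source header; canonical fields
    absent from the mapping are assumed to use their canonical name.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    delimiter: str = "\t"
    na_values: Sequence[str] = ("NA", "NaN", ".", "")

    def __post_init__(self) -> None:
        unknown = set(self.mapping) - set(CANONICAL_FIELDS)
        if unknown:
            raise ValueError(f"unknown canonical fields in column map: {sorted(unknown)}")

    def source_name(self, canonical: str) -> str:
        return self.mapping.get(canonical, canonical)

    def rename_dict(self) -> dict[str, str]:
        """source header -> canonical name."""
        return {self.source_name(c): c for c in CANONICAL_FIELDS}


@dataclass
class GwasDataset:
    """A trait's summary statistics keyed by unique rsID.

    The table always carries the canonical columns in canonical order;
    ``eaf`` and ``n_case`` may hold NaN.
    """

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in ("eaf", "n_case") if c not in self.table.columns]
        tab = self.table.copy()
        for c in missing:
            tab[c] = np.nan
        tab = tab.loc[:, list(CANONICAL_FIELDS)].reset_index(drop=True)
        # n_case/eaf are optional: keep a stable float dtype across round trips
        for c in ("eaf", "n_case"):
            tab[c] = pd.to_numeric(tab[c], errors="coerce").astype(float)
        if tab["snp_id"].duplicated().any():
            dups = tab.loc[tab["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_ids in {self.trait_name}: {dups[:5]}")
        self.table = tab
        self._index = pd.Index(tab["snp_id"])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def get(self, snp_id: str) -> GwasRecord:
        loc = self._index.get_loc(snp_id)
        return self._record(self.table.iloc[loc])

    def records(self) -> Iterator[GwasRecord]:
        for row in self.table.itertuples(index=False):
            yield self._row_record(row)

    @staticmethod
    def _record(row: pd.Series) -> GwasRecord:
        return GwasRecord(
            snp_id=row["snp_id"],
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=None if pd.isna(row["eaf"]) else float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=int(row["n"]),
            n_case=None if pd.isna(row["n_case"]) else int(row["n_case"]),
        )

    @staticmethod
    def _row_record(row) -> GwasRecord:
        return GwasRecord(
            snp_id=row.snp_id,
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            eaf=None if pd.isna(row.eaf) else float(row.eaf),
            beta=float(row.beta),
            se=float(row.se),
            pval=float(row.pval),
            n=int(row.n),
            n_case=None if pd.isna(row.n_case) else int(row.n_case),
        )

    def subset(self, snp_ids: Sequence[str]) -> "GwasDataset":
        keep = self.table[self.table["snp_id"].isin(set(snp_ids))]
        return GwasDataset(self.trait_name, self.trait_type, keep)

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        write_summary_stats(self, path, delimiter=delimiter)


def _validate_frame(df: pd.DataFrame, trait_name: str) -> tuple[pd.DataFrame, dict[str, int]]:
    """Row-level validation; returns clean frame and counts of drop reasons."""
    reasons: dict[str, int] = {}

    def flag(name: str, bad: pd.Series) -> pd.Series:
        n = int(bad.sum())
        if n:
            reasons[name] = n
        return bad

    alle = df["effect_allele"].astype(str).str.upper()
    allo = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=alle, other_allele=allo)

    bad = flag("invalid-allele", ~(alle.isin(VALID_BASES) & allo.isin(VALID_BASES)))
    bad |= flag("identical-alleles", alle == allo)
    bad |= flag("nonpositive-se", ~(pd.to_numeric(df["se"], errors="coerce") > 0))
    bad |= flag("missing-beta", pd.to_numeric(df["beta"], errors="coerce").isna())
    pv = pd.to_numeric(df["pval"], errors="coerce")
    bad |= flag("invalid-pval", ~((pv > 0) & (pv <= 1)))
    nn = pd.to_numeric(df["n"], errors="coerce")
    bad |= flag("invalid-n", ~(nn > 0))
    ef = pd.to_numeric(df["eaf"], errors="coerce")
    bad |= flag("eaf-out-of-range", ef.notna() & ~((ef >= 0) & (ef <= 1)))

    clean = df.loc[~bad].copy()
    for col in ("eaf", "beta", "se", "pval", "n", "n_case"):
        clean[col] = pd.to_numeric(clean[col], errors="coerce")
    clean["n"] = clean["n"].astype(np.int64)
    if reasons:
        total = int(bad.sum())
        logger.warning("%s: dropped %d invalid row(s): %s", trait_name, total, reasons)
    return clean, reasons


def read_summary_stats(
    path: str | Path,
    colmap: ColumnMap | None = None,
    trait_name: str = "",
    trait_type: str = "continuous",
) -> GwasDataset:
    """Read a delimited summary-statistics table into a :class:`GwasDataset`.

    Rows failing field validation (invalid alleles, se <= 0, p outside
    (0,1], ...) are dropped with a logged warning; missing mapped columns
    are fatal.
    """
    colmap = colmap or ColumnMap()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    trait_name = trait_name or path.stem

    df = pd.read_csv(
        path, sep=colmap.delimiter, na_values=list(colmap.na_values),
        keep_default_na=False, dtype={colmap.source_name("snp_id"): str},
        float_precision="round_trip",
    )
    missing = [colmap.source_name(f) for f in REQUIRED_FIELDS
               if colmap.source_name(f) not in df.columns]
    if missing:
        raise ValueError(f"{path}: mapped column(s) not in header: {missing}")

    df = df.rename(columns=colmap.rename_dict())
    for optional in ("eaf", "n_case"):
        if optional not in df.columns:
            df[optional] = np.nan
    df = df.loc[:, list(CANONICAL_FIELDS)]
    clean, _ = _validate_frame(df, trait_name)
    return GwasDataset(trait_name=trait_name, trait_type=trait_type, table=clean)


def write_summary_stats(dataset: GwasDataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write the canonical columns; round-trips exactly through ``read_summary_stats``."""
    out = dataset.table.copy()
    out.to_csv(path, sep=delimiter, index=False, na_rep="NA",
               float_format="%.17g")


def select_instruments(exposure: GwasDataset, p_threshold: float = GENOME_WIDE_P) -> GwasDataset:
    """Genome-wide-significant subset of an exposure GWAS.

    The comparison is strict (p < threshold); boundary p-values are
    excluded.  Raises if no SNP survives.
    """
    if len(exposure) == 0:
        raise ValueError(f"{exposure.trait_name}: empty exposure dataset")
    keep = exposure.table[exposure.table["pval"] < p_threshold]
    if keep.empty:
        raise ValueError(
            f"{exposure.trait_name}: no instruments at p < {p_threshold:g}")
    logger.info("%s: %d/%d SNPs selected at p < %g",
                exposure.trait_name, len(keep), len(exposure), p_threshold)
    return GwasDataset(exposure.trait_name, exposure.trait_type, keep)
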