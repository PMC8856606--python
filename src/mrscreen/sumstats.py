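"""GWAS summary-statistics data model and delimited-text I/O.

A summary-statistics table holds one row per SNP with the nine canonical
association fields (identifier, position, alleles, effect-allele frequency,
standardized effect size, standard error, p-value, sample size).  Foreign
column headers are adapted through a :class:`ColumnMap`; the canonical
on-disk format is tab-delimited with the fixed header
``SNP CHR POS EA OA EAF BETA SE P N``.

Positions are 1-based, genome build 37.  Alleles are single uppercase
characters; multi-character alleles (indels) are dropped because the
pipeline is SNP-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for on-disk summary statistics.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_VALID_ALLELES = frozenset("ACGT")


class SumstatsError(ValueError):
    """Raised for malformed summary-statistics input or configuration."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to source column names.

    ``n_default`` supplies a constant sample size when the source file has
    no N column (common for consortium dumps that report a single n).
    """

    snp: str = "SNP"
    chrom: str = "CHR"
    pos: str = "POS"
    effect_allele: str = "EA"
    other_allele: str = "OA"
    eaf: str = "EAF"
    beta: str = "BETA"
    se: str = "SE"
    pval: str = "P"
    n: str | None = "N"
    n_default: float | None = None
    delimiter: str | None = None  # None -> sniff tab/comma
    na_token: str = "NA"

    def required_columns(self) -> list[str]:
        cols = [self.snp, self.chrom, self.pos, self.effect_allele,
                self.other_allele, self.eaf, self.beta, self.se, self.pval]
        if self.n is not None:
            cols.append(self.n)
        return cols


@dataclass
class SummaryStats:
    """Per-SNP GWAS association records for one trait.

    ``data`` is a DataFrame with the canonical columns; row order is the
    parse order and is preserved by every operation in the package.
    """

    trait_name: str
    data: pd.DataFrame
    trait_type: str = "continuous"  # binary | continuous

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise SumstatsError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SumstatsError(f"summary statistics missing columns: {missing}")
        self.data = self.data.loc[:, CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.data["SNP"].to_numpy()

    def subset(self, mask) -> "SummaryStats":
        """New SummaryStats keeping rows where ``mask`` is true (order kept)."""
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def equals(self, other: "SummaryStats") -> bool:
        return (
            self.trait_name == other.trait_name
            and self.trait_type == other.trait_type
            and self.data.equals(other.data)
        )


def _validate_rows(df: pd.DataFrame, na_token: str) -> tuple[pd.DataFrame, int]:
    """Coerce types, uppercase alleles, and drop unusable rows.

    Returns the clean frame and the number of rows dropped.  A row is
    dropped when any mandatory field is missing/unparseable, an allele is
    not a single A/C/G/T character, the two alleles coincide, the SE is
    not positive, the EAF is outside (0, 1), the p-value is outside
    (0, 1], or the position is < 1.
    """
    n_in = len(df)
    df = df.replace(na_token, np.nan)

    def _parse(x):
        # Python's float() is correctly rounded, so written values
        # round-trip bit-exactly (pandas' fast parser can be 1 ulp off)
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    for col in ("POS", "EAF", "BETA", "SE", "P", "N"):
        df[col] = df[col].map(_parse)
    df["SNP"] = df["SNP"].astype(str)
    df["CHR"] = df["CHR"].astype(str)
    for col in ("EA", "OA"):
        df[col] = df[col].astype(str).str.upper()

    ok = df[CANONICAL_COLUMNS].notna().all(axis=1)
    ok &= df["EA"].isin(_VALID_ALLELES) & df["OA"].isin(_VALID_ALLELES)
    ok &= df["EA"] != df["OA"]
    ok &= df["SE"] > 0
    ok &= (df["EAF"] > 0) & (df["EAF"] < 1)
    ok &= (df["P"] > 0) & (df["P"] <= 1)
    ok &= df["POS"] >= 1
    clean = df.loc[ok].reset_index(drop=True)
    clean["POS"] = clean["POS"].astype(np.int64)
    for col in ("EAF", "BETA", "SE", "P", "N"):
        clean[col] = clean[col].astype(np.float64)
    return clean, n_in - len(clean)


def read_sumstats(
    path,
    colmap: ColumnMap | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
) -> SummaryStats:
    """Read a delimited summary-statistics file into a :class:`SummaryStats`.

    Rows with missing or unparseable mandatory fields are dropped with a
    logged count; parsing is order-preserving.

    Raises
    ------
    SumstatsError
        If a mapped column is absent from the header, or the file is empty.
    """
    colmap = colmap or ColumnMap()
    sep = colmap.delimiter if colmap.delimiter is not None else None
    import csv

    try:
        raw = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                          comment=None, skip_blank_lines=True)
    except (pd.errors.EmptyDataError, csv.Error):
        raise SumstatsError(f"empty summary-statistics file: {path}") from None

    missing = [c for c in colmap.required_columns() if c not in raw.columns]
    if missing:
        raise SumstatsError(
            f"mapped column(s) {missing} not found in header of {path}; "
            f"available columns: {list(raw.columns)}"
        )

    rename = {
        colmap.snp: "SNP", colmap.chrom: "CHR", colmap.pos: "POS",
        colmap.effect_allele: "EA", colmap.other_allele: "OA",
        colmap.eaf: "EAF", colmap.beta: "BETA", colmap.se: "SE",
        colmap.pval: "P",
    }
    if colmap.n is not None:
        rename[colmap.n] = "N"
    df = raw.rename(columns=rename)
    if colmap.n is None:
        if colmap.n_default is None:
            raise SumstatsError(
                "ColumnMap has no N column and no n_default constant"
            )
        df["N"] = colmap.n_default
    df = df.loc[:, CANONICAL_COLUMNS]

    clean, n_dropped = _validate_rows(df, colmap.na_token)
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d unparseable row(s)", path, n_dropped)
    name = trait_name if trait_name is not None else str(path)
    return SummaryStats(trait_name=name, data=clean, trait_type=trait_type)


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write canonical tab-delimited summary statistics (full float precision).

    Raises
    ------
    SumstatsError
        If ``stats`` is empty.
    """
    if len(stats) == 0:
        raise SumstatsError("refusing to write empty SummaryStats")
    stats.data.to_csv(path, sep="\t", index=False, float_format="%.17g")
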