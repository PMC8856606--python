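"""Instrumental-variable selection, LD clumping, harmonization, diagnostics.

The instrument pipeline mirrors standard two-sample MR practice: genome-wide
candidates are thresholded on the exposure p-value, pruned to approximately
independent index SNPs by greedy LD clumping (r² < 0.1 within a 500 kb
window by default), stripped of palindromic variants (A/T, C/G — strand
orientation is ambiguous across studies), and aligned to a common effect
allele against the outcome study.  Instrument strength is summarised by the
variance explained per SNP, 2f(1−f)β² for a standardized phenotype, and the
F statistic R²(n−1−k)/((1−R²)k); F < 10 flags a weak instrument set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryStats, SumstatsError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


class HarmonizationError(ValueError):
    """Raised when exposure and outcome cannot be aligned."""


@dataclass
class LDInfo:
    """Pairwise squared correlations among SNPs.

    ``r2`` is a symmetric matrix with unit diagonal, indexed by ``snp_ids``.
    SNPs absent from the reference are treated per the clumping policy
    (retained as their own index by default, as PLINK does).
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 matrix shape {self.r2.shape} != ({k}, {k})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("r2 matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float | None:
        """r² between two SNPs, or None if either is absent."""
        ia = self._index.get(snp_a)
        ib = self._index.get(snp_b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def read_ld_matrix(path) -> LDInfo:
    """Read a square r² matrix file (header row + leading SNP-id column)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return LDInfo(snp_ids=[str(s) for s in df.index], r2=df.to_numpy(dtype=float))


def read_ld_pairs(path, snp_ids=None) -> LDInfo:
    """Read a 3-column pairwise list (snp_a, snp_b, r2) into an LDInfo.

    Unlisted pairs get r² = 0; ``snp_ids`` fixes the ordering (defaults to
    first-appearance order in the file).
    """
    df = pd.read_csv(path, sep=None, engine="python", header=0)
    a, b, r = df.columns[:3]
    if snp_ids is None:
        seen: dict[str, None] = {}
        for s in pd.concat([df[a], df[b]]).astype(str):
            seen.setdefault(s)
        snp_ids = list(seen)
    idx = {s: i for i, s in enumerate(snp_ids)}
    r2 = np.eye(len(snp_ids))
    for sa, sb, rv in zip(df[a].astype(str), df[b].astype(str), df[r].astype(float)):
        if sa in idx and sb in idx:
            r2[idx[sa], idx[sb]] = r2[idx[sb], idx[sa]] = rv
    return LDInfo(snp_ids=list(snp_ids), r2=r2)


def write_ld_matrix(ld: LDInfo, path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


@dataclass
class HarmonizedSet:
    """Aligned per-SNP effects ready for causal-effect estimation.

    All arrays have length k ≥ 1; effect sizes are on the scale of the
    exposure study's effect allele for both traits.
    """

    snp_ids: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    eaf_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_out: np.ndarray
    n_exp: np.ndarray
    n_out: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("snp_ids", "beta_exp", "se_exp", "eaf_exp",
                     "beta_out", "se_out", "eaf_out", "n_exp", "n_out"):
            a = np.asarray(getattr(self, name))
            if name != "snp_ids":
                a = a.astype(float)
            arrays[name] = a
            setattr(self, name, a)
        k = len(arrays["snp_ids"])
        if k < 1:
            raise HarmonizationError("harmonized set is empty")
        for name, a in arrays.items():
            if len(a) != k:
                raise ValueError(f"{name} has length {len(a)}, expected {k}")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("all standard errors must be > 0")
        if len(np.unique(self.snp_ids)) != k:
            raise ValueError("duplicate snp_ids in harmonized set")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def drop(self, snp_ids) -> "HarmonizedSet":
        """New set without the given SNPs (order of the rest preserved)."""
        mask = ~np.isin(self.snp_ids, list(snp_ids))
        return self.take(np.flatnonzero(mask))

    def take(self, indices) -> "HarmonizedSet":
        idx = np.asarray(indices)
        return HarmonizedSet(
            snp_ids=self.snp_ids[idx],
            beta_exp=self.beta_exp[idx], se_exp=self.se_exp[idx],
            eaf_exp=self.eaf_exp[idx],
            beta_out=self.beta_out[idx], se_out=self.se_out[idx],
            eaf_out=self.eaf_out[idx],
            n_exp=self.n_exp[idx], n_out=self.n_out[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": self.snp_ids,
            "beta_exp": self.beta_exp, "se_exp": self.se_exp,
            "eaf_exp": self.eaf_exp,
            "beta_out": self.beta_out, "se_out": self.se_out,
            "eaf_out": self.eaf_out,
            "n_exp": self.n_exp, "n_out": self.n_out,
        })


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Instrument-strength summary for a harmonized set."""

    r2_exp: float
    r2_out: float
    f_stat: float
    weak_flag: bool


def select_by_pvalue(stats: SummaryStats, threshold: float) -> SummaryStats:
    """Keep rows with p strictly below ``threshold`` (order preserved)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return stats.subset(stats.data["P"].to_numpy() < threshold)


def is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMIC_PAIRS


def drop_palindromic(stats: SummaryStats) -> SummaryStats:
    """Remove SNPs with A/T or C/G allele pairs (strand-ambiguous)."""
    ea = stats.data["EA"].to_numpy()
    oa = stats.data["OA"].to_numpy()
    keep = np.array([not is_palindromic(a, b) for a, b in zip(ea, oa)],
                    dtype=bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("drop_palindromic(%s): removed %d palindromic SNP(s)",
                    stats.trait_name, n_dropped)
    return stats.subset(keep)


def clump(
    stats: SummaryStats,
    ld: LDInfo | None,
    r2_max: float = 0.1,
    window_bp: int = 500_000,
    strict_missing: bool = False,
) -> SummaryStats:
    """Greedy LD clumping to independent index SNPs.

    Repeatedly takes the smallest-p unselected SNP as an index (ties broken
    by chromosome, position, identifier) and discards every unselected SNP
    on the same chromosome within ``window_bp`` of it whose r² with the
    index is ≥ ``r2_max``.  Pairs farther apart than the window are always
    considered independent.  SNPs absent from the LD reference are retained
    as their own index with a warning unless ``strict_missing`` drops them.
    """
    df = stats.data
    if len(df) == 0:
        return stats
    order = df.sort_values(
        ["P", "CHR", "POS", "SNP"], kind="mergesort"
    ).index.to_numpy()

    chrom = df["CHR"].to_numpy()
    pos = df["POS"].to_numpy()
    snp = df["SNP"].to_numpy()

    state = np.zeros(len(df), dtype=np.int8)  # 0 free, 1 index, -1 discarded
    n_missing = 0
    for i in order:
        if state[i] != 0:
            continue
        in_ld_ref = ld is not None and snp[i] in ld._index
        if ld is not None and not in_ld_ref:
            n_missing += 1
            if strict_missing:
                state[i] = -1
                continue
        state[i] = 1
        if ld is None:
            continue
        near = (
            (state == 0)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        for j in np.flatnonzero(near):
            r2 = ld.lookup(snp[i], snp[j])
            if r2 is not None and r2 >= r2_max:
                state[j] = -1
    if n_missing:
        logger.warning("clump(%s): %d SNP(s) missing from LD reference (%s)",
                       stats.trait_name, n_missing,
                       "dropped" if strict_missing else "kept as own index")
    return stats.subset(state == 1)


def harmonize(exp: SummaryStats, out: SummaryStats) -> HarmonizedSet:
    """Align outcome effects to the exposure study's effect alleles.

    Inner join on SNP identifier after removing all copies of duplicated
    identifiers from either side.  Outcome alleles equal to the exposure
    pair are kept as-is; a swapped pair negates the outcome beta and
    reflects its frequency; pairs matching only after complementing both
    outcome alleles (strand flip) follow the same rule post-complement;
    anything else is ambiguous and dropped with a log entry.  Palindromic
    SNPs must have been removed upstream and are dropped defensively here.
    """
    e = exp.data
    o = out.data

    def _dedup(df: pd.DataFrame, label: str) -> pd.DataFrame:
        dup = df["SNP"].duplicated(keep=False)
        if dup.any():
            logger.info("harmonize: dropping %d duplicated SNP row(s) from %s",
                        int(dup.sum()), label)
        return df.loc[~dup]

    e = _dedup(e, "exposure")
    o = _dedup(o, "outcome")

    merged = e.merge(o, on="SNP", suffixes=("_exp", "_out"), how="inner")
    if len(merged) == 0:
        logger.warning("harmonize: no shared SNPs between %s and %s",
                       exp.trait_name, out.trait_name)
        raise HarmonizationError(
            f"no shared SNPs between {exp.trait_name!r} and {out.trait_name!r}"
        )

    beta_out = merged["BETA_out"].to_numpy(dtype=float).copy()
    eaf_out = merged["EAF_out"].to_numpy(dtype=float).copy()
    keep = np.ones(len(merged), dtype=bool)
    n_ambiguous = 0
    for i, row in enumerate(merged.itertuples(index=False)):
        ea_e, oa_e = row.EA_exp, row.OA_exp
        ea_o, oa_o = row.EA_out, row.OA_out
        if is_palindromic(ea_e, oa_e) or is_palindromic(ea_o, oa_o):
            keep[i] = False
            n_ambiguous += 1
            continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            continue
        if (ea_o, oa_o) == (oa_e, ea_e):
            beta_out[i] = -beta_out[i]
            eaf_out[i] = 1.0 - eaf_out[i]
            continue
        ea_c, oa_c = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
        if (ea_c, oa_c) == (ea_e, oa_e):
            continue
        if (ea_c, oa_c) == (oa_e, ea_e):
            beta_out[i] = -beta_out[i]
            eaf_out[i] = 1.0 - eaf_out[i]
            continue
        keep[i] = False
        n_ambiguous += 1
    if n_ambiguous:
        logger.info("harmonize: dropped %d ambiguous/palindromic SNP(s)", n_ambiguous)
    if not keep.any():
        raise HarmonizationError("all shared SNPs were ambiguous")

    m = merged.loc[keep]
    idx = np.flatnonzero(keep)
    return HarmonizedSet(
        snp_ids=m["SNP"].to_numpy(),
        beta_exp=m["BETA_exp"].to_numpy(dtype=float),
        se_exp=m["SE_exp"].to_numpy(dtype=float),
        eaf_exp=m["EAF_exp"].to_numpy(dtype=float),
        beta_out=beta_out[idx],
        se_out=m["SE_out"].to_numpy(dtype=float),
        eaf_out=eaf_out[idx],
        n_exp=m["N_exp"].to_numpy(dtype=float),
        n_out=m["N_out"].to_numpy(dtype=float),
    )


def variance_explained(beta, eaf):
    """Variance in a standardized phenotype explained by a SNP: 2f(1−f)β²."""
    beta = np.asarray(beta, dtype=float)
    f = np.asarray(eaf, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("effect-allele frequency must lie in (0, 1)")
    return 2.0 * f * (1.0 - f) * beta**2


def f_statistic(r2: float, n: float, k: int) -> float:
    """Instrument-strength F statistic: R²(n−1−k) / ((1−R²)k)."""
    if not 0 <= r2 < 1:
        raise ValueError(f"R² must lie in [0, 1), got {r2}")
    if k < 1:
        raise ValueError(f"instrument count must be ≥ 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"sample size {n} must exceed k + 1 = {k + 1}")
    return r2 * (n - 1 - k) / ((1.0 - r2) * k)


def diagnostics(hset: HarmonizedSet) -> InstrumentDiagnostics:
    """Variance explained on both sides and the exposure-side F statistic.

    Sample size per side is the median of the per-SNP values (meta-analysed
    GWAS report slightly varying effective n per variant).
    """
    r2_exp = float(variance_explained(hset.beta_exp, hset.eaf_exp).sum())
    r2_out = float(variance_explained(hset.beta_out, hset.eaf_out).sum())
    n_exp = float(np.median(hset.n_exp))
    f = f_statistic(r2_exp, n_exp, hset.k)
    return InstrumentDiagnostics(
        r2_exp=r2_exp, r2_out=r2_out, f_stat=f, weak_flag=f < 10.0
    )


def read_confounder_table(path) -> pd.DataFrame:
    """Read a SNP × trait matrix of association p-values (SNP ids as index)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def confounder_filter(
    hset: HarmonizedSet, conf_table: pd.DataFrame, alpha: float = 0.05
) -> HarmonizedSet:
    """Drop instruments nominally associated (p < alpha) with any confounder.

    SNPs absent from the table are retained.
    """
    keep = np.ones(hset.k, dtype=bool)
    for i, snp in enumerate(hset.snp_ids):
        if snp in conf_table.index:
            pvals = conf_table.loc[snp].to_numpy(dtype=float)
            if np.any(pvals < alpha):
                keep[i] = False
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("confounder_filter: removed %d instrument(s)", n_removed)
    if not keep.any():
        raise HarmonizationError("confounder filter removed every instrument")
    return hset.take(np.flatnonzero(keep))
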