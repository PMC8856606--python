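"""Exposure × outcome causal screen with per-taxonomic-level significance.

Runs the full instrument pipeline for every exposure–outcome pair —
p-value selection, LD clumping, palindrome removal, harmonization,
optional confounder filtering, MR-PRESSO outlier pruning, the five
estimators, and the sensitivity suite — then flags significance from the
IVW p-value against a Bonferroni threshold computed per taxonomic level
(0.05 divided by the number of taxa tested at that level).  The reverse
screen swaps the roles of traits and taxa and uses a single 0.05/(number
of reverse pairs) threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as est
from . import sensitivity as sens
from .instruments import (HarmonizationError, HarmonizedSet, LDInfo, clump,
                          confounder_filter, diagnostics, drop_palindromic,
                          select_by_pvalue)
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

#: The six taxonomic levels a bacterial feature may belong to.
LEVELS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonMeta:
    """Identity of one bacterial feature (taxon) used as an exposure."""

    feature_id: str
    level: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")


def level_thresholds(counts: dict) -> dict:
    """Bonferroni threshold per level: 0.05 / (taxa tested at that level)."""
    out = {}
    for level, n in counts.items():
        if n <= 0:
            raise ValueError(f"taxa count for level {level!r} must be positive")
        out[level] = 0.05 / n
    return out


@dataclass
class ScreenConfig:
    """Pipeline settings shared by every pair in a screen."""

    selection_pval: float = 1e-5
    clump_r2: float = 0.1
    clump_kb: float = 500.0
    confounder_alpha: float = 0.05
    n_sim: int = 1000          # MR-PRESSO simulations
    n_boot: int = 1000         # weighted-median bootstrap replicates
    seed: int | None = 0
    run_presso: bool = True
    alpha: float = 0.05
    #: optional {level: effective number of independent taxa} override
    effective_counts: dict | None = None


@dataclass
class ScreenResult:
    """Per-pair result table plus retained per-pair detail objects."""

    table: pd.DataFrame
    details: dict
    config: ScreenConfig

    def pair(self, feature_id: str, outcome: str) -> dict:
        key = (feature_id, outcome)
        if key not in self.details:
            raise KeyError(f"pair {key} not present in screen results")
        return self.details[key]


_METHOD_COLS = ["ivw", "mle", "egger", "wme", "presso", "wald_ratio"]


def _empty_row(meta: TaxonMeta | None, fid: str, outcome: str, status: str) -> dict:
    row = {
        "feature_id": fid,
        "level": meta.level if meta else None,
        "feature_name": meta.name if meta else fid,
        "outcome": outcome,
        "status": status,
        "k": 0, "r2_exp": np.nan, "r2_out": np.nan,
        "f_stat": np.nan, "weak_instruments": None,
    }
    for m in _METHOD_COLS:
        row[f"{m}_b"] = np.nan
        row[f"{m}_se"] = np.nan
        row[f"{m}_p"] = np.nan
    row.update({
        "egger_intercept": np.nan, "egger_intercept_p": np.nan,
        "q_ivw_p": np.nan, "q_egger_p": np.nan,
        "presso_global_p": np.nan, "n_outliers_removed": 0,
        "steiger_direction": None, "steiger_p": np.nan,
        "n_methods_concordant": 0,
        "level_threshold": np.nan, "significant": False,
        "primary_p": np.nan,
    })
    return row


def _estimate_pair(hset: HarmonizedSet, cfg: ScreenConfig, pair_seed
                   ) -> tuple[dict, dict]:
    """All applicable estimators + sensitivity for one harmonized pair."""
    results: dict[str, est.MRResult] = {}
    k = hset.k
    if k == 1:
        results["wald_ratio"] = est.wald_ratio(hset)
    if k >= 2:
        results["ivw"] = est.ivw(hset)
        results["mle"] = est.mle(hset)
    if k >= 3:
        results["egger"] = est.egger(hset)
        results["wme"] = est.wme(hset, n_boot=cfg.n_boot, seed=pair_seed)
    report = sens.sensitivity_report(hset, n_sim=cfg.n_sim, seed=pair_seed)
    return results, {"sensitivity": report}


def _concordance(results: dict, primary: est.MRResult, alpha: float) -> int:
    """How many non-primary methods agree with the primary in sign and are
    nominally significant."""
    n = 0
    for name, r in results.items():
        if name == "ivw" or r is None:
            continue
        if np.sign(r.b_xy) == np.sign(primary.b_xy) and r.pval < alpha:
            n += 1
    return n


def _screen_pairs(
    exposures: list,
    outcomes: list[SummaryStats],
    ld: LDInfo | None,
    cfg: ScreenConfig,
    confounders: pd.DataFrame | None,
) -> ScreenResult:
    root = np.random.SeedSequence(cfg.seed)
    pair_seeds = iter(root.spawn(len(exposures) * len(outcomes)))

    rows: list[dict] = []
    details: dict = {}
    for meta, exp_stats in exposures:
        fid = meta.feature_id if isinstance(meta, TaxonMeta) else str(meta)
        m = meta if isinstance(meta, TaxonMeta) else None
        sel = select_by_pvalue(exp_stats, cfg.selection_pval)
        sel = drop_palindromic(sel)
        clumped = clump(sel, ld, r2_max=cfg.clump_r2,
                        window_bp=int(cfg.clump_kb * 1000))
        for out_stats in outcomes:
            pair_seed = next(pair_seeds)
            oname = out_stats.trait_name
            if len(clumped) == 0:
                rows.append(_empty_row(m, fid, oname, "no_instruments"))
                continue
            try:
                hset = _harmonize_safe(clumped, out_stats)
            except HarmonizationError:
                rows.append(_empty_row(m, fid, oname, "no_overlap"))
                continue
            status = "ok"
            if confounders is not None:
                try:
                    hset = confounder_filter(hset, confounders,
                                             cfg.confounder_alpha)
                except HarmonizationError:
                    rows.append(_empty_row(m, fid, oname,
                                           "all_instruments_confounded"))
                    continue

            presso_res = None
            if cfg.run_presso and hset.k >= 4:
                try:
                    presso_res = sens.presso_prune(
                        hset, n_sim=cfg.n_sim,
                        seed=int(pair_seed.generate_state(1)[0] % 2**31))
                    if presso_res.removed_snps:
                        hset = hset.drop(presso_res.removed_snps)
                except sens.UncorrectablePleiotropyError as exc:
                    presso_res = exc.partial
                    status = "presso_uncorrectable"

            wme_seed = int(pair_seed.generate_state(2)[1] % 2**31)
            results, extra = _estimate_pair(hset, cfg, wme_seed)
            if presso_res is not None and presso_res.corrected is not None:
                results["presso"] = presso_res.corrected
            report: sens.SensitivityReport = extra["sensitivity"]
            diag = report.diagnostics

            row = _empty_row(m, fid, oname, status)
            row.update({
                "k": hset.k, "r2_exp": diag.r2_exp, "r2_out": diag.r2_out,
                "f_stat": diag.f_stat, "weak_instruments": diag.weak_flag,
            })
            for name, r in results.items():
                row[f"{name}_b"] = r.b_xy
                row[f"{name}_se"] = r.se
                row[f"{name}_p"] = r.pval
            if "egger" in results:
                row["egger_intercept"] = results["egger"].intercept
                row["egger_intercept_p"] = results["egger"].intercept_pval
            row["q_ivw_p"] = report.q_ivw[2]
            row["q_egger_p"] = report.q_egger[2] if report.q_egger else np.nan
            if presso_res is not None:
                row["presso_global_p"] = presso_res.global_pval
                row["n_outliers_removed"] = len(presso_res.removed_snps)
            row["steiger_direction"] = report.steiger_direction
            row["steiger_p"] = report.steiger_pval
            primary = results.get("ivw", results.get("wald_ratio"))
            row["primary_p"] = primary.pval if primary else np.nan
            if primary is not None:
                row["n_methods_concordant"] = _concordance(
                    results, primary, cfg.alpha)
            rows.append(row)
            details[(fid, oname)] = {
                "hset": hset, "results": results,
                "sensitivity": report, "presso": presso_res,
            }

    table = pd.DataFrame(rows)
    return ScreenResult(table=table, details=details, config=cfg)


def _harmonize_safe(exp_stats: SummaryStats, out_stats: SummaryStats
                    ) -> HarmonizedSet:
    from .instruments import harmonize
    return harmonize(exp_stats, out_stats)


def run_screen(
    exposures: list[tuple[TaxonMeta, SummaryStats]],
    outcomes: list[SummaryStats],
    ld: LDInfo | None = None,
    config: ScreenConfig | None = None,
    confounders: pd.DataFrame | None = None,
) -> ScreenResult:
    """Forward screen: bacterial features as exposures, traits as outcomes.

    Every pair appears exactly once in the result table; pairs that fail a
    pipeline precondition carry a status code instead of being dropped.
    Significance is the IVW p-value (Wald ratio when k = 1) versus the
    per-level threshold 0.05 / (taxa tested at that level); the threshold
    divisor can be overridden with ``config.effective_counts``.
    """
    cfg = config or ScreenConfig()
    result = _screen_pairs(exposures, outcomes, ld, cfg, confounders)
    t = result.table
    tested = t.loc[t["status"].isin(("ok", "presso_uncorrectable"))]
    counts = (tested.groupby("level")["feature_id"].nunique().to_dict()
              if len(tested) else {})
    if cfg.effective_counts:
        counts.update(cfg.effective_counts)
    thresholds = level_thresholds(counts) if counts else {}
    t["level_threshold"] = t["level"].map(thresholds)
    t["significant"] = (t["primary_p"] < t["level_threshold"]).fillna(False)
    return result


def reverse_screen(
    exposures: list[SummaryStats],
    outcomes: list[tuple[TaxonMeta, SummaryStats]],
    ld: LDInfo | None = None,
    config: ScreenConfig | None = None,
    confounders: pd.DataFrame | None = None,
) -> ScreenResult:
    """Reverse screen: traits as exposures, bacterial features as outcomes.

    The pipeline is identical to the forward screen with roles swapped;
    the significance threshold is the single value 0.05 / (number of
    reverse pairs tested).
    """
    cfg = config or ScreenConfig()
    pairs = [(trait.trait_name, trait) for trait in exposures]
    feature_stats = [s for _, s in outcomes]
    result = _screen_pairs(pairs, feature_stats, ld, cfg, confounders)
    t = result.table
    n_tested = int(t["status"].isin(("ok", "presso_uncorrectable")).sum())
    thr = 0.05 / n_tested if n_tested else np.nan
    t["level_threshold"] = thr
    t["significant"] = (t["primary_p"] < thr).fillna(False)
    return result


def export_plot_data(result: ScreenResult, feature_id: str, outcome: str,
                     outdir) -> dict[str, Path]:
    """Write scatter / forest / leave-one-out data files for one pair.

    The scatter file holds one ``point`` row per SNP (effect sizes and SEs
    on both axes) and one ``slope`` row per fitted method (intercept is 0
    except for Egger); the forest file holds per-SNP Wald ratios with 95%
    CIs; the leave-one-out file holds the IVW series of omissions.
    Output is deterministic for identical inputs.
    """
    detail = result.pair(feature_id, outcome)
    hset: HarmonizedSet = detail["hset"]
    results: dict[str, est.MRResult] = detail["results"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{feature_id}__{outcome}".replace("/", "_").replace(" ", "_")

    point_rows = [
        {"kind": "point", "snp": s, "beta_exp": bx, "se_exp": sx,
         "beta_out": by, "se_out": sy, "method": "", "slope": np.nan,
         "intercept": np.nan}
        for s, bx, sx, by, sy in zip(hset.snp_ids, hset.beta_exp,
                                     hset.se_exp, hset.beta_out, hset.se_out)
    ]
    slope_rows = [
        {"kind": "slope", "snp": "", "beta_exp": np.nan, "se_exp": np.nan,
         "beta_out": np.nan, "se_out": np.nan, "method": name,
         "slope": r.b_xy,
         "intercept": r.intercept if r.intercept is not None else 0.0}
        for name, r in sorted(results.items())
    ]
    scatter = pd.DataFrame(point_rows + slope_rows)
    scatter_path = outdir / f"{stem}_scatter.tsv"
    scatter.to_csv(scatter_path, sep="\t", index=False, float_format="%.17g")

    ratios = hset.beta_out / hset.beta_exp
    ratio_se = hset.se_out / np.abs(hset.beta_exp)
    forest = pd.DataFrame({
        "snp": hset.snp_ids, "b_xy": ratios, "se": ratio_se,
        "ci_lower": ratios - 1.959963984540054 * ratio_se,
        "ci_upper": ratios + 1.959963984540054 * ratio_se,
    })
    forest_path = outdir / f"{stem}_forest.tsv"
    forest.to_csv(forest_path, sep="\t", index=False, float_format="%.17g")

    report: sens.SensitivityReport = detail["sensitivity"]
    loo_path = outdir / f"{stem}_loo.tsv"
    loo = report.loo if report.loo is not None else pd.DataFrame(
        columns=["snp", "b_xy", "se", "pval"])
    loo.to_csv(loo_path, sep="\t", index=False, float_format="%.17g")

    return {"scatter": scatter_path, "forest": forest_path, "loo": loo_path}
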