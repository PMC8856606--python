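"""Sensitivity analyses for two-sample MR: pleiotropy, heterogeneity, direction.

* MR-PRESSO: a simulation-based residual-sum-of-squares test.  The global
  test compares the observed weighted RSS around leave-one-out IVW fits to
  its parametric null distribution; the outlier test does the same per SNP.
  The pruning loop removes SNPs in ascending order of their outlier
  p-values, re-running the global test after each removal, until the global
  test is no longer significant — the surviving set then feeds an
  outlier-corrected IVW estimate.
* Cochran's Q (IVW fit, k−1 df) and Rücker's Q′ (Egger fit, k−2 df) for
  heterogeneity.
* Leave-one-out IVW series to detect single-SNP-driven signals.
* Steiger directionality: instruments should explain more variance in the
  exposure than in the outcome if the causal arrow points that way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .estimators import (IVW, EggerRegression, InsufficientInstrumentsError,
                         MRResult, _as_arrays, ivw)
from .instruments import HarmonizedSet, InstrumentDiagnostics, diagnostics

_PRESSO_MIN_K = 4


class UncorrectablePleiotropyError(RuntimeError):
    """Pruning would leave fewer than 4 instruments while the global test
    is still significant; the exposure–outcome pair cannot be corrected.

    The partial result (removals so far) is attached as ``partial``.
    """

    def __init__(self, message: str, partial: "PressoResult"):
        super().__init__(message)
        self.partial = partial


@dataclass
class PressoResult:
    """MR-PRESSO global/outlier test output.

    ``outlier_pvals`` are Bonferroni-adjusted (×k, capped at 1) per-SNP
    p-values from the initial test; ``removed_snps`` lists pruned SNPs in
    removal order; ``corrected`` is the IVW estimate on the survivors
    (method tag ``presso``).
    """

    global_pval: float
    rss_obs: float
    outlier_pvals: pd.Series
    removed_snps: list
    corrected: MRResult | None
    n_sim: int
    seed: int | None
    converged: bool = True


def _loo_slopes(bx, by, w):
    """Leave-one-out origin-constrained WLS slopes, vectorized.

    Works on (k,) vectors or (B, k) matrices (row-wise)."""
    num = np.sum(w * bx * by, axis=-1, keepdims=True) - w * bx * by
    den = np.sum(w * bx**2, axis=-1, keepdims=True) - w * bx**2
    return num / den


def _presso_once(bx, sx, by, sy, n_sim: int, rng
                 ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """One MR-PRESSO global + outlier test.

    Returns (global_pval, rss_obs, raw outlier p-values, observed
    per-SNP weighted squared residuals).
    """
    k = len(bx)
    w = 1.0 / sy**2
    b_loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - b_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(b_loo * bx, sy, size=(n_sim, k))
    b_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    res_sim = w * (by_sim - b_loo_sim * bx_sim) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    outlier_raw = (1.0 + np.sum(res_sim >= res_obs, axis=0)) / (n_sim + 1.0)
    return float(global_pval), rss_obs, outlier_raw, res_obs


class MRPresso(BaseEstimator):
    """MR-PRESSO pleiotropy test with optional recursive outlier pruning.

    Parameters
    ----------
    n_sim : int
        Parametric simulations per global test; the smallest attainable
        p-value is 1/(n_sim + 1).
    random_state : int or None
        Seeds the simulation stream; successive global tests during
        pruning use child streams spawned deterministically from it.
    prune : bool
        Run the recursive removal loop when the initial global test is
        significant at ``global_alpha``.
    rerank : bool
        Re-rank outlier p-values after each removal instead of following
        the initial ascending order.
    global_alpha : float
        Pruning continues while global p ≤ this (p must strictly exceed
        it to stop).
    """

    def __init__(self, n_sim: int = 1000, random_state: int | None = 0,
                 prune: bool = True, rerank: bool = False,
                 global_alpha: float = 0.05):
        self.n_sim = n_sim
        self.random_state = random_state
        self.prune = prune
        self.rerank = rerank
        self.global_alpha = global_alpha

    def fit(self, X, y=None):
        hset = X if isinstance(X, HarmonizedSet) else None
        bx, sx, by, sy = _as_arrays(X)
        k = len(bx)
        if k < _PRESSO_MIN_K:
            raise InsufficientInstrumentsError(
                f"MR-PRESSO requires at least {_PRESSO_MIN_K} instruments, got {k}"
            )
        ids = (hset.snp_ids if hset is not None else
               X["snp"].to_numpy() if isinstance(X, pd.DataFrame) and "snp" in X
               else np.arange(k))
        ids = np.asarray(ids)

        seed_seq = np.random.SeedSequence(self.random_state)
        streams = iter(seed_seq.spawn(k + 1))  # at most k pruning rounds

        g_p, rss, raw, res_obs = _presso_once(
            bx, sx, by, sy, self.n_sim,
            np.random.default_rng(next(streams)))
        adj = pd.Series(np.minimum(1.0, raw * k), index=ids, name="outlier_pval")
        self.global_pval_ = g_p
        self.rss_obs_ = rss
        self.outlier_pvals_ = adj
        removed: list = []

        if self.prune and g_p <= self.global_alpha:
            # ascending initial outlier-p order; p-values are discrete with
            # floor 1/(n_sim+1), so ties (typically several SNPs at the
            # floor) are broken by descending observed weighted residual —
            # the quantity the outlier test ranks
            order = list(np.lexsort((-res_obs, raw)))
            active = np.ones(k, dtype=bool)
            while g_p <= self.global_alpha:
                if active.sum() - 1 < _PRESSO_MIN_K:
                    self.removed_snps_ = removed
                    self.converged_ = False
                    partial = self._result(None)
                    raise UncorrectablePleiotropyError(
                        "pruning would leave fewer than 4 instruments with "
                        "the global test still significant", partial,
                    )
                if self.rerank:
                    sub = np.flatnonzero(active)
                    _, _, raw_sub, res_sub = _presso_once(
                        bx[sub], sx[sub], by[sub], sy[sub], self.n_sim,
                        np.random.default_rng(seed_seq.spawn(1)[0]),
                    )
                    j = sub[int(np.lexsort((-res_sub, raw_sub))[0])]
                else:
                    j = next(i for i in order if active[i])
                active[j] = False
                removed.append(ids[j])
                sub = np.flatnonzero(active)
                g_p, rss, _, _ = _presso_once(
                    bx[sub], sx[sub], by[sub], sy[sub], self.n_sim,
                    np.random.default_rng(next(streams)),
                )
            self.global_pval_ = g_p
            self.rss_obs_ = rss

        self.removed_snps_ = removed
        self.converged_ = True
        survivors = ~np.isin(np.arange(k), [int(np.flatnonzero(ids == r)[0])
                                            for r in removed]) \
            if removed else np.ones(k, dtype=bool)
        corrected = ivw(np.column_stack([bx, sx, by, sy])[survivors])
        corrected.method = "presso"
        self.corrected_ = corrected
        self.b_xy_ = corrected.b_xy
        self.se_ = corrected.se
        self.pval_ = corrected.pval
        self.k_used_ = corrected.k_used
        return self

    def _result(self, corrected) -> PressoResult:
        return PressoResult(
            global_pval=self.global_pval_, rss_obs=self.rss_obs_,
            outlier_pvals=self.outlier_pvals_,
            removed_snps=list(self.removed_snps_),
            corrected=corrected, n_sim=self.n_sim, seed=self.random_state,
            converged=getattr(self, "converged_", True),
        )

    def to_result(self) -> PressoResult:
        return self._result(self.corrected_)


def presso_global(hset, n_sim: int = 1000, seed: int | None = 0) -> PressoResult:
    """MR-PRESSO global and per-SNP outlier tests (no pruning)."""
    return MRPresso(n_sim=n_sim, random_state=seed, prune=False).fit(hset).to_result()


def presso_prune(hset, n_sim: int = 1000, seed: int | None = 0,
                 rerank: bool = False) -> PressoResult:
    """MR-PRESSO with recursive outlier removal until global p > 0.05."""
    return MRPresso(n_sim=n_sim, random_state=seed, prune=True,
                    rerank=rerank).fit(hset).to_result()


def q_test(hset, model: str = "ivw") -> tuple[float, int, float]:
    """Heterogeneity Q statistic about the IVW or Egger fit.

    Returns (Q, df, p) with Q = Σ w_j (β_out,j − fitted_j)², w = 1/se_out²,
    df = k−1 (origin-constrained IVW fit) or k−2 (Egger intercept fit),
    and p from the upper tail of chi-square(df).
    """
    bx, sx, by, sy = _as_arrays(hset)
    k = len(bx)
    w = 1.0 / sy**2
    if model == "ivw":
        if k < 2:
            raise ValueError("Q test (IVW) needs at least 2 instruments")
        b = float(np.sum(w * bx * by) / np.sum(w * bx**2))
        fitted = b * bx
        df = k - 1
    elif model == "egger":
        if k < 3:
            raise ValueError("Q test (Egger) needs at least 3 instruments")
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        est = EggerRegression().fit(np.column_stack([bx, sx, by, sy]))
        fitted = est.intercept_ + est.b_xy_ * bx
        df = k - 2
    else:
        raise ValueError(f"model must be 'ivw' or 'egger', got {model!r}")
    q = float(np.sum(w * (by - fitted) ** 2))
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(hset: HarmonizedSet) -> pd.DataFrame:
    """IVW estimate omitting each instrument in turn.

    Returns a DataFrame (snp, b_xy, se, pval) with one row per omission.
    """
    if hset.k < 3:
        raise InsufficientInstrumentsError(
            "leave-one-out needs at least 3 instruments"
        )
    rows = []
    for j in range(hset.k):
        sub = hset.take([i for i in range(hset.k) if i != j])
        r = ivw(sub, allow_single=True)
        rows.append((hset.snp_ids[j], r.b_xy, r.se, r.pval))
    return pd.DataFrame(rows, columns=["snp", "b_xy", "se", "pval"])


def steiger(hset: HarmonizedSet) -> tuple[bool, float]:
    """Directionality test comparing instrument-explained variance.

    R² on each side is Σ 2f(1−f)β²; the causal direction is credible
    (returns True) when the instruments explain strictly more variance in
    the exposure than in the outcome.  The p-value compares the implied
    correlations √R² via Fisher's z at the two sample sizes.
    """
    if np.any(~np.isfinite(hset.eaf_exp)) or np.any(~np.isfinite(hset.eaf_out)):
        raise ValueError(
            "Steiger test needs effect-allele frequencies on both sides; "
            "frequency imputation is unsupported"
        )
    d = diagnostics(hset)
    r_exp = np.sqrt(d.r2_exp)
    r_out = np.sqrt(d.r2_out)
    n_exp = float(np.median(hset.n_exp))
    n_out = float(np.median(hset.n_out))
    if min(n_exp, n_out) <= 3:
        raise ValueError("sample sizes must exceed 3 for Fisher's z")
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)
    )
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return bool(d.r2_exp > d.r2_out), pval


@dataclass
class SensitivityReport:
    """Per exposure–outcome pair sensitivity summary."""

    q_ivw: tuple[float, int, float]
    q_egger: tuple[float, int, float] | None
    egger_intercept_pval: float | None
    presso: PressoResult | None
    steiger_direction: bool
    steiger_pval: float
    loo: pd.DataFrame | None
    diagnostics: InstrumentDiagnostics


def sensitivity_report(hset: HarmonizedSet, n_sim: int = 1000,
                       seed: int | None = 0) -> SensitivityReport:
    """Assemble the full sensitivity suite for one harmonized pair.

    Components needing more instruments than available are reported as
    None rather than raising.
    """
    k = hset.k
    q_i = q_test(hset, "ivw") if k >= 2 else (0.0, 0, 1.0)
    q_e = q_test(hset, "egger") if k >= 3 else None
    egger_int_p = None
    if k >= 3:
        egger_int_p = EggerRegression().fit(hset).intercept_pval_
    presso = None
    if k >= _PRESSO_MIN_K:
        presso = presso_global(hset, n_sim=n_sim, seed=seed)
    direction, s_p = steiger(hset)
    loo = leave_one_out(hset) if k >= 3 else None
    return SensitivityReport(
        q_ivw=q_i, q_egger=q_e, egger_intercept_pval=egger_int_p,
        presso=presso, steiger_direction=direction, steiger_pval=s_p,
        loo=loo, diagnostics=diagnostics(hset),
    )
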