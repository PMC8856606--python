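"""Causal-effect estimators for two-sample Mendelian randomization.

Each estimator regresses SNP–outcome effects on SNP–exposure effects taken
from two non-overlapping GWAS, under the instrumental-variable assumptions
(relevance, independence from confounders, exclusion restriction).  The
estimators differ in how they trade efficiency against robustness to
horizontal pleiotropy:

``WaldRatio``
    single-instrument ratio β_out/β_exp with first-order delta-method SE.
``IVW``
    inverse-variance weighted combination of per-SNP ratios, equivalent to
    weighted least squares of β_out on β_exp through the origin; assumes no
    horizontal pleiotropy.  Default is a multiplicative random-effects
    model whose SE scale factor is floored at 1.
``MaximumLikelihoodMR``
    joint-normal likelihood that models measurement error in both the
    SNP–exposure and SNP–outcome effects; the per-SNP true effects are
    profiled out in closed form and the causal slope is found by
    one-dimensional profile-likelihood maximization.
``EggerRegression``
    weighted regression with a free intercept; the intercept estimates the
    average directional pleiotropy and a nonzero value flags its presence.
    Consistent (for the slope) even when all instruments are pleiotropic,
    provided pleiotropy is independent of instrument strength.
``WeightedMedian``
    the 50% point of the inverse-variance-weighted empirical distribution
    of per-SNP ratios; consistent when less than half the weight comes from
    invalid instruments.  SE by parametric bootstrap.

All classes follow the scikit-learn estimator protocol: hyperparameters in
``__init__``, ``fit(X)`` with trailing-underscore fitted attributes
(``b_xy_``, ``se_``, ``pval_``, ``k_used_``, and for Egger ``intercept_``
with its SE and p-value), ``get_params``/``set_params`` inherited from
``sklearn.base.BaseEstimator``.  ``X`` may be a :class:`HarmonizedSet`, a
DataFrame with columns ``beta_exp, se_exp, beta_out, se_out``, or a
(k, 4) array in that column order.  Module-level functions wrap the classes
and return :class:`MRResult` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .instruments import HarmonizedSet

_P_FLOOR = np.finfo(float).tiny


class InsufficientInstrumentsError(ValueError):
    """Raised when an estimator receives fewer instruments than it needs."""


class DegenerateInstrumentError(ValueError):
    """Raised when an instrument has zero exposure effect in a ratio."""


class EstimationError(RuntimeError):
    """Raised when numerical optimization fails to converge."""


@dataclass
class MRResult:
    """One estimator's causal estimate with its uncertainty.

    ``b_xy`` is the causal effect of exposure on outcome per unit of
    (standardized) exposure; ``intercept`` fields are populated by the
    Egger regression only.
    """

    method: str
    b_xy: float
    se: float
    pval: float
    k_used: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    extras: dict = field(default_factory=dict)


def _as_arrays(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (beta_exp, se_exp, beta_out, se_out) from any supported input."""
    if isinstance(X, HarmonizedSet):
        bx, sx, by, sy = X.beta_exp, X.se_exp, X.beta_out, X.se_out
    elif isinstance(X, pd.DataFrame):
        try:
            bx = X["beta_exp"].to_numpy(dtype=float)
            sx = X["se_exp"].to_numpy(dtype=float)
            by = X["beta_out"].to_numpy(dtype=float)
            sy = X["se_out"].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(
                "DataFrame input needs columns beta_exp, se_exp, beta_out, se_out"
            ) from exc
    else:
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[1] != 4:
            raise ValueError(
                "array input must have shape (k, 4): beta_exp, se_exp, beta_out, se_out"
            )
        bx, sx, by, sy = A.T
    bx = np.asarray(bx, dtype=float)
    sx = np.asarray(sx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("standard errors must be strictly positive")
    if not (np.all(np.isfinite(bx)) and np.all(np.isfinite(by))):
        raise ValueError("effect sizes must be finite")
    return bx, sx, by, sy


def _norm_p(z: float) -> float:
    return max(float(2.0 * stats.norm.sf(abs(z))), _P_FLOOR)


def _t_p(t: float, df: int) -> float:
    return max(float(2.0 * stats.t.sf(abs(t), df)), _P_FLOOR)


class _MRBase(BaseEstimator):
    """Shared fit plumbing for the MR estimator classes."""

    _method: str = ""
    _min_k: int = 1

    def fit(self, X, y=None):
        bx, sx, by, sy = _as_arrays(X)
        if len(bx) < self._min_k:
            raise InsufficientInstrumentsError(
                f"{self._method} requires at least {self._min_k} instruments, "
                f"got {len(bx)}"
                + (" — use wald_ratio for a single instrument"
                   if self._min_k == 2 else "")
            )
        self.k_used_ = int(len(bx))
        self._fit(bx, sx, by, sy)
        return self

    def _fit(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    def to_result(self) -> MRResult:
        return MRResult(
            method=self._method,
            b_xy=float(self.b_xy_),
            se=float(self.se_),
            pval=float(self.pval_),
            k_used=self.k_used_,
            intercept=getattr(self, "intercept_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_pval=getattr(self, "intercept_pval_", None),
            extras=dict(getattr(self, "extras_", {})),
        )


class WaldRatio(_MRBase):
    """Single-instrument ratio estimate with delta-method SE."""

    _method = "wald_ratio"
    _min_k = 1

    def _fit(self, bx, sx, by, sy):
        if len(bx) != 1:
            raise InsufficientInstrumentsError(
                f"wald_ratio takes exactly one instrument, got {len(bx)}"
            )
        if bx[0] == 0:
            raise DegenerateInstrumentError(
                "exposure effect is zero; the Wald ratio is undefined"
            )
        self.b_xy_ = float(by[0] / bx[0])
        self.se_ = float(sy[0] / abs(bx[0]))
        self.pval_ = _norm_p(self.b_xy_ / self.se_)


class IVW(_MRBase):
    """Inverse-variance weighted estimator (origin-constrained WLS).

    Parameters
    ----------
    effects_model : {"multiplicative_random", "fixed"}
        Random effects scale the fixed-effect SE by the residual standard
        deviation, floored at 1 so under-dispersion never shrinks the SE.
    allow_single : bool
        Permit k = 1, where the estimator coincides with the Wald ratio.
    """

    _method = "ivw"

    def __init__(self, effects_model: str = "multiplicative_random",
                 allow_single: bool = False):
        self.effects_model = effects_model
        self.allow_single = allow_single

    @property
    def _min_k(self) -> int:  # type: ignore[override]
        return 1 if self.allow_single else 2

    def _fit(self, bx, sx, by, sy):
        if self.effects_model not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        w = 1.0 / sy**2
        s_xx = float(np.sum(w * bx**2))
        if s_xx == 0:
            raise DegenerateInstrumentError("all exposure effects are zero")
        b = float(np.sum(w * bx * by) / s_xx)
        se_fixed = s_xx ** -0.5
        k = len(bx)
        scale = 1.0
        if self.effects_model == "multiplicative_random" and k >= 2:
            sigma2 = float(np.sum(w * (by - b * bx) ** 2) / (k - 1))
            scale = max(1.0, np.sqrt(sigma2))
            self.residual_sd_ = float(np.sqrt(sigma2))
        self.b_xy_ = b
        self.se_ = float(se_fixed * scale)
        self.pval_ = _norm_p(b / self.se_)


class MaximumLikelihoodMR(_MRBase):
    """Profile-likelihood maximum-likelihood estimator.

    Joint log-likelihood (up to a constant), with γ_j the latent true
    SNP–exposure effects and b the causal slope::

        l(b, γ) = −½ Σ_j [ (β_exp,j − γ_j)²/se_exp,j²
                          + (β_out,j − b γ_j)²/se_out,j² ]

    For fixed b the optimal γ_j is available in closed form, so b is found
    by maximizing the one-dimensional profile likelihood on
    ``[-bracket, bracket]``; the SE comes from the curvature of the profile
    log-likelihood at the optimum.
    """

    _method = "mle"
    _min_k = 2

    def __init__(self, bracket: float = 50.0, tol: float = 1e-10):
        self.bracket = bracket
        self.tol = tol

    @staticmethod
    def profile_loglik(b, bx, sx, by, sy):
        """Profile log-likelihood of the causal slope (γ maximized out).

        Vectorized over ``b``.
        """
        b = np.atleast_1d(np.asarray(b, dtype=float))[:, None]
        wx = 1.0 / sx**2
        wy = 1.0 / sy**2
        gamma = (bx * wx + b * by * wy) / (wx + b**2 * wy)
        ll = -0.5 * np.sum(
            (bx - gamma) ** 2 * wx + (by - b * gamma) ** 2 * wy, axis=1
        )
        return ll if ll.size > 1 else float(ll[0])

    def _fit(self, bx, sx, by, sy):
        def nll(b):
            return -self.profile_loglik(b, bx, sx, by, sy)

        res = optimize.minimize_scalar(
            nll, bounds=(-self.bracket, self.bracket), method="bounded",
            options={"xatol": self.tol, "maxiter": 2000},
        )
        if not res.success:
            raise EstimationError(f"profile-likelihood optimization failed: {res}")
        b = float(res.x)
        # curvature via central second difference on the profile log-likelihood
        h = 1e-4 * max(1.0, abs(b))
        d2 = (self.profile_loglik(b + h, bx, sx, by, sy)
              - 2.0 * self.profile_loglik(b, bx, sx, by, sy)
              + self.profile_loglik(b - h, bx, sx, by, sy)) / h**2
        if not np.isfinite(d2) or d2 >= 0:
            raise EstimationError(
                f"profile log-likelihood is not locally concave at b = {b}"
            )
        self.b_xy_ = b
        self.se_ = float(np.sqrt(-1.0 / d2))
        self.pval_ = _norm_p(b / self.se_)


class EggerRegression(_MRBase):
    """MR-Egger: weighted regression of β_out on β_exp with free intercept.

    Instruments are oriented so every β_exp is non-negative (both betas
    negated where needed; the fit is invariant to per-SNP orientation).
    The intercept, its SE and p-value quantify directional pleiotropy;
    p-values use Student's t with k − 2 degrees of freedom and the SEs use
    the multiplicative random-effects scale floored at 1.
    """

    _method = "egger"
    _min_k = 3

    def _fit(self, bx, sx, by, sy):
        sign = np.where(bx < 0, -1.0, 1.0)
        bx = bx * sign
        by = by * sign
        w = 1.0 / sy**2
        k = len(bx)

        sw = w.sum()
        swx = float(np.sum(w * bx))
        swxx = float(np.sum(w * bx**2))
        swy = float(np.sum(w * by))
        swxy = float(np.sum(w * bx * by))
        det = sw * swxx - swx**2
        if det <= 0:
            raise DegenerateInstrumentError(
                "exposure effects have no spread; Egger regression is singular"
            )
        slope = (sw * swxy - swx * swy) / det
        intercept = (swxx * swy - swx * swxy) / det
        resid = by - intercept - slope * bx
        sigma2 = float(np.sum(w * resid**2) / (k - 2))
        scale = max(1.0, np.sqrt(sigma2))
        se_slope = np.sqrt(sw / det) * scale
        se_int = np.sqrt(swxx / det) * scale

        self.b_xy_ = float(slope)
        self.se_ = float(se_slope)
        self.pval_ = _t_p(slope / se_slope, k - 2)
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int)
        self.intercept_pval_ = _t_p(intercept / se_int, k - 2)
        self.residual_sd_ = float(np.sqrt(sigma2))


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``values``.

    With weights normalized to sum 1 and values sorted, the cumulative
    weight at value j is s_j = Σ_{i≤j} w_i − w_j/2; the result is the
    linear interpolation of the sorted values at s = 0.5 (clamped to the
    extremes when 0.5 falls outside [s_1, s_k]).
    """
    return float(_weighted_median_rows(values[None, :], weights[None, :])[0])


def _weighted_median_rows(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median for (B, k) matrices."""
    order = np.argsort(V, axis=1)
    Vs = np.take_along_axis(V, order, axis=1)
    Ws = np.take_along_axis(W, order, axis=1)
    Ws = Ws / Ws.sum(axis=1, keepdims=True)
    S = np.cumsum(Ws, axis=1) - Ws / 2.0
    B, k = V.shape
    idx = (S < 0.5).sum(axis=1)  # first position with S >= 0.5
    out = np.empty(B)
    lo_edge = idx == 0
    hi_edge = idx == k
    out[lo_edge] = Vs[lo_edge, 0]
    out[hi_edge] = Vs[hi_edge, -1]
    mid = ~(lo_edge | hi_edge)
    if mid.any():
        i = idx[mid]
        rows = np.flatnonzero(mid)
        s0 = S[rows, i - 1]
        s1 = S[rows, i]
        v0 = Vs[rows, i - 1]
        v1 = Vs[rows, i]
        out[mid] = v0 + (0.5 - s0) / (s1 - s0) * (v1 - v0)
    return out


class WeightedMedian(_MRBase):
    """Weighted median of per-SNP ratio estimates.

    Weights are the first-order inverse variances of the ratios,
    β_exp²/se_out².  The SE is the standard deviation of the estimate over
    ``n_boot`` parametric-bootstrap replicates (both betas resampled from
    their reported normals, weights recomputed); the bootstrap stream is
    fixed by ``random_state``.
    """

    _method = "wme"
    _min_k = 3

    def __init__(self, n_boot: int = 1000, random_state: int | None = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def _fit(self, bx, sx, by, sy):
        if np.any(bx == 0):
            raise DegenerateInstrumentError(
                "zero exposure effect makes a ratio estimate undefined"
            )
        ratios = by / bx
        weights = bx**2 / sy**2
        self.b_xy_ = weighted_median(ratios, weights)

        if self.n_boot < 2:
            raise ValueError("n_boot must be at least 2 for a bootstrap SE")
        rng = np.random.default_rng(self.random_state)
        B = int(self.n_boot)
        bx_b = rng.normal(bx, sx, size=(B, len(bx)))
        by_b = rng.normal(by, sy, size=(B, len(by)))
        ok = np.all(bx_b != 0, axis=1)
        R = by_b[ok] / bx_b[ok]
        W = bx_b[ok] ** 2 / sy**2
        boots = _weighted_median_rows(R, W)
        self.se_ = float(np.std(boots, ddof=1))
        if self.se_ <= 0:
            # degenerate data (all ratios identical); fall back to a tiny SE
            self.se_ = _P_FLOOR ** 0.5
        self.pval_ = _norm_p(self.b_xy_ / self.se_)
        self.boot_estimates_ = boots


def wald_ratio(hset) -> MRResult:
    """Single-instrument causal estimate β_out/β_exp."""
    return WaldRatio().fit(hset).to_result()


def ivw(hset, effects_model: str = "multiplicative_random",
        allow_single: bool = False) -> MRResult:
    """Inverse-variance weighted causal estimate."""
    return IVW(effects_model=effects_model,
               allow_single=allow_single).fit(hset).to_result()


def mle(hset, bracket: float = 50.0, tol: float = 1e-10) -> MRResult:
    """Profile-likelihood maximum-likelihood causal estimate."""
    return MaximumLikelihoodMR(bracket=bracket, tol=tol).fit(hset).to_result()


def egger(hset) -> MRResult:
    """MR-Egger slope and pleiotropy intercept."""
    return EggerRegression().fit(hset).to_result()


def wme(hset, n_boot: int = 1000, seed: int | None = 0) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE."""
    return WeightedMedian(n_boot=n_boot, random_state=seed).fit(hset).to_result()
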