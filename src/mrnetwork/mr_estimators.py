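"""The seven two-sample MR estimators, implemented from their estimating equations.

All estimators consume a harmonized :class:`~mrnetwork.iv_selection.InstrumentSet`
(per-variant exposure effect ``b_X``, outcome effect ``b_Y`` and its ``se_Y``)
and return an :class:`MRResult`.

* ``FE_IVW`` / ``RE_IVW`` — zero-intercept weighted least squares of ``b_Y``
  on ``b_X`` with weights ``1/se_Y^2``; identical point estimate, the RE
  variant inflates the standard error by the multiplicative residual scale
  ``sigma = sqrt(Q / (J - 1))`` (truncated below at 1 by default).
* ``RO_IVW`` — the same regression solved by iteratively reweighted least
  squares with Tukey's biweight; sandwich standard error.
* ``EGGER`` — weighted regression with intercept after orienting all
  exposure effects positive; the slope is the causal estimate and the
  intercept the average directional pleiotropy.
* ``WME`` / ``SM`` — weighted and simple median of the per-variant Wald
  ratios, with parametric-bootstrap standard errors.
* ``WMD`` — weighted kernel-density mode of the Wald ratios (modified
  Silverman bandwidth), parametric-bootstrap standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .iv_selection import InstrumentSet

__all__ = [
    "WaldRatio",
    "MRResult",
    "EstimatorConfig",
    "METHODS",
    "wald_ratios",
    "ivw",
    "egger",
    "median_estimator",
    "weighted_mode",
    "fit_all_models",
]

METHODS = ("RE_IVW", "FE_IVW", "RO_IVW", "EGGER", "WME", "SM", "WMD")

_Z975 = stats.norm.ppf(0.975)
_PMIN = 1e-300  # reported p-values stay strictly inside (0, 1]


@dataclass(frozen=True)
class WaldRatio:
    """Per-variant causal estimate: outcome beta over exposure beta."""

    variant_id: str
    theta: float
    se: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2


@dataclass(frozen=True)
class EstimatorConfig:
    """Tuning constants the estimators need beyond the data itself."""

    bootstrap_B: int = 1000
    mode_phi: float = 1.0
    robust_tuning: float = 4.685
    re_truncate_sigma_at_1: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")


@dataclass
class MRResult:
    """One exposure->outcome causal estimate from one model."""

    exposure_id: str
    outcome_id: str
    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    fdr: float = float("nan")
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    scale_sigma: float | None = None


def _xy(iset: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    r = iset.rows
    return (
        r["b_X"].to_numpy(float),
        r["se_X"].to_numpy(float),
        r["b_Y"].to_numpy(float),
        r["se_Y"].to_numpy(float),
    )


def _finish(
    iset: InstrumentSet, method: str, n: int, beta: float, se: float, **kw
) -> MRResult:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = max(float(2.0 * stats.norm.sf(abs(z))), _PMIN) if np.isfinite(z) else _PMIN
    return MRResult(
        exposure_id=iset.exposure_id,
        outcome_id=iset.outcome_id,
        method=method,
        n_snp=n,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z975 * se),
        ci_high=float(beta + _Z975 * se),
        pval=p,
        **kw,
    )


def wald_ratios(iset: InstrumentSet) -> list[WaldRatio]:
    """Per-IV ratio estimates theta = b_Y / b_X, se = se_Y / |b_X| (delta method).

    Variants with ``b_X = 0`` carry no exposure signal and are excluded with
    a warning.
    """
    out = []
    for r in iset.rows.itertuples(index=False):
        if r.b_X == 0:
            warnings.warn(
                f"{r.variant_id}: b_X = 0, excluded from ratio-based estimators",
                stacklevel=2,
            )
            continue
        out.append(
            WaldRatio(
                variant_id=r.variant_id,
                theta=r.b_Y / r.b_X,
                se=r.se_Y / abs(r.b_X),
            )
        )
    return out


# --------------------------------------------------------------------------
# IVW family
# --------------------------------------------------------------------------

def _ivw_point(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Zero-intercept WLS: returns (beta, fixed-effect se, Cochran's Q)."""
    sxx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y)) / sxx
    fe_se = float(np.sqrt(1.0 / sxx))
    q = float(np.sum(w * (y - beta * x) ** 2))
    return beta, fe_se, q


def ivw(
    iset: InstrumentSet,
    effects_model: str = "multiplicative_random",
    config: EstimatorConfig = EstimatorConfig(),
) -> MRResult:
    """Inverse-variance weighted estimate (fixed, multiplicative-random or robust).

    The point estimate is the zero-intercept WLS slope
    ``sum(b_X b_Y / se_Y^2) / sum(b_X^2 / se_Y^2)``.  The fixed-effect se is
    ``sqrt(1 / sum(b_X^2 / se_Y^2))``; the multiplicative random-effects se
    multiplies it by ``sigma = sqrt(Q / (J - 1))`` (floored at 1 when
    configured); the robust variant re-solves the regression by IRLS with
    Tukey's biweight and reports a sandwich se.
    """
    if effects_model not in ("fixed", "multiplicative_random", "robust"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    x, _, y, se_y = _xy(iset)
    n = len(x)
    if n < 2:
        raise ValueError("IVW requires at least 2 instruments")
    w = 1.0 / se_y**2

    if effects_model == "robust":
        beta, se = _tukey_irls(x, y, w, config.robust_tuning)
        return _finish(iset, "RO_IVW", n, beta, se)

    beta, fe_se, q = _ivw_point(x, y, w)
    if effects_model == "fixed":
        return _finish(iset, "FE_IVW", n, beta, fe_se, scale_sigma=1.0)
    sigma = float(np.sqrt(q / (n - 1))) if n > 1 else 1.0
    if config.re_truncate_sigma_at_1:
        sigma = max(sigma, 1.0)
    return _finish(iset, "RE_IVW", n, beta, fe_se * sigma, scale_sigma=sigma)


def _tukey_irls(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    tuning: float,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Tukey-biweight IRLS for the zero-intercept weighted regression.

    Residuals are standardized by the base weights and scaled by the MAD;
    the returned variance is the HC0 sandwich of the final weighted
    estimating equation.
    """
    sw = np.sqrt(w)
    beta = float(np.sum(w * x * y) / np.sum(w * x * x))  # IVW start
    for _ in range(max_iter):
        r = sw * (y - beta * x)
        # MAD about zero (the regression runs through the origin), normal-consistent
        scale = float(np.median(np.abs(r))) * 1.482602218505602
        if scale <= 0:
            scale = float(np.std(r)) or 1.0
        u = r / (scale * tuning)
        psi_w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        omega = w * psi_w
        denom = float(np.sum(omega * x * x))
        if denom <= 0:  # all points down-weighted to zero; keep last beta
            break
        beta_new = float(np.sum(omega * x * y) / denom)
        if abs(beta_new - beta) < tol * (1.0 + abs(beta)):
            beta = beta_new
            break
        beta = beta_new
    resid = y - beta * x
    denom = float(np.sum(omega * x * x))
    var = float(np.sum((omega * x * resid) ** 2)) / denom**2
    return beta, float(np.sqrt(var))


# --------------------------------------------------------------------------
# MR-Egger
# --------------------------------------------------------------------------

def egger(
    iset: InstrumentSet, config: EstimatorConfig = EstimatorConfig()
) -> MRResult:
    """MR-Egger: weighted regression with intercept, exposure effects oriented positive.

    The slope estimates the causal effect; the intercept the average
    directional pleiotropy.  Standard errors carry the multiplicative
    random-effects scale ``sigma = sqrt(Q_egger / (J - 2))`` (floored at 1
    when configured); both coefficients get two-sided normal p-values.
    """
    x, _, y, se_y = _xy(iset)
    n = len(x)
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.sign(x)
    flip[flip == 0] = 1.0
    x, y = x * flip, y * flip
    w = 1.0 / se_y**2

    X = np.column_stack([np.ones(n), x])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ y)
    a, b = float(coef[0]), float(coef[1])
    q = float(np.sum(w * (y - a - b * x) ** 2))
    sigma = float(np.sqrt(q / (n - 2))) if n > 2 else 1.0
    if config.re_truncate_sigma_at_1:
        sigma = max(sigma, 1.0)
    se_a, se_b = np.sqrt(np.diag(cov_unscaled)) * sigma
    p_a = max(float(2.0 * stats.norm.sf(abs(a / se_a))), _PMIN)
    return _finish(
        iset,
        "EGGER",
        n,
        b,
        float(se_b),
        egger_intercept=a,
        egger_intercept_se=float(se_a),
        egger_intercept_pval=p_a,
        scale_sigma=sigma,
    )


# --------------------------------------------------------------------------
# Median and mode estimators
# --------------------------------------------------------------------------

def _weighted_median_rows(thetas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Interpolated weighted median of each row of ``thetas``.

    ``weights`` is one weight per column; within each row weights follow
    their theta when the row is sorted.  The estimate interpolates linearly
    between the order statistics bracketing cumulative midpoint 1/2.
    """
    thetas = np.atleast_2d(thetas)
    order = np.argsort(thetas, axis=1)
    ts = np.take_along_axis(thetas, order, axis=1)
    ws = np.broadcast_to(weights, thetas.shape)
    ws = np.take_along_axis(ws, order, axis=1)
    ws = ws / ws.sum(axis=1, keepdims=True)
    pk = np.cumsum(ws, axis=1) - ws / 2.0
    out = np.empty(len(thetas))
    for i in range(len(thetas)):
        out[i] = np.interp(0.5, pk[i], ts[i])
    return out


def _ratio_arrays(ratios: Sequence[WaldRatio]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.array([r.theta for r in ratios], dtype=float)
    se = np.array([r.se for r in ratios], dtype=float)
    return theta, se


def median_estimator(
    ratios: Sequence[WaldRatio],
    iset: InstrumentSet,
    weighting: str = "inverse_variance",
    config: EstimatorConfig = EstimatorConfig(),
) -> MRResult:
    """Weighted (WME) or simple (SM) median of the Wald ratios.

    The standard error is the standard deviation of the estimate across
    ``bootstrap_B`` parametric resamples ``theta*_j ~ N(theta_j, se_j)``.
    """
    if weighting not in ("inverse_variance", "simple"):
        raise ValueError(f"unknown weighting {weighting!r}")
    theta, se = _ratio_arrays(ratios)
    n = len(theta)
    if n < 3:
        raise ValueError("median estimators require at least 3 instruments")
    w = 1.0 / se**2 if weighting == "inverse_variance" else np.ones(n)

    est = float(_weighted_median_rows(theta, w)[0])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    draws = rng.normal(theta, se, size=(config.bootstrap_B, n))
    boots = _weighted_median_rows(draws, w)
    se_b = float(np.std(boots, ddof=1))
    method = "WME" if weighting == "inverse_variance" else "SM"
    return _finish(iset, method, n, est, se_b)


def _mode_rows(
    thetas: np.ndarray, weights: np.ndarray, phi: float, grid_points: int = 512
) -> np.ndarray:
    """Weighted KDE mode of each row (Gaussian kernel, modified Silverman bandwidth)."""
    thetas = np.atleast_2d(thetas)
    B, n = thetas.shape
    w = weights / weights.sum()
    sd = np.std(thetas, axis=1, ddof=1)
    iqr = np.subtract(*np.percentile(thetas, [75, 25], axis=1))
    h = phi * 0.9 * np.minimum(sd, iqr / 1.34) * n ** (-0.2)
    out = np.empty(B)
    for lo in range(0, B, 128):
        hi = min(lo + 128, B)
        t = thetas[lo:hi]
        hh = h[lo:hi]
        for i in range(hi - lo):
            ti, hi_ = t[i], hh[i]
            if hi_ <= 0:  # degenerate: all ratios (near-)identical
                out[lo + i] = ti[0]
                continue
            grid = np.linspace(ti.min() - 3 * hi_, ti.max() + 3 * hi_, grid_points)
            dens = np.exp(-0.5 * ((grid[:, None] - ti[None, :]) / hi_) ** 2) @ w
            out[lo + i] = grid[int(np.argmax(dens))]
    return out


def weighted_mode(
    ratios: Sequence[WaldRatio],
    iset: InstrumentSet,
    config: EstimatorConfig = EstimatorConfig(),
) -> MRResult:
    """Weighted mode (WMD): the densest cluster of Wald ratios.

    Inverse-variance weights normalized to sum 1; bandwidth
    ``h = phi * 0.9 * min(sd, IQR/1.34) * J^(-1/5)``; the estimate is the
    argmax of the weighted Gaussian KDE on a 512-point grid spanning
    ``[min - 3h, max + 3h]``; se from the same parametric bootstrap as the
    medians.
    """
    theta, se = _ratio_arrays(ratios)
    n = len(theta)
    if n < 3:
        raise ValueError("weighted mode requires at least 3 instruments")
    w = 1.0 / se**2

    est = float(_mode_rows(theta, w, config.mode_phi)[0])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    draws = rng.normal(theta, se, size=(config.bootstrap_B, n))
    boots = _mode_rows(draws, w, config.mode_phi)
    se_b = float(np.std(boots, ddof=1))
    return _finish(iset, "WMD", n, est, se_b)


def fit_all_models(
    iset: InstrumentSet, config: EstimatorConfig = EstimatorConfig()
) -> list[MRResult]:
    """Fit all seven models on one instrument set (requires >= 3 instruments)."""
    ratios = wald_ratios(iset)
    results = [
        ivw(iset, "multiplicative_random", config),
        ivw(iset, "fixed", config),
        ivw(iset, "robust", config),
        egger(iset, config),
        median_estimator(ratios, iset, "inverse_variance", config),
        median_estimator(ratios, iset, "simple", config),
        weighted_mode(ratios, iset, config),
    ]
    return results
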