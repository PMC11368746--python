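"""Heterogeneity, directional-pleiotropy and MR-PRESSO outlier procedures.

These quantify how badly the instrument set violates the MR assumptions:

* Cochran's Q — weighted heterogeneity of the per-variant Wald ratios
  around the IVW estimate, chi-square(J - 1) under homogeneity.
* Egger intercept test — a nonzero intercept in the Egger regression
  indicates average directional pleiotropy.
* MR-PRESSO — a parametric-simulation residual-sum-of-squares test: the
  global test compares the observed leave-one-out weighted RSS against its
  simulated null distribution; the outlier test compares each variant's
  weighted residual against its own simulated distribution (Bonferroni
  corrected across variants) and prunes the flagged instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .iv_selection import InstrumentSet
from .mr_estimators import MRResult

__all__ = [
    "SensitivityResult",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "sensitivity_suite",
]


@dataclass
class SensitivityResult:
    """Sensitivity statistics for one exposure-outcome pair."""

    Q: float = float("nan")
    Q_df: int = 0
    Q_pval: float = float("nan")
    egger_intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_pval: float = float("nan")
    presso_global_pval: float = float("nan")
    presso_outliers: list[str] = field(default_factory=list)
    presso_sims: int = 0


def cochran_q(
    iset: InstrumentSet, ivw_beta: float | None = None
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test around the IVW estimate.

    ``Q = sum_j w_j (theta_j - beta)^2`` with ratio weights
    ``w_j = b_X^2 / se_Y^2``; upper-tail chi-square with J - 1 df.
    When ``ivw_beta`` is omitted the IVW point estimate is computed here.
    """
    r = iset.rows
    x = r["b_X"].to_numpy(float)
    y = r["b_Y"].to_numpy(float)
    se_y = r["se_Y"].to_numpy(float)
    n = len(x)
    if n < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    w = 1.0 / se_y**2
    if ivw_beta is None:
        ivw_beta = float(np.sum(w * x * y) / np.sum(w * x * x))
    wj = x**2 / se_y**2
    theta = y / x
    q = float(np.sum(wj * (theta - ivw_beta) ** 2))
    df = n - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(egger_result: MRResult) -> tuple[float, float, float]:
    """Directional-pleiotropy test: two-sided normal z-test on the Egger intercept."""
    if egger_result.egger_intercept is None or egger_result.egger_intercept_se is None:
        raise ValueError("result does not carry an Egger intercept")
    a = egger_result.egger_intercept
    se = egger_result.egger_intercept_se
    p = float(2.0 * stats.norm.sf(abs(a / se))) if se > 0 else 0.0
    return a, se, p


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over the left-out index.

    Works on 1-D arrays or on (sims, J) matrices (per-row totals).
    """
    wxy = w * x * y
    wxx = w * x * x
    sxy = wxy.sum(axis=-1, keepdims=True)
    sxx = wxx.sum(axis=-1, keepdims=True)
    return (sxy - wxy) / (sxx - wxx)


def mr_presso(
    iset: InstrumentSet,
    sims: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> tuple[SensitivityResult, InstrumentSet]:
    """MR-PRESSO global and outlier tests; returns statistics plus the pruned set.

    Observed statistic: ``RSS = sum_j w_j (b_Yj - beta_{-j} b_Xj)^2`` with
    ``w_j = 1/se_Yj^2`` and ``beta_{-j}`` the leave-one-out IVW slope.  The
    null distribution comes from ``sims`` parametric draws
    ``b*_X ~ N(b_X, se_X)``, ``b*_Y ~ N(beta_{-j} b_X, se_Y)`` with the RSS
    recomputed on each draw; global p uses add-one smoothing.  Per-variant
    residuals are compared with their own simulated distributions and
    Bonferroni-corrected across the J variants; flagged variants are removed
    from the returned instrument set (provenance updated).
    """
    r = iset.rows
    x = r["b_X"].to_numpy(float)
    y = r["b_Y"].to_numpy(float)
    se_x = r["se_X"].to_numpy(float)
    se_y = r["se_Y"].to_numpy(float)
    n = len(x)
    if n < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    w = 1.0 / se_y**2

    beta_loo = _loo_slopes(x, y, w)
    resid_obs = w * (y - beta_loo * x) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    x_star = rng.normal(x, se_x, size=(sims, n))
    y_star = rng.normal(beta_loo * x, se_y, size=(sims, n))
    beta_loo_star = _loo_slopes(x_star, y_star, w)
    resid_star = w * (y_star - beta_loo_star * x_star) ** 2
    rss_star = resid_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (sims + 1))
    pj = (1 + np.sum(resid_star >= resid_obs, axis=0)) / (sims + 1)
    pj_bonf = np.minimum(pj * n, 1.0)
    flagged = pj_bonf < outlier_alpha
    outliers = r.loc[flagged, "variant_id"].tolist()

    pruned_rows = r.loc[~flagged].reset_index(drop=True)
    prov = dict(iset.provenance)
    prov["presso_outlier"] = int(flagged.sum())
    prov["final"] = len(pruned_rows)
    pruned = InstrumentSet(
        exposure_id=iset.exposure_id,
        outcome_id=iset.outcome_id,
        rows=pruned_rows,
        provenance=prov,
    )
    result = SensitivityResult(
        presso_global_pval=global_p,
        presso_outliers=outliers,
        presso_sims=sims,
    )
    return result, pruned


def sensitivity_suite(
    iset: InstrumentSet,
    egger_result: MRResult | None = None,
    ivw_beta: float | None = None,
    presso: SensitivityResult | None = None,
) -> SensitivityResult:
    """Assemble the full sensitivity record for one pair."""
    out = presso if presso is not None else SensitivityResult()
    q, df, qp = cochran_q(iset, ivw_beta)
    out.Q, out.Q_df, out.Q_pval = q, df, qp
    if egger_result is not None and egger_result.egger_intercept is not None:
        a, se, p = egger_intercept_test(egger_result)
        out.egger_intercept, out.intercept_se, out.intercept_pval = a, se, p
    return out
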