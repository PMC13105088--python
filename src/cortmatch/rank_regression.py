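"""Rank-transformed OLS models of a target map on a few feature maps.

All variables (target and each predictor, independently) are replaced by
their within-map average ranks (1 = lowest value, P = highest) before an
ordinary least-squares fit with intercept. The coefficient of
determination R^2 of this fit is a multivariate analogue of squared
Spearman correlation; with a single predictor the two coincide exactly.

Significance is assessed against the target's variogram-matched surrogate
ensemble: each surrogate is rank-transformed and regressed on the same
rank-transformed predictors, and the one-sided p-value is the (add-one)
proportion of surrogate R^2 values at or above the observed one. Because
surrogates inherit the target's spatial smoothness, predictors that share
that smoothness achieve high R^2 on surrogates too — the null adapts to
autocorrelation instead of rewarding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .geometry import BrainMap
from .surrogates import SurrogateEnsemble

__all__ = [
    "RegressionResult",
    "CollinearityError",
    "rank_transform",
    "fit_rank_ols",
    "surrogate_r2_test",
    "residual_map",
]

CONDITION_LIMIT = 1e8


class CollinearityError(ValueError):
    """Design matrix is numerically rank deficient."""


@dataclass(frozen=True)
class RegressionResult:
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, rank units
    r2: float
    fitted: np.ndarray
    residuals: np.ndarray  # observed rank - fitted rank
    target: BrainMap
    p_one_sided: float | None = None
    null_r2: np.ndarray | None = None
    null_r2_median: float | None = None


def rank_transform(brain_map: BrainMap) -> BrainMap:
    """Average ranks, 1 = lowest value, P = highest."""
    return BrainMap(
        name=f"rank({brain_map.name})",
        values=stats.rankdata(brain_map.values),
        geometry=brain_map.geometry,
    )


def _design(X: list[BrainMap]) -> np.ndarray:
    cols = [stats.rankdata(x.values) for x in X]
    return sm.add_constant(np.column_stack(cols))


def _check_design(design: np.ndarray, names: list[str]) -> None:
    if np.linalg.cond(design) > CONDITION_LIMIT:
        # identify predictor pairs with perfectly dependent ranks
        culprits = []
        k = design.shape[1] - 1
        for i in range(k):
            for j in range(i + 1, k):
                r = np.corrcoef(design[:, i + 1], design[:, j + 1])[0, 1]
                if abs(r) > 1 - 1e-10:
                    culprits.append(f"{names[i]} ~ {names[j]}")
        detail = "; ".join(culprits) if culprits else ", ".join(names)
        raise CollinearityError(
            f"rank-deficient design (condition number > {CONDITION_LIMIT:g}): {detail}"
        )


def fit_rank_ols(y: BrainMap, X: list[BrainMap]) -> RegressionResult:
    """OLS with intercept on rank-transformed target and predictors."""
    P = y.geometry.n_parcels
    if not 1 <= len(X) < P - 1:
        raise ValueError("need 1 <= n_predictors < P - 1")
    for x in X:
        y.check_aligned(x)
    names = [x.name for x in X]
    design = _design(X)
    _check_design(design, names)
    yr = stats.rankdata(y.values)
    fit = sm.OLS(yr, design).fit()
    return RegressionResult(
        predictor_names=tuple(names),
        coefficients=np.asarray(fit.params),
        r2=float(fit.rsquared),
        fitted=np.asarray(fit.fittedvalues),
        residuals=yr - np.asarray(fit.fittedvalues),
        target=y,
    )


def _batched_r2(design: np.ndarray, Y_ranks: np.ndarray) -> np.ndarray:
    """R^2 of OLS(design) for many response rows at once via the thin-QR
    projection (the design already contains the intercept column)."""
    Q, _ = np.linalg.qr(design)
    proj = Y_ranks @ Q  # (S, k+1)
    fitted = proj @ Q.T
    resid = Y_ranks - fitted
    ss_res = (resid**2).sum(axis=1)
    ybar = Y_ranks.mean(axis=1, keepdims=True)
    ss_tot = ((Y_ranks - ybar) ** 2).sum(axis=1)
    return 1.0 - ss_res / ss_tot


def surrogate_r2_test(
    y: BrainMap, X: list[BrainMap], ensemble: SurrogateEnsemble
) -> RegressionResult:
    """Observed rank-OLS fit plus its one-sided surrogate R^2 test.

    p = (1 + #{R^2_surrogate >= R^2_observed}) / (S + 1).
    """
    ensemble.check_target(y)
    base = fit_rank_ols(y, X)
    design = _design(X)
    surrogate_ranks = stats.rankdata(ensemble.maps, axis=1)
    null_r2 = _batched_r2(design, surrogate_ranks)
    S = null_r2.size
    p = (1 + int(np.sum(null_r2 >= base.r2))) / (S + 1)
    return RegressionResult(
        predictor_names=base.predictor_names,
        coefficients=base.coefficients,
        r2=base.r2,
        fitted=base.fitted,
        residuals=base.residuals,
        target=y,
        p_one_sided=p,
        null_r2=null_r2,
        null_r2_median=float(np.median(null_r2)),
    )


def residual_map(result: RegressionResult) -> BrainMap:
    """Signed residuals per parcel; positive where the target is higher
    (in rank) than the model predicts."""
    return BrainMap(
        name=f"residuals({result.target.name})",
        values=result.residuals,
        geometry=result.target.geometry,
    )
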