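"""Propensity-score estimation, ATE inverse-probability weights, c-statistic.

The propensity score e(x) = P(Z=1 | X=x) is fit by maximum-likelihood logistic
regression (IRLS).  ATE weights are 1/e(x) for the exposed and 1/(1-e(x)) for
the unexposed, producing a pseudo-population in which measured covariates are
balanced between arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

__all__ = [
    "PSModel",
    "SeparationError",
    "fit_logistic",
    "ate_weights",
    "c_statistic",
    "weighted_smd",
    "PS_CLIP",
    "SEPARATION_LOGIT_BOUND",
]

# Clip fitted probabilities away from {0,1} before weighting; prevents
# infinite weights without materially altering estimates.
PS_CLIP = (1e-6, 1.0 - 1e-6)

# |coefficient| beyond this on the logit scale is treated as (quasi-)complete
# separation.
SEPARATION_LOGIT_BOUND = 15.0


class SeparationError(ValueError):
    """Raised when the logistic MLE diverges (perfect/quasi separation)."""


@dataclass
class PSModel:
    """Fitted logistic propensity model."""

    coefficients: pd.Series  # intercept first, then one entry per covariate
    fitted_ps: np.ndarray    # in (0,1) after clipping
    converged: bool
    iterations: int


def _design(X: pd.DataFrame | np.ndarray | None, n: int) -> tuple[np.ndarray, list[str]]:
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        return np.ones((n, 1)), ["intercept"]
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(mat.shape[1])]
    return np.column_stack([np.ones(len(mat)), mat]), ["intercept", *names]


def fit_logistic(
    X: pd.DataFrame | np.ndarray | None,
    Z: np.ndarray,
    *,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> PSModel:
    """ML logistic regression of exposure Z on covariates X (IRLS).

    Raises on degenerate exposure vectors, singular designs, and detected
    separation (any |coefficient| beyond ``SEPARATION_LOGIT_BOUND``).
    """
    z = np.asarray(Z, dtype=float)
    if np.isnan(z).any() or (X is not None and np.asarray(X, dtype=float).size
                             and np.isnan(np.asarray(X, dtype=float)).any()):
        raise ValueError("missing values in propensity-model inputs")
    if z.sum() == 0:
        raise ValueError("no exposed participants: logistic MLE diverges")
    if z.sum() == len(z):
        raise ValueError("no unexposed participants: logistic MLE diverges")

    design, names = _design(X, len(z))
    if len(z) < design.shape[1]:
        raise ValueError(
            f"n={len(z)} smaller than parameter count {design.shape[1]}"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix (collinear or constant covariate)")

    model = sm.GLM(z, design, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=tol)
    coefs = pd.Series(res.params, index=names)

    worst = coefs.abs().idxmax()
    if abs(coefs[worst]) > SEPARATION_LOGIT_BOUND:
        raise SeparationError(
            f"separation detected: coefficient for {worst!r} is "
            f"{coefs[worst]:.2f} on the logit scale"
        )

    ps = np.clip(np.asarray(res.fittedvalues, dtype=float), *PS_CLIP)
    return PSModel(
        coefficients=coefs,
        fitted_ps=ps,
        converged=bool(res.converged),
        iterations=int(getattr(res.fit_history, "iteration", 0)
                       if not isinstance(res.fit_history, dict)
                       else res.fit_history.get("iteration", 0)),
    )


def ate_weights(ps: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """ATE inverse-probability weights: 1/e for exposed, 1/(1-e) otherwise."""
    e = np.asarray(ps, dtype=float)
    z = np.asarray(Z)
    if np.any(e <= 0.0) or np.any(e >= 1.0):
        raise ValueError("propensity scores must lie strictly inside (0,1)")
    w = np.where(z == 1, 1.0 / e, 1.0 / (1.0 - e))
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite weights")
    return w


def c_statistic(ps: np.ndarray, Z: np.ndarray) -> float:
    """Rank-based AUC: P(ps_exposed > ps_unexposed), ties counted 1/2."""
    e = np.asarray(ps, dtype=float)
    z = np.asarray(Z)
    n1 = int((z == 1).sum())
    n0 = int((z == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic needs both exposed and unexposed rows")
    ranks = rankdata(e)  # average ranks handle ties as 1/2
    u = ranks[z == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def weighted_smd(x: np.ndarray, Z: np.ndarray, w: np.ndarray | None = None) -> float:
    """(Weighted) standardized mean difference of one covariate between arms.

    Uses the unweighted pooled standard deviation as denominator so weighted
    and unweighted SMDs are on the same scale.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(Z)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    m1 = np.average(x[z == 1], weights=w[z == 1])
    m0 = np.average(x[z == 0], weights=w[z == 0])
    v1 = np.var(x[z == 1], ddof=1)
    v0 = np.var(x[z == 0], ddof=1)
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0.0:
        return 0.0
    return float((m1 - m0) / pooled)
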