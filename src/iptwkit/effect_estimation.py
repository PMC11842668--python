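"""Crude and IPTW-weighted risk difference / risk ratio with sandwich SEs.

Two outcome models, both with a single binary regressor (exposure):

* absolute risk difference (aRD): Gaussian GLM with identity link — weighted
  least squares of Y on (1, Z); the slope is the aRD;
* relative risk ratio (rRR): modified Poisson regression — Poisson GLM with log
  link on the binary outcome; exp(slope) is the rRR.

Both use the heteroskedasticity-robust (HC0) sandwich with IPTW weights
treated as fixed: bread = weighted information, meat = sum of weighted score
outer products.  For a saturated (two-arm) design the MLE is the pair of
weighted arm means, which is used directly; the sandwich is assembled
explicitly so the closed-form crude SEs are reproduced exactly at unit
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .synthetic_cohort import TwoByTwo

__all__ = [
    "EffectEstimate",
    "crude_effects",
    "crude_rr",
    "weighted_rd_glm",
    "weighted_rr_modified_poisson",
]

# floor for fitted Poisson means when evaluating the variance
_MU_CLIP = (1e-10, 1.0 - 1e-10)


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate with sandwich SE and Wald CI.

    For scale="RR" the point and CI bounds are on the ratio scale while ``se``
    is the SE of log RR; for scale="RD" everything is on the risk scale.
    """

    scale: str  # "RD" or "RR"
    point: float
    se: float
    ci_level: float
    ci_low: float
    ci_high: float
    n: int | None = None
    cases: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("RD", "RR"):
            raise ValueError(f"scale must be 'RD' or 'RR', got {self.scale!r}")
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.scale == "RR" and self.point <= 0:
            raise ValueError("risk ratio must be positive")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("point estimate must lie inside its CI")


def _arm_stats(Y, Z, w):
    y = np.asarray(Y, dtype=float)
    z = np.asarray(Z)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    m1 = z == 1
    m0 = z == 0
    if not m1.any() or not m0.any():
        raise ValueError("both exposure arms must be present")
    return y, z, w, m1, m0


def _wald(point, se, ci_level):
    zcrit = norm.ppf(0.5 + ci_level / 2.0)
    return point - zcrit * se, point + zcrit * se


def crude_effects(t: TwoByTwo, ci_level: float = 0.95):
    """Closed-form crude RD and RR from a 2x2 table.

    RD = a/(a+b) - c/(c+d) with SE sqrt(p1 q1/n1 + p0 q0/n0);
    RR = [a/(a+b)] / [c/(c+d)] with SE(log RR)
    sqrt((1-p1)/(n1 p1) + (1-p0)/(n0 p0)).  Returns ``(rd, rr)``; when an arm
    has zero cases the RR is undefined and ``rr`` is None (``crude_rr`` raises
    with the reason), while the RD is still returned.
    """
    n1, n0 = t.n_exposed, t.n_unexposed
    p1, p0 = t.risk_exposed, t.risk_unexposed

    rd_point = p1 - p0
    rd_se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
    lo, hi = _wald(rd_point, rd_se, ci_level)
    rd = EffectEstimate("RD", rd_point, rd_se, ci_level, lo, hi,
                        n=t.total, cases=t.a + t.c)

    try:
        rr = crude_rr(t, ci_level)
    except ZeroDivisionError:
        rr = None
    return rd, rr


def crude_rr(t: TwoByTwo, ci_level: float = 0.95) -> EffectEstimate:
    """Closed-form crude RR; raises when an arm has zero cases."""
    n1, n0 = t.n_exposed, t.n_unexposed
    p1, p0 = t.risk_exposed, t.risk_unexposed
    if t.c < 1:
        raise ZeroDivisionError(
            "relative risk undefined: zero cases among the unexposed "
            "(the risk difference is still defined)"
        )
    if t.a < 1:
        raise ZeroDivisionError(
            "relative risk degenerate: zero exposed cases (log CI undefined)"
        )
    rr_point = p1 / p0
    rr_se = float(np.sqrt((1 - p1) / (n1 * p1) + (1 - p0) / (n0 * p0)))
    lo, hi = _wald(np.log(rr_point), rr_se, ci_level)
    return EffectEstimate("RR", rr_point, rr_se, ci_level,
                          float(np.exp(lo)), float(np.exp(hi)),
                          n=t.total, cases=t.a + t.c)


def _sandwich_2x2(design, w, resid, dmu_deta, var_weight):
    """bread^{-1} meat bread^{-1} for a GLM with score w * (y-mu)/... x.

    ``dmu_deta`` and ``var_weight`` give the IRLS working weight
    w_i * dmu_deta_i^2 / V_i; the score contribution is
    w_i * (y_i - mu_i) * dmu_deta_i / V_i * x_i.
    """
    ww = w * dmu_deta**2 / var_weight
    bread = design.T @ (ww[:, None] * design)
    score = (w * resid * dmu_deta / var_weight)[:, None] * design
    meat = score.T @ score
    binv = np.linalg.inv(bread)
    return binv @ meat @ binv


def weighted_rd_glm(Y, Z, w=None, ci_level: float = 0.95) -> EffectEstimate:
    """Weighted identity-link Gaussian GLM of Y on (1, Z): slope = aRD.

    Sandwich (HC0) variance with the weights treated as fixed.
    """
    y, z, w, m1, m0 = _arm_stats(Y, Z, w)
    p1 = np.average(y[m1], weights=w[m1])
    p0 = np.average(y[m0], weights=w[m0])
    point = float(p1 - p0)

    design = np.column_stack([np.ones_like(y), z.astype(float)])
    mu = np.where(z == 1, p1, p0)
    cov = _sandwich_2x2(design, w, y - mu,
                        dmu_deta=np.ones_like(y), var_weight=np.ones_like(y))
    se = float(np.sqrt(cov[1, 1]))
    lo, hi = _wald(point, se, ci_level)
    return EffectEstimate("RD", point, se, ci_level, lo, hi,
                          n=len(y), cases=int(y.sum()))


def weighted_rr_modified_poisson(Y, Z, w=None, ci_level: float = 0.95) -> EffectEstimate:
    """Weighted modified Poisson regression of Y on (1, Z): exp(slope) = rRR.

    Log-link Poisson on the binary outcome; robust sandwich variance on the
    log scale; Wald CI exponentiated.  Requires at least one case per arm
    (the log-link MLE diverges otherwise).
    """
    y, z, w, m1, m0 = _arm_stats(Y, Z, w)
    if y[m1].sum() == 0 or y[m0].sum() == 0:
        raise ValueError("zero cases in one arm: log-link MLE diverges")
    p1 = np.average(y[m1], weights=w[m1])
    p0 = np.average(y[m0], weights=w[m0])
    point = float(p1 / p0)

    design = np.column_stack([np.ones_like(y), z.astype(float)])
    mu = np.where(z == 1, p1, p0)
    mu_v = np.clip(mu, *_MU_CLIP)
    # Poisson, log link: dmu/deta = mu, V = mu  ->  working weight w*mu,
    # score w*(y-mu) x
    cov = _sandwich_2x2(design, w, y - mu, dmu_deta=mu_v, var_weight=mu_v)
    se = float(np.sqrt(cov[1, 1]))
    lo, hi = _wald(np.log(point), se, ci_level)
    return EffectEstimate("RR", point, se, ci_level,
                          float(np.exp(lo)), float(np.exp(hi)),
                          n=len(y), cases=int(y.sum()))
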