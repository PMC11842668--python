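"""Non-probabilistic multiple-bias analysis with the bounding factor.

For an unmeasured confounder U with risk-ratio associations RR_UE (U with
exposure) and RR_UD (U with outcome), both taken >= 1, the bounding factor

    B = (RR_UD * RR_UE) / (RR_UD + RR_UE - 1)

is the largest factor by which joint unmeasured confounding of those strengths
can attenuate an observed risk ratio; the adjusted ratio is
RR_POST = RR_PRE / B.  The minimum equal joint strength that fully explains
away an observed RR (the E-value) is the positive root of
x^2 - 2*RR*x + RR = 0, i.e. x = RR + sqrt(RR*(RR-1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BiasGrid",
    "bounding_factor",
    "adjusted_rr",
    "min_joint_strength",
    "bias_grid",
    "nullification_summary",
]


def bounding_factor(rr_ud, rr_ue):
    """B = (RR_UD * RR_UE) / (RR_UD + RR_UE - 1); inputs must be >= 1."""
    ud = np.asarray(rr_ud, dtype=float)
    ue = np.asarray(rr_ue, dtype=float)
    if np.any(ud < 1.0) or np.any(ue < 1.0):
        raise ValueError(
            "bounding factor assumes harmful-direction ratios: RR_UD and "
            "RR_UE must be >= 1"
        )
    b = ud * ue / (ud + ue - 1.0)
    return float(b) if b.ndim == 0 else b


def adjusted_rr(rr_pre, b):
    """RR_POST = RR_PRE / B."""
    pre = np.asarray(rr_pre, dtype=float)
    bb = np.asarray(b, dtype=float)
    if np.any(pre <= 0.0):
        raise ValueError("observed risk ratio must be positive")
    if np.any(bb < 1.0):
        raise ValueError("bounding factor must be >= 1")
    out = pre / bb
    return float(out) if out.ndim == 0 else out


def min_joint_strength(rr) -> float:
    """Smallest x >= 1 with bounding_factor(x, x) >= rr (the E-value).

    Closed form: x = rr + sqrt(rr * (rr - 1)).
    """
    rr = float(rr)
    if rr < 1.0:
        raise ValueError("rr must be >= 1 (invert protective ratios first)")
    return rr + float(np.sqrt(rr * (rr - 1.0)))


@dataclass
class BiasGrid:
    """Lattice of adjusted risk ratios over (RR_UE, RR_UD) confounder strengths."""

    rr_pre: float
    rr_ue: np.ndarray      # axis values
    rr_ud: np.ndarray
    b: np.ndarray          # (len(rr_ud), len(rr_ue))
    rr_post: np.ndarray    # same shape

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with one row per lattice point."""
        ud, ue = np.meshgrid(self.rr_ud, self.rr_ue, indexing="ij")
        return pd.DataFrame({
            "rr_ue": ue.ravel(),
            "rr_ud": ud.ravel(),
            "b": self.b.ravel(),
            "rr_post": self.rr_post.ravel(),
        })


def bias_grid(rr_pre: float, axis_max: float = 15.0, step: float = 0.5) -> BiasGrid:
    """Adjusted RR over the full (RR_UE, RR_UD) lattice from 1 to ``axis_max``."""
    if rr_pre <= 0:
        raise ValueError("observed risk ratio must be positive")
    axis = np.arange(1.0, axis_max + step / 2, step)
    ud, ue = np.meshgrid(axis, axis, indexing="ij")
    b = bounding_factor(ud, ue)
    return BiasGrid(
        rr_pre=float(rr_pre), rr_ue=axis.copy(), rr_ud=axis.copy(),
        b=b, rr_post=adjusted_rr(rr_pre, b),
    )


def nullification_summary(rr_pre: float, ci_bound: float | None = None) -> dict:
    """E-values for the point estimate and (optionally) the CI bound nearer 1.

    The headline robustness number is the strength needed to move the
    confidence bound nearer the null all the way to 1 — for the motivating
    analysis that is the lower 95% bound of the IPTW risk ratio.
    """
    out = {
        "rr_pre": float(rr_pre),
        "evalue_point": min_joint_strength(rr_pre),
    }
    if ci_bound is not None:
        out["ci_bound"] = float(ci_bound)
        out["evalue_ci_bound"] = (
            1.0 if ci_bound <= 1.0 else min_joint_strength(ci_bound)
        )
    return out
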