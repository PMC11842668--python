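"""End-to-end orchestration: PS -> weights -> effects, bias grids, flow tables.

Every table written by this module carries a comment header with the package
version, the seed and a hash of the configuration, so a run can be tied back
to what produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias_analysis import BiasGrid, bias_grid, nullification_summary
from .effect_estimation import (EffectEstimate, weighted_rd_glm,
                                weighted_rr_modified_poisson)
from .propensity import PSModel, ate_weights, c_statistic, fit_logistic
from .synthetic_cohort import CohortTable

__all__ = [
    "FrequentistResult",
    "run_frequentist",
    "run_bias",
    "flow_report",
    "STUDY_FLOW",
    "percent",
    "config_hash",
    "write_table",
]

log = logging.getLogger("iptwkit")

# Published participant-flow counts of the motivating survey:
# (stage label, count, denominator).
STUDY_FLOW: tuple[tuple[str, int, int], ...] = (
    ("responses_received", 8536, 14086),
    ("fraudulent_excluded", 489, 14086),
    ("eligible", 8047, 14086),
    ("pregnant", 1780, 8047),
    ("followup_unreachable_or_fraud", 435, 14086),
    ("followup_responses", 1345, 14086),
    ("still_pregnant_excluded", 342, 14086),
    ("analyzed", 1003, 14086),
)


@dataclass
class FrequentistResult:
    """One frequentist IPTW run: model, weights and both effect scales."""

    n: int
    n_exposed: int
    cases: int
    ps_model: PSModel | None
    c_statistic: float | None
    weights: np.ndarray
    rd: EffectEstimate
    rr: EffectEstimate

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for est in (self.rd, self.rr):
            rows.append({
                "scale": est.scale, "point": est.point, "se": est.se,
                "ci_level": est.ci_level, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "n": est.n, "cases": est.cases,
            })
        return pd.DataFrame(rows)


def run_frequentist(
    cohort: CohortTable,
    covariates: list[str] | None = None,
    *,
    ci_level: float = 0.95,
) -> FrequentistResult:
    """Fit the PS model, weight, and estimate aRD and rRR with sandwich CIs.

    ``covariates=None`` uses every covariate column in the cohort; an empty
    list runs unadjusted (unit weights, no PS model).
    """
    y, z = cohort.outcome, cohort.exposure
    names = cohort.covariate_names if covariates is None else list(covariates)
    missing = [c for c in names if c not in cohort.frame.columns]
    if missing:
        raise KeyError(
            f"propensity stage: covariate column(s) missing from input: {missing}"
        )

    cases = int(y.sum())
    if cases < 5:
        log.warning("rare outcome: only %d cases in the cohort", cases)
    if int(z.sum()) < 5:
        log.warning("rare exposure: only %d exposed rows", int(z.sum()))

    if names:
        ps_model = fit_logistic(cohort.covariates(names), z)
        weights = ate_weights(ps_model.fitted_ps, z)
        cstat = c_statistic(ps_model.fitted_ps, z)
    else:
        ps_model, cstat = None, None
        weights = np.ones(cohort.n)

    rd = weighted_rd_glm(y, z, weights, ci_level=ci_level)
    rr = weighted_rr_modified_poisson(y, z, weights, ci_level=ci_level)
    log.info(
        "frequentist stage: n=%d exposed=%d cases=%d c=%s aRD=%.4f rRR=%.3f",
        cohort.n, int(z.sum()), cases,
        "NA" if cstat is None else f"{cstat:.3f}", rd.point, rr.point,
    )
    return FrequentistResult(
        n=cohort.n, n_exposed=int(z.sum()), cases=cases, ps_model=ps_model,
        c_statistic=cstat, weights=weights, rd=rd, rr=rr,
    )


def run_bias(
    rr_pre: float | None,
    ci_bound: float | None = None,
    *,
    axis_max: float = 15.0,
    step: float = 0.5,
) -> tuple[BiasGrid, dict]:
    """Bounding-factor grid plus E-value nullification summary."""
    if rr_pre is None:
        raise ValueError(
            "bias stage: no observed risk ratio available (provide rr_pre "
            "from a prior estimation run or the configuration)"
        )
    grid = bias_grid(rr_pre, axis_max=axis_max, step=step)
    summary = nullification_summary(rr_pre, ci_bound)
    log.info("bias stage: rr_pre=%.3f evalue_point=%.3f", rr_pre,
             summary["evalue_point"])
    return grid, summary


def percent(count: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (survey-flow convention)."""
    if denominator <= 0:
        raise ZeroDivisionError("flow stage: zero denominator")
    if count < 0:
        raise ValueError("counts must be non-negative")
    frac = Decimal(count) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def flow_report(stages=STUDY_FLOW) -> pd.DataFrame:
    """Stage counts with percentages of their stated denominators."""
    rows = [
        {"stage": label, "count": c, "denominator": d, "percent": percent(c, d)}
        for label, c, d in stages
    ]
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-compatible configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """CSV with a provenance comment header (version, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [
        f"# iptwkit {__version__}",
        f"# seed={seed}",
        f"# config_sha={config_hash(config or {})}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)
    return path
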