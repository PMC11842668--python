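"""Synthetic rare-exposure / rare-outcome cohorts, and the published 2x2 counts.

The generator emulates the structure of a pregnancy cohort in which a small
fraction of participants used heated tobacco products (HTPs) in the first
trimester and placental abruption (PA) is a rare binary outcome: binary
covariates with configurable marginal prevalences, a logistic exposure model,
and a log-risk (multiplicative) baseline outcome model with a constant additive
causal risk difference of exposure on outcome.

Potential outcomes are drawn with a shared per-subject uniform (monotone
coupling), so the true average treatment effect equals ``exposure_effect_rd``
exactly by construction and parameter-recovery tests have a known estimand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "CovariateSpec",
    "GenerationConfig",
    "CohortTable",
    "TwoByTwo",
    "ConfigurationError",
    "generate_cohort",
    "expand_two_by_two",
    "study_two_by_two",
    "default_covariates",
    "default_config",
    "confounded_config",
    "calibrate_intercept",
    "marginal_rate",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration implies invalid probabilities."""


@dataclass(frozen=True)
class CovariateSpec:
    """One binary covariate: marginal prevalence and its effects.

    ``beta_exposure`` is the log-odds effect on exposure (logistic model);
    ``beta_outcome`` is the log-risk effect on the untreated outcome risk
    (log link, i.e. a risk-ratio effect of ``exp(beta_outcome)``).
    """

    name: str
    prevalence: float
    beta_exposure: float = 0.0
    beta_outcome: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError(
                f"covariate {self.name!r}: prevalence must lie in (0,1), "
                f"got {self.prevalence}"
            )
        if not (np.isfinite(self.beta_exposure) and np.isfinite(self.beta_outcome)):
            raise ConfigurationError(f"covariate {self.name!r}: effects must be finite")


# Marginal prevalences follow the published baseline table of the motivating
# cohort (counts out of 1003).  Effect sizes are package defaults chosen to
# produce clinically plausible confounding while keeping the log-risk outcome
# model valid for every covariate pattern (see docs/methods.md).
_TABLE_ROWS: tuple[tuple[str, int, float, float], ...] = (
    # name, count/1003, beta_exposure (log-odds), beta_outcome (log-risk)
    ("age_extreme", 264, 0.30, 0.25),
    ("parity_ge3", 29, -0.50, 0.15),
    ("ivf", 17, 1.60, 0.20),
    ("alcohol", 38, 0.30, 0.10),
    ("chronic_hypertension", 6, 0.80, 0.30),
    ("pregestational_diabetes", 5, 0.80, 0.20),
    ("thyroid_dysfunction", 37, 0.50, 0.10),
    ("previous_abruption", 2, 1.20, 0.60),
    ("hypertensive_disorders", 59, 0.20, 0.35),
    ("prom", 91, 1.00, 0.30),
    ("placenta_previa", 27, 0.90, 0.25),
    ("sga_fetus", 70, 0.30, 0.20),
    ("male_fetus", 507, 0.15, 0.00),
    ("traditional_smoking", 17, 1.60, 0.30),
    ("partner_traditional_smoking", 133, 1.00, 0.10),
    ("partner_htp_smoking", 163, 1.50, 0.15),
)


def default_covariates() -> list[CovariateSpec]:
    """The 16 default binary covariates with baseline-table prevalences."""
    return [
        CovariateSpec(name, count / 1003, be, by)
        for name, count, be, by in _TABLE_ROWS
    ]


@dataclass(frozen=True)
class GenerationConfig:
    """Full description of a synthetic cohort.

    Validation guarantees that the implied untreated and treated outcome
    probabilities lie in [0,1] for *every* covariate pattern, so the additive
    effect never needs truncation and the true ATE is exactly
    ``exposure_effect_rd``.
    """

    n: int
    exposure_intercept: float
    outcome_intercept: float
    exposure_effect_rd: float
    covariates: list[CovariateSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("covariate names must be unique")
        worst = [c.name for c in self.covariates if c.beta_outcome > 0]
        log_p0_max = self.outcome_intercept + sum(
            max(c.beta_outcome, 0.0) for c in self.covariates
        )
        p0_max = float(np.exp(log_p0_max))
        p1_max = p0_max + self.exposure_effect_rd
        if p0_max > 1.0 or not (0.0 <= p1_max <= 1.0):
            pattern = "+".join(worst) if worst else "(baseline)"
            raise ConfigurationError(
                f"outcome probability out of [0,1] for covariate pattern "
                f"{pattern}: p0={p0_max:.4g}, p0+rd={p1_max:.4g}"
            )
        p1_min = float(np.exp(
            self.outcome_intercept
            + sum(min(c.beta_outcome, 0.0) for c in self.covariates)
        )) + self.exposure_effect_rd
        if p1_min < 0.0:
            raise ConfigurationError(
                f"treated outcome probability negative for the all-protective "
                f"pattern: p0+rd={p1_min:.4g}"
            )

    @property
    def expected_outcome_rate(self) -> float:
        """Marginal P(Y0=1) under independent covariates (exact)."""
        return marginal_rate(
            self.outcome_intercept,
            [c.beta_outcome for c in self.covariates],
            [c.prevalence for c in self.covariates],
            link="log",
        )

    @property
    def expected_exposure_rate(self) -> float:
        """Marginal P(Z=1) under independent covariates (exact)."""
        return marginal_rate(
            self.exposure_intercept,
            [c.beta_exposure for c in self.covariates],
            [c.prevalence for c in self.covariates],
            link="logit",
        )


@dataclass
class CohortTable:
    """Individual-level cohort: exposure Z, outcome Y, binary covariates X.

    Backed by a tidy DataFrame with columns ``id, exposure, outcome,
    <covariates...>`` and, for synthetic cohorts, the potential outcomes
    ``y0, y1``.
    """

    frame: pd.DataFrame

    _RESERVED = ("id", "exposure", "outcome", "y0", "y1")

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("id", "exposure", "outcome"):
            if col not in df.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        if df.isna().any().any():
            raise ValueError("cohort table contains missing values")
        if len(set(df.columns)) != len(df.columns):
            raise ValueError("cohort table column names must be unique")
        for col in [c for c in df.columns if c != "id"]:
            vals = np.asarray(df[col])
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"column {col!r} must be binary 0/1")

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def exposure(self) -> np.ndarray:
        return np.asarray(self.frame["exposure"], dtype=int)

    @property
    def outcome(self) -> np.ndarray:
        return np.asarray(self.frame["outcome"], dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self._RESERVED]

    def covariates(self, subset: list[str] | None = None) -> pd.DataFrame:
        names = self.covariate_names if subset is None else list(subset)
        missing = [c for c in names if c not in self.frame.columns]
        if missing:
            raise KeyError(f"covariate column(s) not in cohort: {missing}")
        return self.frame[names].astype(int)

    @property
    def potential_outcomes(self) -> tuple[np.ndarray, np.ndarray] | None:
        if "y0" in self.frame.columns and "y1" in self.frame.columns:
            return (
                np.asarray(self.frame["y0"], dtype=int),
                np.asarray(self.frame["y1"], dtype=int),
            )
        return None

    def two_by_two(self) -> "TwoByTwo":
        z, y = self.exposure, self.outcome
        return TwoByTwo(
            a=int(((z == 1) & (y == 1)).sum()),
            b=int(((z == 1) & (y == 0)).sum()),
            c=int(((z == 0) & (y == 1)).sum()),
            d=int(((z == 0) & (y == 0)).sum()),
        )

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path_or_buf=None) -> str | None:
        return self.frame.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CohortTable":
        return cls(pd.read_csv(path_or_buf, comment="#"))


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts: a=Z1Y1, b=Z1Y0, c=Z0Y1, d=Z0Y0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name} must be a non-negative integer")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("each exposure arm needs at least one participant")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def risk_exposed(self) -> float:
        return self.a / self.n_exposed

    @property
    def risk_unexposed(self) -> float:
        return self.c / self.n_unexposed


def study_two_by_two() -> TwoByTwo:
    """Published exposure-by-outcome counts of the motivating cohort.

    2 of 23 first-trimester HTP smokers and 7 of 980 non-smokers experienced
    placental abruption (n = 1003).
    """
    return TwoByTwo(a=2, b=21, c=7, d=973)


def expand_two_by_two(t: TwoByTwo) -> CohortTable:
    """Individual-level table reproducing the counts exactly (no covariates)."""
    z = np.repeat([1, 1, 0, 0], [t.a, t.b, t.c, t.d])
    y = np.repeat([1, 0, 1, 0], [t.a, t.b, t.c, t.d])
    df = pd.DataFrame(
        {"id": np.arange(1, t.total + 1), "exposure": z, "outcome": y}
    )
    return CohortTable(df)


# ---------------------------------------------------------------------------
# intercept calibration under independent binary covariates
# ---------------------------------------------------------------------------

def _score_distribution(betas, prevs) -> tuple[np.ndarray, np.ndarray]:
    """Exact atoms and probabilities of sum(X_j * beta_j), X_j ~ Bern(p_j)."""
    sums = np.zeros(1)
    probs = np.ones(1)
    for b, p in zip(betas, prevs):
        if b == 0.0:
            continue
        sums = np.concatenate([sums, sums + b])
        probs = np.concatenate([probs * (1 - p), probs * p])
    return sums, probs


def marginal_rate(intercept, betas, prevs, link="logit") -> float:
    """Exact marginal event rate E[g^{-1}(intercept + X beta)]."""
    sums, probs = _score_distribution(betas, prevs)
    eta = intercept + sums
    if link == "logit":
        return float(np.sum(probs * expit(eta)))
    if link == "log":
        return float(np.sum(probs * np.exp(eta)))
    raise ValueError(f"unknown link {link!r}")


def calibrate_intercept(target, betas, prevs, link="logit") -> float:
    """Intercept whose exact marginal rate equals ``target``."""
    if not 0.0 < target < 1.0:
        raise ConfigurationError("target rate must lie in (0,1)")
    f = lambda a: marginal_rate(a, betas, prevs, link) - target
    lo, hi = -30.0, 5.0
    return float(brentq(f, lo, hi, xtol=1e-12))


def default_config(
    n: int = 1003,
    *,
    exposure_rate: float = 23 / 1003,
    outcome_rate: float = 0.007,
    exposure_effect_rd: float = 0.07,
    seed: int = 42,
) -> GenerationConfig:
    """Default study-like cohort: n=1003, ~2.3% exposed, ~0.7% baseline risk.

    Intercepts are calibrated exactly (by enumeration over covariate patterns)
    so the marginal exposure and untreated-outcome rates hit the targets.
    """
    covs = default_covariates()
    a_z = calibrate_intercept(
        exposure_rate, [c.beta_exposure for c in covs], [c.prevalence for c in covs],
        link="logit",
    )
    a_y = calibrate_intercept(
        outcome_rate, [c.beta_outcome for c in covs], [c.prevalence for c in covs],
        link="log",
    )
    return GenerationConfig(
        n=n,
        exposure_intercept=a_z,
        outcome_intercept=a_y,
        exposure_effect_rd=exposure_effect_rd,
        covariates=covs,
        seed=seed,
    )


def confounded_config(
    n: int = 5000,
    *,
    exposure_rate: float = 0.126,
    outcome_rate: float = 0.007,
    exposure_effect_rd: float = 0.07,
    seed: int = 0,
) -> GenerationConfig:
    """Two strong confounders; used for parameter-recovery and coverage runs.

    Both covariates raise the odds of exposure and the untreated outcome risk,
    so the crude risk difference is biased upward while IPTW removes the bias.
    The default exposure prevalence is the general-population HTP smoking rate
    (12.6%) rather than the pregnancy-cohort 2.3%: estimator-validation runs
    need enough exposed cases for Wald/sandwich asymptotics to apply; with
    2.3% exposure and a 0.7% baseline risk a cohort of 5000 carries only ~9
    exposed cases and Wald intervals visibly undercover (see docs/methods.md).
    """
    covs = [
        CovariateSpec("confounder_strong", 0.25, np.log(8.0), np.log(8.0)),
        CovariateSpec("confounder_mild", 0.15, np.log(3.0), np.log(3.0)),
    ]
    a_z = calibrate_intercept(
        exposure_rate, [c.beta_exposure for c in covs], [c.prevalence for c in covs],
        link="logit",
    )
    a_y = calibrate_intercept(
        outcome_rate, [c.beta_outcome for c in covs], [c.prevalence for c in covs],
        link="log",
    )
    return GenerationConfig(
        n=n,
        exposure_intercept=a_z,
        outcome_intercept=a_y,
        exposure_effect_rd=exposure_effect_rd,
        covariates=covs,
        seed=seed,
    )


def generate_cohort(config: GenerationConfig) -> CohortTable:
    """Draw a cohort under the configured exposure and outcome models.

    Exposure: logit P(Z=1|X) = exposure_intercept + X beta_exposure.
    Outcome:  P(Y0=1|X) = exp(outcome_intercept + X beta_outcome),
              P(Y1=1|X) = P(Y0=1|X) + exposure_effect_rd,
    with Y0 and Y1 coupled through one uniform draw per subject, and
    Y = Z*Y1 + (1-Z)*Y0.  Reproducible given ``config.seed``; independent RNG
    streams are spawned for covariates, exposure and outcomes.
    """
    exp_cases = config.n * config.expected_outcome_rate
    if exp_cases < 5:
        warnings.warn(
            f"expected case count {exp_cases:.1f} < 5: risk estimates from this "
            "cohort will be unstable",
            UserWarning,
            stacklevel=2,
        )
    ss = np.random.SeedSequence(config.seed)
    rng_x, rng_z, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))

    n, p = config.n, len(config.covariates)
    X = np.empty((n, p), dtype=int)
    for j, cov in enumerate(config.covariates):
        X[:, j] = rng_x.random(n) < cov.prevalence

    be = np.array([c.beta_exposure for c in config.covariates])
    by = np.array([c.beta_outcome for c in config.covariates])
    p_z = expit(config.exposure_intercept + X @ be)
    z = (rng_z.random(n) < p_z).astype(int)

    p0 = np.exp(config.outcome_intercept + X @ by)
    p1 = p0 + config.exposure_effect_rd
    u = rng_y.random(n)
    y0 = (u < p0).astype(int)
    y1 = (u < p1).astype(int)
    y = np.where(z == 1, y1, y0)

    df = pd.DataFrame({"id": np.arange(1, n + 1), "exposure": z, "outcome": y})
    for j, cov in enumerate(config.covariates):
        df[cov.name] = X[:, j]
    df["y0"] = y0
    df["y1"] = y1
    return CohortTable(df)
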