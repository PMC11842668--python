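"""Generator calibration, determinism, and the packaged published counts."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iptwkit import (CohortTable, ConfigurationError, CovariateSpec,
                     GenerationConfig, TwoByTwo, confounded_config,
                     default_config, expand_two_by_two, generate_cohort,
                     study_two_by_two)
from iptwkit.synthetic_cohort import calibrate_intercept, marginal_rate


class TestStudyCounts:
    def test_published_two_by_two(self):
        t = study_two_by_two()
        assert (t.a, t.b, t.c, t.d) == (2, 21, 7, 973)
        assert t.n_exposed == 23
        assert t.n_unexposed == 980
        assert t.total == 1003

    def test_expand_reproduces_counts(self):
        coh = expand_two_by_two(study_two_by_two())
        assert coh.n == 1003
        assert coh.exposure.sum() == 23
        assert coh.outcome.sum() == 9

    def test_expand_no_cases(self):
        coh = expand_two_by_two(TwoByTwo(0, 5, 0, 5))
        assert coh.n == 10
        assert coh.outcome.sum() == 0

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    def test_expand_round_trip(self, a, b, c, d):
        if a + b < 1 or c + d < 1:
            with pytest.raises(ValueError):
                TwoByTwo(a, b, c, d)
            return
        t = TwoByTwo(a, b, c, d)
        assert expand_two_by_two(t).two_by_two() == t


class TestGenerator:
    def test_seed_determinism_byte_for_byte(self):
        cfg = default_config(n=500, seed=7)
        csv1 = generate_cohort(cfg).to_csv()
        csv2 = generate_cohort(cfg).to_csv()
        assert csv1 == csv2
        other = generate_cohort(default_config(n=500, seed=8)).to_csv()
        assert other != csv1

    def test_no_covariate_exposure_prevalence(self):
        cfg = GenerationConfig(
            n=10_000, exposure_intercept=0.0, outcome_intercept=math.log(0.05),
            exposure_effect_rd=0.0, covariates=[], seed=1,
        )
        coh = generate_cohort(cfg)
        sd = math.sqrt(0.25 / cfg.n)
        assert abs(coh.exposure.mean() - 0.5) < 3 * sd

    def test_null_effect_exact_under_coupling(self):
        cfg = GenerationConfig(
            n=10_000, exposure_intercept=-2.0, outcome_intercept=math.log(0.02),
            exposure_effect_rd=0.0, covariates=[], seed=2,
        )
        y0, y1 = generate_cohort(cfg).potential_outcomes
        assert np.array_equal(y0, y1)  # shared uniform draw, zero effect

    def test_default_exposed_count_near_target(self, default_cohort):
        p = 23 / 1003
        sd = math.sqrt(1003 * p * (1 - p))
        assert abs(default_cohort.exposure.sum() - 23) < 3 * sd

    def test_true_ate_bookkeeping(self):
        cfg = confounded_config(n=50_000, seed=11)
        y0, y1 = generate_cohort(cfg).potential_outcomes
        ate = (y1 - y0).mean()
        mc_se = math.sqrt(0.07 * 0.93 / cfg.n)
        assert abs(ate - 0.07) < 3 * mc_se

    def test_marginal_calibration(self, default_cohort):
        cfg = default_config()
        X = default_cohort.covariates()
        for cov in cfg.covariates:
            emp = X[cov.name].mean()
            sd = math.sqrt(cov.prevalence * (1 - cov.prevalence) / cfg.n)
            assert abs(emp - cov.prevalence) < 3 * sd, cov.name

    def test_calibrated_intercepts_hit_targets_exactly(self):
        cfg = default_config()
        assert cfg.expected_exposure_rate == pytest.approx(23 / 1003, abs=1e-9)
        assert cfg.expected_outcome_rate == pytest.approx(0.007, abs=1e-9)

    def test_invalid_outcome_probability_names_pattern(self):
        covs = [CovariateSpec("huge_risk", 0.1, 0.0, 3.0)]
        with pytest.raises(ConfigurationError, match="huge_risk"):
            GenerationConfig(
                n=100, exposure_intercept=-3.0, outcome_intercept=math.log(0.5),
                exposure_effect_rd=0.07, covariates=covs, seed=0,
            )

    def test_rare_event_guard_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            generate_cohort(default_config(n=200, seed=5))

    def test_covariate_spec_validation(self):
        with pytest.raises(ConfigurationError):
            CovariateSpec("bad", 1.5)
        with pytest.raises(ConfigurationError):
            CovariateSpec("bad", 0.5, beta_exposure=math.inf)


class TestCohortTable:
    def test_csv_round_trip(self, default_cohort):
        buf = io.StringIO(default_cohort.to_csv())
        again = CohortTable.from_csv(buf)
        assert again.frame.equals(default_cohort.frame)

    def test_rejects_nonbinary_and_missing(self):
        import pandas as pd
        df = pd.DataFrame({"id": [1, 2], "exposure": [0, 2], "outcome": [0, 1]})
        with pytest.raises(ValueError, match="binary"):
            CohortTable(df)
        df2 = pd.DataFrame({"id": [1], "exposure": [np.nan], "outcome": [0]})
        with pytest.raises(ValueError, match="missing"):
            CohortTable(df2)


class TestCalibration:
    @pytest.mark.parametrize("link", ["logit", "log"])
    def test_calibrate_inverts_marginal_rate(self, link):
        betas = [0.4, -0.3, 1.1]
        prevs = [0.2, 0.5, 0.05]
        target = 0.03
        a = calibrate_intercept(target, betas, prevs, link=link)
        assert marginal_rate(a, betas, prevs, link=link) == pytest.approx(
            target, abs=1e-10
        )
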