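"""Marginal effects, partial R-squared, earnings model and index comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cati import (
    DataError,
    binary_validity,
    compare_indices,
    earnings_validity,
    equal_weight_index,
    generate_cohort,
    score_index,
    true_weights,
)
from cati.design import add_constant, component_frame, demographic_design
from cati.synthetic_cohort import OutcomeModel, recovery_preset
from cati.validity import _ame_logit, _fit_glm
from cati.weighting import standardize

from conftest import make_validity_frame


def fit_on_frame(df):
    X = add_constant(pd.concat([df["score"], demographic_design(df)], axis=1))
    return _fit_glm(X, df["ever_fair_poor_health"].to_numpy(float),
                    df["attrition_weight"].to_numpy(float), "logit")


class TestAME:
    def test_matches_bruteforce_finite_difference(self):
        df = make_validity_frame(3000, seed=0, score_effect=-0.5)
        fit = fit_on_frame(df)
        ame, _ = _ame_logit(fit)
        # independent oracle: per-row predicted-probability difference
        j = fit.columns.index("score")
        brute = 0.0
        for i in range(len(df)):
            x0 = fit.X[i].copy()
            x1 = x0.copy()
            x1[j] += 1.0
            brute += fit.w[i] * (expit(x1 @ fit.beta) - expit(x0 @ fit.beta))
        brute /= fit.w.sum()
        assert ame == pytest.approx(brute, abs=1e-10)

    def test_invariant_to_affine_demographic_recoding(self):
        df = make_validity_frame(2000, seed=1, score_effect=-0.4)
        ame_a, _ = _ame_logit(fit_on_frame(df))
        recoded = df.copy()
        recoded["age"] = 2.0 * recoded["age"] + 5.0
        ame_b, _ = _ame_logit(fit_on_frame(recoded))
        assert ame_a == pytest.approx(ame_b, abs=1e-8)

    def test_null_score_gives_null_effect(self):
        df = make_validity_frame(5000, seed=2, score_effect=0.0)
        eff = binary_validity([df, df], [df["score"], df["score"]], "ever_fair_poor_health")
        assert abs(eff.estimate) < 2 * eff.se
        assert eff.partial_r2 < 0.005
        assert eff.partial_r2 == pytest.approx(eff.r2_full - eff.r2_base, abs=1e-9)

    def test_protective_index_detected(self):
        """An index built from the generator's true weights should carry a
        clearly negative 1-SD effect on poor health when the components
        dominate the outcome model."""
        cfg = recovery_preset(n_children=8000, seed=3)
        cfg.outcomes = OutcomeModel(component_scale=4.0)
        cohort = generate_cohort(cfg)
        weights = true_weights(cfg)
        scores = score_index(component_frame(cohort), weights)
        eff = binary_validity([cohort, cohort], [scores, scores], "ever_fair_poor_health")
        assert eff.estimate < 0
        assert eff.ci95[1] < 0

    def test_constant_outcome_rejected(self):
        df = make_validity_frame(200, seed=4)
        df["ever_fair_poor_health"] = 1.0
        with pytest.raises(DataError):
            binary_validity([df, df], [df["score"], df["score"]], "ever_fair_poor_health")


def earnings_frame(n, seed, beta_score, overdisperse=0.0):
    rng = np.random.default_rng(seed)
    df = make_validity_frame(n, seed=seed)
    eta = 8.0 + beta_score * df["score"].to_numpy() + overdisperse * rng.standard_normal(n)
    df["peak_earnings"] = rng.poisson(np.exp(eta)).astype(float)
    return df


class TestEarnings:
    def test_percent_change_matches_exp_beta(self):
        df = earnings_frame(2000, seed=5, beta_score=0.08)
        eff = earnings_validity([df, df], [df["score"], df["score"]])
        b = eff.extra["beta_score"]
        assert eff.estimate == pytest.approx(100 * (np.exp(b) - 1), abs=1e-12)

    def test_permuted_score_is_null(self):
        df = earnings_frame(4000, seed=6, beta_score=0.1)
        rng = np.random.default_rng(7)
        permuted = pd.Series(rng.permutation(df["score"].to_numpy()), index=df.index)
        eff = earnings_validity([df, df], [permuted, permuted])
        assert abs(eff.estimate) < 2 * eff.se

    def test_recovers_ten_percent_effect(self):
        df = earnings_frame(10000, seed=8, beta_score=np.log(1.10))
        eff = earnings_validity([df, df], [df["score"], df["score"]])
        assert eff.estimate == pytest.approx(10.0, abs=1.0)

    def test_robust_se_exceeds_model_se_under_overdispersion(self):
        df = earnings_frame(3000, seed=9, beta_score=0.05, overdisperse=0.8)
        controls = pd.concat(
            [demographic_design(df),
             df[["years_observed_20_29", "enrolled_at_peak"]].astype(float)], axis=1
        )
        X = add_constant(pd.concat([df["score"], controls], axis=1))
        fit = _fit_glm(X, df["peak_earnings"].to_numpy(float),
                       df["attrition_weight"].to_numpy(float), "poisson")
        j = fit.columns.index("score")
        assert np.sqrt(fit.cov_robust[j, j]) > np.sqrt(fit.cov_model[j, j])

    def test_all_zero_earnings_rejected(self):
        df = earnings_frame(100, seed=10, beta_score=0.0)
        df["peak_earnings"] = 0.0
        with pytest.raises(DataError):
            earnings_validity([df, df], [df["score"], df["score"]])


class TestEqualWeightIndex:
    def test_counts_positives(self):
        comp = pd.DataFrame({"a": [1, 0, 1.0], "b": [1, 0, 0.0], "c": [1, 1, 0.0]})
        scores = equal_weight_index(comp)
        assert list(scores.values) == [3, 1, 1]

    def test_affine_equivalent_to_uniformly_weighted_index(self):
        rng = np.random.default_rng(11)
        comp = pd.DataFrame((rng.random((300, 6)) < 0.5).astype(float), columns=list("abcdef"))
        from cati.weighting import WeightVector

        uniform = WeightVector(
            raw=pd.Series(1.0, index=comp.columns),
            normalized=pd.Series(1 / 6, index=comp.columns),
        )
        a = equal_weight_index(comp).standardized
        b = score_index(comp, uniform).standardized
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(DataError):
            equal_weight_index(pd.DataFrame(index=range(3)), [])


class TestCompareIndices:
    def test_self_comparison_is_exactly_null(self):
        df = make_validity_frame(1000, seed=12, score_effect=-0.4)
        res = compare_indices(
            df["ever_fair_poor_health"], df["score"], df["score"],
            demographic_design(df), weights=df["attrition_weight"],
        )
        assert res.difference == 0.0
        assert res.p_value == 1.0

    def test_mismatched_samples_rejected(self):
        df = make_validity_frame(500, seed=13)
        with pytest.raises(DataError):
            compare_indices(
                df["ever_fair_poor_health"], df["score"][:-1], df["score"],
                demographic_design(df),
            )

    def test_stacked_and_bootstrap_agree(self):
        rng = np.random.default_rng(14)
        df = make_validity_frame(1200, seed=14, score_effect=-0.5)
        other = pd.Series(
            standardize(0.5 * df["score"].to_numpy() + rng.standard_normal(len(df))),
            index=df.index,
        )
        args = (df["ever_fair_poor_health"], df["score"], other, demographic_design(df))
        stacked = compare_indices(*args, weights=df["attrition_weight"])
        boot = compare_indices(*args, weights=df["attrition_weight"],
                               method="bootstrap", n_boot=199, seed=15)
        assert stacked.difference == pytest.approx(boot.difference, abs=1e-12)
        assert stacked.se == pytest.approx(boot.se, rel=0.5)

    def test_detects_more_predictive_index(self):
        """Power check: the truly weighted index vs the equal-weight count
        on a cohort where components drive the outcome; the stacked test
        should separate them in most replicates."""
        detected = 0
        n_reps = 10
        for seed in range(n_reps):
            cfg = recovery_preset(n_children=4000, seed=200 + seed)
            cfg.outcomes = OutcomeModel(component_scale=6.0, health_slope=-0.9)
            cohort = generate_cohort(cfg)
            comp = component_frame(cohort)
            weighted = score_index(comp, true_weights(cfg))
            equal = equal_weight_index(comp)
            res = compare_indices(
                cohort["ever_fair_poor_health"], weighted, equal,
                demographic_design(cohort), weights=cohort["attrition_weight"],
            )
            detected += res.p_value < 0.05
        assert detected >= 8  # power > 0.8 at this effect size
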