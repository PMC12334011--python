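import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from crimedyn.estimation import (
    COEF_NAMES,
    design_matrix,
    fit_all_transitions,
    fit_random_intercept_logit,
    fit_transition,
    params_from_subgroup_table,
    predict_probability,
    simulate_logit_outcomes,
    subgroup_table,
)
from crimedyn.model import PARAM_NAMES
from crimedyn.states import build_transitions
from crimedyn.synth import SynthConfig, generate_panel


def _covariates(n_person, waves, rng):
    groups = np.repeat(np.arange(n_person), waves)
    age = (rng.integers(12, 18, n_person).repeat(waves)
           + np.tile(np.arange(waves), n_person))
    woman = rng.random(n_person).repeat(waves) < 0.49
    race = rng.choice(["White", "Black", "Hispanic"], n_person,
                      p=[0.524, 0.262, 0.214]).repeat(waves)
    X = design_matrix(age, woman, race == "Black", race == "Hispanic")
    return X, groups


class TestFitRandomInterceptLogit:
    def test_sigma_zero_reduces_to_plain_logit(self):
        rng = np.random.default_rng(0)
        X, groups = _covariates(1500, 6, rng)
        y = simulate_logit_outcomes(X, [-2.0, 0.1, 0, -0.4, 0.5, 0, 0, 0],
                                    0.0, groups, rng)
        ours = fit_random_intercept_logit(y, X, groups, fix_sigma_zero=True)
        ref = sm.Logit(y, X).fit(disp=0, tol=1e-12)
        assert np.abs(ours.beta - ref.params).max() < 1e-6
        assert ours.sigma_u == 0.0

    def test_intercept_recovery_no_effects(self):
        rng = np.random.default_rng(1)
        X, groups = _covariates(2000, 6, rng)
        X0 = X.copy()
        X0[:, 1:] = 0.0  # intercept-only generating model
        p_true = 0.15
        y = simulate_logit_outcomes(X0, [logit(p_true), 0, 0, 0, 0, 0, 0, 0],
                                    0.0, groups, rng)
        fit = fit_random_intercept_logit(y, np.ones((len(y), 1)), groups,
                                         fix_sigma_zero=True)
        assert abs(fit.beta[0] - logit(p_true)) < 2 * fit.se_beta[0]

    def test_generating_value_recovery_with_random_intercept(self):
        # X->A-style generating values: constant -3.70, Black 0.56
        rng = np.random.default_rng(2)
        X, groups = _covariates(5000, 6, rng)
        beta_true = np.array([-3.70, 0, 0, 0, 0.56, 0, 0, 0])
        y = simulate_logit_outcomes(X, beta_true, 0.8, groups, rng)
        fit = fit_random_intercept_logit(y, X, groups, outcome="X->A")
        assert abs(fit.beta[0] - beta_true[0]) < 2 * fit.se_beta[0]
        assert abs(fit.beta[4] - beta_true[4]) < 2 * fit.se_beta[4]
        assert abs(fit.sigma_u - 0.8) < 3 * max(fit.se_sigma_u, 0.05)

    def test_single_observation_per_person_warns(self):
        rng = np.random.default_rng(3)
        X, _ = _covariates(800, 1, rng)
        groups = np.arange(800)
        y = simulate_logit_outcomes(X, [-1.0, 0, 0, 0, 0, 0, 0, 0],
                                    0.0, groups, rng)
        fit = fit_random_intercept_logit(y, X, groups)
        assert fit.sigma_u == 0.0
        assert any("unidentified" in w for w in fit.warnings)
        ref = sm.Logit(y, X).fit(disp=0, tol=1e-12)
        assert np.abs(fit.beta - ref.params).max() < 1e-6

    def test_quadrature_stability_21_vs_41_nodes(self):
        # adaptive 21- and 41-node rules agree to ~2e-7 per person even at
        # sigma_u = 2 (the total difference scales with the person count)
        rng = np.random.default_rng(4)
        n_person = 600
        X, groups = _covariates(n_person, 6, rng)
        y = simulate_logit_outcomes(X, [-1.5, 0, 0, 0.3, 0.2, 0, 0, 0],
                                    2.0, groups, rng)
        f21 = fit_random_intercept_logit(y, X, groups, n_nodes=21)
        f41 = fit_random_intercept_logit(y, X, groups, n_nodes=41)
        assert abs(f21.loglik - f41.loglik) / n_person < 1e-6
        assert np.abs(f21.beta - f41.beta).max() < 1e-4
        assert abs(f21.sigma_u - f41.sigma_u) < 1e-4

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_random_intercept_logit([0, 1, 2], np.ones((3, 1)), [0, 1, 2])

    def test_coverage_over_replicates(self):
        # parameter-recovery property: >= 90% of replicate fits recover each
        # generating coefficient within 2 estimated SEs
        beta_true = np.array([-2.2, 0.05, -0.01, -0.3, 0.45, 0.1, -0.2, 0.15])
        n_rep = 50
        hits = np.zeros(len(beta_true))
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            X, groups = _covariates(800, 6, rng)
            y = simulate_logit_outcomes(X, beta_true, 0.6, groups, rng)
            fit = fit_random_intercept_logit(y, X, groups)
            hits += (np.abs(fit.beta - beta_true) < 2 * fit.se_beta)
        assert np.all(hits / n_rep >= 0.9), hits / n_rep


@pytest.fixture(scope="module")
def null_fit():
    rng = np.random.default_rng(5)
    X, groups = _covariates(400, 6, rng)
    y = simulate_logit_outcomes(X, [0.0] * 8, 0.0, groups, rng)
    return fit_random_intercept_logit(y, X, groups, fix_sigma_zero=True,
                                      coef_names=COEF_NAMES)


class TestPredictProbability:
    def test_all_zero_coefficients_give_half(self, null_fit):
        fit = null_fit
        fit.beta = np.zeros(8)
        fit.sigma_u = 0.0
        for sex, race in [("man", "White"), ("woman", "Black")]:
            assert predict_probability(fit, 14, sex, race) == pytest.approx(0.5)

    def test_reference_cell_is_inverse_logit_of_constant(self, null_fit):
        fit = null_fit
        fit.beta = np.array([-3.10, 0, 0, 0, 0, 0, 0, 0])
        fit.sigma_u = 0.0
        p = predict_probability(fit, 16, "man", "White",
                                integrate_random_effect=False)
        assert p == pytest.approx(float(expit(-3.10)), abs=1e-12)
        assert p == pytest.approx(0.0431, abs=1e-4)

    def test_integration_shrinks_toward_half(self, null_fit):
        fit = null_fit
        fit.beta = np.array([-2.0, 0, 0, 0, 0, 0, 0, 0])
        fit.sigma_u = 1.0
        conditional = predict_probability(fit, 16, "man", "White",
                                          integrate_random_effect=False)
        integrated = predict_probability(fit, 16, "man", "White",
                                         integrate_random_effect=True)
        assert conditional < integrated < 0.5

    def test_integration_matches_numeric_quadrature_oracle(self, null_fit):
        from scipy.integrate import quad
        from scipy.stats import norm

        fit = null_fit
        fit.beta = np.array([-1.3, 0, 0, 0, 0, 0, 0, 0])
        fit.sigma_u = 0.9
        got = predict_probability(fit, 16, "man", "White")
        want, _ = quad(lambda u: expit(-1.3 + u) * norm.pdf(u, scale=0.9),
                       -10, 10)
        assert got == pytest.approx(want, abs=1e-8)


@pytest.fixture(scope="module")
def fitted_panel(black_men):
    cfg = SynthConfig(n_persons=3000, params=black_men, mode="markov", seed=31)
    panel, truth = generate_panel(cfg)
    transitions = build_transitions(truth)
    fits = fit_all_transitions(transitions, panel, fix_sigma_zero=True)
    return panel, transitions, fits


class TestTransitionFits:
    def test_risk_set_restricted_to_origin(self, fitted_panel):
        panel, transitions, _ = fitted_panel
        fit = fit_transition(transitions, panel, "C2->A", fix_sigma_zero=True)
        n_c2 = (transitions["from_state"] == "C2").sum()
        assert fit.n_obs == n_c2

    def test_unknown_outcome_rejected(self, fitted_panel):
        panel, transitions, _ = fitted_panel
        with pytest.raises(KeyError):
            fit_transition(transitions, panel, "X->R")

    def test_subgroup_table_recovers_generating_rates(self, fitted_panel,
                                                      black_men):
        panel, transitions, fits = fitted_panel
        table = subgroup_table(fits, panel, ci="none")
        demo = panel.drop_duplicates("person_id").set_index("person_id")
        trans = transitions.join(demo[["sex", "race"]], on="person_id")
        for name in PARAM_NAMES:
            origin = name.split("->")[0]
            true_p = black_men.value(name)
            for _, row in table[table["transition"] == name].iterrows():
                n_cell = ((trans["from_state"] == origin)
                          & (trans["sex"] == row["sex"])
                          & (trans["race"] == row["race"])).sum()
                se = np.sqrt(true_p * (1 - true_p) / max(n_cell, 1))
                # single generating set: every subgroup should recover it
                assert abs(row["probability"] - true_p) <= 4 * se + 0.01, (
                    name, row["sex"], row["race"])

    def test_derived_stays_complete_each_origin(self, fitted_panel):
        _, _, fits = fitted_panel
        panel = fitted_panel[0]
        table = subgroup_table(fits, panel, ci="none")
        for (sex, race), grp in table.groupby(["sex", "race"]):
            for origin in ("X", "C1", "A", "R", "C2"):
                outflow = grp[grp["transition"].str.startswith(origin + "->")]
                assert outflow["probability"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_age_effect_prediction_independent_of_age_mix(self, fitted_panel):
        panel, _, fits = fitted_panel
        fit = fits["X->C1"]
        fit.beta = fit.beta.copy()
        fit.beta[1] = fit.beta[2] = 0.0
        p_young = predict_probability(fit, 12, "man", "White")
        p_old = predict_probability(fit, 18, "man", "White")
        assert p_young == pytest.approx(p_old, abs=1e-12)

    def test_bootstrap_intervals_bracket_point(self, fitted_panel):
        panel, _, fits = fitted_panel
        table = subgroup_table(fits, panel, ci="bootstrap", n_boot=200, seed=1)
        ok = ((table["lower"] <= table["probability"] + 1e-9)
              & (table["probability"] <= table["upper"] + 1e-9))
        assert ok.mean() > 0.95
        assert table["lower"].between(0, 1).all()
        assert table["upper"].between(0, 1).all()

    def test_delta_intervals_finite(self, fitted_panel):
        panel, _, fits = fitted_panel
        table = subgroup_table(fits, panel, ci="delta")
        assert np.isfinite(table["lower"]).all()
        assert np.isfinite(table["upper"]).all()
        assert (table["lower"] <= table["upper"]).all()

    def test_params_from_subgroup_table(self, fitted_panel, black_men):
        panel, _, fits = fitted_panel
        table = subgroup_table(fits, panel, ci="none")
        sex = panel["sex"].iloc[0]
        race = panel["race"].iloc[0]
        params = params_from_subgroup_table(table, sex, race)
        assert np.abs(params.as_array() - black_men.as_array()).max() < 0.12
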