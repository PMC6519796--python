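"""Comparator models: the published office-based risk equation, LASSO
preselection, Cox proportional hazards, and grid-searched classifiers."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from prognopipe.cohort import CORE7
from prognopipe.models import (
    GRID_FAMILIES,
    fit_cox_ph,
    fit_grid_searched_classifier,
    framingham_bmi_risk,
    framingham_model,
    lasso_preselect,
    load_framingham_coefficients,
)

# 10-year risk of the fixed reference profile (male, age 55, SBP 130
# untreated, non-smoker, no diabetes, BMI 25) under the published equation;
# frozen from the closed form below.
REFERENCE_PROFILE_RISK_10Y = 0.12422914648382521


class TestFramingham:
    def test_reference_profile_matches_closed_form(self):
        c = load_framingham_coefficients().male
        lp = (c["ln_age"] * np.log(55) + c["ln_bmi"] * np.log(25)
              + c["ln_sbp_untreated"] * np.log(130))
        expected = 1.0 - c["baseline_survival_10y"] ** np.exp(lp - c["mean_linear_predictor"])
        got = framingham_bmi_risk(55, 25, 130, 0, 0, 0, 1, horizon_years=10.0)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(REFERENCE_PROFILE_RISK_10Y, abs=1e-12)

    def test_risk_increases_with_age(self):
        risks = [framingham_bmi_risk(a, 25, 130, 0, 0, 0, 1) for a in (45, 55, 65, 75)]
        assert np.all(np.diff(risks) > 0)

    def test_treated_sbp_raises_risk(self):
        base = framingham_bmi_risk(60, 27, 140, 0, 0, 0, 0)
        treated = framingham_bmi_risk(60, 27, 140, 1, 0, 0, 0)
        assert treated > base

    def test_gender_specific_coefficients(self):
        m = framingham_bmi_risk(60, 27, 140, 0, 1, 0, 1)
        f = framingham_bmi_risk(60, 27, 140, 0, 1, 0, 0)
        assert m != f and 0 < m < 1 and 0 < f < 1

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            framingham_bmi_risk(0, 25, 130, 0, 0, 0, 1)
        with pytest.raises(ValueError):
            framingham_bmi_risk(55, 25, -1, 0, 0, 0, 1)

    def test_invariant_to_noncore_variables(self, complete_cohort):
        table, _, _ = complete_cohort
        model = framingham_model(horizon_years=5.0)
        p1 = model.predict(table.covariates)
        perturbed = table.covariates.copy()
        noncore = [c for c in perturbed.columns if c not in CORE7]
        perturbed[noncore] = perturbed[noncore] + 100.0
        np.testing.assert_array_equal(p1, model.predict(perturbed))
        assert p1.min() >= 0.0 and p1.max() <= 1.0


class TestLassoPreselect:
    GRID = tuple(np.logspace(-4, -1.5, 6))

    def _planted(self, seed=1, n=5000, p=105, k=5, beta=0.5):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"v{i}" for i in range(p)])
        coefs = np.zeros(p)
        coefs[:k] = beta
        y = (rng.random(n) < expit(X.values @ coefs)).astype(int)
        return X, y

    def test_recovers_planted_variables(self):
        X, y = self._planted()
        selected = lasso_preselect(X, y, self.GRID, folds=3, seed=0)
        assert {f"v{i}" for i in range(5)} <= set(selected)

    def test_null_selection_is_sparse(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((5000, 100)),
                         columns=[f"v{i}" for i in range(100)])
        y = (rng.random(5000) < 0.3).astype(int)
        selected = lasso_preselect(X, y, self.GRID, folds=3, seed=0)
        assert len(selected) <= 5  # <= 5% of variables under the null

    def test_huge_penalty_selects_nothing(self):
        X, y = self._planted(n=500, p=10)
        assert lasso_preselect(X, y, [1e6], folds=3, seed=0) == []

    def test_invalid_inputs(self):
        X, y = self._planted(n=200, p=5)
        with pytest.raises(ValueError):
            lasso_preselect(X, y, [], folds=3)
        with pytest.raises(ValueError):
            lasso_preselect(X, np.zeros(200), self.GRID, folds=3)


class TestCoxPH:
    def _planted_survival(self, seed=2, n=5000, betas=(0.5, -0.3)):
        rng = np.random.default_rng(seed)
        Z = pd.DataFrame(rng.standard_normal((n, len(betas))),
                         columns=[f"z{i}" for i in range(len(betas))])
        hazard = 0.1 * np.exp(Z.values @ np.array(betas))
        T = rng.exponential(1.0 / hazard)
        event = (T <= 5.0).astype(int)
        obs = np.minimum(T, 5.0)
        return Z, event, obs, betas

    def test_recovers_planted_coefficients(self):
        Z, event, obs, betas = self._planted_survival()
        model = fit_cox_ph(Z, list(Z.columns), event, obs)
        # covariates are standard normal, so the standardized fit estimates
        # the original coefficients directly
        np.testing.assert_allclose(model.fitter.params_.values, betas, atol=0.1)

    def test_monotone_in_positive_coefficient(self):
        Z, event, obs, _ = self._planted_survival()
        model = fit_cox_ph(Z, list(Z.columns), event, obs)
        lo = pd.DataFrame({"z0": [0.0], "z1": [0.0]})
        hi = pd.DataFrame({"z0": [2.0], "z1": [0.0]})
        assert model.predict(hi)[0] > model.predict(lo)[0]
        assert 0.0 <= model.predict(lo)[0] <= 1.0

    def test_no_events_errors(self):
        Z = pd.DataFrame({"z0": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            fit_cox_ph(Z, ["z0"], [0, 0, 0], [5.0, 5.0, 5.0])


class TestGridSearchedClassifiers:
    def _separable(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        y = (X["a"].values > 0).astype(int)  # margin-free separable rule
        return X, y

    @pytest.mark.parametrize("family", GRID_FAMILIES)
    def test_separable_data_reaches_high_cv_auc(self, family):
        X, y = self._separable()
        model = fit_grid_searched_classifier(X, y, family, folds=3, seed=0)
        assert model.cv_auc >= 0.99
        p = model.predict(X)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_single_point_grid_equals_direct_fit(self):
        X, y = self._separable()
        grid = {"clf__n_estimators": [50]}
        m1 = fit_grid_searched_classifier(X, y, "random_forest", grid=grid, folds=3, seed=1)
        m2 = fit_grid_searched_classifier(X, y, "random_forest", grid=grid, folds=3, seed=1)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
        assert m1.best_params == {"clf__n_estimators": 50}

    def test_same_seed_selects_same_grid_point(self, toy_classification):
        X, y = toy_classification
        Xc = X.fillna(X.mean())
        m1 = fit_grid_searched_classifier(Xc, y, "gradient_boosting", folds=3, seed=3)
        m2 = fit_grid_searched_classifier(Xc, y, "gradient_boosting", folds=3, seed=3)
        assert m1.best_params == m2.best_params
        np.testing.assert_array_equal(m1.predict(Xc), m2.predict(Xc))

    def test_empty_grid_errors(self):
        X, y = self._separable(n=100)
        with pytest.raises(ValueError):
            fit_grid_searched_classifier(X, y, "random_forest", grid={}, folds=3)
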