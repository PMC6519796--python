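"""Comparator risk models.

Three families of baselines are provided against which richer models are
judged:

* the published office-based (BMI) Framingham risk equation, applied with
  its fixed published coefficients (never refit);
* Cox proportional-hazards models — one on the seven conventional risk
  factors, one on all variables after LASSO preselection of the binary
  outcome (fitting Cox directly in high dimension is numerically fragile);
* grid-searched standard classifiers (linear SVM, random forest, neural
  network, AdaBoost, gradient boosting).

All fitted models share a single contract: ``predict(table)`` returns
per-participant event probabilities in [0, 1] for any table containing the
model's variable list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier, HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from prognopipe.cohort import CORE7

GRID_FAMILIES = ("linear_svm", "random_forest", "neural_net", "adaboost", "gradient_boosting")


# ---------------------------------------------------------------------------
# Framingham office-based (BMI) risk equation
# ---------------------------------------------------------------------------

@dataclass
class FraminghamCoefficients:
    """Published per-gender coefficients of the office-based risk equation."""

    male: dict
    female: dict
    version: str = "2008-bmi"

    def __post_init__(self) -> None:
        for g in (self.male, self.female):
            if not 0.0 < g["baseline_survival_10y"] < 1.0:
                raise ValueError("baseline survival must be in (0, 1)")


def load_framingham_coefficients() -> FraminghamCoefficients:
    """Load the versioned constants file shipped with the package."""
    text = resources.files("prognopipe.data").joinpath("framingham_bmi.json").read_text()
    raw = json.loads(text)
    return FraminghamCoefficients(male=raw["male"], female=raw["female"], version=raw["version"])


def framingham_bmi_risk(
    age,
    bmi,
    sbp,
    htn_treatment,
    smoking,
    diabetes,
    gender,
    horizon_years: float = 10.0,
    coeffs: FraminghamCoefficients | None = None,
):
    """Event risk over ``horizon_years`` from the office-based equation.

    risk = 1 - S0(t)^exp(LP - mean LP), with gender-specific coefficients on
    log(age), log(BMI), log(SBP) (treated/untreated), smoking and diabetes.
    The published baseline survival is at 10 years; other horizons use
    constant-hazard scaling S0(t) = S0(10)^(t/10). Inputs may be scalars or
    aligned arrays; ``gender`` is 1 = male, 0 = female.
    """
    if coeffs is None:
        coeffs = load_framingham_coefficients()
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    if np.any(age <= 0) or np.any(bmi <= 0) or np.any(sbp <= 0):
        raise ValueError("age, BMI and SBP must be positive (log-transformed predictors)")
    treated = np.asarray(htn_treatment, dtype=float)
    smk = np.asarray(smoking, dtype=float)
    dia = np.asarray(diabetes, dtype=float)
    male = np.asarray(gender, dtype=float)

    risk = np.empty(np.broadcast(age, male).shape or (1,), dtype=float)
    for flag, c in ((1.0, coeffs.male), (0.0, coeffs.female)):
        lp = (c["ln_age"] * np.log(age)
              + c["ln_bmi"] * np.log(bmi)
              + np.where(treated > 0, c["ln_sbp_treated"], c["ln_sbp_untreated"]) * np.log(sbp)
              + c["smoking"] * smk
              + c["diabetes"] * dia)
        s0 = c["baseline_survival_10y"] ** (horizon_years / 10.0)
        r = 1.0 - s0 ** np.exp(lp - c["mean_linear_predictor"])
        sel = np.broadcast_to(male, risk.shape) == flag
        risk[sel] = np.broadcast_to(r, risk.shape)[sel]
    return risk if risk.size > 1 else float(risk[0])


@dataclass
class FittedModel:
    """A fitted risk model: a tag, a variable list, and a predict contract."""

    model_tag: str
    variables: list
    _predict_fn: object

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.variables]
        p = np.asarray(self._predict_fn(X), dtype=float)
        return np.clip(p, 0.0, 1.0)


def framingham_model(horizon_years: float = 5.0,
                     coeffs: FraminghamCoefficients | None = None) -> FittedModel:
    """The Framingham comparator wrapped in the shared model contract."""
    coeffs = coeffs or load_framingham_coefficients()

    def _predict(X: pd.DataFrame) -> np.ndarray:
        return framingham_bmi_risk(
            X["age"].values, X["bmi"].values, X["sbp"].values,
            X["htn_treatment"].values, X["smoking"].values, X["diabetes"].values,
            X["gender"].values, horizon_years=horizon_years, coeffs=coeffs)

    return FittedModel(model_tag="framingham_bmi", variables=list(CORE7), _predict_fn=_predict)


# ---------------------------------------------------------------------------
# LASSO preselection + Cox proportional hazards
# ---------------------------------------------------------------------------

def lasso_preselect(table: pd.DataFrame, outcome, lambda_grid, folds: int = 5,
                    seed: int = 0, rule: str = "1se") -> list:
    """Variables with non-zero coefficients in an L1-penalized linear model
    of the binary outcome, with the penalty chosen by cross-validation.

    The squared-error LASSO is fitted to the 0/1 outcome on standardized
    covariates. ``rule='1se'`` (default) picks the largest penalty whose
    mean CV squared error is within one standard error of the minimum,
    which keeps the selected set sparse under the null; ``rule='min'``
    picks the CV-error minimiser (useful at very low event rates, where
    the one-standard-error rule can shrink everything away).
    """
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    lambda_grid = sorted(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda_grid must be non-empty")
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; LASSO selection undefined")
    X = StandardScaler().fit_transform(table.values)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    mean_err, se_err = [], []
    for lam in lambda_grid:
        errs = []
        for tr, te in cv.split(X):
            m = Lasso(alpha=lam, max_iter=5000)
            m.fit(X[tr], y[tr])
            errs.append(np.mean((m.predict(X[te]) - y[te]) ** 2))
        mean_err.append(np.mean(errs))
        se_err.append(np.std(errs, ddof=1) / np.sqrt(len(errs)))
    i_min = int(np.argmin(mean_err))
    if rule == "min":
        best = lambda_grid[i_min]
    else:
        cutoff = mean_err[i_min] + se_err[i_min]
        best = max(lam for lam, err in zip(lambda_grid, mean_err) if err <= cutoff)
    final = Lasso(alpha=best, max_iter=5000).fit(X, y)
    cols = np.asarray(table.columns)
    return cols[np.abs(final.coef_) > 1e-10].tolist()


def fit_cox_ph(table: pd.DataFrame, variables, outcome, follow_up,
               horizon_years: float = 5.0, penalizer: float = 0.0) -> FittedModel:
    """Cox proportional-hazards risk model with risk-at-horizon predictions.

    Predicted risk is 1 - S0(horizon)^exp(centred linear predictor) from the
    Breslow baseline. Covariates are standardized with training statistics
    inside the model, so prediction only needs the raw variable columns.
    """
    variables = list(variables)
    y = np.asarray(outcome).astype(int)
    if y.sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    scaler = StandardScaler().fit(table[variables].values)
    df = pd.DataFrame(scaler.transform(table[variables].values), columns=variables)
    df["duration"] = np.asarray(follow_up, dtype=float)
    df["event"] = y
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event")
    except Exception as exc:  # collinear/singular designs surface here
        raise ValueError(f"Cox PH fit failed (singular or ill-conditioned design): {exc}") from exc

    def _predict(X: pd.DataFrame) -> np.ndarray:
        Z = pd.DataFrame(scaler.transform(X[variables].values), columns=variables)
        surv = cph.predict_survival_function(Z, times=[horizon_years])
        return 1.0 - surv.iloc[0].values

    model = FittedModel(model_tag="cox_ph", variables=variables, _predict_fn=_predict)
    model.fitter = cph
    return model


# ---------------------------------------------------------------------------
# Grid-searched standard classifiers
# ---------------------------------------------------------------------------

_DEFAULT_GRIDS = {
    "linear_svm": {"clf__C": [0.01, 0.1, 1.0]},
    "random_forest": {"clf__n_estimators": [100, 300], "clf__min_samples_leaf": [1, 20]},
    "neural_net": {"clf__hidden_layer_sizes": [(32,), (64, 32)], "clf__alpha": [1e-4, 1e-2]},
    "adaboost": {"clf__n_estimators": [50, 200], "clf__learning_rate": [0.5, 1.0]},
    "gradient_boosting": {"clf__max_iter": [100, 300], "clf__learning_rate": [0.05, 0.1]},
}


def _family_estimator(family: str, seed: int):
    if family == "linear_svm":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LinearSVC(random_state=seed, max_iter=5000))])
    if family == "random_forest":
        return Pipeline([("clf", RandomForestClassifier(random_state=seed, n_jobs=1))])
    if family == "neural_net":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", MLPClassifier(random_state=seed, max_iter=300))])
    if family == "adaboost":
        return Pipeline([("clf", AdaBoostClassifier(random_state=seed))])
    if family == "gradient_boosting":
        return Pipeline([("clf", HistGradientBoostingClassifier(random_state=seed))])
    raise ValueError(f"unknown family {family!r}; expected one of {GRID_FAMILIES}")


def fit_grid_searched_classifier(table: pd.DataFrame, outcome, family: str,
                                 grid: dict | None = None, folds: int = 3,
                                 seed: int = 0) -> FittedModel:
    """Hyper-parameter grid search by mean CV AUC, refit on all training data.

    Margin-based families (linear SVM) pass their decision values through a
    monotone logistic map fitted on the training data, which calibrates the
    output range without changing the ranking (AUC is preserved).
    """
    grid = _DEFAULT_GRIDS[family] if grid is None else grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyper-parameter grid")
    y = np.asarray(outcome).astype(int)
    est = _family_estimator(family, seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, n_jobs=1, refit=True)
        search.fit(table.values, y)
    best = search.best_estimator_

    if hasattr(best, "predict_proba"):
        def _predict(X: pd.DataFrame) -> np.ndarray:
            return best.predict_proba(X.values)[:, 1]
    else:
        # Platt-style monotone map from margins to probabilities.
        margins = best.decision_function(table.values).reshape(-1, 1)
        link = LogisticRegression().fit(margins, y)

        def _predict(X: pd.DataFrame) -> np.ndarray:
            return link.predict_proba(best.decision_function(X.values).reshape(-1, 1))[:, 1]

    model = FittedModel(model_tag=f"grid_{family}", variables=list(table.columns),
                        _predict_fn=_predict)
    model.best_params = search.best_params_
    model.cv_auc = float(search.best_score_)
    return model
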