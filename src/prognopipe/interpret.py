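"""Post-hoc interpretation of fitted risk models.

Two tools: (1) permutation-based variable importance of a model's
predictions via a random-forest surrogate — the surrogate regresses the
model's predicted risks on the covariates, and each variable's score is the
mean increase in held-out surrogate loss when that variable is permuted;
(2) a per-variable, age-adjusted predictive screen — for each gender a
baseline model on age alone is compared with a model on {age, variable},
and the AUC improvement is tested by a paired bootstrap over held-out
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from prognopipe.evaluation import auc_roc, stratified_folds


@dataclass
class ImportanceRanking:
    """Ordered per-variable importance shares within one stratum."""

    stratum: str
    entries: list  # (variable, score) ordered by descending score
    normalization: str = "sum-to-1"

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(s < 0 or not np.isfinite(s) for s in scores):
            raise ValueError("importance scores must be finite and non-negative")
        self.entries = sorted(self.entries, key=lambda e: -e[1])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["variable", "score"])


def posthoc_importance(
    model_predictions,
    table: pd.DataFrame,
    stratum_mask=None,
    stratum: str = "all",
    n_repeats: int = 5,
    seed: int = 0,
    permutation_seed: int | None = None,
    binarize_at: float | None = None,
    target: str = "logit",
    n_trees: int = 200,
) -> ImportanceRanking:
    """Permutation importance of a model's predictions via a surrogate forest.

    A random-forest regressor is fitted to (covariates -> model predictions)
    within the stratum; each variable's raw score is the mean increase in
    held-out squared error over ``n_repeats`` permutations of that variable.
    With rare outcomes the predicted risks are heavily right-skewed and a
    squared-error surrogate is dominated by a handful of tail participants,
    so the default regresses on the log-odds of the predictions
    (``target='logit'``, monotone, variance-stabilizing); ``target='risk'``
    uses the raw probabilities. With ``binarize_at`` set, predictions are
    thresholded and a classification surrogate scores the mean decrease in
    accuracy instead. Negative raw scores are floored at zero and the
    result is normalized to sum to one within the stratum, so scores behave
    as shares.
    """
    if target not in ("logit", "risk"):
        raise ValueError("target must be 'logit' or 'risk'")
    preds = np.asarray(model_predictions, dtype=float)
    if stratum_mask is not None:
        mask = np.asarray(stratum_mask, dtype=bool)
        preds = preds[mask]
        table = table.loc[mask]
    if np.ptp(preds) < 1e-12:
        raise ValueError("constant predictions: surrogate importance undefined")

    X = table.values.astype(float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)  # surrogate needs complete input
    rng = np.random.default_rng(seed if permutation_seed is None else permutation_seed)

    if binarize_at is not None:
        target = (preds >= binarize_at).astype(int)
        surrogate = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        loss = lambda y, yhat: float(np.mean(y != yhat))
        predict = lambda Z: surrogate.predict(Z)
    else:
        if target == "logit":
            clipped = np.clip(preds, 1e-6, 1.0 - 1e-6)
            target = np.log(clipped) - np.log1p(-clipped)
        else:
            target = preds
        surrogate = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        loss = lambda y, yhat: float(np.mean((y - yhat) ** 2))
        predict = lambda Z: surrogate.predict(Z)

    idx_tr, idx_te = train_test_split(np.arange(len(target)), test_size=0.25, random_state=seed)
    surrogate.fit(X[idx_tr], target[idx_tr])
    base_loss = loss(target[idx_te], predict(X[idx_te]))

    # one stacked forest call per variable (n_repeats permuted copies)
    raw = np.zeros(X.shape[1])
    Xte = X[idx_te]
    n_te = len(idx_te)
    for j in range(X.shape[1]):
        stacked = np.tile(Xte, (n_repeats, 1))
        for r in range(n_repeats):
            rows = slice(r * n_te, (r + 1) * n_te)
            stacked[rows, j] = Xte[rng.permutation(n_te), j]
        yhat = predict(stacked)
        increases = [loss(target[idx_te], yhat[r * n_te:(r + 1) * n_te]) - base_loss
                     for r in range(n_repeats)]
        raw[j] = np.mean(increases)

    raw = np.maximum(raw, 0.0)
    total = raw.sum()
    shares = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
    entries = list(zip(table.columns.tolist(), shares.tolist()))
    return ImportanceRanking(stratum=stratum, entries=entries)


@dataclass
class ScreenResult:
    """Per (gender, variable) age-adjusted predictive ability."""

    table: pd.DataFrame  # gender, variable, auc_with_variable, auc_age_only, delta, significant
    significance_level: float = 0.05

    def flagged(self, gender: str | None = None) -> list:
        t = self.table
        if gender is not None:
            t = t[t["gender"] == gender]
        return t.loc[t["significant"], "variable"].tolist()


def _cv_out_of_fold_probs(X, y, k, seed):
    """Out-of-fold logistic predictions, mean-imputing within training folds."""
    folds = stratified_folds(y, k, seed)
    probs = np.empty(len(y))
    for f in range(k):
        te = folds == f
        tr = ~te
        mu = np.nanmean(X[tr], axis=0)
        Xtr = np.where(np.isnan(X[tr]), mu, X[tr])
        Xte = np.where(np.isnan(X[te]), mu, X[te])
        scaler = StandardScaler().fit(Xtr)
        model = LogisticRegression(max_iter=1000).fit(scaler.transform(Xtr), y[tr])
        probs[te] = model.predict_proba(scaler.transform(Xte))[:, 1]
    return probs


def per_variable_screen(
    table: pd.DataFrame,
    outcome,
    gender_column: str = "gender",
    variables=None,
    significance_level: float = 0.05,
    seed: int = 0,
    k_folds: int = 5,
    n_bootstrap: int = 1000,
) -> ScreenResult:
    """Age-adjusted single-variable predictive screen, fitted per gender.

    For each gender stratum: a baseline risk model on age alone, then one
    model per variable on {age, variable}; held-out AUCs come from
    stratified CV, and the AUC improvement is tested with a paired bootstrap
    over the held-out predictions (flagged iff the one-sided improvement is
    significant at ``significance_level``).
    """
    if "age" not in table.columns:
        raise ValueError("screen requires a complete age column")
    y_all = np.asarray(outcome).astype(int)
    if variables is None:
        variables = [c for c in table.columns if c not in ("age", gender_column)]
    rng = np.random.default_rng(seed)
    rows = []
    for gender_tag, gender_value in (("male", 1.0), ("female", 0.0)):
        sel = table[gender_column].values == gender_value
        y = y_all[sel]
        sub = table.loc[sel]
        age = sub[["age"]].values.astype(float)
        base_probs = _cv_out_of_fold_probs(age, y, k_folds, seed)
        auc_base = auc_roc(base_probs, y)
        boot_idx = [rng.choice(len(y), len(y), replace=True) for _ in range(n_bootstrap)]
        for var in variables:
            col = sub[var].values.astype(float)
            if np.isnan(col).all():
                raise ValueError(f"variable {var!r} missing for all rows of {gender_tag}")
            X = np.column_stack([age.ravel(), col])
            probs = _cv_out_of_fold_probs(X, y, k_folds, seed)
            auc_var = auc_roc(probs, y)
            worse = 0
            valid = 0
            for idx in boot_idx:
                yb = y[idx]
                if yb.sum() == 0 or yb.sum() == len(yb):
                    continue
                valid += 1
                if auc_roc(probs[idx], yb) <= auc_roc(base_probs[idx], yb):
                    worse += 1
            p_value = (worse + 1) / (valid + 1) if valid else 1.0
            rows.append({
                "gender": gender_tag, "variable": var,
                "auc_with_variable": auc_var, "auc_age_only": auc_base,
                "delta": auc_var - auc_base,
                "p_value": p_value,
                "significant": p_value < significance_level,
            })
    return ScreenResult(table=pd.DataFrame(rows), significance_level=significance_level)
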