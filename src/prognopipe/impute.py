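"""Missing-data handling: simple fills, iterative random-forest imputation
(MissForest-style), multiple draws, and prediction pooling.

The multiple-imputation contract used throughout the package is pragmatic:
``m`` completed copies of the covariate table are drawn (differing only in
imputed cells), a model is applied to each, and the per-participant
predictions are averaged arithmetically. Only predictions are pooled —
coefficient-level variance combination is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

_SIMPLE_METHODS = ("mean", "median", "most_frequent")


@dataclass
class ImputationDraws:
    """A set of ``m`` completed covariate tables sharing all observed cells."""

    draws: list
    imputer_tag: str
    seed: int

    @property
    def m(self) -> int:
        return len(self.draws)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("at least one imputation draw is required")
        for d in self.draws:
            if d.isna().any().any():
                raise ValueError("imputation draws must have no missing cells")


def impute_simple(table: pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Fill missing cells with a per-column statistic of the observed values."""
    if method not in _SIMPLE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_SIMPLE_METHODS}")
    fully_missing = table.columns[table.isna().all()]
    if len(fully_missing):
        raise ValueError(f"columns with no observed values: {list(fully_missing)}")
    if method == "mean":
        fill = table.mean()
    elif method == "median":
        fill = table.median()
    else:
        fill = table.apply(lambda c: c.dropna().mode().iloc[0])
    return table.fillna(fill)


def _missforest_single(table, categorical, max_iter, rng):
    """One MissForest completion: iterate variables in increasing-missingness
    order, re-predicting each variable's missing cells from all others with a
    random forest, until the normalized change in imputed values first
    increases (continuous and categorical tracked separately)."""
    mask = table.isna()
    order = mask.sum().sort_values(kind="stable")
    todo = [c for c in order.index if order[c] > 0]
    current = impute_simple(table, "mean")
    for c in categorical:
        if c in todo:  # categorical initial fill: most frequent observed code
            current[c] = table[c].fillna(table[c].dropna().mode().iloc[0])
    if not todo:
        return current

    prev_gamma_cont = np.inf
    prev_gamma_cat = np.inf
    best = current.copy()
    for _ in range(max_iter):
        previous = current.copy()
        for col in todo:
            obs = ~mask[col].values
            X = current.drop(columns=[col]).values
            y = current[col].values
            if col in categorical:
                model = RandomForestClassifier(
                    n_estimators=50, random_state=int(rng.integers(2**31)), n_jobs=1)
                model.fit(X[obs], y[obs].astype(int))
                pred = model.predict(X[~obs]).astype(float)
            else:
                model = RandomForestRegressor(
                    n_estimators=50, random_state=int(rng.integers(2**31)), n_jobs=1)
                model.fit(X[obs], y[obs])
                pred = model.predict(X[~obs])
            vals = current[col].values.copy()
            vals[~obs] = pred
            current[col] = vals

        cont = [c for c in todo if c not in categorical]
        cat = [c for c in todo if c in categorical]
        gamma_cont = 0.0
        if cont:
            num = sum(((current[c] - previous[c]) ** 2).sum() for c in cont)
            den = sum((current[c] ** 2).sum() for c in cont)
            gamma_cont = num / max(den, 1e-12)
        gamma_cat = 0.0
        if cat:
            changed = sum((current[c] != previous[c]).sum() for c in cat)
            n_miss = sum(int(mask[c].sum()) for c in cat)
            gamma_cat = changed / max(n_miss, 1)
        if gamma_cont > prev_gamma_cont or gamma_cat > prev_gamma_cat:
            return best  # stopping rule: first increase -> keep previous state
        best = current.copy()
        prev_gamma_cont, prev_gamma_cat = gamma_cont, gamma_cat
    return best


def impute_missforest(
    table: pd.DataFrame,
    n_draws: int = 5,
    max_iter: int = 10,
    seed: int = 0,
    categorical=(),
) -> ImputationDraws:
    """MissForest-style multiple imputation.

    Draws differ only through their random-forest seeds; all observed cells
    are preserved exactly. ``categorical`` names columns imputed with a
    classifier (and the categorical stopping statistic) rather than a
    regressor.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    fully_missing = table.columns[table.isna().all()]
    if len(fully_missing):
        raise ValueError(f"columns with no observed values: {list(fully_missing)}")
    categorical = set(categorical)
    draws = []
    for d in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence([seed, d]))
        draws.append(_missforest_single(table, categorical, max_iter, rng))
    return ImputationDraws(draws=draws, imputer_tag="missforest", seed=seed)


def rubin_average_predictions(predict_fn, draws: ImputationDraws) -> np.ndarray:
    """Pool predictions across imputation draws by the arithmetic mean.

    ``predict_fn`` maps one completed covariate table to per-participant
    probabilities in [0, 1]; the pooled risk is their mean over draws.
    """
    if draws.m < 1:
        raise ValueError("empty draws")
    preds = []
    for d in draws.draws:
        p = np.asarray(predict_fn(d), dtype=float)
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("predict_fn must return probabilities in [0, 1]")
        preds.append(p)
    return np.mean(preds, axis=0)
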