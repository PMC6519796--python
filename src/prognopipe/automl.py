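"""Automated pipeline search: design space, Bayesian-optimization search,
weighted ensembling, and probability calibration.

A *pipeline* is one choice per stage — data imputation, feature processing,
classification, calibration — together with hyper-parameter settings. The
default catalog mirrors the four-stage design space of automated prognostic
modeling frameworks: 8 imputation entries, 9 feature processors, 20
classifiers and 3 calibration methods. Reduced catalogs are first-class so
tests and desk-scale studies can search small spaces exhaustively.

The search is sequential model-based optimization: an initial random design,
then a random-forest surrogate over fixed-length pipeline descriptors
(one-hot stage entries + normalized hyper-parameters) proposing the next
pipeline by expected improvement over random candidate draws. A
kernel-based surrogate is deliberately avoided: the space is mixed
discrete/continuous and a forest surrogate is robust there. Every pipeline
is scored by stratified cross-validated AUC with all preprocessing fitted
on training folds only.

The final model is a weighted ensemble of the top pipelines refit on the
full training data, with softmax-over-CV-score weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.cluster import FeatureAgglomeration
from sklearn.decomposition import FastICA, KernelPCA, PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.feature_selection import GenericUnivariateSelect, SelectFromModel, SelectKBest, f_classif
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.impute import IterativeImputer, SimpleImputer
from sklearn.isotonic import IsotonicRegression
from sklearn.kernel_approximation import Nystroem, RBFSampler
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import BernoulliNB, GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler, PolynomialFeatures, StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from prognopipe.evaluation import auc_roc

CATALOG_VERSION = "default-1"

STAGES = ("imputation", "feature", "classification", "calibration")


# ---------------------------------------------------------------------------
# Catalog entries
# ---------------------------------------------------------------------------
# Hyper-parameter domains: ("int", lo, hi), ("float", lo, hi, log?) per entry.

IMPUTATION_DOMAINS = {
    "missforest": {"n_estimators": ("int", 10, 50)},
    "mean": {},
    "mice": {"max_iter": ("int", 2, 5)},
    "median": {},
    "em": {"max_iter": ("int", 2, 5)},
    "none": {},
    "most_frequent": {},
    "matrix_completion": {"rank": ("int", 2, 8)},
}

FEATURE_DOMAINS = {
    "feature_agglomeration": {"n_clusters": ("int", 4, 24)},
    "random_kitchen_sinks": {"n_components": ("int", 20, 100)},
    "select_rates": {"alpha": ("float", 0.01, 0.3)},
    "kernel_pca": {"n_components": ("int", 4, 20)},
    "fast_ica": {"n_components": ("int", 4, 20)},
    "nystroem": {"n_components": ("int", 20, 100)},
    "polynomial": {"k_base": ("int", 5, 12)},
    "pca": {"n_components": ("int", 4, 24)},
    "linear_svm_select": {"C": ("float", 0.01, 1.0)},
}

CLASSIFICATION_DOMAINS = {
    "bernoulli_nb": {},
    "linear_svm": {"C": ("float", 0.01, 1.0)},
    "gaussian_nb": {},
    "multinomial_nb": {"alpha": ("float", 0.1, 2.0)},
    "lightgbm": {"n_estimators": ("int", 50, 300), "learning_rate": ("float", 0.02, 0.2)},
    "survival_forest": {"n_estimators": ("int", 30, 100)},
    "cox_regression": {"penalizer": ("float", 0.001, 0.5)},
    "adaboost": {"n_estimators": ("int", 50, 200)},
    "gradient_boosting": {"max_iter": ("int", 50, 300), "learning_rate": ("float", 0.02, 0.2)},
    "xgboost": {"n_estimators": ("int", 50, 300), "max_depth": ("int", 2, 6)},
    "random_forest": {"n_estimators": ("int", 100, 300), "min_samples_leaf": ("int", 1, 20)},
    "logistic_regression": {"C": ("float", 0.01, 10.0)},
    "bagging": {"n_estimators": ("int", 10, 50)},
    "ridge_classifier": {"alpha": ("float", 0.1, 10.0)},
    "decision_tree": {"max_depth": ("int", 2, 10)},
    "lda": {},
    "extra_trees": {"n_estimators": ("int", 100, 300)},
    "neural_network": {"alpha": ("float", 1e-4, 1e-1)},
    "gaussian_process": {},
    "knn": {"n_neighbors": ("int", 5, 100)},
}

CALIBRATION_DOMAINS = {"sigmoid": {}, "isotonic": {}, "none": {}}

DOMAINS = {
    "imputation": IMPUTATION_DOMAINS,
    "feature": FEATURE_DOMAINS,
    "classification": CLASSIFICATION_DOMAINS,
    "calibration": CALIBRATION_DOMAINS,
}

# Rows fed to quadratic-cost fitters are capped by subsampling the training
# fold; transform/predict still runs on all rows.
_KPCA_MAX_FIT = 1000
_GP_MAX_FIT = 400
_SURVIVAL_MAX_FIT = 2000


@dataclass
class DesignSpace:
    """Per-stage catalogs of pipeline entries (with hyper-parameter domains)."""

    imputation: list
    feature: list
    classification: list
    calibration: list
    version: str = CATALOG_VERSION

    def __post_init__(self) -> None:
        for stage in STAGES:
            entries = getattr(self, stage)
            unknown = [e for e in entries if e not in DOMAINS[stage]]
            if unknown:
                raise ValueError(f"unknown {stage} entries: {unknown}")
            if len(set(entries)) != len(entries):
                raise ValueError(f"duplicate {stage} entries")
            if not entries:
                raise ValueError(f"{stage} catalog must be non-empty")

    @property
    def cardinality(self) -> int:
        """Number of distinct pipelines, hyper-parameters excluded."""
        out = 1
        for stage in STAGES:
            out *= len(getattr(self, stage))
        return out

    def stage_entries(self, stage: str) -> list:
        return list(getattr(self, stage))

    # -- sampling -----------------------------------------------------------
    def _sample_params(self, stage, entry, rng) -> dict:
        params = {}
        for pname, dom in DOMAINS[stage][entry].items():
            kind, lo, hi = dom[0], dom[1], dom[2]
            if kind == "int":
                params[pname] = int(rng.integers(lo, hi + 1))
            else:
                params[pname] = float(rng.uniform(lo, hi))
        return params

    def _default_params(self, stage, entry) -> dict:
        params = {}
        for pname, dom in DOMAINS[stage][entry].items():
            kind, lo, hi = dom[0], dom[1], dom[2]
            mid = (lo + hi) / 2.0
            params[pname] = int(round(mid)) if kind == "int" else float(mid)
        return params

    def sample_spec(self, rng) -> "PipelineSpec":
        choice = {}
        for stage in STAGES:
            entries = self.stage_entries(stage)
            entry = entries[int(rng.integers(len(entries)))]
            choice[stage] = (entry, self._sample_params(stage, entry, rng))
        return PipelineSpec(**choice)

    def enumerate_default_specs(self) -> list:
        """All entry combinations at default hyper-parameters, in catalog order."""
        specs = []
        for im in self.imputation:
            for fe in self.feature:
                for cl in self.classification:
                    for ca in self.calibration:
                        specs.append(PipelineSpec(
                            imputation=(im, self._default_params("imputation", im)),
                            feature=(fe, self._default_params("feature", fe)),
                            classification=(cl, self._default_params("classification", cl)),
                            calibration=(ca, self._default_params("calibration", ca)),
                        ))
        return specs

    # -- descriptors for the surrogate --------------------------------------
    def descriptor(self, spec: "PipelineSpec") -> np.ndarray:
        """Fixed-length encoding: one-hot entries + normalized hyper-parameters."""
        parts = []
        for stage in STAGES:
            entries = self.stage_entries(stage)
            entry, params = getattr(spec, stage)
            onehot = np.zeros(len(entries))
            onehot[entries.index(entry)] = 1.0
            parts.append(onehot)
            for e in entries:
                for pname, dom in sorted(DOMAINS[stage][e].items()):
                    if e == entry and pname in params:
                        lo, hi = dom[1], dom[2]
                        parts.append(np.array([(params[pname] - lo) / max(hi - lo, 1e-12)]))
                    else:
                        parts.append(np.zeros(1))
        return np.concatenate(parts)


def default_design_space() -> DesignSpace:
    """The full four-stage catalog (8 x 9 x 20 x 3 entries)."""
    return DesignSpace(
        imputation=list(IMPUTATION_DOMAINS),
        feature=list(FEATURE_DOMAINS),
        classification=list(CLASSIFICATION_DOMAINS),
        calibration=list(CALIBRATION_DOMAINS),
    )


def reduced_design_space(imputation=("mean",), feature=("select_rates",),
                         classification=("gradient_boosting", "logistic_regression"),
                         calibration=("sigmoid", "none")) -> DesignSpace:
    """A small catalog for desk-scale searches and tests."""
    return DesignSpace(imputation=list(imputation), feature=list(feature),
                       classification=list(classification), calibration=list(calibration))


def enumerate_design_space(catalog_config: dict | None = None) -> DesignSpace:
    """Build a design space from a catalog configuration mapping stage ->
    entry names; the default configuration yields the full catalog."""
    if catalog_config is None:
        return default_design_space()
    kwargs = {stage: list(catalog_config.get(stage, list(DOMAINS[stage]))) for stage in STAGES}
    return DesignSpace(**kwargs)


@dataclass(frozen=True)
class PipelineSpec:
    """One (entry, hyper-parameters) choice per pipeline stage."""

    imputation: tuple
    feature: tuple
    classification: tuple
    calibration: tuple

    def __post_init__(self) -> None:
        for stage in STAGES:
            entry, params = getattr(self, stage)
            for pname, value in params.items():
                dom = DOMAINS[stage][entry].get(pname)
                if dom is None:
                    raise ValueError(f"unknown hyper-parameter {pname!r} for {stage}:{entry}")
                if not dom[1] <= value <= dom[2]:
                    raise ValueError(
                        f"{stage}:{entry} hyper-parameter {pname}={value} outside {dom[1:3]}")

    def to_dict(self) -> dict:
        return {stage: {"entry": getattr(self, stage)[0], "params": dict(getattr(self, stage)[1])}
                for stage in STAGES}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineSpec":
        return cls(**{stage: (d[stage]["entry"], dict(d[stage]["params"])) for stage in STAGES})

    def __repr__(self) -> str:  # compact: imputation/feature/classifier/calibration
        return "|".join(getattr(self, stage)[0] for stage in STAGES)


@dataclass
class SearchRecord:
    """One search iteration: the spec tried and its cross-validated score."""

    iteration: int
    spec: PipelineSpec
    cv_score: float
    fold_scores: list = field(default_factory=list)
    proposal: str = "random"
    error: str | None = None


# ---------------------------------------------------------------------------
# Stage factories
# ---------------------------------------------------------------------------

class _MissForestTransform:
    """Inductive MissForest-style imputer: mean-fill initialisation, then a
    per-column random forest (fitted on the training completion) re-predicts
    missing cells of any table it is applied to."""

    def __init__(self, n_estimators=30, n_iter=2, seed=0):
        self.n_estimators = int(n_estimators)
        self.n_iter = int(n_iter)
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.means_ = np.nanmean(X, axis=0)
        self.models_ = {}
        current = np.where(np.isnan(X), self.means_, X)
        mask = np.isnan(X)
        cols = np.argsort(mask.sum(axis=0), kind="stable")
        rng = np.random.default_rng(self.seed)
        for _ in range(self.n_iter):
            for j in cols:
                if not mask[:, j].any():
                    continue
                obs = ~mask[:, j]
                rf = RandomForestRegressor(n_estimators=self.n_estimators,
                                           random_state=int(rng.integers(2**31)), n_jobs=1)
                Xo = np.delete(current, j, axis=1)
                rf.fit(Xo[obs], X[obs, j])
                current[mask[:, j], j] = rf.predict(Xo[mask[:, j]])
                self.models_[j] = rf
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        current = np.where(mask, self.means_, X)
        for j, rf in self.models_.items():
            if mask[:, j].any():
                Xo = np.delete(current, j, axis=1)
                current[mask[:, j], j] = rf.predict(Xo[mask[:, j]])
        return current


class _MatrixCompletion:
    """Soft-impute style low-rank completion: alternate mean-fill and
    truncated-SVD reconstruction of the missing cells."""

    def __init__(self, rank=4, n_iter=5):
        self.rank = int(rank)
        self.n_iter = n_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.means_ = np.nanmean(X, axis=0)
        self.scales_ = np.nanstd(X, axis=0)
        self.scales_[self.scales_ == 0] = 1.0
        self._complete(X)  # learn components on training data
        return self

    def _complete(self, X):
        mask = np.isnan(X)
        Z = (np.where(mask, self.means_, X) - self.means_) / self.scales_
        r = min(self.rank, min(Z.shape) - 1) if min(Z.shape) > 1 else 1
        for _ in range(self.n_iter):
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            approx = (U[:, :r] * s[:r]) @ Vt[:r]
            Z[mask] = approx[mask]
        self.Vt_ = Vt[:r]
        return Z * self.scales_ + self.means_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        Z = (np.where(mask, self.means_, X) - self.means_) / self.scales_
        for _ in range(self.n_iter):
            approx = (Z @ self.Vt_.T) @ self.Vt_
            Z[mask] = approx[mask]
        return Z * self.scales_ + self.means_


class _Identity:
    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)


def _make_imputer(entry, params, seed):
    if entry == "missforest":
        return _MissForestTransform(n_estimators=params.get("n_estimators", 30), seed=seed)
    if entry in ("mean", "median", "most_frequent"):
        return SimpleImputer(strategy=entry)
    if entry == "mice":
        return IterativeImputer(max_iter=int(params.get("max_iter", 3)),
                                sample_posterior=True, random_state=seed)
    if entry == "em":
        return IterativeImputer(max_iter=int(params.get("max_iter", 3)),
                                sample_posterior=False, random_state=seed)
    if entry == "none":
        return _Identity()
    if entry == "matrix_completion":
        return _MatrixCompletion(rank=params.get("rank", 4))
    raise ValueError(f"unknown imputation entry {entry!r}")


class _CapComponents:
    """Clip a width-like parameter to the number of input columns at fit."""

    def __init__(self, factory, param, value):
        self.factory = factory
        self.param = param
        self.value = int(value)

    def fit(self, X, y=None):
        capped = min(self.value, np.asarray(X).shape[1])
        self.transformer_ = self.factory(**{self.param: capped})
        self.transformer_.fit(X, y)
        return self

    def transform(self, X):
        return self.transformer_.transform(np.asarray(X))


class _SubsampleFit:
    """Fit an expensive transformer on a row subsample, transform everything."""

    def __init__(self, transformer, max_rows, seed):
        self.transformer = transformer
        self.max_rows = max_rows
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X)
        if len(X) > self.max_rows:
            idx = np.random.default_rng(self.seed).choice(len(X), self.max_rows, replace=False)
            self.transformer.fit(X[idx])
        else:
            self.transformer.fit(X)
        return self

    def transform(self, X):
        return self.transformer.transform(np.asarray(X))


class _SafeSelect:
    """Univariate selection that passes everything through when no column
    survives the rate test (pure-noise inputs)."""

    def __init__(self, selector):
        self.selector = selector

    def fit(self, X, y=None):
        self.selector.fit(X, y)
        self.passthrough_ = not self.selector.get_support().any()
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X if self.passthrough_ else self.selector.transform(X)


class _PolyOnTopFeatures:
    """Degree-2 polynomial expansion of the top-k univariately ranked columns
    (caps the dimension blow-up of a full polynomial basis)."""

    def __init__(self, k_base=8):
        self.k_base = int(k_base)

    def fit(self, X, y=None):
        self.select_ = SelectKBest(f_classif, k=min(self.k_base, X.shape[1])).fit(X, y)
        self.poly_ = PolynomialFeatures(degree=2, include_bias=False)
        self.poly_.fit(self.select_.transform(X))
        return self

    def transform(self, X):
        return self.poly_.transform(self.select_.transform(np.asarray(X)))


def _make_feature(entry, params, seed):
    if entry == "feature_agglomeration":
        return _CapComponents(lambda n_clusters: FeatureAgglomeration(n_clusters=n_clusters),
                              "n_clusters", params.get("n_clusters", 10))
    if entry == "random_kitchen_sinks":
        return RBFSampler(n_components=int(params.get("n_components", 50)), random_state=seed)
    if entry == "select_rates":
        return _SafeSelect(GenericUnivariateSelect(f_classif, mode="fpr",
                                                   param=float(params.get("alpha", 0.1))))
    if entry == "kernel_pca":
        return _SubsampleFit(KernelPCA(n_components=int(params.get("n_components", 10)),
                                       kernel="rbf", random_state=seed),
                             _KPCA_MAX_FIT, seed)
    if entry == "fast_ica":
        return _CapComponents(
            lambda n_components: FastICA(n_components=n_components, random_state=seed,
                                         max_iter=300, tol=1e-2, whiten="unit-variance"),
            "n_components", params.get("n_components", 10))
    if entry == "nystroem":
        return Nystroem(n_components=int(params.get("n_components", 50)), random_state=seed)
    if entry == "polynomial":
        return _PolyOnTopFeatures(k_base=params.get("k_base", 8))
    if entry == "pca":
        return _CapComponents(
            lambda n_components: PCA(n_components=n_components, random_state=seed),
            "n_components", params.get("n_components", 10))
    if entry == "linear_svm_select":
        base = LinearSVC(C=float(params.get("C", 0.1)), penalty="l1", dual=False, max_iter=3000)
        return _SafeSelect(SelectFromModel(base))
    raise ValueError(f"unknown feature entry {entry!r}")


class _PlattScored:
    """Classifier scored through a monotone logistic map of its margins."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        margins = self._margin(X).reshape(-1, 1)
        self.link_ = LogisticRegression().fit(margins, y)
        return self

    def _margin(self, X):
        return np.asarray(self.estimator.decision_function(X), dtype=float)

    def predict_proba_1(self, X):
        return self.link_.predict_proba(self._margin(X).reshape(-1, 1))[:, 1]


class _ScaledProba:
    """StandardScaler + probabilistic classifier."""

    def __init__(self, estimator, scaler=None):
        self.estimator = estimator
        self.scaler = scaler or StandardScaler()

    def fit(self, X, y):
        Z = self.scaler.fit_transform(X)
        self.estimator.fit(Z, y)
        return self

    def predict_proba_1(self, X):
        return self.estimator.predict_proba(self.scaler.transform(X))[:, 1]


class _ProbaWrap:
    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict_proba_1(self, X):
        return self.estimator.predict_proba(X)[:, 1]


class _SubsampledProba(_ProbaWrap):
    """Quadratic-cost classifier fitted on a capped row subsample."""

    def __init__(self, estimator, max_rows, seed):
        super().__init__(estimator)
        self.max_rows = max_rows
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if len(X) > self.max_rows:
            # stratified subsample so the rare class is kept
            idx, _ = train_test_split(np.arange(len(X)), train_size=self.max_rows,
                                      stratify=y, random_state=self.seed)
            X, y = X[idx], y[idx]
        self.estimator.fit(X, y)
        return self


class _MinMaxProba(_ProbaWrap):
    """Min-max rescaling in front of classifiers requiring non-negative input."""

    def fit(self, X, y):
        self.scaler_ = MinMaxScaler().fit(X)
        self.estimator.fit(self.scaler_.transform(X), y)
        return self

    def predict_proba_1(self, X):
        return self.estimator.predict_proba(self.scaler_.transform(X))[:, 1]


class _SurvivalRankScored:
    """Survival-style scorers reduced to the binary-probability contract.

    Without an event-time column in the pipeline data contract, events are
    assigned pseudo-times before censoring (0.5 vs 1.0), which preserves the
    event/non-event ranking objective; the model's risk score is mapped to
    [0, 1] with a monotone logistic link.
    """

    def __init__(self, kind, params, seed):
        self.kind = kind
        self.params = params
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if self.kind == "survival_forest":
            from sksurv.ensemble import RandomSurvivalForest
            if len(X) > _SURVIVAL_MAX_FIT:
                idx, _ = train_test_split(np.arange(len(X)), train_size=_SURVIVAL_MAX_FIT,
                                          stratify=y, random_state=self.seed)
            else:
                idx = np.arange(len(X))
            times = np.where(y[idx] == 1, 0.5, 1.0)
            yy = np.array(list(zip(y[idx].astype(bool), times)),
                          dtype=[("event", bool), ("time", float)])
            self.model_ = RandomSurvivalForest(
                n_estimators=int(self.params.get("n_estimators", 50)),
                min_samples_leaf=15, random_state=self.seed, n_jobs=1)
            self.model_.fit(X[idx], yy)
            scores = self.model_.predict(X)
        else:  # cox_regression
            from lifelines import CoxPHFitter
            self.scaler_ = StandardScaler().fit(X)
            df = pd.DataFrame(self.scaler_.transform(X))
            df.columns = [f"x{j}" for j in range(X.shape[1])]
            df["duration"] = np.where(y == 1, 0.5, 1.0)
            df["event"] = y
            self.model_ = CoxPHFitter(penalizer=float(self.params.get("penalizer", 0.1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.model_.fit(df, duration_col="duration", event_col="event")
            scores = self._cox_scores(X)
        self.link_ = LogisticRegression().fit(np.asarray(scores).reshape(-1, 1), y)
        return self

    def _cox_scores(self, X):
        df = pd.DataFrame(self.scaler_.transform(np.asarray(X, dtype=float)))
        df.columns = [f"x{j}" for j in range(df.shape[1])]
        return self.model_.predict_partial_hazard(df).values

    def predict_proba_1(self, X):
        if self.kind == "survival_forest":
            scores = self.model_.predict(np.asarray(X, dtype=float))
        else:
            scores = self._cox_scores(X)
        return self.link_.predict_proba(np.asarray(scores).reshape(-1, 1))[:, 1]


def _make_classifier(entry, params, seed):
    p = params
    if entry == "bernoulli_nb":
        return _ScaledProba(BernoulliNB())
    if entry == "linear_svm":
        return _PlattScored(LinearSVC(C=float(p.get("C", 0.1)), max_iter=5000, random_state=seed))
    if entry == "gaussian_nb":
        return _ProbaWrap(GaussianNB())
    if entry == "multinomial_nb":
        return _MinMaxProba(MultinomialNB(alpha=float(p.get("alpha", 1.0))))
    if entry == "lightgbm":
        from lightgbm import LGBMClassifier
        return _ProbaWrap(LGBMClassifier(
            n_estimators=int(p.get("n_estimators", 100)),
            learning_rate=float(p.get("learning_rate", 0.1)),
            random_state=seed, verbose=-1, n_jobs=1))
    if entry in ("survival_forest", "cox_regression"):
        return _SurvivalRankScored(entry, p, seed)
    if entry == "adaboost":
        return _ProbaWrap(AdaBoostClassifier(
            n_estimators=int(p.get("n_estimators", 100)), random_state=seed))
    if entry == "gradient_boosting":
        return _ProbaWrap(HistGradientBoostingClassifier(
            max_iter=int(p.get("max_iter", 150)),
            learning_rate=float(p.get("learning_rate", 0.1)), random_state=seed))
    if entry == "xgboost":
        from xgboost import XGBClassifier
        return _ProbaWrap(XGBClassifier(
            n_estimators=int(p.get("n_estimators", 150)),
            max_depth=int(p.get("max_depth", 4)),
            tree_method="hist", random_state=seed, n_jobs=1, verbosity=0))
    if entry == "random_forest":
        return _ProbaWrap(RandomForestClassifier(
            n_estimators=int(p.get("n_estimators", 200)),
            min_samples_leaf=int(p.get("min_samples_leaf", 5)),
            random_state=seed, n_jobs=1))
    if entry == "logistic_regression":
        return _ScaledProba(LogisticRegression(C=float(p.get("C", 1.0)), max_iter=2000))
    if entry == "bagging":
        return _ProbaWrap(BaggingClassifier(
            n_estimators=int(p.get("n_estimators", 20)), random_state=seed, n_jobs=1))
    if entry == "ridge_classifier":
        return _PlattScored(RidgeClassifier(alpha=float(p.get("alpha", 1.0)), random_state=seed))
    if entry == "decision_tree":
        return _ProbaWrap(DecisionTreeClassifier(
            max_depth=int(p.get("max_depth", 5)), random_state=seed))
    if entry == "lda":
        return _ProbaWrap(LinearDiscriminantAnalysis())
    if entry == "extra_trees":
        return _ProbaWrap(ExtraTreesClassifier(
            n_estimators=int(p.get("n_estimators", 200)), min_samples_leaf=5,
            random_state=seed, n_jobs=1))
    if entry == "neural_network":
        return _ScaledProba(MLPClassifier(
            hidden_layer_sizes=(32,), alpha=float(p.get("alpha", 1e-3)),
            max_iter=200, random_state=seed))
    if entry == "gaussian_process":
        return _SubsampledProba(GaussianProcessClassifier(random_state=seed), _GP_MAX_FIT, seed)
    if entry == "knn":
        return _ScaledProba(KNeighborsClassifier(n_neighbors=int(p.get("n_neighbors", 25))))
    raise ValueError(f"unknown classification entry {entry!r}")


class _SigmoidCalibrator:
    def fit(self, scores, y):
        self.link_ = LogisticRegression().fit(np.asarray(scores).reshape(-1, 1), y)
        return self

    def transform(self, scores):
        return self.link_.predict_proba(np.asarray(scores).reshape(-1, 1))[:, 1]


class _IsotonicCalibrator:
    def fit(self, scores, y):
        self.iso_ = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        self.iso_.fit(np.asarray(scores, dtype=float), np.asarray(y, dtype=float))
        return self

    def transform(self, scores):
        return self.iso_.predict(np.asarray(scores, dtype=float))


# ---------------------------------------------------------------------------
# Fitted pipelines
# ---------------------------------------------------------------------------

class FittedPipeline:
    """One fitted pipeline: imputer -> feature processor -> classifier ->
    calibrator, with every stage fitted on training data only.

    Calibration (when not ``none``) is fitted on an internal stratified
    20% split of the training data so the calibrator never sees the
    classifier's own training scores.
    """

    def __init__(self, spec: PipelineSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed

    def fit(self, X: pd.DataFrame, y) -> "FittedPipeline":
        self.columns_ = list(X.columns)
        Xv = X.values.astype(float)
        y = np.asarray(y).astype(int)
        imp_name, imp_p = self.spec.imputation
        fea_name, fea_p = self.spec.feature
        clf_name, clf_p = self.spec.classification
        cal_name, _ = self.spec.calibration

        cal_idx = None
        fit_idx = np.arange(len(y))
        if cal_name != "none" and y.sum() >= 10:
            fit_idx, cal_idx = train_test_split(
                np.arange(len(y)), test_size=0.2, stratify=y, random_state=self.seed)

        self.imputer_ = _make_imputer(imp_name, imp_p, self.seed)
        self.feature_ = _make_feature(fea_name, fea_p, self.seed)
        self.classifier_ = _make_classifier(clf_name, clf_p, self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xi = self.imputer_.fit(Xv[fit_idx], y[fit_idx]).transform(Xv[fit_idx])
            if np.isnan(Xi).any():
                raise ValueError(f"imputation entry {imp_name!r} left missing cells")
            Xf = self.feature_.fit(Xi, y[fit_idx]).transform(Xi)
            if Xf.shape[1] == 0:
                raise ValueError(f"feature entry {fea_name!r} removed every column")
            self.classifier_.fit(Xf, y[fit_idx])

            self.calibrator_ = None
            if cal_name != "none" and cal_idx is not None:
                scores = self._raw_scores(Xv[cal_idx])
                if len(np.unique(y[cal_idx])) < 2:
                    raise ValueError("single-class calibration split")
                cal = _SigmoidCalibrator() if cal_name == "sigmoid" else _IsotonicCalibrator()
                self.calibrator_ = cal.fit(scores, y[cal_idx])
        return self

    def _raw_scores(self, Xv) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xi = self.imputer_.transform(Xv)
            Xf = self.feature_.transform(Xi)
            return self.classifier_.predict_proba_1(Xf)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self._raw_scores(X[self.columns_].values.astype(float))
        if self.calibrator_ is not None:
            scores = self.calibrator_.transform(scores)
        return np.clip(np.asarray(scores, dtype=float), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def evaluate_pipeline_cv(spec: PipelineSpec, table: pd.DataFrame, outcome,
                         k_folds: int = 3, seed: int = 0,
                         iteration: int = -1, proposal: str = "random") -> SearchRecord:
    """Stratified k-fold CV score (mean held-out AUC) of one pipeline.

    The pipeline — including imputation and feature-processing statistics —
    is refitted inside each training fold; no information from the held-out
    fold leaks into preprocessing. Deterministic given (spec, seed).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(outcome).astype(int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_scores = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        if len(np.unique(y[te])) < 2:
            raise ValueError("fold with a single outcome class")
        pipe = FittedPipeline(spec, seed=seed).fit(table.iloc[tr], y[tr])
        fold_scores.append(auc_roc(pipe.predict(table.iloc[te]), y[te]))
    return SearchRecord(iteration=iteration, spec=spec,
                        cv_score=float(np.mean(fold_scores)),
                        fold_scores=fold_scores, proposal=proposal)


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-9)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def bo_search(space: DesignSpace, table: pd.DataFrame, outcome, budget: int,
              k_folds: int = 3, seed: int = 0, n_init: int = 10,
              mode: str = "bo", n_candidates: int = 500) -> list:
    """Sequential model-based pipeline search.

    ``mode='bo'``: random initial design of ``n_init`` pipelines, then a
    random-forest surrogate over pipeline descriptors proposes each next
    pipeline by expected improvement over ``n_candidates`` random draws.
    ``mode='exhaustive'``: evaluate the default-hyper-parameter enumeration
    of the space in catalog order (budget must not exceed the cardinality).
    Failed pipeline evaluations are recorded with score 0 rather than
    aborting the search. Deterministic given the seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    y = np.asarray(outcome).astype(int)
    rng = np.random.default_rng(seed)
    history: list[SearchRecord] = []

    def _evaluate(spec, i, proposal):
        try:
            rec = evaluate_pipeline_cv(spec, table, y, k_folds=k_folds, seed=seed,
                                       iteration=i, proposal=proposal)
        except Exception as exc:
            rec = SearchRecord(iteration=i, spec=spec, cv_score=0.0,
                               fold_scores=[], proposal=proposal, error=str(exc))
        history.append(rec)
        return rec

    if mode == "exhaustive":
        specs = space.enumerate_default_specs()
        if budget > len(specs):
            raise ValueError(f"budget {budget} exceeds enumerable space of {len(specs)}")
        for i, spec in enumerate(specs[:budget]):
            _evaluate(spec, i, "exhaustive")
        return history
    if mode != "bo":
        raise ValueError("mode must be 'bo' or 'exhaustive'")

    for i in range(min(n_init, budget)):
        _evaluate(space.sample_spec(rng), i, "random")

    while len(history) < budget:
        i = len(history)
        ok = [r for r in history if r.error is None]
        try:
            if len(ok) < 2:
                raise RuntimeError("too few successful evaluations for a surrogate")
            X = np.vstack([space.descriptor(r.spec) for r in ok])
            s = np.array([r.cv_score for r in ok])
            forest = RandomForestRegressor(n_estimators=50, random_state=seed, n_jobs=1)
            forest.fit(X, s)
            candidates = [space.sample_spec(rng) for _ in range(n_candidates)]
            D = np.vstack([space.descriptor(c) for c in candidates])
            per_tree = np.stack([t.predict(D) for t in forest.estimators_])
            ei = _expected_improvement(per_tree.mean(axis=0), per_tree.std(axis=0), s.max())
            spec = candidates[int(np.argmax(ei))]
            _evaluate(spec, i, "surrogate")
        except Exception as exc:
            warnings.warn(f"surrogate proposal failed ({exc}); falling back to random draw")
            _evaluate(space.sample_spec(rng), i, "random")
    return history


# ---------------------------------------------------------------------------
# Ensembles & calibration
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Weighted ensemble of fitted pipelines with a calibrated risk contract."""

    members: list  # (PipelineSpec, FittedPipeline, weight)
    calibrator_tag: str = "per-pipeline"
    catalog_version: str = CATALOG_VERSION
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array([m[2] for m in self.members], dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("ensemble weights must be non-negative and sum to 1")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        preds = np.vstack([pipe.predict(X) for _, pipe, _ in self.members])
        w = np.array([m[2] for m in self.members])
        return np.clip(w @ preds, 0.0, 1.0)

    # -- serialization: specs + weights + seed; reload refits on data -------
    def to_config(self) -> dict:
        return {
            "catalog_version": self.catalog_version,
            "seed": self.seed,
            "calibrator_tag": self.calibrator_tag,
            "members": [{"spec": spec.to_dict(), "weight": float(w)}
                        for spec, _, w in self.members],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_config(), fh, indent=2)

    @classmethod
    def load(cls, path, table: pd.DataFrame, outcome) -> "EnsembleModel":
        """Rebuild the ensemble bundle by refitting its member specs on the
        given training data with the stored seed (bit-for-bit on a platform)."""
        with open(path) as fh:
            cfg = json.load(fh)
        y = np.asarray(outcome).astype(int)
        members = []
        for m in cfg["members"]:
            spec = PipelineSpec.from_dict(m["spec"])
            pipe = FittedPipeline(spec, seed=cfg["seed"]).fit(table, y)
            members.append((spec, pipe, m["weight"]))
        return cls(members=members, calibrator_tag=cfg["calibrator_tag"],
                   catalog_version=cfg["catalog_version"], seed=cfg["seed"])


def build_ensemble(history: list, table: pd.DataFrame, outcome, top_k: int = 5,
                   temperature: float = 0.1, seed: int = 0) -> EnsembleModel:
    """Refit the ``top_k`` pipelines by CV score on the full training data and
    weight them by softmax(CV score / temperature)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ok = sorted((r for r in history if r.error is None),
                key=lambda r: (-r.cv_score, r.iteration))
    if not ok:
        raise ValueError("no successful pipelines in history")
    chosen = ok[:top_k]
    y = np.asarray(outcome).astype(int)
    scores = np.array([r.cv_score for r in chosen])
    w = np.exp((scores - scores.max()) / temperature)
    w = w / w.sum()
    members = []
    for rec, weight in zip(chosen, w):
        pipe = FittedPipeline(rec.spec, seed=seed).fit(table, y)
        members.append((rec.spec, pipe, float(weight)))
    return EnsembleModel(members=members, seed=seed)


class CalibratedModel:
    """A model whose outputs pass through a post-hoc calibration map."""

    def __init__(self, base, calibrator, tag):
        self.base = base
        self.calibrator = calibrator
        self.tag = tag

    def predict(self, X) -> np.ndarray:
        p = self.base.predict(X)
        if self.calibrator is None:
            return p
        return np.clip(self.calibrator.transform(p), 0.0, 1.0)


def calibrate_model(model, table: pd.DataFrame, outcome, method: str = "sigmoid"):
    """Fit a post-hoc calibration map on held-out data.

    ``sigmoid`` fits a two-parameter logistic map (strictly monotone, so the
    AUC is unchanged); ``isotonic`` fits a monotone step map; ``none``
    returns the model unchanged. The table passed here should be held out
    from the model's training data.
    """
    if method == "none":
        return CalibratedModel(model, None, "none")
    y = np.asarray(outcome).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class calibration data")
    scores = model.predict(table)
    cal = _SigmoidCalibrator() if method == "sigmoid" else _IsotonicCalibrator()
    if method not in ("sigmoid", "isotonic"):
        raise ValueError("method must be one of {'sigmoid', 'isotonic', 'none'}")
    cal.fit(scores, y)
    return CalibratedModel(model, cal, method)
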