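"""Pipeline search engine: design-space structure, CV evaluation without
leakage, exhaustive-equivalence of the search, ensembling and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from prognopipe import automl
from prognopipe.evaluation import auc_roc, brier_score


def _tiny_space():
    return automl.reduced_design_space(
        imputation=("mean",), feature=("select_rates",),
        classification=("gradient_boosting", "logistic_regression"),
        calibration=("sigmoid", "none"))


def _signal_data(seed=0, n=800, p=8, missing=0.1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"v{i}" for i in range(p)])
    y = (rng.random(n) < expit(1.5 * X["v0"] - 1.0 * X["v1"])).astype(int)
    if missing:
        X.iloc[rng.random((n, p)) < missing] = np.nan
    return X, y


class TestDesignSpace:
    def test_default_catalog_stage_counts(self):
        space = automl.default_design_space()
        assert len(space.imputation) == 8
        assert len(space.feature) == 9
        assert len(space.classification) == 20
        assert len(space.calibration) == 3

    def test_reduced_catalog_cardinality_is_product(self):
        space = automl.reduced_design_space(
            imputation=("mean", "median"), feature=("pca",),
            classification=("logistic_regression", "decision_tree"),
            calibration=("none",))
        assert space.cardinality == 4
        assert len(space.enumerate_default_specs()) == 4

    def test_sampled_specs_have_one_entry_per_stage_in_domain(self):
        space = automl.default_design_space()
        rng = np.random.default_rng(0)
        for _ in range(50):
            spec = space.sample_spec(rng)
            for stage in automl.STAGES:
                entry, params = getattr(spec, stage)
                assert entry in space.stage_entries(stage)
                for pname, value in params.items():
                    dom = automl.DOMAINS[stage][entry][pname]
                    assert dom[1] <= value <= dom[2]

    def test_unknown_entry_rejected(self):
        with pytest.raises(ValueError):
            automl.enumerate_design_space({"imputation": ["quantum"]})
        with pytest.raises(ValueError):
            automl.PipelineSpec(("mean", {"bogus": 1}), ("pca", {}),
                                ("lda", {}), ("none", {}))

    def test_descriptor_fixed_length(self):
        space = automl.default_design_space()
        rng = np.random.default_rng(1)
        lengths = {len(space.descriptor(space.sample_spec(rng))) for _ in range(20)}
        assert len(lengths) == 1


class TestEvaluatePipelineCV:
    def test_deterministic_record(self):
        X, y = _signal_data()
        spec = _tiny_space().enumerate_default_specs()[0]
        r1 = automl.evaluate_pipeline_cv(spec, X, y, k_folds=3, seed=4)
        r2 = automl.evaluate_pipeline_cv(spec, X, y, k_folds=3, seed=4)
        assert r1.cv_score == r2.cv_score
        assert r1.fold_scores == r2.fold_scores

    def test_separable_data_scores_high(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((400, 4)), columns=list("abcd"))
        y = (X["a"].values > 0).astype(int)
        spec = automl.PipelineSpec(("mean", {}), ("select_rates", {}),
                                   ("logistic_regression", {}), ("none", {}))
        rec = automl.evaluate_pipeline_cv(spec, X, y, k_folds=3, seed=0)
        assert rec.cv_score >= 0.99

    def test_single_fold_errors(self):
        X, y = _signal_data(n=100)
        spec = _tiny_space().enumerate_default_specs()[0]
        with pytest.raises(ValueError):
            automl.evaluate_pipeline_cv(spec, X, y, k_folds=1)


class TestBOSearch:
    def test_exhaustive_equals_brute_force(self):
        X, y = _signal_data(seed=2)
        space = _tiny_space()
        budget = space.cardinality
        history = automl.bo_search(space, X, y, budget=budget, k_folds=3,
                                   seed=0, mode="exhaustive")
        # independent brute force over the same enumeration
        brute = [automl.evaluate_pipeline_cv(s, X, y, k_folds=3, seed=0)
                 for s in space.enumerate_default_specs()]
        best_search = max(history, key=lambda r: r.cv_score)
        best_brute = max(brute, key=lambda r: r.cv_score)
        assert repr(best_search.spec) == repr(best_brute.spec)
        assert best_search.cv_score == pytest.approx(best_brute.cv_score)

    def test_exhaustive_budget_cannot_exceed_space(self):
        X, y = _signal_data(n=100)
        with pytest.raises(ValueError):
            automl.bo_search(_tiny_space(), X, y, budget=100, mode="exhaustive")

    def test_fixed_seed_reproduces_history(self):
        X, y = _signal_data(seed=3, n=500)
        space = _tiny_space()
        h1 = automl.bo_search(space, X, y, budget=7, k_folds=3, seed=5, n_init=4)
        h2 = automl.bo_search(space, X, y, budget=7, k_folds=3, seed=5, n_init=4)
        assert [repr(r.spec) for r in h1] == [repr(r.spec) for r in h2]
        assert [r.cv_score for r in h1] == [r.cv_score for r in h2]
        assert [r.iteration for r in h1] == list(range(7))

    def test_budget_one_is_single_random_record(self):
        X, y = _signal_data(n=300)
        history = automl.bo_search(_tiny_space(), X, y, budget=1, seed=0)
        assert len(history) == 1 and history[0].proposal == "random"

    def test_search_maximum_is_monotone_in_budget(self):
        # the best score after the surrogate phase can never fall below the
        # best of the random initialisation it contains
        X, y = _signal_data(seed=4, n=500)
        history = automl.bo_search(_tiny_space(), X, y, budget=14, k_folds=3,
                                   seed=0, n_init=6)
        best_init = max(r.cv_score for r in history[:6])
        best_all = max(r.cv_score for r in history)
        assert best_all >= best_init


class TestEnsemble:
    def _history(self, X, y, scores):
        specs = _tiny_space().enumerate_default_specs()
        return [automl.SearchRecord(iteration=i, spec=specs[i % len(specs)], cv_score=s)
                for i, s in enumerate(scores)]

    def test_single_member_gets_weight_one(self):
        X, y = _signal_data(n=300)
        ens = automl.build_ensemble(self._history(X, y, [0.7]), X, y, top_k=3)
        assert len(ens.members) == 1
        assert ens.members[0][2] == pytest.approx(1.0)

    def test_softmax_weights_closed_form(self):
        X, y = _signal_data(n=300)
        ens = automl.build_ensemble(self._history(X, y, [0.8, 0.6]), X, y,
                                    top_k=2, temperature=0.1)
        w = sorted((m[2] for m in ens.members), reverse=True)
        expected_hi = np.exp(8.0) / (np.exp(8.0) + np.exp(6.0))
        assert w[0] == pytest.approx(expected_hi, abs=1e-6)
        assert w[1] == pytest.approx(1.0 - expected_hi, abs=1e-6)

    def test_prediction_is_convex_combination(self):
        X, y = _signal_data(seed=5, n=400)
        ens = automl.build_ensemble(self._history(X, y, [0.7, 0.65, 0.6]), X, y, top_k=3)
        member_preds = np.vstack([pipe.predict(X) for _, pipe, _ in ens.members])
        pooled = ens.predict(X)
        assert np.all(pooled >= member_preds.min(axis=0) - 1e-12)
        assert np.all(pooled <= member_preds.max(axis=0) + 1e-12)

    def test_weights_invariant_to_history_order(self):
        X, y = _signal_data(n=300)
        hist = self._history(X, y, [0.6, 0.8, 0.7])
        w1 = sorted(m[2] for m in automl.build_ensemble(hist, X, y, top_k=3).members)
        w2 = sorted(m[2] for m in automl.build_ensemble(hist[::-1], X, y, top_k=3).members)
        assert w1 == pytest.approx(w2)

    def test_simplex_weights_enforced(self):
        X, y = _signal_data(n=300)
        ens = automl.build_ensemble(self._history(X, y, [0.8, 0.7, 0.6]), X, y, top_k=3)
        w = np.array([m[2] for m in ens.members])
        assert np.all(w >= 0) and w.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            automl.build_ensemble(self._history(X, y, [0.7]), X, y, top_k=0)

    def test_bundle_reload_reproduces_predictions(self, tmp_path):
        X, y = _signal_data(seed=6, n=400)
        ens = automl.build_ensemble(self._history(X, y, [0.75, 0.7]), X, y, top_k=2, seed=3)
        path = tmp_path / "bundle.json"
        ens.save(path)
        back = automl.EnsembleModel.load(path, X, y)
        np.testing.assert_array_equal(back.predict(X), ens.predict(X))


class TestCalibration:
    def _overconfident(self, seed=0, n=4000):
        rng = np.random.default_rng(seed)
        true_p = rng.beta(2, 5, n)
        labels = (rng.random(n) < true_p).astype(int)
        scores = expit(3.0 * (np.log(true_p) - np.log1p(-true_p)))  # pushed to 0/1
        return scores, labels

    class _Fixed:
        def __init__(self, p):
            self.p = np.asarray(p)

        def predict(self, X):
            return self.p

    def test_none_is_identity(self):
        scores, labels = self._overconfident()
        model = self._Fixed(scores)
        cal = automl.calibrate_model(model, pd.DataFrame(index=range(len(labels))),
                                     labels, method="none")
        np.testing.assert_array_equal(cal.predict(None), scores)

    def test_sigmoid_preserves_auc(self):
        scores, labels = self._overconfident()
        model = self._Fixed(scores)
        cal = automl.calibrate_model(model, pd.DataFrame(index=range(len(labels))),
                                     labels, method="sigmoid")
        assert auc_roc(cal.predict(None), labels) == pytest.approx(auc_roc(scores, labels))

    def test_sigmoid_improves_brier_of_overconfident_scores(self):
        scores, labels = self._overconfident(seed=1)
        half = len(labels) // 2
        model = self._Fixed(scores[:half])
        cal = automl.calibrate_model(model, pd.DataFrame(index=range(half)),
                                     labels[:half], method="sigmoid")
        eval_model = self._Fixed(scores[half:])
        calibrated = automl.CalibratedModel(eval_model, cal.calibrator, "sigmoid")
        assert (brier_score(calibrated.predict(None), labels[half:])
                <= brier_score(scores[half:], labels[half:]))

    def test_single_class_calibration_errors(self):
        model = self._Fixed([0.2, 0.4])
        with pytest.raises(ValueError):
            automl.calibrate_model(model, pd.DataFrame(index=range(2)), [1, 1],
                                   method="sigmoid")


class TestNoLeakage:
    def test_imputation_statistics_come_from_training_rows_only(self):
        # canary: the held-out block has wildly shifted values; a leaky
        # imputer would move its fill statistic toward them
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"a": rng.standard_normal(200),
                              "b": rng.standard_normal(200)})
        train.loc[:20, "a"] = np.nan
        y = rng.integers(0, 2, 200)
        spec = automl.PipelineSpec(("mean", {}), ("select_rates", {}),
                                   ("logistic_regression", {}), ("none", {}))
        pipe = automl.FittedPipeline(spec, seed=0).fit(train, y)
        fill = pipe.imputer_.statistics_[0]
        assert fill == pytest.approx(train["a"].mean(), abs=1e-12)

    def test_fitted_state_unchanged_by_heldout_perturbation(self):
        X, y = _signal_data(seed=7, n=400)
        spec = automl.PipelineSpec(("mean", {}), ("select_rates", {}),
                                   ("gradient_boosting", {}), ("none", {}))
        pipe = automl.FittedPipeline(spec, seed=0).fit(X.iloc[:300], y[:300])
        probe = X.iloc[:50]
        before = pipe.predict(probe)
        held_out = X.iloc[300:] * 1000.0  # perturb and score held-out data
        pipe.predict(held_out)
        np.testing.assert_array_equal(pipe.predict(probe), before)
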