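"""Metric oracles: AUC against brute-force pairwise concordance, the Wilson
closed form and its coverage, Brier/NRI hand-computed toys, stratified folds,
and threshold classification arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from prognopipe.evaluation import (
    auc_roc,
    brier_score,
    confusion_at_threshold,
    net_reclassification_index,
    stratified_folds,
    subgroup_evaluate,
    wilson_interval,
)


def brute_force_auc(scores, labels):
    """Independent oracle: mean concordance over all case-control pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_roc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_are_chance(self):
        assert auc_roc([0.5] * 6, [0, 1, 0, 1, 1, 0]) == 0.5

    def test_hand_computed_tie_case(self):
        # 6 case-control pairs; one tie counts one half -> 3.5/6
        assert auc_roc([0.2, 0.3, 0.3, 0.1, 0.9], [0, 1, 0, 1, 1]) == pytest.approx(3.5 / 6)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.2], [1, 1])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_on_small_inputs(self, data):
        n = data.draw(st.integers(2, 12))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)
                           .filter(lambda l: 0 < sum(l) < len(l)))
        # a coarse score grid guarantees plenty of ties
        scores = data.draw(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                                    min_size=n, max_size=n))
        assert auc_roc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


class TestWilson:
    def test_matches_reference_implementation(self):
        for est, n in [(0.5, 10), (0.3, 100), (0.774, 4801), (0.01, 50)]:
            lo, hi = wilson_interval(est, n, 0.95)
            ref_lo, ref_hi = proportion_confint(est * n, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(ref_lo, abs=1e-10)
            assert hi == pytest.approx(ref_hi, abs=1e-10)

    def test_closed_form_example(self):
        lo, hi = wilson_interval(0.5, 10, 0.95)
        assert lo == pytest.approx(0.2366, abs=5e-4)
        assert hi == pytest.approx(0.7634, abs=5e-4)

    def test_zero_estimate_boundary(self):
        lo, hi = wilson_interval(0.0, 100)
        assert lo == 0.0 and 0.0 < hi < 0.1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(est=st.floats(0.0, 1.0), n=st.integers(1, 10_000))
    def test_contained_in_unit_interval_and_contains_estimate(self, est, n):
        lo, hi = wilson_interval(est, n)
        assert 0.0 <= lo <= est <= hi <= 1.0

    def test_coverage_near_nominal(self):
        # 10,000 binomial draws at n=100, p=0.3; 95% interval should cover
        # the truth between 93% and 97% of the time
        rng = np.random.default_rng(12345)
        n, p, sims = 100, 0.3, 10_000
        counts = rng.binomial(n, p, sims)
        covered = 0
        for c in counts:
            lo, hi = wilson_interval(c / n, n, 0.95)
            covered += lo <= p <= hi
        assert 0.93 <= covered / sims <= 0.97

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            wilson_interval(0.5, 10, level=1.2)


class TestBrier:
    def test_perfect_and_constant(self):
        assert brier_score([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0
        assert brier_score([0.5] * 4, [0, 1, 0, 1]) == 0.25

    def test_hand_computed(self):
        assert brier_score([0.8, 0.2, 0.6], [1, 0, 0]) == pytest.approx(0.44 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            brier_score([0.5], [0, 1])


class TestConfusionAtThreshold:
    def test_counts_sum_and_recompute(self):
        rng = np.random.default_rng(0)
        probs = rng.random(500)
        labels = rng.integers(0, 2, 500)
        cs = confusion_at_threshold(probs, labels, 0.4)
        assert cs.n == 500
        assert cs.tp + cs.fn == labels.sum()
        assert cs.sensitivity == pytest.approx(cs.tp / (cs.tp + cs.fn))
        assert cs.ppv == pytest.approx(cs.tp / (cs.tp + cs.fp))

    def test_zero_threshold_catches_everyone(self):
        cs = confusion_at_threshold([0.0, 0.2, 0.9], [1, 1, 1], 0.0)
        assert cs.sensitivity == 1.0

    def test_boundary_value_is_called_positive(self):
        cs = confusion_at_threshold([0.075], [1], 0.075)
        assert cs.tp == 1


class TestNRI:
    def test_model_vs_itself_is_zero(self):
        p = [0.1, 0.8, 0.3, 0.05]
        assert net_reclassification_index(p, p, [1, 1, 0, 0], 0.5) == 0.0

    def test_enumerated_toy(self):
        # 4 events: new model up-classifies 2, down-classifies 1;
        # 5 non-events: down-classifies 1, up-classifies 0
        # NRI = (2-1)/4 + (1-0)/5 = 0.25 + 0.20 = 0.45
        old = [0.1, 0.1, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.9]
        new = [0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0]
        assert net_reclassification_index(new, old, labels, 0.5) == pytest.approx(0.45)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(200), rng.random(200)
        labels = rng.integers(0, 2, 200)
        ab = net_reclassification_index(a, b, labels, 0.3)
        ba = net_reclassification_index(b, a, labels, 0.3)
        assert ab == pytest.approx(-ba)
        assert -2.0 <= ab <= 2.0

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            net_reclassification_index([0.1], [0.2], [1], 0.5)


class TestStratifiedFolds:
    def test_partition_and_balanced_cases(self):
        y = np.r_[np.ones(100, dtype=int), np.zeros(900, dtype=int)]
        folds = stratified_folds(y, 10, seed=0)
        assert sorted(np.unique(folds)) == list(range(10))
        assert len(folds) == 1000
        for f in range(10):
            assert y[folds == f].sum() == 10  # 100 cases split evenly

    def test_deterministic(self):
        y = np.r_[np.ones(30, dtype=int), np.zeros(70, dtype=int)]
        np.testing.assert_array_equal(stratified_folds(y, 5, 3), stratified_folds(y, 5, 3))

    def test_too_few_cases_errors(self):
        with pytest.raises(ValueError):
            stratified_folds([1, 0, 0, 0, 0], 2 + 1)
        with pytest.raises(ValueError):
            stratified_folds([1, 0] * 10, 1)


class TestSubgroupEvaluate:
    def test_whole_population_subgroup_equals_overall(self):
        rng = np.random.default_rng(2)
        probs = rng.random(400)
        labels = (rng.random(400) < probs).astype(int)
        out = subgroup_evaluate(probs, labels, np.ones(400, dtype=bool))
        assert out["subgroup"].auc == pytest.approx(auc_roc(probs, labels))
        assert out["complement"] == {"flag": "empty stratum"}

    def test_empty_subgroup_errors(self):
        with pytest.raises(ValueError):
            subgroup_evaluate([0.1, 0.9], [0, 1], [False, False])

    def test_single_class_stratum_flagged(self):
        probs = [0.1, 0.9, 0.4, 0.6]
        labels = [0, 1, 1, 1]
        out = subgroup_evaluate(probs, labels, np.array([False, False, True, True]))
        assert out["subgroup"] == {"flag": "single-class stratum"}
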