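"""Technique fits, evaluation statistics and the AUC-weighted consensus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bryoclim import models
from bryoclim.models import (
    EnsembleModel,
    EvaluationResult,
    NoPassingModelError,
    auc,
    build_consensus,
    evaluate,
    fit_envelope,
    fit_maxent_like,
    fit_random_forest,
    prevalence_weights,
    tss,
)


# ---------------------------------------------------------------------------
# independent oracles


def auc_all_pairs(sp, sa):
    wins = ties = 0
    for p in sp:
        for a in sa:
            if p > a:
                wins += 1
            elif p == a:
                ties += 1
    return (wins + 0.5 * ties) / (len(sp) * len(sa))


def tss_threshold_scan(sp, sa):
    best = -1.0
    for t in sorted(set(list(sp) + list(sa))):
        tp = sum(1 for s in sp if s >= t)
        tn = sum(1 for s in sa if s < t)
        best = max(best, tp / len(sp) + tn / len(sa) - 1.0)
    return best


class TestAucTss:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert tss([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert auc([0.8, 0.3], [0.5, 0.1]) == pytest.approx(0.75)

    def test_identical_score_multisets_carry_no_information(self):
        s = [0.2, 0.5, 0.5, 0.9]
        assert auc(s, s) == pytest.approx(0.5)
        assert tss(s, s) == pytest.approx(0.0)

    def test_matches_oracles_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_p = rng.integers(1, 15)
            n_a = rng.integers(1, 15)
            # discretized scores force ties to be handled
            sp = np.round(rng.random(n_p), 1)
            sa = np.round(rng.random(n_a), 1)
            assert auc(sp, sa) == pytest.approx(auc_all_pairs(sp, sa), abs=1e-12)
            assert tss(sp, sa) == pytest.approx(tss_threshold_scan(sp, sa), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestPrevalenceWeights:
    @pytest.mark.parametrize("np_,na,expected", [((100), 100, (1, 1)), (50, 1000, (1, 0.05))])
    def test_examples(self, np_, na, expected):
        assert prevalence_weights(np_, na) == pytest.approx(expected)

    @given(st.integers(1, 10000), st.integers(1, 10000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_total_class_weights_equal_exactly(self, n_p, n_a):
        w_p, w_a = prevalence_weights(n_p, n_a)
        assert w_p * n_p == pytest.approx(w_a * n_a, rel=1e-15)
        assert w_p == 1.0

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            prevalence_weights(0, 5)


class TestEnvelope:
    def test_median_query_scores_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(21, 3))
        m = fit_envelope(x, ["a", "b", "c"])
        medians = np.median(x, axis=0)
        assert m.predict(medians[None, :])[0] == pytest.approx(1.0)

    def test_below_minimum_scores_zero(self):
        x = np.random.default_rng(2).normal(size=(10, 2))
        m = fit_envelope(x, ["a", "b"])
        q = np.array([[x[:, 0].min() - 1.0, np.median(x[:, 1])]])
        assert m.predict(q)[0] == 0.0

    def test_matches_brute_force_cdf_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 2))
        m = fit_envelope(x, ["a", "b"])
        for _ in range(50):
            q = rng.normal(size=2)
            scores = []
            for j in range(2):
                vals = x[:, j]
                if q[j] < vals.min() or q[j] > vals.max():
                    scores.append(0.0)
                else:
                    f = (np.sum(vals < q[j]) + 0.5 * np.sum(vals == q[j])) / len(vals)
                    scores.append(1.0 - 2.0 * abs(f - 0.5))
            assert m.predict(q[None, :])[0] == pytest.approx(min(scores), abs=1e-12)

    def test_constant_variable_degenerates_to_spike(self):
        x = np.column_stack([np.full(10, 5.0), np.arange(10.0)])
        m = fit_envelope(x, ["const", "b"])
        at = m.predict(np.array([[5.0, 4.5]]))[0]
        off = m.predict(np.array([[5.1, 4.5]]))[0]
        assert at > 0
        assert off == 0.0

    def test_too_few_presences_rejected(self):
        with pytest.raises(models.ModelError):
            fit_envelope(np.zeros((2, 2)), ["a", "b"])


class TestMaxentLike:
    def test_uninformative_predictor_gives_constant_suitability(self):
        rng = np.random.default_rng(4)
        same = rng.normal(size=(150, 1))
        m = fit_maxent_like(same, same.copy(), ["x"], regularization=1.0)
        preds = m.predict(rng.normal(size=(100, 1)))
        assert preds.std() < 0.02
        assert abs(m.linear_coef_["x"]) < 0.05

    def test_recovers_logistic_slope_within_25_percent(self):
        """Parameter-recovery oracle: data from a 1-D logistic model."""
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.uniform(-3, 3, size=(n, 1))
        beta = 1.5
        p = 1 / (1 + np.exp(-(0.0 + beta * x[:, 0])))
        y = rng.random(n) < p
        m = fit_maxent_like(x[y], x[~y], ["x"], regularization=0.01, features="l")
        got = m.linear_coef_["x"]
        assert abs(got - beta) / beta < 0.25

    def test_stronger_regularization_never_adds_coefficients(self):
        rng = np.random.default_rng(6)
        xp = rng.normal(size=(80, 4)) + np.array([1.0, 0.5, 0.0, 0.0])
        xb = rng.normal(size=(400, 4))
        counts = []
        for reg in [0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]:
            m = fit_maxent_like(xp, xb, list("abcd"), regularization=reg)
            counts.append(int(np.sum(np.abs(m.coef) > 1e-6)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_predictions_bounded_in_unit_interval(self):
        rng = np.random.default_rng(7)
        m = fit_maxent_like(rng.normal(size=(30, 2)), rng.normal(size=(100, 2)), ["a", "b"])
        p = m.predict(rng.normal(size=(200, 2)) * 10)
        assert (p >= 0).all() and (p <= 1).all()

    def test_background_smaller_than_presences_rejected(self):
        with pytest.raises(models.ModelError):
            fit_maxent_like(np.zeros((10, 1)), np.zeros((5, 1)), ["x"])


class TestRandomForest:
    def test_separable_data_reaches_near_perfect_auc(self):
        rng = np.random.default_rng(8)
        xp = rng.uniform(1, 2, size=(100, 1))
        xb = rng.uniform(-2, -1, size=(100, 1))
        m = fit_random_forest(xp[:70], xb[:70], ["x"], seed=0)
        assert auc(m.predict(xp[70:]), m.predict(xb[70:])) >= 0.99

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(9)
        pool = rng.normal(size=(400, 2))  # labels carry no signal
        m = fit_random_forest(pool[:150], pool[150:300], ["a", "b"], seed=1)
        held = rng.normal(size=(400, 2))
        a = auc(m.predict(held[:200]), m.predict(held[200:]))
        assert 0.4 <= a <= 0.6

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(10)
        xp, xb = rng.normal(size=(50, 2)), rng.normal(size=(200, 2))
        q = rng.normal(size=(50, 2))
        a = fit_random_forest(xp, xb, ["a", "b"], seed=3).predict(q)
        b = fit_random_forest(xp, xb, ["a", "b"], seed=3).predict(q)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(models.ModelError):
            fit_random_forest(np.zeros((0, 2)), np.zeros((10, 2)), ["a", "b"])


class _PerfectScorer:
    variables = ["x"]

    def predict(self, env):
        return (np.atleast_2d(env)[:, 0] > 0).astype(float)


class TestEvaluate:
    def test_mean_auc_below_cutoff_fails(self):
        ev = EvaluationResult("m", aucs=[0.79] * 10, tsses=[0.9] * 10)
        assert not ev.passed

    def test_both_criteria_required(self):
        ev = EvaluationResult("m", aucs=[0.95] * 10, tsses=[0.65] * 10)
        assert not ev.passed
        assert EvaluationResult("m", aucs=[0.85] * 10, tsses=[0.75] * 10).passed

    def test_perfectly_separable_scorer_passes_every_split(self):
        rng = np.random.default_rng(11)
        xp = rng.uniform(0.5, 2, size=(40, 1))
        xb = rng.uniform(-2, -0.5, size=(200, 1))
        ev = evaluate(lambda p, b: _PerfectScorer(), xp, xb, seed=2)
        assert ev.aucs == [1.0] * 10
        assert ev.passed

    def test_infeasible_split_raises(self):
        with pytest.raises(models.ModelError):
            evaluate(lambda p, b: _PerfectScorer(), np.zeros((3, 1)), np.zeros((200, 1)))

    def test_splits_reproducible_under_seed(self):
        rng = np.random.default_rng(12)
        xp = rng.normal(1.0, 1.0, size=(40, 1))
        xb = rng.normal(-1.0, 1.0, size=(200, 1))
        fitter = lambda p, b: fit_envelope(p, ["x"])  # noqa: E731
        a = evaluate(fitter, xp, xb, seed=7)
        b = evaluate(fitter, xp, xb, seed=7)
        assert a.aucs == b.aucs and a.tsses == b.tsses


class _Const:
    def __init__(self, value, variables=("x",)):
        self.value = value
        self.variables = list(variables)
        self.technique = "const"

    def predict(self, env):
        return np.full(np.atleast_2d(env).shape[0], self.value)


class TestConsensus:
    def test_single_passing_model_is_identity(self):
        ev_pass = EvaluationResult("a", [0.9] * 10, [0.8] * 10)
        ev_fail = EvaluationResult("b", [0.6] * 10, [0.3] * 10)
        ens = build_consensus([(_Const(0.42), ev_pass), (_Const(0.9), ev_fail)])
        assert len(ens.members) == 1
        assert ens.weights[0] == 1.0
        assert ens.predict(np.zeros((3, 1)))[0] == pytest.approx(0.42)

    def test_weights_proportional_to_mean_auc(self):
        e1 = EvaluationResult("a", [0.9] * 10, [0.8] * 10)
        e2 = EvaluationResult("b", [0.85] * 10, [0.8] * 10)
        ens = build_consensus([(_Const(1.0), e1), (_Const(0.0), e2)])
        np.testing.assert_allclose(ens.weights, [0.9 / 1.75, 0.85 / 1.75])
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_prediction_is_convex_combination_of_members(self):
        rng = np.random.default_rng(13)
        members = [_Const(v) for v in rng.random(3)]
        evs = [EvaluationResult(str(i), [a] * 10, [0.8] * 10) for i, a in enumerate([0.95, 0.9, 0.82])]
        ens = build_consensus(list(zip(members, evs)))
        pred = ens.predict(np.zeros((5, 1)))
        vals = [m.value for m in members]
        assert (pred >= min(vals) - 1e-12).all() and (pred <= max(vals) + 1e-12).all()

    def test_no_passing_model_raises_with_detail(self):
        ev = EvaluationResult("a", [0.6] * 10, [0.3] * 10)
        with pytest.raises(NoPassingModelError, match="AUC=0.600"):
            build_consensus([(_Const(0.5), ev)])
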