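"""AUC machinery: rank statistic, surrogate, saddle objective, min-max step."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from grape import auc_loss
from grape._autograd import Tensor
from grape.auc_loss import (AUCState, LossConfig, NonFiniteGradient,
                            empirical_auc, minmax_saddle_value, mixed_loss,
                            optimal_aux, pairwise_auc_enumeration,
                            pairwise_surrogate_loss, saddle_loss_mean,
                            saddle_objective_F, saddle_update_step)


def random_scores(rng, n, with_ties=False):
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
    if labels.sum() == 0 or labels.sum() == n:
        labels[0], labels[-1] = 1, 0
    scores = rng.normal(size=n)
    if with_ties:
        scores = np.round(scores, 1)
    return scores, labels


class TestEmpiricalAUC:
    def test_perfect_separation(self):
        assert empirical_auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_tie_counts_one_half(self):
        assert empirical_auc([0.5, 0.5], [1, 0]) == 0.5

    def test_enumerated_example(self):
        # pairs: (.9,.6)+ (.9,.2)+ (.4,.6)- (.4,.2)+ -> 3/4
        assert empirical_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_rank_statistic_equals_pair_enumeration(self, rng):
        for _ in range(100):
            scores, labels = random_scores(
                rng, int(rng.integers(2, 201)), with_ties=True)
            assert empirical_auc(scores, labels) == pytest.approx(
                pairwise_auc_enumeration(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        for _ in range(20):
            scores, labels = random_scores(rng, 50, with_ties=True)
            assert empirical_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_auc([0.1, 0.2], [1, 1])


class TestPairwiseSurrogate:
    def test_hand_substitution(self):
        # one pos f=0.8, one neg f=0.3 -> (1 - 0.5)^2
        assert pairwise_surrogate_loss([0.8, 0.3], [1, 0]) == pytest.approx(0.25)

    def test_exact_margin_gives_zero(self):
        assert pairwise_surrogate_loss([1.2, 1.2, 0.2, 0.2],
                                       [1, 1, 0, 0]) == pytest.approx(0.0)

    def test_all_equal_scores_give_one(self):
        assert pairwise_surrogate_loss([0.3] * 5, [1, 1, 0, 0, 0]) == 1.0


class TestSaddleObjective:
    def test_degenerate_prior_vanishes(self):
        state = AUCState(a=0.0, b=0.0, alpha=0.0, p=0.0)
        assert saddle_objective_F(0.0, 1, state) == 0.0

    def test_positive_sample_hand_value(self):
        state = AUCState(a=0.2, b=0.0, alpha=0.0, p=0.5)
        assert saddle_objective_F(0.3, 1, state) == pytest.approx(-0.295)

    def test_negative_sample_hand_value(self):
        state = AUCState(a=0.0, b=0.1, alpha=0.0, p=0.5)
        assert saddle_objective_F(-0.4, -1, state) == pytest.approx(-0.275)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            saddle_objective_F(0.0, 0, AUCState())

    def test_batch_mean_matches_per_sample(self, rng):
        scores, labels = random_scores(rng, 12)
        state = AUCState(a=0.3, b=-0.2, alpha=0.4, p=float(labels.mean()))
        per_sample = np.mean([
            saddle_objective_F(s, 1 if y else -1, state)
            for s, y in zip(scores, labels)])
        assert saddle_loss_mean(scores, labels, state) == pytest.approx(per_sample)


class TestSaddleOracleEquivalence:
    def test_stationary_point_is_class_means_and_gap(self, rng):
        scores, labels = random_scores(rng, 20)
        a, b, alpha = optimal_aux(scores, labels)
        assert a == pytest.approx(scores[labels == 1].mean())
        assert b == pytest.approx(scores[labels == 0].mean())
        assert alpha == pytest.approx(b - a)

    def test_minmax_equals_scaled_surrogate_minus_constant(self, rng):
        """min over (a,b), max over alpha of mean F reproduces the pairwise
        squared surrogate: min-max F = p(1-p)(L_pair - 1), the per-sample
        decomposition of the pair objective (the margin constant is the
        only additive offset)."""
        for _ in range(100):
            scores, labels = random_scores(rng, int(rng.integers(2, 31)))
            p = float(labels.mean())
            lhs = minmax_saddle_value(scores, labels, p)
            rhs = p * (1 - p) * (pairwise_surrogate_loss(scores, labels) - 1.0)
            assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_stationarity_numerically(self, rng):
        scores, labels = random_scores(rng, 15)
        p = float(labels.mean())
        a, b, alpha = optimal_aux(scores, labels)
        star = saddle_loss_mean(scores, labels, AUCState(a, b, alpha, p))
        for da, db in [(1e-3, 0), (0, 1e-3), (-1e-3, 0)]:
            assert saddle_loss_mean(
                scores, labels, AUCState(a + da, b + db, alpha, p)) >= star
        for dal in (1e-3, -1e-3):
            assert saddle_loss_mean(
                scores, labels, AUCState(a, b, alpha + dal, p)) <= star


class TestMixedLoss:
    @pytest.mark.parametrize("tau,expected", [
        (0.0, 0.4), (1.0, 0.2), (0.5, 0.3)])
    def test_endpoints_and_midpoint(self, tau, expected):
        assert mixed_loss(0.2, 0.4, tau) == pytest.approx(expected)

    def test_affine_in_tau(self):
        l1, l2, l3 = (mixed_loss(0.7, 0.1, t) for t in (0.2, 0.5, 0.8))
        assert l2 == pytest.approx((l1 + l3) / 2)

    def test_out_of_range_tau(self):
        with pytest.raises(ValueError):
            mixed_loss(0.1, 0.1, 1.5)


class TestSaddleUpdateStep:
    def static_forward(self, scores):
        return lambda params: Tensor(np.asarray(scores, dtype=float))

    def test_zero_learning_rates_leave_state_unchanged(self):
        state = AUCState(a=0.1, b=0.2, alpha=0.3, p=0.5)
        cfg = LossConfig(tau=0.5, model_lr=0.0, aux_lr=0.0)
        saddle_update_step(self.static_forward([0.5, -0.5]), [1, 0], {},
                           state, cfg)
        assert (state.a, state.b, state.alpha) == (0.1, 0.2, 0.3)

    def test_aux_iteration_converges_to_closed_form(self, rng):
        scores, labels = random_scores(rng, 10)
        p = float(labels.mean())
        state = AUCState(p=p)
        cfg = LossConfig(tau=1.0, aux_lr=0.05)
        fwd = self.static_forward(scores)
        for _ in range(3000):
            saddle_update_step(fwd, labels, {}, state, cfg)
        a, b, alpha = optimal_aux(scores, labels)
        assert state.a == pytest.approx(a, abs=1e-3)
        assert state.b == pytest.approx(b, abs=1e-3)
        assert state.alpha == pytest.approx(alpha, abs=1e-3)

    def test_model_params_descend(self):
        w = Tensor(np.zeros(2), requires_grad=True)
        x = np.array([[1.0, 0.0], [-1.0, 0.0]])

        def fwd(params):
            return Tensor(x) @ params["w"]

        state = AUCState(p=0.5)
        cfg = LossConfig(tau=0.0, model_lr=0.5, aux_lr=0.0)
        info = saddle_update_step(fwd, [1, 0], {"w": w}, state, cfg)
        assert info["l_bce"] == pytest.approx(np.log(2))
        assert w.data[0] > 0  # moved to score the positive higher

    def test_non_finite_gradient_rejected(self):
        state = AUCState(p=0.5)
        cfg = LossConfig(tau=0.5)
        with pytest.raises(NonFiniteGradient):
            saddle_update_step(self.static_forward([np.inf, 0.0]), [1, 0],
                               {}, state, cfg)


class TestRankStatisticProperties:
    """Distribution-free invariants of the empirical AUC."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    scores_labels = st.lists(
        st.tuples(st.floats(-100, 100, allow_nan=False),
                  st.integers(0, 1)),
        min_size=4, max_size=60,
    ).filter(lambda rows: 0 < sum(y for _, y in rows) < len(rows))

    @settings(derandomize=True, max_examples=60)
    @given(scores_labels)
    def test_bounded_and_antisymmetric(self, rows):
        scores = np.array([s for s, _ in rows])
        labels = np.array([y for _, y in rows])
        auc = empirical_auc(scores, labels)
        assert 0.0 <= auc <= 1.0
        # negating scores while flipping labels preserves the statistic
        assert empirical_auc(-scores, 1 - labels) == pytest.approx(auc)

    @settings(derandomize=True, max_examples=60)
    @given(scores_labels, st.floats(0.01, 100, allow_nan=False))
    def test_invariant_under_positive_rescaling(self, rows, gain):
        scores = np.array([s for s, _ in rows])
        labels = np.array([y for _, y in rows])
        assert empirical_auc(gain * scores, labels) == pytest.approx(
            empirical_auc(scores, labels))
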