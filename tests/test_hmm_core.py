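"""Bernoulli HMM estimation, likelihood and Viterbi decoding."""

import itertools
import math

import numpy as np
import pytest

from hybridhmm import (
    EmissionScores,
    EstimationError,
    FeatureMatrix,
    HMMParams,
    LabelSequence,
    bernoulli_log_emissions,
    decode,
    estimate_supervised,
    joint_loglik,
    sample_hmm,
    viterbi,
    viterbi_path,
)
from hybridhmm.hmm_core import EPS


def fm(values):
    values = np.asarray(values, dtype=np.uint8)
    return FeatureMatrix(values, [f"f{i}" for i in range(values.shape[1])])


def ls(labels, q):
    return LabelSequence(np.asarray(labels), [f"c{i}" for i in range(q)])


def brute_force_best(pi, trans, log_em):
    """Exhaustive maximization of the joint path score (test oracle)."""
    t_len, q = log_em.shape
    log_pi = np.log(np.clip(pi, EPS, None))
    log_a = np.log(np.clip(trans, EPS, None))
    best_score, best_path = -np.inf, None
    for path in itertools.product(range(q), repeat=t_len):
        score = log_pi[path[0]] + log_em[0, path[0]]
        for t in range(1, t_len):
            score += log_a[path[t - 1], path[t]] + log_em[t, path[t]]
        if score > best_score:
            best_score, best_path = score, path
    return best_score, np.array(best_path)


def path_score(pi, trans, log_em, path):
    log_pi = np.log(np.clip(pi, EPS, None))
    log_a = np.log(np.clip(trans, EPS, None))
    s = log_pi[path[0]] + log_em[0, path[0]]
    for t in range(1, len(path)):
        s += log_a[path[t - 1], path[t]] + log_em[t, path[t]]
    return s


def random_instance(rng, q, t_len):
    pi = rng.dirichlet(np.ones(q))
    trans = rng.dirichlet(np.ones(q), size=q)
    log_em = np.log(rng.random((t_len, q)) + 1e-3)
    return pi, trans, log_em


class TestEstimateSupervised:
    def test_degenerate_single_class(self):
        feat = fm([[1], [0], [1]])
        params = estimate_supervised(feat, ls([1, 1, 1], 1), alpha=0)
        assert params.pi.tolist() == [1.0]
        assert params.trans.tolist() == [[1.0]]
        assert params.mu[0, 0] == pytest.approx(2 / 3)

    def test_transition_counts_from_consecutive_pairs(self):
        # pairs 1->1, 1->2, 2->2
        feat = fm([[0]] * 4)
        params = estimate_supervised(feat, ls([1, 1, 2, 2], 2), alpha=0)
        assert params.trans.tolist() == [[0.5, 0.5], [0.0, 1.0]]
        assert params.pi.tolist() == [0.5, 0.5]

    def test_smoothing_keeps_parameters_interior(self):
        feat = fm([[1], [1], [0], [0]])
        params = estimate_supervised(feat, ls([1, 1, 2, 2], 3), alpha=1.0)
        for arr in (params.pi, params.trans, params.mu):
            assert (arr > 0).all() and (arr < 1).all()

    def test_unobserved_class_with_zero_alpha_raises(self):
        feat = fm([[0], [1]])
        with pytest.raises(EstimationError, match="c2"):
            estimate_supervised(feat, ls([1, 2], 3), alpha=0)

    def test_multi_day_transitions_do_not_cross_midnight(self):
        # within days: 1->2, 2->2, 1->1, 1->2; the boundary 2->1 not counted
        feats = [fm([[0]] * 3), fm([[0]] * 3)]
        labels = [ls([1, 2, 2], 2), ls([1, 1, 2], 2)]
        params = estimate_supervised(feats, labels, alpha=0)
        assert params.trans[1].tolist() == [0.0, 1.0]

    def test_json_round_trip(self):
        feat = fm([[1, 0], [0, 1], [1, 1], [0, 0]])
        params = estimate_supervised(feat, ls([1, 2, 2, 1], 2), alpha=1)
        back = HMMParams.from_json(params.to_json())
        np.testing.assert_allclose(back.trans, params.trans)
        np.testing.assert_allclose(back.mu, params.mu)
        assert back.class_names == params.class_names


class TestBernoulliEmissions:
    def test_uninformative_mu_gives_constant_scores(self):
        params = HMMParams([1.0], [[1.0]], [[0.5, 0.5, 0.5]])
        em = bernoulli_log_emissions(params, fm([[1, 0, 1], [0, 0, 0]]))
        np.testing.assert_allclose(em.values, 3 * math.log(0.5))

    def test_single_feature_closed_form(self):
        params = HMMParams([1.0], [[1.0]], [[0.9]])
        em = bernoulli_log_emissions(params, fm([[1]]))
        assert em.values[0, 0] == pytest.approx(math.log(0.9))

    def test_two_feature_product(self):
        params = HMMParams([1.0], [[1.0]], [[0.9, 0.2]])
        em = bernoulli_log_emissions(params, fm([[1, 0]]))
        assert em.values[0, 0] == pytest.approx(math.log(0.9) + math.log(0.8))

    def test_degenerate_mu_is_floored_not_minus_inf(self):
        params = HMMParams([1.0], [[1.0]], [[0.0, 1.0]])
        em = bernoulli_log_emissions(params, fm([[1, 0]]))
        assert np.isfinite(em.values).all()
        assert em.values[0, 0] == pytest.approx(2 * math.log(EPS), rel=1e-6)


class TestViterbi:
    def test_single_state_returns_all_ones(self):
        em = EmissionScores(np.zeros((4, 1)))
        seq = viterbi([1.0], [[1.0]], em, ["only"])
        assert seq.labels.tolist() == [1, 1, 1, 1]

    def test_single_slice_is_prior_times_emission_argmax(self):
        em = EmissionScores(np.array([[0.0, 3.0]]))
        seq = viterbi([0.9, 0.1], [[0.5, 0.5], [0.5, 0.5]], em, ["a", "b"])
        # log 0.9 + 0 = -0.105  <  log 0.1 + 3 = 0.697
        assert seq.labels.tolist() == [2]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            q = int(rng.integers(2, 5))
            t_len = int(rng.integers(2, 7))
            pi, trans, log_em = random_instance(rng, q, t_len)
            best_score, _ = brute_force_best(pi, trans, log_em)
            path = viterbi_path(pi, trans, log_em)
            assert path_score(pi, trans, log_em, path) == pytest.approx(best_score)

    def test_ties_break_toward_lowest_state(self):
        em = EmissionScores(np.zeros((3, 2)))
        seq = viterbi([0.5, 0.5], np.full((2, 2), 0.5), em, ["a", "b"])
        assert seq.labels.tolist() == [1, 1, 1]


class TestJointLoglik:
    def test_single_slice(self):
        params = HMMParams([0.4, 0.6], np.full((2, 2), 0.5), [[0.9], [0.1]])
        ll = joint_loglik(params, fm([[1]]), ls([1], 2))
        assert ll == pytest.approx(math.log(0.4) + math.log(0.9))

    def test_uninformative_closed_form(self):
        params = HMMParams([1.0], [[1.0]], [[0.5]])
        ll = joint_loglik(params, fm([[1], [0], [1]]), ls([1, 1, 1], 1))
        assert ll == pytest.approx(3 * math.log(0.5))

    def test_term_by_term_hand_computation(self):
        params = HMMParams([0.7, 0.3], [[0.8, 0.2], [0.4, 0.6]],
                           [[0.9, 0.1], [0.2, 0.8]])
        ll = joint_loglik(params, fm([[1, 0], [0, 1]]), ls([1, 2], 2))
        # t=1: pi_1 * mu_11 * (1-mu_12); t=2: a_12 * (1-mu_21) * mu_22
        expected = (math.log(0.7) + math.log(0.9) + math.log(0.9)
                    + math.log(0.2) + math.log(0.8) + math.log(0.8))
        assert ll == pytest.approx(expected)

    def test_viterbi_path_is_loglik_optimal(self):
        rng = np.random.default_rng(3)
        q, t_len, n = 3, 5, 4
        mu = rng.random((q, n))
        pi = rng.dirichlet(np.ones(q))
        trans = rng.dirichlet(np.ones(q), size=q)
        params = HMMParams(pi, trans, mu,
                           class_names=[f"c{i}" for i in range(q)])
        feat = fm(rng.integers(0, 2, size=(t_len, n)))
        best = decode(params, feat)
        best_ll = joint_loglik(params, feat, best)
        for other in itertools.product(range(1, q + 1), repeat=t_len):
            ll = joint_loglik(params, feat, ls(list(other), q))
            assert best_ll >= ll - 1e-9


class TestParameterRecovery:
    def test_recovery_from_simulated_slices(self):
        """Sampling 5,000 slices from a well-separated 3-state model and
        re-estimating with alpha=0 recovers transitions and means closely."""
        rng = np.random.default_rng(11)
        q, n = 3, 6
        mu = np.where(rng.random((q, n)) < 0.5, 0.1, 0.9)
        trans = np.full((q, q), 0.05 / (q - 1))
        np.fill_diagonal(trans, 0.95)
        params = HMMParams(np.full(q, 1 / q), trans, mu)
        x, y = sample_hmm(params, 5000, seed=5)
        est = estimate_supervised(
            FeatureMatrix(x, [f"f{i}" for i in range(n)]),
            LabelSequence(y + 1, [f"c{i}" for i in range(q)]), alpha=0)
        assert np.abs(est.trans - trans).max() < 0.04
        assert np.abs(est.mu - mu).max() < 0.04
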