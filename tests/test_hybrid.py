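"""Hybrid HMM/classifier training and prediction."""

import numpy as np
import pytest

from hybridhmm import (
    ClassPriors,
    EmitterConfig,
    FeatureMatrix,
    HMMParams,
    HybridModel,
    LabelSequence,
    PosteriorMatrix,
    ShapeError,
    TrainOptions,
    predict,
    predict_static,
    train_hybrid,
)
from hybridhmm.hmm_core import viterbi_path


class TableEmitter:
    """Stub emitter returning a fixed posterior table (oracle adapter)."""

    def __init__(self, values, class_names):
        self.values = np.asarray(values, dtype=float)
        self.class_names = list(class_names)

    def posteriors(self, feat):
        return PosteriorMatrix(self.values[: feat.n_slices], self.class_names)


def fm(t, n=2):
    return FeatureMatrix(np.zeros((t, n), dtype=np.uint8),
                         [f"f{i}" for i in range(n)])


def model_from(post, pi, trans, priors, names):
    q = len(names)
    return HybridModel(
        hmm=HMMParams(pi, trans, np.full((q, 2), 0.5), list(names)),
        emitter=TableEmitter(post, names),
        priors=ClassPriors(priors),
        class_names=list(names),
        feature_names=["f0", "f1"],
    )


class TestPredict:
    def test_one_hot_posteriors_dominate_any_positive_dynamics(self):
        post = np.eye(3)[[0, 1, 2, 1, 0]]
        post = np.clip(post, 1e-9, 1)
        post /= post.sum(axis=1, keepdims=True)
        rng = np.random.default_rng(0)
        trans = rng.dirichlet(np.ones(3) * 5, size=3)
        model = model_from(post, np.full(3, 1 / 3), trans,
                           np.full(3, 1 / 3), list("abc"))
        assert predict(model, fm(5)).labels.tolist() == [1, 2, 3, 2, 1]

    def test_sticky_transitions_smooth_a_single_slice_blip(self):
        # posterior favors class 2 only at t=3, margin below the
        # transition penalty: brute-force optimum is the constant path
        post = np.full((7, 2), [0.6, 0.4])
        post[3] = [0.45, 0.55]
        trans = np.array([[0.99, 0.01], [0.01, 0.99]])
        model = model_from(post, [0.5, 0.5], trans, [0.5, 0.5], ["a", "b"])
        assert predict(model, fm(7)).labels.tolist() == [1] * 7

    def test_single_slice_is_argmax_of_prior_plus_scaled_likelihood(self):
        post = np.array([[0.6, 0.4]])
        model = model_from(post, [0.2, 0.8], np.full((2, 2), 0.5),
                           [0.5, 0.5], ["a", "b"])
        # log 0.2 + log(0.6/0.5) vs log 0.8 + log(0.4/0.5)
        assert predict(model, fm(1)).labels.tolist() == [2]

    def test_feature_mismatch_raises(self):
        model = model_from(np.full((3, 2), 0.5), [0.5, 0.5],
                           np.full((2, 2), 0.5), [0.5, 0.5], ["a", "b"])
        with pytest.raises(ShapeError):
            predict(model, FeatureMatrix(np.zeros((3, 5), dtype=np.uint8),
                                         [f"g{i}" for i in range(5)]))


class TestPredictStatic:
    def test_argmax_of_one_hot_posteriors(self):
        emitter = TableEmitter(np.eye(2)[[1, 0, 1]], ["a", "b"])
        assert predict_static(emitter, fm(3)).labels.tolist() == [2, 1, 2]

    def test_uniform_posteriors_tie_to_lowest_class(self):
        emitter = TableEmitter(np.full((4, 3), 1 / 3), list("abc"))
        assert predict_static(emitter, fm(4, 2)).labels.tolist() == [1] * 4

    def test_agrees_with_hybrid_under_uniform_dynamics_and_priors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            q = int(rng.integers(2, 5))
            t = int(rng.integers(1, 12))
            post = rng.dirichlet(np.ones(q), size=t)
            names = [f"c{i}" for i in range(q)]
            emitter = TableEmitter(post, names)
            model = HybridModel(
                hmm=HMMParams(np.full(q, 1 / q), np.full((q, q), 1 / q),
                              np.full((q, 2), 0.5), names),
                emitter=emitter,
                priors=ClassPriors(np.full(q, 1 / q)),
                class_names=names,
                feature_names=["f0", "f1"],
            )
            static = predict_static(emitter, fm(t))
            hybrid = predict(model, fm(t))
            assert np.array_equal(static.labels, hybrid.labels)


def alternating_days(n_days=3, period=20, t=120):
    """Noiseless separable data: feature 0 on in class 2, off in class 1."""
    days = []
    for _ in range(n_days):
        labels = (np.arange(t) // period) % 2 + 1
        x = np.zeros((t, 2), dtype=np.uint8)
        x[labels == 2, 0] = 1
        days.append((FeatureMatrix(x, ["f0", "f1"]),
                     LabelSequence(labels, ["a", "b"])))
    return days


class TestTrainHybrid:
    def test_single_pass_training_predicts_separable_data(self):
        days = alternating_days()
        model = train_hybrid(days, EmitterConfig(kind="mlp", seed=0))
        pred = predict(model, days[0][0])
        assert (pred.labels == days[0][1].labels).mean() > 0.95

    def test_realignment_is_a_fixed_point_on_separable_data(self):
        days = alternating_days()
        one_pass = train_hybrid(days, EmitterConfig(kind="svm", seed=0),
                                TrainOptions(realign=False))
        realigned = train_hybrid(days, EmitterConfig(kind="svm", seed=0),
                                 TrainOptions(realign=True, max_iterations=3))
        p1 = predict(one_pass, days[1][0])
        p2 = predict(realigned, days[1][0])
        assert np.array_equal(p1.labels, p2.labels)
        np.testing.assert_allclose(one_pass.priors.probs,
                                   realigned.priors.probs)

    def test_same_seed_gives_identical_predictions(self):
        days = alternating_days()
        config = EmitterConfig(kind="mlp", seed=3)
        m1 = train_hybrid(days, config)
        m2 = train_hybrid(days, config)
        assert np.array_equal(predict(m1, days[0][0]).labels,
                              predict(m2, days[0][0]).labels)
        np.testing.assert_array_equal(m1.hmm.trans, m2.hmm.trans)

    def test_priors_and_transitions_come_from_labels(self):
        days = alternating_days()
        model = train_hybrid(days, EmitterConfig(kind="mlp", seed=0))
        np.testing.assert_allclose(model.priors.probs, [0.5, 0.5], atol=1e-6)
        assert model.hmm.trans[0, 0] > 0.9  # persistent activities

    def test_emitter_subsample_thins_classifier_training_only(self):
        days = alternating_days()
        model = train_hybrid(days, EmitterConfig(kind="svm", seed=0),
                             TrainOptions(emitter_subsample=4))
        # dynamics still estimated from all slices
        np.testing.assert_allclose(model.priors.probs, [0.5, 0.5], atol=1e-6)
        pred = predict(model, days[0][0])
        assert (pred.labels == days[0][1].labels).mean() > 0.9


class TestScaledLikelihoodContracts:
    def test_uniform_priors_leave_viterbi_path_unchanged(self):
        """Scaled likelihoods with uniform priors shift every row by the
        same constant, so the decode equals Viterbi on log-posteriors."""
        rng = np.random.default_rng(7)
        from hybridhmm import scaled_likelihoods

        for _ in range(25):
            q = int(rng.integers(2, 5))
            t = int(rng.integers(2, 15))
            post = rng.dirichlet(np.ones(q), size=t)
            pi = rng.dirichlet(np.ones(q))
            trans = rng.dirichlet(np.ones(q), size=q)
            em = scaled_likelihoods(
                PosteriorMatrix(post, [f"c{i}" for i in range(q)]),
                ClassPriors(np.full(q, 1 / q)))
            assert np.array_equal(viterbi_path(pi, trans, em.values),
                                  viterbi_path(pi, trans, np.log(post)))

    def test_row_scaling_does_not_change_the_decode(self):
        rng = np.random.default_rng(8)
        from hybridhmm import scaled_likelihoods

        q, t = 3, 10
        post = rng.dirichlet(np.ones(q), size=t)
        priors = ClassPriors(rng.dirichlet(np.ones(q)))
        pi = rng.dirichlet(np.ones(q))
        trans = rng.dirichlet(np.ones(q), size=q)
        base = scaled_likelihoods(
            PosteriorMatrix(post, list("abc")), priors).values
        scaled = base + np.log(rng.uniform(0.5, 2.0, size=(t, 1)))
        assert np.array_equal(viterbi_path(pi, trans, base),
                              viterbi_path(pi, trans, scaled))
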