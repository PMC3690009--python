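"""The hybrid generative/discriminative recognizer.

An HMM supplies the temporal structure (initial distribution and
transitions, estimated from label frequencies); a discriminative classifier
supplies the per-slice evidence as posteriors, converted to scaled
likelihoods.  Prediction is a Viterbi decode over

    log pi_{y1} + sum_t log a_{y_{t-1} y_t}
                + sum_t [log p(y_t | x_t) - log p(y_t)]

Training is supervised: one pass initializes pi/A from the labels and fits
the emitter on all training slices.  Because the labels are complete, a
single pass is well-defined; an optional EM-like *realignment* loop is also
provided, in which the current model re-decodes the training days, the
emitter is refitted on the decoded labels, and the loop stops when the
decoded paths no longer change (or ``max_iterations`` is reached).  By
default pi/A stay fixed at their label-frequency estimates during
realignment; ``reestimate_transitions`` refits them too.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .emitters import (
    ClassPriors,
    Emitter,
    EmitterConfig,
    estimate_priors,
    fit_emitter,
    scaled_likelihoods,
)
from .errors import EstimationError, ShapeError
from .features import FeatureMatrix
from .hmm_core import HMMParams, bernoulli_log_emissions, estimate_supervised, viterbi
from .sensor_data import LabelSequence

__all__ = [
    "TrainOptions",
    "HybridModel",
    "train_hybrid",
    "predict",
    "predict_static",
    "make_hybrid_trainer",
    "make_static_trainer",
    "make_hmm_trainer",
    "save_model",
    "load_model",
]

DaySequence = tuple[FeatureMatrix, LabelSequence]


@dataclass
class TrainOptions:
    """Hybrid training options.

    ``realign=False`` (default) performs a single supervised pass.  With
    ``realign=True`` the Viterbi-realignment loop runs for at most
    ``max_iterations`` refits, stopping early when the decoded training
    paths are identical between consecutive iterations.
    ``emitter_subsample`` fits the classifier on every k-th training slice
    (k=1: all slices); HMM transitions and priors always use all slices.
    """

    max_iterations: int = 1
    realign: bool = False
    reestimate_transitions: bool = False
    trans_alpha: float = 1.0
    emitter_subsample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.emitter_subsample < 1:
            raise ValueError("emitter_subsample must be >= 1")


@dataclass
class HybridModel:
    """A fitted hybrid recognizer: HMM dynamics + discriminative emitter."""

    hmm: HMMParams
    emitter: Emitter
    priors: ClassPriors
    class_names: list[str]
    feature_names: list[str]
    config: EmitterConfig | None = None
    options: TrainOptions | None = None


def _pool(days: Sequence[DaySequence], stride: int = 1) -> DaySequence:
    feats = [f for f, _ in days]
    labels = [l for _, l in days]
    pooled_feat = FeatureMatrix(
        np.vstack([f.values for f in feats]), feats[0].column_names)
    pooled_labels = LabelSequence(
        np.concatenate([l.labels for l in labels]), labels[0].class_names)
    if stride > 1:
        pooled_feat = FeatureMatrix(pooled_feat.values[::stride],
                                    pooled_feat.column_names)
        pooled_labels = LabelSequence(pooled_labels.labels[::stride],
                                      pooled_labels.class_names)
    return pooled_feat, pooled_labels


def train_hybrid(
    day_sequences: Sequence[DaySequence],
    emitter_config: EmitterConfig,
    options: TrainOptions | None = None,
) -> HybridModel:
    """Train the hybrid recognizer on per-day (features, labels) pairs."""
    if not day_sequences:
        raise EstimationError("training needs at least one day")
    options = options or TrainOptions()
    feats = [f for f, _ in day_sequences]
    labels = [l for _, l in day_sequences]
    class_names = labels[0].class_names

    hmm = estimate_supervised(feats, labels, alpha=options.trans_alpha)
    current_labels = labels

    def fit_on(lbls: Sequence[LabelSequence]) -> Emitter:
        pf, pl = _pool(list(zip(feats, lbls)), options.emitter_subsample)
        return fit_emitter(pf, pl, emitter_config)

    emitter = fit_on(current_labels)

    if options.realign:
        for _ in range(options.max_iterations):
            priors = estimate_priors(list(current_labels))
            decoded = []
            for f in feats:
                em = scaled_likelihoods(emitter.posteriors(f), priors)
                decoded.append(viterbi(hmm.pi, hmm.trans, em, class_names))
            if all(np.array_equal(d.labels, c.labels)
                   for d, c in zip(decoded, current_labels)):
                break
            n_classes_seen = np.unique(
                np.concatenate([d.labels for d in decoded])).size
            if n_classes_seen < 2:
                warnings.warn(
                    "realignment collapsed the training labels to a single "
                    "class; keeping the pre-collapse model"
                )
                break
            current_labels = decoded
            emitter = fit_on(current_labels)
            if options.reestimate_transitions:
                hmm = estimate_supervised(feats, list(current_labels),
                                          alpha=options.trans_alpha)

    priors = estimate_priors(list(current_labels))
    return HybridModel(
        hmm=hmm,
        emitter=emitter,
        priors=priors,
        class_names=list(class_names),
        feature_names=list(feats[0].column_names),
        config=emitter_config,
        options=options,
    )


def predict(model: HybridModel, feat: FeatureMatrix) -> LabelSequence:
    """Viterbi decode of one sequence under the hybrid model."""
    if feat.n_features != len(model.feature_names):
        raise ShapeError(
            f"feature matrix has {feat.n_features} columns, model was trained "
            f"on {len(model.feature_names)}"
        )
    em = scaled_likelihoods(model.emitter.posteriors(feat), model.priors)
    return viterbi(model.hmm.pi, model.hmm.trans, em, model.class_names)


def predict_static(emitter: Emitter, feat: FeatureMatrix) -> LabelSequence:
    """Per-slice argmax of the emitter's posteriors (sliding-window use).

    This is the emitter as a standalone classifier, with no temporal model;
    ties go to the lowest class index.
    """
    post = emitter.posteriors(feat)
    return LabelSequence(np.argmax(post.values, axis=1) + 1, emitter.class_names)


# ---------------------------------------------------------------------------
# Trainer factories for the evaluation harness.  Each returns
# fit(train_days) -> predict_fn(feat) -> LabelSequence.

Trainer = Callable[[Sequence[DaySequence]], Callable[[FeatureMatrix], LabelSequence]]


def make_hybrid_trainer(
    config: EmitterConfig, options: TrainOptions | None = None
) -> Trainer:
    """Hybrid HMM/classifier trainer for leave-one-day-out evaluation."""

    def fit(train_days: Sequence[DaySequence]):
        model = train_hybrid(train_days, config, options)
        return lambda feat: predict(model, feat)

    return fit


def make_static_trainer(
    config: EmitterConfig, options: TrainOptions | None = None
) -> Trainer:
    """Standalone (sliding-window) classifier trainer: no temporal model."""
    options = options or TrainOptions()

    def fit(train_days: Sequence[DaySequence]):
        pf, pl = _pool(list(train_days), options.emitter_subsample)
        emitter = fit_emitter(pf, pl, config)
        return lambda feat: predict_static(emitter, feat)

    return fit


def make_hmm_trainer(alpha: float = 1.0) -> Trainer:
    """Pure generative Bernoulli-HMM trainer (the classic baseline)."""

    def fit(train_days: Sequence[DaySequence]):
        feats = [f for f, _ in train_days]
        labels = [l for _, l in train_days]
        params = estimate_supervised(feats, labels, alpha=alpha)

        def predict_fn(feat: FeatureMatrix) -> LabelSequence:
            em = bernoulli_log_emissions(params, feat)
            return viterbi(params.pi, params.trans, em, params.class_names)

        return predict_fn

    return fit


# ---------------------------------------------------------------------------
# Serialization (runtime artifact; joblib keeps the fitted sklearn emitter)


def save_model(path: Union[str, os.PathLike], model: HybridModel) -> None:
    """Persist a fitted hybrid model (joblib pickle)."""
    import joblib

    joblib.dump(model, os.fspath(path))


def load_model(path: Union[str, os.PathLike]) -> HybridModel:
    import joblib

    return joblib.load(os.fspath(path))
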