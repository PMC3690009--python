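"""Discriminative emission-probability estimators and the scaled-likelihood
conversion.

In the hybrid scheme the HMM's observation model is replaced by a static
classifier trained on labeled slices.  The classifier outputs a posterior
``p(y | x)`` per slice; Bayes' rule turns that into the quantity Viterbi
needs, ``p(x | y) = p(y | x) p(x) / p(y)``.  During decoding ``p(x)`` is the
same for every state, so the *scaled likelihood* ``p(y | x) / p(y)`` can be
used directly as the emission score — here in log space:
``log p(y|x) - log p(y)``, with class priors ``p(y)`` estimated from the
relative label frequencies of the training data.

Two estimators are provided:

* **MLP** — a single-hidden-layer perceptron trained by error
  back-propagation on the cross-entropy (relative entropy) criterion, with
  a softmax output layer, so its outputs are posterior estimates directly.
* **SVM** — RBF-kernel support vector machines; the multiclass problem is
  reduced to binary subproblems (one-vs-rest by default, one-vs-one
  optionally) and each margin score is mapped to a probability by a Platt
  sigmoid fitted on cross-validated decision values.  Per-class
  probabilities are renormalized so every posterior row sums to 1.

Any object exposing ``posteriors(feat) -> PosteriorMatrix`` and
``class_names`` can serve as an emitter, so external classifiers plug into
the hybrid without modification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence, Union, runtime_checkable

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import CalibrationError, EstimationError, ShapeError, ValidationError
from .features import FeatureMatrix
from .hmm_core import EPS, EmissionScores
from .sensor_data import LabelSequence

__all__ = [
    "PosteriorMatrix",
    "PlattParams",
    "ClassPriors",
    "EmitterConfig",
    "Emitter",
    "MLPEmitter",
    "SVMEmitter",
    "fit_emitter",
    "fit_platt",
    "posteriors",
    "mlp_posteriors",
    "svm_posteriors",
    "estimate_priors",
    "scaled_likelihoods",
    "combine_one_vs_rest",
    "median_heuristic_sigma",
]


@dataclass
class PosteriorMatrix:
    """T x Q matrix of classifier posteriors ``p(y_t | x_t)``.

    Rows are forced to sum to 1; entries lie in [0, 1].
    """

    values: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("posterior values must be 2-D")
        if self.values.shape[1] != len(self.class_names):
            raise ShapeError("posterior columns must match class_names")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValidationError("posterior entries must lie in [0, 1]")
        rows = self.values.sum(axis=1)
        if self.values.shape[0] and np.abs(rows - 1.0).max() > 1e-9:
            raise ValidationError("posterior rows must sum to 1")


@dataclass(frozen=True)
class PlattParams:
    """Sigmoid calibration ``p(positive | s) = 1 / (1 + exp(-(a*s + b)))``.

    A positive ``a_slope`` makes the probability increase with the decision
    value ``s`` (the usual orientation when positives score high).
    """

    a_slope: float
    b_offset: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a_slope) and np.isfinite(self.b_offset)):
            raise ValidationError("Platt parameters must be finite")

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return expit(self.a_slope * np.asarray(scores, dtype=float) + self.b_offset)


@dataclass
class ClassPriors:
    """Class prior probabilities ``p(y)`` from training-label frequencies."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size < 1:
            raise ShapeError("priors must be a non-empty vector")
        if self.probs.min() < 0 or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValidationError("priors must be non-negative and sum to 1")


@dataclass
class EmitterConfig:
    """Configuration of a discriminative emitter.

    Parameters
    ----------
    kind:
        ``"mlp"`` or ``"svm"``.
    hidden_units:
        MLP hidden-layer width; ``None`` means twice the feature count.
    rbf_sigma:
        RBF bandwidth sigma of ``K(x,y) = exp(-|x-y|^2 / (2 sigma^2))``;
        ``None`` selects it by the median heuristic on pairwise distances.
    cost:
        SVM soft-margin cost C.
    multiclass_scheme:
        ``"one_vs_rest"`` (default) or ``"one_vs_one"``.
    max_iter:
        Back-propagation epochs (MLP) or libsvm iteration cap (SVM; -1 =
        unlimited).
    early_stopping:
        Stop MLP training when accuracy on a held-out 10% of the training
        slices plateaus.  Off by default: under the heavy class imbalance
        of this domain, held-out *accuracy* saturates once the dominant
        classes are learned, long before the rare classes are — and rare
        classes carry half the weight of every macro-averaged metric.
    seed:
        Seed controlling weight initialization, early-stopping split and
        calibration folds; the same data and seed reproduce the fitted
        emitter bit-for-bit.
    """

    kind: str = "mlp"
    hidden_units: int | None = None
    rbf_sigma: float | None = None
    cost: float = 1.0
    multiclass_scheme: str = "one_vs_rest"
    max_iter: int = 500
    early_stopping: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "svm"):
            raise ValidationError(f"unknown emitter kind {self.kind!r}")
        if self.multiclass_scheme not in ("one_vs_rest", "one_vs_one"):
            raise ValidationError(
                f"unknown multiclass scheme {self.multiclass_scheme!r}"
            )
        if self.hidden_units is not None and self.hidden_units < 1:
            raise ValidationError("hidden_units must be positive")
        if self.rbf_sigma is not None and self.rbf_sigma <= 0:
            raise ValidationError("rbf_sigma must be positive")
        if self.cost <= 0:
            raise ValidationError("cost must be positive")


@runtime_checkable
class Emitter(Protocol):
    """Anything that maps a feature matrix to a posterior over classes."""

    class_names: list[str]

    def posteriors(self, feat: FeatureMatrix) -> PosteriorMatrix: ...


# ---------------------------------------------------------------------------
# Platt sigmoid calibration


def fit_platt(scores: np.ndarray, labels: np.ndarray) -> PlattParams:
    """Fit the Platt sigmoid to (decision value, binary indicator) pairs.

    Minimizes the negative log-likelihood of
    ``p = 1 / (1 + exp(-(a*s + b)))`` with Platt's smoothed targets
    ``t+ = (N+ + 1)/(N+ + 2)`` and ``t- = 1/(N- + 2)``, which regularize the
    fit against overconfident sigmoids on separable data.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if s.size != y.size or s.size == 0:
        raise CalibrationError("scores and labels must be equal-length, non-empty")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("calibration needs both positive and negative examples")
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_grad(ab: np.ndarray):
        z = ab[0] * s + ab[1]
        # -t log p - (1-t) log(1-p), written stably with logaddexp
        loss = float(np.sum(t * np.logaddexp(0.0, -z) + (1 - t) * np.logaddexp(0.0, z)))
        r = expit(z) - t
        return loss, np.array([np.dot(r, s), r.sum()])

    t_bar = float(t.mean())
    b0 = float(np.log(t_bar / (1.0 - t_bar)))  # intercept-only optimum
    best = None
    for start in ((0.0, b0), (1.0, 0.0)):
        res = minimize(nll_grad, np.asarray(start, dtype=float), jac=True,
                       method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    return PlattParams(float(best.x[0]), float(best.x[1]))


def median_heuristic_sigma(
    x: np.ndarray, rng: np.random.Generator, max_points: int = 500
) -> float:
    """RBF bandwidth: median pairwise Euclidean distance on a subsample."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] > max_points:
        x = x[rng.choice(x.shape[0], max_points, replace=False)]
    sq = np.sum(x**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    med = float(np.median(np.sqrt(d2[np.triu_indices_from(d2, k=1)])))
    return med if med > 0 else 1.0


# ---------------------------------------------------------------------------
# Emitters


def _check_training_labels(labels: LabelSequence) -> None:
    if np.unique(labels.labels).size < 2:
        raise EstimationError(
            "emitter training needs at least two classes in the labels"
        )


def _expand_to_full(
    probs: np.ndarray, present: np.ndarray, n_classes: int
) -> np.ndarray:
    """Spread columns for the classes present in training over the full Q."""
    full = np.zeros((probs.shape[0], n_classes))
    full[:, present] = probs
    return full


class MLPEmitter:
    """Softmax multi-layer perceptron posterior estimator.

    A single hidden layer (default width 2x the feature count) trained by
    back-propagation on cross-entropy.  Optional early stopping holds out
    10% of the training slices; it is skipped when any class has fewer
    than two examples (a stratified split needs that many).
    """

    def __init__(self, config: EmitterConfig):
        if config.kind != "mlp":
            raise ValidationError("MLPEmitter requires kind='mlp'")
        self.config = config
        self.class_names: list[str] = []
        self._model: MLPClassifier | None = None
        self._present: np.ndarray | None = None

    def fit(self, feat: FeatureMatrix, labels: LabelSequence) -> "MLPEmitter":
        _check_training_labels(labels)
        self.class_names = list(labels.class_names)
        y = labels.indices
        hidden = self.config.hidden_units or 2 * feat.n_features
        counts = np.bincount(y, minlength=labels.n_classes)
        can_stratify = counts[counts > 0].min() >= 2
        self._model = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=self.config.max_iter,
            random_state=self.config.seed,
            early_stopping=self.config.early_stopping and bool(can_stratify),
            validation_fraction=0.1,
            n_iter_no_change=10,
        )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self._model.fit(feat.values.astype(float), y)
        self._present = np.asarray(self._model.classes_, dtype=int)
        return self

    def posteriors(self, feat: FeatureMatrix) -> PosteriorMatrix:
        if self._model is None:
            raise EstimationError("emitter is not fitted")
        probs = self._model.predict_proba(feat.values.astype(float))
        full = _expand_to_full(probs, self._present, len(self.class_names))
        full /= full.sum(axis=1, keepdims=True)
        return PosteriorMatrix(full, self.class_names)


def combine_one_vs_rest(sigmoids: np.ndarray) -> np.ndarray:
    """Normalize per-class sigmoid outputs into posterior rows summing to 1.

    Rows whose sigmoids are all (numerically) zero become uniform, with a
    warning: the calibrated classifiers then carry no information about the
    slice.
    """
    sig = np.asarray(sigmoids, dtype=float)
    totals = sig.sum(axis=1, keepdims=True)
    dead = totals[:, 0] <= EPS
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} slices had all-zero class sigmoids; "
            "using uniform posteriors there"
        )
        sig[dead] = 1.0
        totals = sig.sum(axis=1, keepdims=True)
    return sig / totals


class SVMEmitter:
    """RBF-kernel SVM posterior estimator with Platt-calibrated outputs.

    The multiclass problem is reduced to binary subproblems.  For each
    subproblem a Platt sigmoid is fitted on decision values pooled from a
    3-fold cross-validation over the training slices (falling back to the
    full-fit decision values when a side of the split has fewer than 3
    examples), so the sigmoid is not fitted on optimistically separable
    scores.
    """

    CALIBRATION_FOLDS = 3

    def __init__(self, config: EmitterConfig):
        if config.kind != "svm":
            raise ValidationError("SVMEmitter requires kind='svm'")
        self.config = config
        self.class_names: list[str] = []
        self.platt: dict[tuple, PlattParams] = {}
        self._models: dict[tuple, SVC] = {}
        self._present: np.ndarray | None = None
        self._sigma: float | None = None

    # -- internals -----------------------------------------------------

    def _make_svc(self, gamma: float) -> SVC:
        return SVC(kernel="rbf", C=self.config.cost, gamma=gamma,
                   max_iter=self.config.max_iter if self.config.max_iter > 0 else -1)

    def _cv_decision_values(
        self, x: np.ndarray, y_bin: np.ndarray, gamma: float,
        rng_seed: int,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pool out-of-fold decision values for calibration."""
        n_pos = int(y_bin.sum())
        n_neg = int(y_bin.size - n_pos)
        k = self.CALIBRATION_FOLDS
        if min(n_pos, n_neg) < k:
            model = self._make_svc(gamma).fit(x, y_bin)
            return model.decision_function(x), y_bin
        scores = np.empty(y_bin.size)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
        for tr, te in skf.split(x, y_bin):
            m = self._make_svc(gamma).fit(x[tr], y_bin[tr])
            scores[te] = m.decision_function(x[te])
        return scores, y_bin

    # -- API -----------------------------------------------------------

    def fit(self, feat: FeatureMatrix, labels: LabelSequence) -> "SVMEmitter":
        _check_training_labels(labels)
        self.class_names = list(labels.class_names)
        x = feat.values.astype(float)
        y = labels.indices
        rng = np.random.default_rng(self.config.seed)
        self._sigma = self.config.rbf_sigma or median_heuristic_sigma(x, rng)
        gamma = 1.0 / (2.0 * self._sigma**2)
        self._present = np.unique(y)
        self._models.clear()
        self.platt.clear()

        if self.config.multiclass_scheme == "one_vs_rest":
            for c in self._present:
                y_bin = (y == c).astype(int)
                self._models[(int(c),)] = self._make_svc(gamma).fit(x, y_bin)
                dv, ind = self._cv_decision_values(x, y_bin, gamma,
                                                  self.config.seed + int(c))
                self.platt[(int(c),)] = fit_platt(dv, ind)
        else:  # one_vs_one
            for ai in range(self._present.size):
                for bi in range(ai + 1, self._present.size):
                    a, b = int(self._present[ai]), int(self._present[bi])
                    mask = (y == a) | (y == b)
                    y_bin = (y[mask] == a).astype(int)
                    xs = x[mask]
                    self._models[(a, b)] = self._make_svc(gamma).fit(xs, y_bin)
                    dv, ind = self._cv_decision_values(
                        xs, y_bin, gamma, self.config.seed + 31 * a + b)
                    self.platt[(a, b)] = fit_platt(dv, ind)
        return self

    def posteriors(self, feat: FeatureMatrix) -> PosteriorMatrix:
        if self._present is None:
            raise EstimationError("emitter is not fitted")
        x = feat.values.astype(float)
        q_full = len(self.class_names)
        if self.config.multiclass_scheme == "one_vs_rest":
            sig = np.column_stack([
                self.platt[(int(c),)].predict(
                    self._models[(int(c),)].decision_function(x))
                for c in self._present
            ])
            probs = combine_one_vs_rest(sig)
        else:
            # vote-weighted pairwise coupling: average each class's pairwise
            # win probabilities, then renormalize
            scores = np.zeros((x.shape[0], self._present.size))
            pos = {int(c): i for i, c in enumerate(self._present)}
            for (a, b), model in self._models.items():
                p_ab = self.platt[(a, b)].predict(model.decision_function(x))
                scores[:, pos[a]] += p_ab
                scores[:, pos[b]] += 1.0 - p_ab
            probs = combine_one_vs_rest(scores)
        full = _expand_to_full(probs, self._present, q_full)
        full /= full.sum(axis=1, keepdims=True)
        return PosteriorMatrix(full, self.class_names)


def fit_emitter(
    feat: FeatureMatrix, labels: LabelSequence, config: EmitterConfig
) -> Union[MLPEmitter, SVMEmitter]:
    """Fit the emitter named by ``config.kind`` on labeled slices."""
    emitter = MLPEmitter(config) if config.kind == "mlp" else SVMEmitter(config)
    return emitter.fit(feat, labels)


def posteriors(model: Emitter, feat: FeatureMatrix) -> PosteriorMatrix:
    """Posterior matrix of any fitted emitter (API convenience)."""
    return model.posteriors(feat)


def mlp_posteriors(model: MLPEmitter, feat: FeatureMatrix) -> PosteriorMatrix:
    """Softmax posteriors of a fitted MLP emitter."""
    return model.posteriors(feat)


def svm_posteriors(model: SVMEmitter, feat: FeatureMatrix) -> PosteriorMatrix:
    """Platt-calibrated, renormalized posteriors of a fitted SVM emitter."""
    return model.posteriors(feat)


# ---------------------------------------------------------------------------
# Priors and the scaled-likelihood conversion


def estimate_priors(
    labels: Union[LabelSequence, Sequence[LabelSequence]]
) -> ClassPriors:
    """Relative class frequencies, floored at ``EPS`` and renormalized.

    Classes absent from the labels get the floor instead of exactly zero so
    the scaled-likelihood division stays finite.
    """
    if isinstance(labels, LabelSequence):
        labels = [labels]
    if not labels or sum(len(l) for l in labels) == 0:
        raise ValidationError("priors need at least one labeled slice")
    q = labels[0].n_classes
    counts = np.zeros(q)
    for l in labels:
        counts += np.bincount(l.indices, minlength=q)
    probs = counts / counts.sum()
    probs = np.clip(probs, EPS, None)
    return ClassPriors(probs / probs.sum())


def scaled_likelihoods(post: PosteriorMatrix, priors: ClassPriors) -> EmissionScores:
    """Log scaled likelihoods ``log p(y|x) - log p(y)``.

    The observation marginal ``p(x)`` of Bayes' rule is dropped: it is
    constant across states at each slice, so it shifts every score in a row
    equally and cannot change any Viterbi decision.
    """
    if post.values.shape[1] != priors.probs.size:
        raise ShapeError("posterior columns and prior length disagree")
    log_post = np.log(np.clip(post.values, EPS, None))
    log_prior = np.log(np.clip(priors.probs, EPS, None))
    return EmissionScores(log_post - log_prior[None, :], kind="scaled_likelihood")
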