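"""Bernoulli-emission hidden Markov model: supervised estimation, likelihood
and Viterbi decoding.

The generative model factorizes the joint probability of an activity path
``y_1:T`` and binary observations ``x_1:T`` as

    p(y_1:T, x_1:T) = p(y_1) p(x_1|y_1) prod_t p(y_t|y_t-1) p(x_t|y_t)

with an initial distribution ``pi``, a row-stochastic transition matrix
``A`` and, for the pure generative model, a naive-Bayes emission in which
every binary feature is an independent Bernoulli:
``p(x_t|y_t=i) = prod_n mu_in^x (1-mu_in)^(1-x)``.

All computation is in log space.  Probabilities are floored at ``EPS``
before taking logs, so emission scores are always finite even when an
estimated ``mu`` hits 0 or 1 exactly.

Because training data are fully labeled, parameters are estimated by
(smoothed) relative frequencies; there is no Baum-Welch here.  Each
recording day is treated as an independent sequence: ``pi`` applies at each
day's first slice and no transition is counted across midnight.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .errors import EstimationError, ShapeError, ValidationError
from .features import FeatureMatrix
from .sensor_data import LabelSequence

__all__ = [
    "EPS",
    "HMMParams",
    "EmissionScores",
    "estimate_supervised",
    "bernoulli_log_emissions",
    "viterbi",
    "viterbi_path",
    "joint_loglik",
    "decode",
]

#: Probability floor applied before any log.
EPS = 1e-12


@dataclass
class HMMParams:
    """Initial, transition and Bernoulli-emission parameters.

    ``pi[i]`` = p(y_1 = i+1); ``trans[i, j]`` = p(y_t = j+1 | y_t-1 = i+1);
    ``mu[i, n]`` = p(x^n = 1 | y = i+1).
    """

    pi: np.ndarray
    trans: np.ndarray
    mu: np.ndarray
    class_names: list[str] | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        q = self.pi.size
        if q < 1 or self.mu.shape[0] != q or self.trans.shape != (q, q):
            raise ShapeError("pi, trans and mu disagree on the number of states")
        if self.mu.shape[1] < 1:
            raise ShapeError("mu must have at least one feature column")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValidationError("pi must sum to 1")
        if np.abs(self.trans.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValidationError("each transition row must sum to 1")
        if self.mu.min() < 0 or self.mu.max() > 1:
            raise ValidationError("mu entries must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_features(self) -> int:
        return self.mu.shape[1]

    def to_json(self) -> str:
        doc = {
            "pi": self.pi.tolist(),
            "trans": self.trans.tolist(),
            "mu": self.mu.tolist(),
            "class_names": self.class_names,
            "feature_names": self.feature_names,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HMMParams":
        doc = json.loads(text)
        return cls(
            np.asarray(doc["pi"]), np.asarray(doc["trans"]), np.asarray(doc["mu"]),
            doc.get("class_names"), doc.get("feature_names"),
        )

    def save(self, path: Union[str, os.PathLike]) -> None:
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "HMMParams":
        with open(os.fspath(path), "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


@dataclass
class EmissionScores:
    """T x Q matrix of per-slice, per-state log emission scores.

    ``kind`` records whether scores are Bernoulli log-likelihoods or
    scaled likelihoods (classifier posterior over class prior).  All
    entries are finite by construction (flooring at ``EPS``).
    """

    values: np.ndarray
    kind: str = "bernoulli"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("emission scores must be 2-D")
        if self.kind not in ("bernoulli", "scaled_likelihood"):
            raise ValidationError(f"unknown emission kind {self.kind!r}")
        if not np.isfinite(self.values).all():
            raise ValidationError("emission scores must be finite")


def _as_pairs(
    feat: Union[FeatureMatrix, Sequence[FeatureMatrix]],
    labels: Union[LabelSequence, Sequence[LabelSequence]],
) -> list[tuple[FeatureMatrix, LabelSequence]]:
    if isinstance(feat, FeatureMatrix):
        feat = [feat]
        labels = [labels]
    pairs = list(zip(feat, labels, strict=True))
    for f, l in pairs:
        if f.n_slices != len(l):
            raise ShapeError("features and labels differ in length")
    return pairs


def estimate_supervised(
    feat: Union[FeatureMatrix, Sequence[FeatureMatrix]],
    labels: Union[LabelSequence, Sequence[LabelSequence]],
    alpha: float = 1.0,
) -> HMMParams:
    """Estimate ``pi``, ``A`` and ``mu`` from fully labeled slices.

    Accepts one (features, labels) pair or parallel sequences of pairs, one
    per independent day; transitions are counted only within a day.  With
    pseudocount ``alpha``:

    * ``pi_i    = (count(y=i) + alpha) / (T + Q*alpha)`` (relative state
      frequencies over all slices),
    * ``A_ij   = (count(i->j) + alpha) / (count(i->.) + Q*alpha)``,
    * ``mu_in  = (count(y=i, x_n=1) + alpha) / (count(y=i) + 2*alpha)``.

    With ``alpha = 0`` a class that never occurs in the labels raises
    :class:`EstimationError`.  A state observed only at day ends has no
    outgoing transitions; with ``alpha = 0`` its row falls back to uniform.
    """
    if alpha < 0:
        raise ValidationError("alpha must be non-negative")
    pairs = _as_pairs(feat, labels)
    q = pairs[0][1].n_classes
    n = pairs[0][0].n_features
    class_names = pairs[0][1].class_names
    feature_names = pairs[0][0].column_names

    occ = np.zeros(q)
    ones = np.zeros((q, n))
    pair_counts = np.zeros((q, q))
    total = 0
    for f, l in pairs:
        if f.n_features != n or l.n_classes != q:
            raise ShapeError("all sequences must share feature and class sets")
        idx = l.indices
        occ += np.bincount(idx, minlength=q)
        np.add.at(ones, idx, f.values)
        np.add.at(pair_counts, (idx[:-1], idx[1:]), 1)
        total += len(l)

    if alpha == 0 and (occ == 0).any():
        missing = [class_names[i] for i in np.flatnonzero(occ == 0)]
        raise EstimationError(
            f"classes never observed with alpha=0: {missing}"
        )

    pi = (occ + alpha) / (total + q * alpha)
    row_tot = pair_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = (pair_counts + alpha) / (row_tot + q * alpha)
    empty = (row_tot[:, 0] + q * alpha) == 0
    trans[empty] = 1.0 / q
    mu = (ones + alpha) / (occ + 2 * alpha)[:, None]
    mu = np.where(np.isfinite(mu), mu, 0.5)  # occ=0 only reachable with alpha=0 guard
    return HMMParams(pi, trans, np.clip(mu, 0.0, 1.0), class_names, feature_names)


def bernoulli_log_emissions(params: HMMParams, feat: FeatureMatrix) -> EmissionScores:
    """Naive-Bayes Bernoulli log-likelihood of each slice under each state."""
    if feat.n_features != params.n_features:
        raise ShapeError(
            f"feature matrix has {feat.n_features} columns, model expects "
            f"{params.n_features}"
        )
    mu = np.clip(params.mu, EPS, 1.0 - EPS)
    x = feat.values.astype(float)
    scores = x @ np.log(mu).T + (1.0 - x) @ np.log1p(-mu).T
    return EmissionScores(scores, kind="bernoulli")


def viterbi_path(pi: np.ndarray, trans: np.ndarray, log_em: np.ndarray) -> np.ndarray:
    """Maximum-score state path (0-based) by dynamic programming.

    Ties are broken toward the lowest state index at every step, so the
    decode is deterministic.
    """
    pi = np.asarray(pi, dtype=float)
    trans = np.asarray(trans, dtype=float)
    log_em = np.asarray(log_em, dtype=float)
    t_len, q = log_em.shape
    if pi.size != q or trans.shape != (q, q):
        raise ShapeError("pi/trans dimensions do not match emission columns")
    log_pi = np.log(np.clip(pi, EPS, None))
    log_a = np.log(np.clip(trans, EPS, None))

    delta = log_pi + log_em[0]
    back = np.zeros((t_len, q), dtype=np.int64)
    for t in range(1, t_len):
        cand = delta[:, None] + log_a  # cand[i, j]: best-so-far ending i, then j
        back[t] = np.argmax(cand, axis=0)  # argmax returns lowest index on ties
        delta = cand[back[t], np.arange(q)] + log_em[t]
    path = np.zeros(t_len, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi(
    pi: np.ndarray,
    trans: np.ndarray,
    em: EmissionScores,
    class_names: Sequence[str],
) -> LabelSequence:
    """Viterbi decode returning 1-based labels over ``class_names``."""
    path = viterbi_path(pi, trans, em.values)
    return LabelSequence(path + 1, list(class_names))


def joint_loglik(
    params: HMMParams, feat: FeatureMatrix, labels: LabelSequence
) -> float:
    """Complete-data log joint probability of (labels, features)."""
    if feat.n_slices != len(labels):
        raise ShapeError("features and labels differ in length")
    em = bernoulli_log_emissions(params, feat).values
    idx = labels.indices
    log_pi = np.log(np.clip(params.pi, EPS, None))
    log_a = np.log(np.clip(params.trans, EPS, None))
    total = log_pi[idx[0]] + em[0, idx[0]]
    if len(labels) > 1:
        total += log_a[idx[:-1], idx[1:]].sum()
        total += em[np.arange(1, len(labels)), idx[1:]].sum()
    return float(total)


def decode(params: HMMParams, feat: FeatureMatrix) -> LabelSequence:
    """Viterbi decode of a feature matrix under the pure Bernoulli HMM."""
    if params.class_names is None:
        raise ValidationError("params carry no class names; decode needs them")
    em = bernoulli_log_emissions(params, feat)
    return viterbi(params.pi, params.trans, em, params.class_names)
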