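"""Feature representations of the binary sensor stream.

Three encodings of the same T x N slice matrix are supported, used standalone
or concatenated:

* **raw** — the slice matrix as observed: 1 while the sensor is active.
* **change point** — 1 exactly when a sensor changes state (0→1 or 1→0)
  between consecutive slices; row 0 is compared against an implicit
  pre-stream state of all zeros, so a stream that starts active registers a
  change at t=0.
* **last sensor** — at each slice, the sensor(s) that changed state most
  recently (at or before that slice) carry 1 and every other sensor is 0;
  before the first change the row is all zeros.  If several sensors change
  in the same most-recent slice they all carry 1, since sub-slice ordering
  is not observable at slice granularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ShapeError, ValidationError
from .sensor_data import ObservationMatrix

__all__ = [
    "FeatureMatrix",
    "raw",
    "change_point",
    "last_sensor",
    "concat",
    "featurize",
    "REPRESENTATIONS",
]


@dataclass
class FeatureMatrix:
    """T x M binary feature matrix with ``<representation>:<sensor>`` columns."""

    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ShapeError("feature values must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ShapeError("column_names length must match column count")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("feature entries must be 0 or 1")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def raw(obs: ObservationMatrix) -> FeatureMatrix:
    """The slice matrix unchanged."""
    return FeatureMatrix(obs.values.copy(),
                         [f"raw:{sid}" for sid in obs.sensor_ids])


def _changes(values: np.ndarray) -> np.ndarray:
    prev = np.vstack([np.zeros((1, values.shape[1]), dtype=values.dtype),
                      values[:-1]])
    return (values != prev).astype(np.uint8)


def change_point(obs: ObservationMatrix) -> FeatureMatrix:
    """1 where a sensor flips state between consecutive slices."""
    return FeatureMatrix(_changes(obs.values),
                         [f"cp:{sid}" for sid in obs.sensor_ids])


def last_sensor(obs: ObservationMatrix) -> FeatureMatrix:
    """1 on the most recently changed sensor(s), 0 elsewhere."""
    cp = _changes(obs.values)
    out = np.zeros_like(cp)
    any_change = cp.any(axis=1)
    # index of the latest row with a change, at or before each t (-1: none yet)
    latest = np.where(any_change, np.arange(cp.shape[0]), -1)
    latest = np.maximum.accumulate(latest)
    has = latest >= 0
    out[has] = cp[latest[has]]
    return FeatureMatrix(out, [f"ls:{sid}" for sid in obs.sensor_ids])


def concat(parts: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of representations sharing T."""
    if not parts:
        raise ValidationError("concat needs at least one feature matrix")
    t = parts[0].n_slices
    for p in parts[1:]:
        if p.n_slices != t:
            raise ShapeError(
                f"cannot concatenate feature matrices with {t} and "
                f"{p.n_slices} slices"
            )
    return FeatureMatrix(
        np.hstack([p.values for p in parts]),
        [name for p in parts for name in p.column_names],
    )


_BUILDERS = {"raw": raw, "cp": change_point, "ls": last_sensor}

#: The seven representation combinations used in the evaluation grids.
REPRESENTATIONS = ("raw", "cp", "ls", "raw+cp", "raw+ls", "cp+ls", "raw+cp+ls")


def featurize(obs: ObservationMatrix, representation: str) -> FeatureMatrix:
    """Build a representation from its spec string, e.g. ``"raw+cp+ls"``.

    Tokens are ``raw``, ``cp`` (change point) and ``ls`` (last sensor),
    joined by ``+``; matrices are concatenated in the order given.
    """
    parts = []
    for token in representation.split("+"):
        token = token.strip().lower()
        if token not in _BUILDERS:
            raise ValidationError(
                f"unknown representation token {token!r}; expected raw|cp|ls"
            )
        parts.append(_BUILDERS[token](obs))
    return concat(parts)
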