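"""Synthetic single-resident smart-home generator.

Emulates the statistical structure of a binary-sensor home deployment so the
whole recognition stack can be exercised without real recordings: the
resident moves through a small set of daily activities (a semi-Markov chain
whose dwell times and hour-of-day preferences are configurable), and each
activity drives every sensor with its own per-slice firing probability,
corrupted by independent bit flips.  Contiguous firing slices are merged
into timed sensor events and contiguous non-idle label runs into activity
annotations, so the generator's output looks exactly like a recorded
dataset — and discretizing it reproduces the ground-truth slice matrix
bit-exactly.

Draw order (fixed so fixtures are reproducible across versions): first the
activity schedule (alternating dwell-length and next-activity draws), then
one uniform per (slice, sensor) for firing, then one uniform per
(slice, sensor) for noise flips — all from a single seeded generator.

The packaged default configuration (:func:`small_home`) describes a home in
the shape of the smaller real deployments this generator imitates:
8 activities including idle, 12 sensors, 14 days at 60-second slices, with
one dominant resting class, a dominant sleeping class and several sub-1%
activities — the characteristic class imbalance of this domain.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Union

import numpy as np
import yaml

from .errors import ValidationError
from .hmm_core import HMMParams
from .sensor_data import (
    ActivityInterval,
    LabelSequence,
    ObservationMatrix,
    SensorEvent,
    save_discretized,
    write_activities,
    write_events,
)

__all__ = [
    "ActivitySpec",
    "SimConfig",
    "SimOutput",
    "sample_home",
    "sample_hmm",
    "write_fixture",
    "read_fixture_config",
    "small_home",
]


@dataclass
class ActivitySpec:
    """One activity: name, mean dwell (minutes) and 24 hourly weights.

    The hourly weights steer *when* the activity tends to be entered; they
    are relative (unnormalized) and evaluated at the hour the previous
    activity ends.
    """

    name: str
    mean_dwell_minutes: float
    hourly_weights: list[float] = field(default_factory=lambda: [1.0] * 24)

    def __post_init__(self) -> None:
        if self.mean_dwell_minutes <= 0:
            raise ValidationError("mean dwell must be positive")
        if len(self.hourly_weights) != 24:
            raise ValidationError("hourly_weights must have 24 entries")
        if min(self.hourly_weights) < 0:
            raise ValidationError("hourly weights must be non-negative")


@dataclass
class SimConfig:
    """Simulation configuration.

    ``activities[0]`` is the idle class.  ``fire_prob[a, s]`` is the
    per-slice Bernoulli probability that sensor ``s`` is active while
    activity ``a`` runs; ``noise_flip_prob`` independently flips each bit of
    the slice matrix afterwards.  ``dwell_mode`` is ``"geometric"``
    (memoryless dwell, matching first-order HMM assumptions) or
    ``"lognormal"`` (heavier-tailed dwell that violates them, useful for
    robustness experiments).
    """

    activities: list[ActivitySpec]
    sensor_ids: list[str]
    fire_prob: np.ndarray
    n_days: int = 14
    dt: float = 60.0
    noise_flip_prob: float = 0.02
    dwell_mode: str = "geometric"
    lognormal_sigma: float = 0.6
    start: datetime = field(default_factory=lambda: datetime(2012, 1, 2))
    seed: int = 0

    def __post_init__(self) -> None:
        self.fire_prob = np.asarray(self.fire_prob, dtype=float)
        if len(self.activities) < 2:
            raise ValidationError("need at least 2 activities (incl. idle)")
        if len(self.sensor_ids) < 1:
            raise ValidationError("need at least 1 sensor")
        if self.fire_prob.shape != (len(self.activities), len(self.sensor_ids)):
            raise ValidationError("fire_prob must be activities x sensors")
        if self.fire_prob.min() < 0 or self.fire_prob.max() > 1:
            raise ValidationError("fire_prob entries must lie in [0, 1]")
        if not (0 <= self.noise_flip_prob < 1):
            raise ValidationError("noise_flip_prob must lie in [0, 1)")
        if self.n_days < 1 or self.dt <= 0:
            raise ValidationError("n_days and dt must be positive")
        if self.dwell_mode not in ("geometric", "lognormal"):
            raise ValidationError(f"unknown dwell_mode {self.dwell_mode!r}")

    @property
    def class_names(self) -> list[str]:
        return [a.name for a in self.activities]

    # -- round-trippable document form ---------------------------------

    def to_dict(self) -> dict:
        return {
            "activities": [
                {"name": a.name, "mean_dwell_minutes": a.mean_dwell_minutes,
                 "hourly_weights": list(map(float, a.hourly_weights))}
                for a in self.activities
            ],
            "sensor_ids": list(self.sensor_ids),
            "fire_prob": self.fire_prob.tolist(),
            "n_days": self.n_days,
            "dt": self.dt,
            "noise_flip_prob": self.noise_flip_prob,
            "dwell_mode": self.dwell_mode,
            "lognormal_sigma": self.lognormal_sigma,
            "start": self.start.strftime("%Y-%m-%d %H:%M:%S"),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SimConfig":
        return cls(
            activities=[ActivitySpec(a["name"], a["mean_dwell_minutes"],
                                     list(a.get("hourly_weights", [1.0] * 24)))
                        for a in doc["activities"]],
            sensor_ids=list(doc["sensor_ids"]),
            fire_prob=np.asarray(doc["fire_prob"], dtype=float),
            n_days=int(doc.get("n_days", 14)),
            dt=float(doc.get("dt", 60.0)),
            noise_flip_prob=float(doc.get("noise_flip_prob", 0.02)),
            dwell_mode=doc.get("dwell_mode", "geometric"),
            lognormal_sigma=float(doc.get("lognormal_sigma", 0.6)),
            start=datetime.fromisoformat(doc.get("start", "2012-01-02 00:00:00")),
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, os.PathLike]) -> "SimConfig":
        with open(os.fspath(path), "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: Union[str, os.PathLike]) -> None:
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SimOutput:
    """One simulated recording: raw records plus the ground truth grid."""

    events: list[SensorEvent]
    activities: list[ActivityInterval]
    truth: tuple[ObservationMatrix, LabelSequence]
    config: SimConfig


def _draw_dwell(rng: np.random.Generator, cfg: SimConfig, mean_slices: float) -> int:
    if cfg.dwell_mode == "geometric":
        return int(rng.geometric(min(1.0, 1.0 / max(mean_slices, 1.0))))
    mu = math.log(max(mean_slices, 1.0)) - cfg.lognormal_sigma**2 / 2.0
    return max(1, int(round(rng.lognormal(mu, cfg.lognormal_sigma))))


def _schedule(rng: np.random.Generator, cfg: SimConfig, n_slices: int) -> np.ndarray:
    """Per-slice 0-based activity indices from the semi-Markov chain."""
    weights = np.array([a.hourly_weights for a in cfg.activities], dtype=float)
    slices_per_hour = max(1, int(round(3600.0 / cfg.dt)))
    start_hour = cfg.start.hour

    def draw_next(t: int, exclude: int | None) -> int:
        hour = (start_hour + t // slices_per_hour) % 24
        w = weights[:, hour].copy()
        if exclude is not None:
            w[exclude] = 0.0
        if w.sum() <= 0:
            w = np.ones(len(cfg.activities))
            if exclude is not None:
                w[exclude] = 0.0
        return int(rng.choice(len(cfg.activities), p=w / w.sum()))

    labels = np.empty(n_slices, dtype=np.int64)
    t = 0
    current = draw_next(0, exclude=None)
    while t < n_slices:
        mean_slices = cfg.activities[current].mean_dwell_minutes * 60.0 / cfg.dt
        dwell = _draw_dwell(rng, cfg, mean_slices)
        stop = min(n_slices, t + dwell)
        labels[t:stop] = current
        t = stop
        if t < n_slices:
            current = draw_next(t, exclude=current)
    return labels


def _runs(mask: np.ndarray):
    """(start, stop) slice-index pairs of maximal True runs."""
    padded = np.concatenate([[False], mask.astype(bool), [False]])
    change = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(change[::2], change[1::2]))


def sample_home(config: SimConfig, seed: int | None = None) -> SimOutput:
    """Simulate one recording; fully deterministic given (config, seed).

    ``seed`` overrides ``config.seed`` when given.
    """
    used = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(used)
    slices_per_day = int(round(86400.0 / config.dt))
    n_slices = config.n_days * slices_per_day
    n_sensors = len(config.sensor_ids)

    labels0 = _schedule(rng, config, n_slices)
    fire = rng.random((n_slices, n_sensors)) < config.fire_prob[labels0]
    if config.noise_flip_prob > 0:
        flips = rng.random((n_slices, n_sensors)) < config.noise_flip_prob
        fire ^= flips

    t0 = config.start

    def slice_time(t: int) -> datetime:
        return t0 + timedelta(seconds=float(t) * config.dt)

    events = []
    for s, sid in enumerate(config.sensor_ids):
        for start, stop in _runs(fire[:, s]):
            events.append(SensorEvent(sid, slice_time(start), slice_time(stop)))
    events.sort(key=lambda e: (e.start, e.end, e.sensor_id))

    intervals = []
    names = config.class_names
    boundaries = np.flatnonzero(np.diff(labels0)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [n_slices]])
    for a, b in zip(starts, stops):
        if labels0[a] != 0:  # idle runs stay unannotated
            intervals.append(ActivityInterval(names[labels0[a]],
                                              slice_time(a), slice_time(b)))

    obs = ObservationMatrix(fire.astype(np.uint8), list(config.sensor_ids),
                            t0, config.dt)
    seq = LabelSequence(labels0 + 1, names)
    cfg_used = SimConfig.from_dict({**config.to_dict(), "seed": used})
    return SimOutput(events, intervals, (obs, seq), cfg_used)


def sample_hmm(
    params: HMMParams, n_slices: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (X, y) directly from a Bernoulli HMM (0-based states).

    A plain generative draw from the model — handy as the ground truth of
    parameter-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    q = params.n_states
    y = np.empty(n_slices, dtype=np.int64)
    y[0] = rng.choice(q, p=params.pi)
    for t in range(1, n_slices):
        y[t] = rng.choice(q, p=params.trans[y[t - 1]])
    x = (rng.random((n_slices, params.n_features)) < params.mu[y]).astype(np.uint8)
    return x, y


def write_fixture(out_dir: Union[str, os.PathLike], sim: SimOutput) -> None:
    """Write a simulated recording as a fixture directory.

    ``events.tsv`` and ``activities.tsv`` in the standard dialect, the
    discretized truth (``observations.tsv``/``labels.tsv``/``meta.json``)
    and ``sim.json`` holding the (config, seed) pair the fixture can be
    regenerated from.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    write_events(os.path.join(out, "events.tsv"), sim.events)
    write_activities(os.path.join(out, "activities.tsv"), sim.activities)
    save_discretized(out, *sim.truth)
    with open(os.path.join(out, "sim.json"), "w", encoding="utf-8") as fh:
        json.dump(sim.config.to_dict(), fh, indent=2)


def read_fixture_config(fixture_dir: Union[str, os.PathLike]) -> SimConfig:
    """The (config, seed) a fixture directory was generated from."""
    with open(os.path.join(os.fspath(fixture_dir), "sim.json"),
              encoding="utf-8") as fh:
        return SimConfig.from_dict(json.load(fh))


def small_home(
    n_days: int = 14,
    dt: float = 60.0,
    noise_flip_prob: float = 0.02,
    seed: int = 0,
    dwell_mode: str = "geometric",
) -> SimConfig:
    """The packaged default home: 8 activities (incl. idle), 12 sensors.

    Schedules and firing profiles give the characteristic imbalance of real
    deployments (sleeping and leisure dominate; toileting, showering and
    meals are rare, minutes-long activities).  Breakfast and lunch share
    almost the same kitchen-sensor signature on purpose: per-slice
    classifiers confuse them, temporal context disambiguates.
    """
    night = [4.0] * 7 + [0.5] + [0.0] * 14 + [2.0, 4.0]
    morning = [0.0] * 6 + [2.0, 3.0, 1.0] + [0.0] * 15
    midday = [0.0] * 12 + [1.0, 3.0, 1.0] + [0.0] * 9
    daytime = [0.0] * 8 + [1.5] * 10 + [0.5] * 4 + [0.0] * 2
    evening = [0.0] * 9 + [0.5] * 7 + [2.0] * 7 + [0.5]
    waking = [0.2] * 6 + [1.0] * 17 + [0.5]

    activities = [
        ActivitySpec("Idle", 25.0, waking),
        ActivitySpec("Leaving", 150.0, daytime),
        ActivitySpec("Toileting", 4.0, waking),
        ActivitySpec("Showering", 9.0, morning),
        ActivitySpec("Sleeping", 420.0, night),
        ActivitySpec("Breakfast", 16.0, morning),
        ActivitySpec("Lunch", 25.0, midday),
        ActivitySpec("SpareTime", 130.0, evening),
    ]
    sensor_ids = [
        "bed", "bedroom_pir", "bathroom_door", "toilet_flush", "shower",
        "bathroom_pir", "fridge", "cupboard", "microwave", "kitchen_pir",
        "front_door", "living_pir",
    ]
    #                 bed   bpir  bdoor flush showr bapir fridg cupbd micro kpir  door  lpir
    fire_prob = np.array([
        [0.02, 0.05, 0.02, 0.01, 0.00, 0.03, 0.03, 0.03, 0.01, 0.10, 0.01, 0.30],  # Idle
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.04, 0.00],  # Leaving
        [0.02, 0.10, 0.70, 0.40, 0.02, 0.80, 0.01, 0.01, 0.00, 0.02, 0.00, 0.05],  # Toileting
        [0.01, 0.05, 0.35, 0.05, 0.90, 0.80, 0.00, 0.00, 0.00, 0.01, 0.00, 0.02],  # Showering
        [0.95, 0.10, 0.01, 0.00, 0.00, 0.01, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],  # Sleeping
        [0.01, 0.02, 0.01, 0.00, 0.00, 0.01, 0.40, 0.50, 0.25, 0.90, 0.00, 0.10],  # Breakfast
        [0.01, 0.02, 0.01, 0.00, 0.00, 0.01, 0.45, 0.45, 0.35, 0.90, 0.00, 0.10],  # Lunch
        [0.01, 0.03, 0.02, 0.01, 0.00, 0.02, 0.05, 0.02, 0.01, 0.08, 0.01, 0.85],  # SpareTime
    ])
    return SimConfig(
        activities=activities,
        sensor_ids=sensor_ids,
        fire_prob=fire_prob,
        n_days=n_days,
        dt=dt,
        noise_flip_prob=noise_flip_prob,
        dwell_mode=dwell_mode,
        seed=seed,
    )
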