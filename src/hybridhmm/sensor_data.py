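"""Binary sensor event streams and their time-slice discretization.

A home deployment (or the simulator) produces two kinds of timed records:
sensor activations (a reed switch held open, a PIR firing) and activity
annotations (the resident was "Sleeping" from 23:05 to 06:40).  Recognition
models operate instead on a regular time grid: the timeline is cut into
slices of length ``dt`` seconds and each slice ``t`` carries a binary vector
``x_t`` — component ``i`` is 1 iff sensor ``i`` was active at some point
during the slice — plus a single activity label ``y_t``.

Slices are half-open ``[t, t+dt)`` with 0-based row indices; a trailing
partial slice is dropped, so ``T = floor((t1 - t0)/dt)``.  Unannotated time
maps to an explicit idle class, which is always the first entry of
``class_names`` and participates in training and scoring like any other
class.  Labels are 1-based (``y_t in {1..Q}``, idle = 1).

File dialect: tab- (or comma-) separated text, ISO-8601 timestamps at second
resolution, comment/header lines starting with ``#``.  Events are
``start<TAB>end<TAB>sensor_id``; annotations are
``start<TAB>end<TAB>activity``.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence, TextIO, Union

import numpy as np

from .errors import FormatError, ShapeError, ValidationError

__all__ = [
    "SensorEvent",
    "ActivityInterval",
    "ObservationMatrix",
    "LabelSequence",
    "read_events",
    "read_activities",
    "write_events",
    "write_activities",
    "discretize",
    "split_days",
    "save_discretized",
    "load_discretized",
]

TIME_FORMAT = "%Y-%m-%d %H:%M:%S"

Source = Union[str, os.PathLike, TextIO]


@dataclass(frozen=True)
class SensorEvent:
    """One activation interval of one binary sensor."""

    sensor_id: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if not self.sensor_id:
            raise ValidationError("sensor_id must be non-empty")
        if self.end < self.start:
            raise ValidationError(
                f"event for {self.sensor_id!r} ends before it starts "
                f"({self.end} < {self.start})"
            )


@dataclass(frozen=True)
class ActivityInterval:
    """One annotated activity span."""

    label: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("activity label must be non-empty")
        if self.end < self.start:
            raise ValidationError(
                f"activity {self.label!r} ends before it starts "
                f"({self.end} < {self.start})"
            )


@dataclass
class ObservationMatrix:
    """T x N binary matrix of time slices.

    ``values[t, i]`` is 1 iff sensor ``sensor_ids[i]`` was active for at
    least one second during slice ``[t0 + t*dt, t0 + (t+1)*dt)``.
    """

    values: np.ndarray
    sensor_ids: list[str]
    t0: datetime
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ShapeError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.sensor_ids):
            raise ShapeError(
                f"matrix has {self.values.shape[1]} columns but "
                f"{len(self.sensor_ids)} sensor ids were given"
            )
        if self.values.shape[0] < 1:
            raise ShapeError("matrix must have at least one slice")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("observation entries must be 0 or 1")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelSequence:
    """Per-slice activity labels, 1-based over ``class_names``.

    ``class_names[0]`` is by convention the idle/unlabeled class (label 1).
    """

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ShapeError("labels must be a 1-D vector")
        q = len(self.class_names)
        if q < 1:
            raise ValidationError("class_names must be non-empty")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > q):
            raise ValidationError(f"labels must lie in 1..{q}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def indices(self) -> np.ndarray:
        """0-based label indices (for array indexing)."""
        return self.labels - 1

    def names(self) -> list[str]:
        return [self.class_names[i] for i in self.indices]


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _open(source: Source):
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r", encoding="utf-8"), True


def _parse_timestamp(text: str, lineno: int, what: str) -> datetime:
    try:
        return datetime.fromisoformat(text.strip())
    except ValueError:
        raise FormatError(
            f"line {lineno}: unparseable {what} timestamp {text.strip()!r}"
        ) from None


def _parse_lines(source: Source, what: str):
    """Yield (lineno, start, end, third_field) for each data line."""
    fh, close = _open(source)
    try:
        first_data = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = [f for f in line.split(",")]
            fields = [f.strip() for f in fields]
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: expected 3 delimited fields, got {len(fields)}"
                )
            if first_data:
                first_data = False
                # an optional header row: first field not a timestamp
                try:
                    datetime.fromisoformat(fields[0])
                except ValueError:
                    continue
            start = _parse_timestamp(fields[0], lineno, "start")
            end = _parse_timestamp(fields[1], lineno, "end")
            yield lineno, start, end, fields[2]
    finally:
        if close:
            fh.close()


def read_events(source: Source) -> list[SensorEvent]:
    """Read sensor activations from delimited text, sorted by start time.

    Lines are ``start<SEP>end<SEP>sensor_id`` with ``SEP`` a tab or comma
    and ISO-8601 timestamps; ``#`` lines and an optional header are skipped.
    """
    events = []
    for lineno, start, end, sid in _parse_lines(source, "event"):
        if end < start:
            raise ValidationError(
                f"line {lineno}: event for {sid!r} ends before it starts"
            )
        events.append(SensorEvent(sid, start, end))
    events.sort(key=lambda e: (e.start, e.end, e.sensor_id))
    return events


def read_activities(source: Source) -> list[ActivityInterval]:
    """Read activity annotations; overlapping intervals are a load error."""
    acts = []
    for lineno, start, end, label in _parse_lines(source, "activity"):
        if end < start:
            raise ValidationError(
                f"line {lineno}: activity {label!r} ends before it starts"
            )
        acts.append(ActivityInterval(label, start, end))
    acts.sort(key=lambda a: (a.start, a.end, a.label))
    for prev, cur in zip(acts, acts[1:]):
        if cur.start < prev.end:
            raise ValidationError(
                "overlapping activity intervals: "
                f"{prev.label!r} [{prev.start} .. {prev.end}] and "
                f"{cur.label!r} [{cur.start} .. {cur.end}]"
            )
    return acts


def _write_records(target: Source, header: str, rows: Iterable[tuple]) -> None:
    fh, close = (target, False) if hasattr(target, "write") else (
        open(os.fspath(target), "w", encoding="utf-8"), True)
    try:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    finally:
        if close:
            fh.close()


def write_events(target: Source, events: Sequence[SensorEvent]) -> None:
    """Write events in the same dialect ``read_events`` accepts."""
    _write_records(
        target,
        "# start\tend\tsensor_id",
        ((e.start.strftime(TIME_FORMAT), e.end.strftime(TIME_FORMAT), e.sensor_id)
         for e in events),
    )


def write_activities(target: Source, acts: Sequence[ActivityInterval]) -> None:
    _write_records(
        target,
        "# start\tend\tactivity",
        ((a.start.strftime(TIME_FORMAT), a.end.strftime(TIME_FORMAT), a.label)
         for a in acts),
    )


# ---------------------------------------------------------------------------
# Discretization


def _overlap_seconds(a0: float, a1: float, b0: float, b1: float) -> float:
    return min(a1, b1) - max(a0, b0)


def discretize(
    events: Sequence[SensorEvent],
    activities: Sequence[ActivityInterval],
    t0: datetime,
    t1: datetime,
    dt: float,
    sensor_ids: Sequence[str],
    class_names: Sequence[str],
    *,
    strict: bool = True,
) -> tuple[ObservationMatrix, LabelSequence]:
    """Cut ``[t0, t1)`` into slices of ``dt`` seconds and binarize.

    Entry ``(t, i)`` is 1 iff an event of sensor ``i`` overlaps slice ``t``
    by at least one second.  Each slice's label is the activity with the
    greatest temporal overlap (ties broken by earlier interval start); slices
    no activity touches get the idle class ``class_names[0]``.

    With ``strict=True`` an event naming an unknown sensor, or an annotation
    with an unknown activity, raises :class:`ValidationError`; otherwise the
    offending record is dropped with a warning.
    """
    if t1 <= t0:
        raise ValidationError("t1 must be after t0")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    span = (t1 - t0).total_seconds()
    n_slices = int(math.floor(span / dt + 1e-9))
    if n_slices < 1:
        raise ValidationError("span shorter than one slice")
    n_sensors = len(sensor_ids)
    col = {sid: i for i, sid in enumerate(sensor_ids)}
    cls = {name: k for k, name in enumerate(class_names)}

    values = np.zeros((n_slices, n_sensors), dtype=np.uint8)
    for ev in events:
        if ev.sensor_id not in col:
            if strict:
                raise ValidationError(f"event names unknown sensor {ev.sensor_id!r}")
            warnings.warn(f"dropping event of unknown sensor {ev.sensor_id!r}")
            continue
        s = (ev.start - t0).total_seconds()
        e = (ev.end - t0).total_seconds()
        first = max(0, int(math.floor(s / dt)))
        last = min(n_slices - 1, int(math.floor(e / dt)))
        for t in range(first, last + 1):
            if _overlap_seconds(s, e, t * dt, (t + 1) * dt) >= 1.0:
                values[t, col[ev.sensor_id]] = 1

    # best (overlap, -start) per slice; idle where nothing overlaps
    labels = np.ones(n_slices, dtype=np.int64)
    best_ovl = np.zeros(n_slices)
    best_start = np.full(n_slices, np.inf)
    for act in activities:
        if act.label not in cls:
            if strict:
                raise ValidationError(f"annotation names unknown activity {act.label!r}")
            warnings.warn(f"dropping annotation of unknown activity {act.label!r}")
            continue
        s = (act.start - t0).total_seconds()
        e = (act.end - t0).total_seconds()
        first = max(0, int(math.floor(s / dt)))
        last = min(n_slices - 1, int(math.floor(e / dt)))
        for t in range(first, last + 1):
            ovl = _overlap_seconds(s, e, t * dt, (t + 1) * dt)
            if ovl <= 0:
                continue
            if ovl > best_ovl[t] or (ovl == best_ovl[t] and s < best_start[t]):
                best_ovl[t] = ovl
                best_start[t] = s
                labels[t] = cls[act.label] + 1

    obs = ObservationMatrix(values, list(sensor_ids), t0, float(dt))
    seq = LabelSequence(labels, list(class_names))
    return obs, seq


def split_days(
    obs: ObservationMatrix, labels: LabelSequence
) -> list[tuple[ObservationMatrix, LabelSequence]]:
    """Split a discretized recording into midnight-to-midnight days.

    Day boundaries fall on calendar midnights of the (timezone-naive) local
    clock; each returned pair is an independent sequence.  Partial first or
    last days are kept as (shorter) days.
    """
    if obs.n_slices != len(labels):
        raise ShapeError("observation matrix and labels differ in length")
    out = []
    start = 0
    while start < obs.n_slices:
        t_start = obs.t0 + timedelta(seconds=start * obs.dt)
        next_midnight = datetime.combine(
            t_start.date() + timedelta(days=1), datetime.min.time()
        )
        n = int(math.ceil(((next_midnight - t_start).total_seconds()) / obs.dt - 1e-9))
        stop = min(obs.n_slices, start + max(n, 1))
        out.append(
            (
                ObservationMatrix(
                    obs.values[start:stop], obs.sensor_ids, t_start, obs.dt
                ),
                LabelSequence(labels.labels[start:stop], labels.class_names),
            )
        )
        start = stop
    return out


# ---------------------------------------------------------------------------
# Matrix export: delimited text + JSON sidecar


def save_discretized(
    out_dir: Union[str, os.PathLike], obs: ObservationMatrix, labels: LabelSequence
) -> None:
    """Write ``observations.tsv``, ``labels.tsv`` and ``meta.json``."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    np.savetxt(os.path.join(out, "observations.tsv"), obs.values, fmt="%d",
               delimiter="\t")
    np.savetxt(os.path.join(out, "labels.tsv"), labels.labels, fmt="%d")
    meta = {
        "sensor_ids": obs.sensor_ids,
        "class_names": labels.class_names,
        "t0": obs.t0.strftime(TIME_FORMAT),
        "dt": obs.dt,
    }
    with open(os.path.join(out, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def load_discretized(
    in_dir: Union[str, os.PathLike]
) -> tuple[ObservationMatrix, LabelSequence]:
    src = os.fspath(in_dir)
    with open(os.path.join(src, "meta.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    values = np.loadtxt(os.path.join(src, "observations.tsv"), dtype=np.uint8,
                        delimiter="\t", ndmin=2)
    labels = np.loadtxt(os.path.join(src, "labels.tsv"), dtype=np.int64, ndmin=1)
    obs = ObservationMatrix(values, list(meta["sensor_ids"]),
                            datetime.fromisoformat(meta["t0"]), float(meta["dt"]))
    return obs, LabelSequence(labels, list(meta["class_names"]))
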