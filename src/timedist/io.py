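"""Data model for treadmill sessions and spike trains, plus readers/writers.

Two on-disk dialects are supported:

* a **portable dialect** — ``sessions.json`` (run schedule and session metadata),
  ``spikes.csv`` (one spike per row) and an optional ``ground_truth.csv`` with
  generator labels.  This is what the synthetic generator emits and what the
  test-suite round-trips.
* **MAT files** (v5 via :mod:`scipy.io`, v7.3/HDF5 via :mod:`h5py`) as deposited
  by electrophysiology studies.  Because archive-internal variable names vary,
  the caller supplies a ``field_map`` from logical names to variable names.

All times are seconds on an absolute session clock with t=0 at session start;
velocities are cm/s and constant within a run.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TimedistError",
    "ValidationError",
    "ConfigError",
    "DegenerateDesignError",
    "FIXED_TIME",
    "FIXED_DISTANCE",
    "SESSION_TYPES",
    "CELL_LABELS",
    "CONSISTENCY_RTOL",
    "Run",
    "Session",
    "SpikeTrain",
    "Dataset",
    "read_portable",
    "write_portable",
    "read_mat_dataset",
]


class TimedistError(Exception):
    """Base class for all package errors."""


class ValidationError(TimedistError):
    """An input object violates a structural invariant."""


class ConfigError(TimedistError):
    """A configuration entry is missing, unknown, or points nowhere."""


class DegenerateDesignError(TimedistError):
    """A statistical fit was requested on a degenerate design (e.g. one velocity)."""


FIXED_TIME = "fixed_time"
FIXED_DISTANCE = "fixed_distance"
SESSION_TYPES = (FIXED_TIME, FIXED_DISTANCE)

CELL_LABELS = ("time", "distance", "conjunctive", "untuned")

#: Relative tolerance for within-session consistency of run durations
#: (fixed-time) or run distances (fixed-distance); allows treadmill control jitter.
CONSISTENCY_RTOL = 0.02


@dataclass(frozen=True)
class Run:
    """One treadmill run at constant belt velocity.

    ``analysis_cap``, when set, limits the per-run analysis window to that many
    seconds after run start (used by the common-horizon truncation of the
    shuffle test); it is an analysis-time attribute, not part of the recorded
    schedule, and is not serialized.
    """

    run_index: int
    start_time: float
    stop_time: float
    velocity: float
    analysis_cap: float | None = None

    def __post_init__(self) -> None:
        if self.run_index < 0:
            raise ValidationError(f"run_index must be >= 0, got {self.run_index}")
        if not (math.isfinite(self.start_time) and math.isfinite(self.stop_time)):
            raise ValidationError("run start/stop times must be finite")
        if not self.stop_time > self.start_time:
            raise ValidationError(
                f"run {self.run_index}: stop_time ({self.stop_time}) must exceed "
                f"start_time ({self.start_time})"
            )
        if not self.velocity > 0:
            raise ValidationError(f"run {self.run_index}: velocity must be > 0")

    @property
    def duration(self) -> float:
        return self.stop_time - self.start_time

    @property
    def distance(self) -> float:
        """Belt distance traversed during the run, cm."""
        return self.duration * self.velocity

    @property
    def effective_duration(self) -> float:
        """Run duration after any truncation cap."""
        if self.analysis_cap is not None:
            return min(self.duration, self.analysis_cap)
        return self.duration

    @property
    def capped(self) -> bool:
        return self.analysis_cap is not None and self.duration > self.analysis_cap


@dataclass
class Session:
    """A recording session: an ordered, non-overlapping run schedule plus metadata."""

    session_id: str
    animal_id: str
    session_type: str
    runs: list[Run]

    def __post_init__(self) -> None:
        if self.session_type not in SESSION_TYPES:
            raise ValidationError(
                f"session {self.session_id}: session_type must be one of "
                f"{SESSION_TYPES}, got {self.session_type!r}"
            )
        if not self.runs:
            raise ValidationError(f"session {self.session_id}: needs at least one run")
        for prev, cur in zip(self.runs, self.runs[1:]):
            if cur.start_time < prev.stop_time:
                raise ValidationError(
                    f"session {self.session_id}: runs {prev.run_index} and "
                    f"{cur.run_index} overlap or are out of order"
                )
        # Type-consistency on the *recorded* schedule (caps are analysis-time).
        if self.session_type == FIXED_TIME:
            values = np.array([r.duration for r in self.runs])
            what = "duration"
        else:
            values = np.array([r.distance for r in self.runs])
            what = "distance"
        mean = values.mean()
        if mean > 0 and np.abs(values - mean).max() > CONSISTENCY_RTOL * mean:
            raise ValidationError(
                f"session {self.session_id}: run {what}s vary by more than "
                f"{CONSISTENCY_RTOL:.0%} in a {self.session_type} session"
            )


@dataclass
class SpikeTrain:
    """Absolute spike times (s) of one cell within one session."""

    cell_id: str
    session_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValidationError(f"cell {self.cell_id}: spike_times must be 1-D")
        if t.size and not np.all(np.isfinite(t)):
            raise ValidationError(f"cell {self.cell_id}: spike_times must be finite")
        if t.size and t.min() < 0:
            raise ValidationError(f"cell {self.cell_id}: spike_times must be >= 0")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValidationError(
                f"cell {self.cell_id}: spike_times must be nondecreasing"
            )
        object.__setattr__(self, "spike_times", t)


@dataclass
class Dataset:
    """Sessions plus spike trains; ground-truth labels only for synthetic data."""

    sessions: list[Session]
    spike_trains: list[SpikeTrain]
    ground_truth: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [s.session_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate session_id in dataset")
        known = set(ids)
        for st in self.spike_trains:
            if st.session_id not in known:
                raise ValidationError(
                    f"spike train {st.cell_id}: unknown session_id {st.session_id!r}"
                )
        if self.ground_truth is not None:
            for cell, label in self.ground_truth.items():
                if label not in CELL_LABELS:
                    raise ValidationError(
                        f"ground_truth[{cell!r}]: unknown label {label!r}"
                    )

    def session(self, session_id: str) -> Session:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)


# ---------------------------------------------------------------------------
# Portable dialect
# ---------------------------------------------------------------------------

def write_portable(dataset: Dataset, directory: str | Path) -> None:
    """Write ``sessions.json``, ``spikes.csv`` (+ ``ground_truth.csv``).

    Output bytes are deterministic for a fixed dataset.  Spike trains with no
    spikes have no row representation in ``spikes.csv`` and are therefore not
    recoverable by :func:`read_portable`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    payload = [
        {
            "session_id": s.session_id,
            "animal_id": s.animal_id,
            "session_type": s.session_type,
            "runs": [
                {
                    "run_index": r.run_index,
                    "start_time": r.start_time,
                    "stop_time": r.stop_time,
                    "velocity": r.velocity,
                }
                for r in s.runs
            ],
        }
        for s in dataset.sessions
    ]
    with open(directory / "sessions.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")

    with open(directory / "spikes.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["cell_id", "session_id", "spike_time"])
        for st in dataset.spike_trains:
            for t in st.spike_times:
                writer.writerow([st.cell_id, st.session_id, repr(float(t))])

    if dataset.ground_truth is not None:
        with open(directory / "ground_truth.csv", "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["cell_id", "label"])
            for cell_id in sorted(dataset.ground_truth):
                writer.writerow([cell_id, dataset.ground_truth[cell_id]])


def read_portable(directory: str | Path) -> Dataset:
    """Read a portable-dialect directory back into a validated :class:`Dataset`."""
    directory = Path(directory)
    sessions_path = directory / "sessions.json"
    spikes_path = directory / "spikes.csv"
    if not sessions_path.exists():
        raise ConfigError(f"missing {sessions_path}")
    if not spikes_path.exists():
        raise ConfigError(f"missing {spikes_path}")

    with open(sessions_path, encoding="utf-8") as fh:
        payload = json.load(fh)
    sessions = []
    for entry in payload:
        try:
            runs = [
                Run(
                    run_index=int(r["run_index"]),
                    start_time=float(r["start_time"]),
                    stop_time=float(r["stop_time"]),
                    velocity=float(r["velocity"]),
                )
                for r in entry["runs"]
            ]
            sessions.append(
                Session(
                    session_id=str(entry["session_id"]),
                    animal_id=str(entry["animal_id"]),
                    session_type=str(entry["session_type"]),
                    runs=runs,
                )
            )
        except KeyError as exc:
            raise ValidationError(
                f"sessions.json: missing field {exc.args[0]!r}"
            ) from exc

    trains: list[SpikeTrain] = []
    order: dict[tuple[str, str], list[float]] = {}
    with open(spikes_path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"cell_id", "session_id", "spike_time"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise ValidationError(
                f"spikes.csv: header must contain fields {sorted(expected)}"
            )
        for row in reader:
            key = (row["cell_id"], row["session_id"])
            order.setdefault(key, []).append(float(row["spike_time"]))
    for (cell_id, session_id), times in order.items():
        trains.append(
            SpikeTrain(cell_id=cell_id, session_id=session_id,
                       spike_times=np.asarray(times))
        )

    ground_truth = None
    gt_path = directory / "ground_truth.csv"
    if gt_path.exists():
        ground_truth = {}
        with open(gt_path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"cell_id", "label"}.issubset(
                reader.fieldnames
            ):
                raise ValidationError("ground_truth.csv: header must be cell_id,label")
            for row in reader:
                ground_truth[row["cell_id"]] = row["label"]

    return Dataset(sessions=sessions, spike_trains=trains, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# MAT dialect
# ---------------------------------------------------------------------------

_FIELD_MAP_REQUIRED = ("spike_times", "velocities")


def _load_mat_variables(path: Path, names: list[str]) -> dict[str, object]:
    """Load the named variables from a MAT file (v5 or v7.3)."""
    try:
        from scipy.io import loadmat

        mat = loadmat(path, simplify_cells=True)
        return {k: v for k, v in mat.items() if not k.startswith("__")}
    except NotImplementedError:
        pass  # v7.3: HDF5 container
    except (OSError, ValueError) as exc:
        raise TimedistError(f"could not parse MAT file {path}: {exc}") from exc

    import h5py

    out: dict[str, object] = {}
    with h5py.File(path, "r") as fh:
        def fetch(node):
            data = node[()]
            if isinstance(data, np.ndarray) and data.dtype == object:
                # cell array of object references
                return [np.squeeze(np.asarray(fh[ref])) for ref in data.ravel()]
            return np.squeeze(np.asarray(data))

        for name in names:
            if name in fh:
                out[name] = fetch(fh[name])
    return out


def read_mat_dataset(
    path: str | Path,
    field_map: dict[str, str],
    *,
    session_id: str | None = None,
    animal_id: str = "unknown",
    session_type: str | None = None,
) -> Dataset:
    """Read a single-session MAT file using a logical-name → variable-name map.

    ``field_map`` must provide ``spike_times`` (cell array / list of per-neuron
    spike-time vectors) and ``velocities`` (per-run, cm/s), plus either
    ``run_intervals`` (n_runs × 2 start/stop matrix) or both ``run_starts`` and
    ``run_stops``.  Optional entries: ``cell_ids``, ``session_type`` (variable
    holding the type string), ``time_scale`` and ``velocity_scale`` (numeric
    conversion factors into seconds / cm/s, default 1.0).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"MAT file not found: {path}")

    time_scale = float(field_map.get("time_scale", 1.0))
    velocity_scale = float(field_map.get("velocity_scale", 1.0))
    var_names = [
        v for k, v in field_map.items() if k not in ("time_scale", "velocity_scale")
    ]
    variables = _load_mat_variables(path, var_names)

    def need(logical: str):
        var = field_map.get(logical)
        if var is None:
            raise ConfigError(f"field_map is missing required entry {logical!r}")
        if var not in variables:
            raise ConfigError(
                f"variable {var!r} (field_map entry {logical!r}) not found in {path}"
            )
        return variables[var]

    for logical in _FIELD_MAP_REQUIRED:
        need(logical)

    if "run_intervals" in field_map:
        intervals = np.atleast_2d(np.asarray(need("run_intervals"), dtype=float))
        if intervals.shape[1] != 2 and intervals.shape[0] == 2:
            intervals = intervals.T
        starts, stops = intervals[:, 0], intervals[:, 1]
    else:
        starts = np.atleast_1d(np.asarray(need("run_starts"), dtype=float)).ravel()
        stops = np.atleast_1d(np.asarray(need("run_stops"), dtype=float)).ravel()
    velocities = np.atleast_1d(np.asarray(need("velocities"), dtype=float)).ravel()
    if not (len(starts) == len(stops) == len(velocities)):
        raise ValidationError(
            f"{path}: run starts ({len(starts)}), stops ({len(stops)}) and "
            f"velocities ({len(velocities)}) disagree in length"
        )

    starts = starts * time_scale
    stops = stops * time_scale
    velocities = velocities * velocity_scale

    if session_type is None and "session_type" in field_map:
        raw = variables.get(field_map["session_type"])
        if raw is not None:
            session_type = str(np.squeeze(np.asarray(raw)))
    if session_type is None:
        raise ConfigError(
            "session_type must be given as a keyword or via field_map['session_type']"
        )

    sid = session_id if session_id is not None else path.stem
    runs = [
        Run(run_index=i, start_time=float(a), stop_time=float(b), velocity=float(v))
        for i, (a, b, v) in enumerate(zip(starts, stops, velocities))
    ]
    session = Session(
        session_id=sid, animal_id=animal_id, session_type=session_type, runs=runs
    )

    raw_trains = need("spike_times")
    if isinstance(raw_trains, np.ndarray) and raw_trains.dtype == object:
        raw_trains = list(raw_trains.ravel())
    elif np.isscalar(raw_trains) or (
        isinstance(raw_trains, np.ndarray) and raw_trains.ndim <= 1
    ):
        # single neuron stored as a plain vector (or collapsed to a scalar)
        raw_trains = [np.atleast_1d(raw_trains)]
    cell_ids = None
    if "cell_ids" in field_map and field_map["cell_ids"] in variables:
        raw_ids = variables[field_map["cell_ids"]]
        cell_ids = [str(x) for x in np.atleast_1d(np.asarray(raw_ids)).ravel()]
    trains = []
    for i, vec in enumerate(raw_trains):
        times = np.sort(np.atleast_1d(np.asarray(vec, dtype=float)).ravel()) * time_scale
        cid = cell_ids[i] if cell_ids is not None else f"{sid}-c{i:03d}"
        trains.append(SpikeTrain(cell_id=cid, session_id=sid, spike_times=times))

    return Dataset(sessions=[session], spike_trains=trains)


def replace_runs(session: Session, runs: list[Run]) -> Session:
    """Session copy with a new run list (used by truncation)."""
    return Session(
        session_id=session.session_id,
        animal_id=session.animal_id,
        session_type=session.session_type,
        runs=runs,
    )
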