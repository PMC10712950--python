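"""Synthetic treadmill sessions with ground-truth time/distance/conjunctive/untuned cells.

The generator emulates the statistical structure the downstream analysis
assumes: sessions of 31–57 constant-velocity runs with velocities drawn
uniformly from 35–49 cm/s, operated either for a fixed duration (default 16 s)
or a fixed belt distance (default 600 cm, so durations straddle 16 s over the
velocity range), and per-cell inhomogeneous-Poisson spike trains.

Rate models (t is time from run start, d = V·t the belt distance):

* time cell        λ(t) = b + (p−b)·exp(−(t − (t* + δ))² / 2σ_t²)
* distance cell    λ(t) = b + (p−b)·exp(−(d − d*)² / 2σ_d²), center jittered by δ in time
* conjunctive      λ(t) = b + min(time term, distance term)
* untuned          λ(t) = b

with baseline b, peak p, per-run temporal jitter δ ~ N(0, onset_jitter_sd²).
Between runs the rate is the baseline.  Spikes are drawn by thinning a
homogeneous Poisson process at the peak rate, which bounds every rate above.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import (
    CELL_LABELS,
    FIXED_DISTANCE,
    FIXED_TIME,
    Dataset,
    Run,
    Session,
    SpikeTrain,
    ValidationError,
)

__all__ = [
    "ScheduleParams",
    "CellParams",
    "sample_runs",
    "simulate_cell_spikes",
    "generate_dataset",
    "derive_seed",
]

#: run-count range observed per session in the study conditions
RUN_RANGE = (31, 57)


def derive_seed(master: int, *parts: object) -> int:
    """Stable per-entity seed below 2**31 derived from a master seed."""
    h = zlib.crc32(repr((int(master),) + tuple(str(p) for p in parts)).encode())
    return int(h % (2**31 - 1))


@dataclass
class ScheduleParams:
    """Treadmill schedule for one synthetic session."""

    n_runs: int = 40
    velocity_range: tuple[float, float] = (35.0, 49.0)
    session_type: str = FIXED_TIME
    fixed_duration: float = 16.0          # s, fixed_time sessions
    fixed_distance: float = 600.0         # cm, fixed_distance sessions
    inter_run_interval: float = 10.0      # s between stop and next start
    seed: int | None = None               # None → derived by generate_dataset
    session_id: str | None = None
    animal_id: str = "synthetic"
    enforce_run_range: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.velocity_range
        if not (0 < lo <= hi):
            raise ValidationError("velocity_range must satisfy 0 < v_min <= v_max")
        if self.enforce_run_range and not (RUN_RANGE[0] <= self.n_runs <= RUN_RANGE[1]):
            raise ValidationError(
                f"n_runs={self.n_runs} outside the default session range "
                f"{RUN_RANGE}; pass enforce_run_range=False to override"
            )
        if self.n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        if self.inter_run_interval <= 0:
            raise ValidationError("inter_run_interval must be > 0")


@dataclass
class CellParams:
    """Tuning parameters of one synthetic unit.

    ``field_width_time`` (s) and ``field_width_distance`` (cm) are the Gaussian
    tuning σ in each dimension; only the one matching ``label`` is used except
    for conjunctive cells, which use both.
    """

    label: str = "untuned"
    preferred_time: float | None = None       # s from run start
    preferred_distance: float | None = None   # cm from run start
    field_width_time: float = 0.5             # s
    field_width_distance: float = 20.0        # cm
    peak_rate: float = 20.0                   # Hz
    baseline_rate: float = 0.5                # Hz
    onset_jitter_sd: float = 0.2              # s, per-run center jitter

    def __post_init__(self) -> None:
        if self.label not in CELL_LABELS:
            raise ValidationError(f"unknown cell label {self.label!r}")
        if not self.peak_rate > self.baseline_rate >= 0:
            if self.label == "untuned" and self.peak_rate == self.baseline_rate:
                pass  # degenerate homogeneous unit is allowed
            else:
                raise ValidationError("need peak_rate > baseline_rate >= 0")
        if self.field_width_time <= 0 or self.field_width_distance <= 0:
            raise ValidationError("field widths must be > 0")
        if self.label in ("time", "conjunctive") and self.preferred_time is None:
            raise ValidationError(f"{self.label} cell needs preferred_time")
        if self.label in ("distance", "conjunctive") and self.preferred_distance is None:
            raise ValidationError(f"{self.label} cell needs preferred_distance")


def sample_runs(params: ScheduleParams) -> Session:
    """Draw a run schedule; velocities i.i.d. uniform on the velocity range."""
    if params.seed is None:
        raise ValidationError(
            "ScheduleParams.seed is unset; set it or go through generate_dataset"
        )
    rng = np.random.default_rng(params.seed)
    lo, hi = params.velocity_range
    velocities = rng.uniform(lo, hi, size=params.n_runs)
    if params.session_type == FIXED_TIME:
        durations = np.full(params.n_runs, float(params.fixed_duration))
    elif params.session_type == FIXED_DISTANCE:
        durations = params.fixed_distance / velocities
    else:
        raise ValidationError(f"unknown session_type {params.session_type!r}")

    runs = []
    t = params.inter_run_interval  # lead-in so run 0 has a pre-run baseline epoch
    for i in range(params.n_runs):
        runs.append(
            Run(
                run_index=i,
                start_time=float(t),
                stop_time=float(t + durations[i]),
                velocity=float(velocities[i]),
            )
        )
        t += durations[i] + params.inter_run_interval

    sid = params.session_id or f"{params.session_type}-seed{params.seed}"
    return Session(
        session_id=sid,
        animal_id=params.animal_id,
        session_type=params.session_type,
        runs=runs,
    )


def _rate_in_run(
    t_rel: np.ndarray, velocity: float, cell: CellParams, delta: float
) -> np.ndarray:
    """Tuned rate above baseline for in-run relative times (Hz)."""
    amp = cell.peak_rate - cell.baseline_rate
    if cell.label == "untuned" or amp <= 0:
        return np.zeros_like(t_rel)
    terms = []
    if cell.label in ("time", "conjunctive"):
        center = cell.preferred_time + delta
        terms.append(np.exp(-0.5 * ((t_rel - center) / cell.field_width_time) ** 2))
    if cell.label in ("distance", "conjunctive"):
        d = velocity * t_rel
        center = cell.preferred_distance + velocity * delta
        terms.append(np.exp(-0.5 * ((d - center) / cell.field_width_distance) ** 2))
    tuned = terms[0] if len(terms) == 1 else np.minimum(terms[0], terms[1])
    return amp * tuned


def simulate_cell_spikes(session: Session, cell: CellParams, seed: int) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train over the whole session span.

    Thinning against the constant envelope λ_max = peak_rate (an exact upper
    bound of every rate model used), so the draw is exact.
    """
    if cell.preferred_time is not None:
        max_dur = max(r.duration for r in session.runs)
        if cell.preferred_time > max_dur:
            import warnings

            warnings.warn(
                f"preferred_time {cell.preferred_time} s exceeds every run duration "
                f"({max_dur:.1f} s); the cell may never fire in-window",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    span = session.runs[-1].stop_time + 6.0
    lam_max = max(cell.peak_rate, cell.baseline_rate, 1e-12)

    n_cand = rng.poisson(lam_max * span)
    t_cand = np.sort(rng.uniform(0.0, span, size=n_cand))
    u = rng.uniform(0.0, lam_max, size=n_cand)
    deltas = rng.normal(0.0, cell.onset_jitter_sd, size=len(session.runs))

    rate = np.full(n_cand, float(cell.baseline_rate))
    starts = np.array([r.start_time for r in session.runs])
    stops = np.array([r.stop_time for r in session.runs])
    idx = np.searchsorted(starts, t_cand, side="right") - 1
    for k, run in enumerate(session.runs):
        mask = (idx == k) & (t_cand < stops[k])
        if not mask.any():
            continue
        t_rel = t_cand[mask] - run.start_time
        rate[mask] += _rate_in_run(t_rel, run.velocity, cell, deltas[k])

    accepted = t_cand[u < rate]
    return SpikeTrain(cell_id="", session_id=session.session_id, spike_times=accepted)


def generate_dataset(
    schedules: list[ScheduleParams],
    population: list[CellParams] | list[list[CellParams]],
    seed: int,
) -> Dataset:
    """Simulate all sessions and cells; ground truth filled; fully seeded.

    ``population`` may be a flat list (same cell battery in every session) or a
    list of per-session lists.  Cells are per-session units: each (session,
    cell-params) pair yields one spike train with its own derived seed.
    """
    if not schedules or not population:
        raise ValidationError("schedules and population must be nonempty")
    per_session: list[list[CellParams]]
    if isinstance(population[0], CellParams):
        per_session = [list(population)] * len(schedules)  # type: ignore[arg-type]
    else:
        per_session = [list(p) for p in population]  # type: ignore[union-attr]
        if len(per_session) != len(schedules):
            raise ValidationError("per-session population list length mismatch")

    sessions: list[Session] = []
    trains: list[SpikeTrain] = []
    ground_truth: dict[str, str] = {}
    for s_idx, sched in enumerate(schedules):
        if sched.session_id is None:
            sched = ScheduleParams(**{**sched.__dict__, "session_id": f"s{s_idx:02d}"})
        if sched.seed is None:
            sched = ScheduleParams(
                **{**sched.__dict__, "seed": derive_seed(seed, "schedule", sched.session_id)}
            )
        session = sample_runs(sched)
        sessions.append(session)
        for c_idx, cell in enumerate(per_session[s_idx]):
            cell_id = f"{session.session_id}-c{c_idx:03d}"
            train = simulate_cell_spikes(
                session, cell, derive_seed(seed, "spikes", session.session_id, c_idx)
            )
            train.cell_id = cell_id
            trains.append(train)
            ground_truth[cell_id] = cell.label

    return Dataset(sessions=sessions, spike_trains=trains, ground_truth=ground_truth)
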