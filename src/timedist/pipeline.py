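"""End-to-end orchestration: config, staged execution, artifact files, sweeps.

The pipeline is deterministic given (input bytes, master seed): every stage
seed is derived by stable hashing of (master seed, stage name, entity id), and
each output file carries the config hash and the seed in ``stats.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import population as pop
from .detect import DetectionConfig, onset_tables_to_frame
from .io import (
    FIXED_DISTANCE,
    FIXED_TIME,
    ConfigError,
    Dataset,
    TimedistError,
    ValidationError,
    read_mat_dataset,
    read_portable,
    write_portable,
)
from .metrics import METRICS, results_to_frame
from .synth import CellParams, ScheduleParams, generate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "sweep", "load_dataset"]

log = logging.getLogger("timedist")


class PipelineError(TimedistError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Flat key-value configuration; unknown keys in a config file are errors."""

    # input
    input_kind: str = "synthetic"           # synthetic | portable | mat
    input_path: str | None = None           # portable dir or MAT file
    mat_field_map: dict | None = None       # mat input only
    session_type: str | None = None         # mat input only
    animal_id: str = "unknown"              # mat input only
    # synthetic generation
    n_sessions_fixed_time: int = 1
    n_sessions_fixed_distance: int = 1
    n_runs: int = 40
    v_min: float = 35.0
    v_max: float = 49.0
    fixed_duration: float = 16.0
    fixed_distance: float = 600.0
    inter_run_interval: float = 10.0
    n_time_cells: int = 10
    n_distance_cells: int = 10
    n_conjunctive_cells: int = 0
    n_untuned_cells: int = 5
    peak_rate: float = 20.0
    baseline_rate: float = 0.5
    field_width_time: float = 0.5
    field_width_distance: float = 20.0
    onset_jitter_sd: float = 0.2
    align_cells_to_session_type: bool = True
    # detection / classification
    bin_width: float = 0.1
    extension: float = 5.0
    silence: float = 1.0
    anchor: str = "onset"
    metric: str = "celltype"
    alpha: float = 0.05
    min_runs: int = 10
    min_peak_rate: float = 0.5
    distance_weight: str = "inverse_square_velocity"
    # shuffle
    shuffle_n: int = 1000
    shuffle_horizon: float = 16.0
    # misc
    seed: int = 0
    out_dir: str = "timedist_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # analysis-irrelevant
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _synthetic_population(cfg: PipelineConfig, session_type: str) -> list[CellParams]:
    """Cell battery for one session; tuned cells' preferred values are spread
    deterministically over ranges well inside every run."""
    cells: list[CellParams] = []

    def spread(lo, hi, n, i):
        return lo + (hi - lo) * (i + 0.5) / n if n > 0 else lo

    want_time = cfg.n_time_cells
    want_dist = cfg.n_distance_cells
    if cfg.align_cells_to_session_type:
        if session_type == FIXED_TIME:
            want_dist = 0
        else:
            want_time = 0
    for i in range(want_time):
        cells.append(
            CellParams(
                label="time",
                preferred_time=spread(3.0, 9.0, want_time, i),
                field_width_time=cfg.field_width_time,
                peak_rate=cfg.peak_rate,
                baseline_rate=cfg.baseline_rate,
                onset_jitter_sd=cfg.onset_jitter_sd,
            )
        )
    for i in range(want_dist):
        cells.append(
            CellParams(
                label="distance",
                preferred_distance=spread(150.0, 450.0, want_dist, i),
                field_width_distance=cfg.field_width_distance,
                peak_rate=cfg.peak_rate,
                baseline_rate=cfg.baseline_rate,
                onset_jitter_sd=cfg.onset_jitter_sd,
            )
        )
    for i in range(cfg.n_conjunctive_cells):
        cells.append(
            CellParams(
                label="conjunctive",
                preferred_time=spread(3.0, 9.0, cfg.n_conjunctive_cells, i),
                preferred_distance=spread(150.0, 450.0, cfg.n_conjunctive_cells, i),
                field_width_time=cfg.field_width_time,
                field_width_distance=cfg.field_width_distance,
                peak_rate=cfg.peak_rate,
                baseline_rate=cfg.baseline_rate,
                onset_jitter_sd=cfg.onset_jitter_sd,
            )
        )
    for _ in range(cfg.n_untuned_cells):
        cells.append(CellParams(label="untuned", baseline_rate=cfg.baseline_rate,
                                peak_rate=cfg.baseline_rate))
    return cells


def load_dataset(cfg: PipelineConfig) -> Dataset:
    """Input stage: synthesize, or read portable/MAT input."""
    if cfg.input_kind == "synthetic":
        schedules = []
        pops = []
        idx = 0
        for _ in range(cfg.n_sessions_fixed_time):
            schedules.append(
                ScheduleParams(
                    n_runs=cfg.n_runs,
                    velocity_range=(cfg.v_min, cfg.v_max),
                    session_type=FIXED_TIME,
                    fixed_duration=cfg.fixed_duration,
                    inter_run_interval=cfg.inter_run_interval,
                    session_id=f"ft{idx:02d}",
                    animal_id=f"synthA{idx % 3}",
                    enforce_run_range=False,
                )
            )
            pops.append(_synthetic_population(cfg, FIXED_TIME))
            idx += 1
        for _ in range(cfg.n_sessions_fixed_distance):
            schedules.append(
                ScheduleParams(
                    n_runs=cfg.n_runs,
                    velocity_range=(cfg.v_min, cfg.v_max),
                    session_type=FIXED_DISTANCE,
                    fixed_distance=cfg.fixed_distance,
                    inter_run_interval=cfg.inter_run_interval,
                    session_id=f"fd{idx:02d}",
                    animal_id=f"synthA{idx % 3}",
                    enforce_run_range=False,
                )
            )
            pops.append(_synthetic_population(cfg, FIXED_DISTANCE))
            idx += 1
        return generate_dataset(schedules, pops, seed=cfg.seed)
    if cfg.input_kind == "portable":
        if cfg.input_path is None:
            raise ConfigError("portable input needs input_path")
        return read_portable(cfg.input_path)
    if cfg.input_kind == "mat":
        if cfg.input_path is None or cfg.mat_field_map is None:
            raise ConfigError("mat input needs input_path and mat_field_map")
        return read_mat_dataset(
            cfg.input_path,
            cfg.mat_field_map,
            session_type=cfg.session_type,
            animal_id=cfg.animal_id,
        )
    raise ConfigError(f"unknown input_kind {cfg.input_kind!r}")


def _detection_config(cfg: PipelineConfig) -> DetectionConfig:
    return DetectionConfig(
        bin_width=cfg.bin_width,
        extension=cfg.extension,
        silence=cfg.silence,
        min_runs=cfg.min_runs,
        min_peak_rate=cfg.min_peak_rate,
        anchor=cfg.anchor,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages, write artifacts under ``cfg.out_dir``, return the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        dataset = load_dataset(cfg)
    except TimedistError as exc:
        raise PipelineError("sessions_io", str(exc)) from exc
    if cfg.input_kind == "synthetic":
        write_portable(dataset, out / "dataset")

    try:
        det_cfg = _detection_config(cfg)
        tables, results = pop.classify_dataset(
            dataset,
            config=det_cfg,
            metric=cfg.metric,
            alpha=cfg.alpha,
            distance_weight=cfg.distance_weight,
        )
    except TimedistError as exc:
        raise PipelineError("response_detection", str(exc)) from exc

    onset_tables_to_frame(tables).to_csv(out / "onsets.csv", index=False)
    results_to_frame(results).to_csv(out / "encoding.csv", index=False)

    exclusions: dict[str, int] = {}
    for t in tables:
        if not t.included:
            exclusions[t.exclusion_reason or "unknown"] = (
                exclusions.get(t.exclusion_reason or "unknown", 0) + 1
            )
    log.info(
        "inclusion: %d/%d cells included; exclusions: %s",
        len(results), len(tables), exclusions or "none",
    )

    summary: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "metric": cfg.metric,
        "anchor": cfg.anchor,
        "distance_weight": cfg.distance_weight,
        "n_cells_input": len(tables),
        "n_cells_included": len(results),
        "exclusions": exclusions,
        "shuffle_statistic": "tdi(fixed_distance) - tdi(fixed_time)",
    }

    try:
        tallies = pop.tally_results(results, metric=cfg.metric)
        rows = []
        for t in tallies:
            rows.append(
                {
                    "group": "|".join(t.group_key),
                    "n_distance": t.n_distance,
                    "n_time": t.n_time,
                    "n_unclassified": t.n_unclassified,
                    "tdi": pop.compute_tdi(t),
                }
            )
        pd.DataFrame(rows).to_csv(out / "tallies.csv", index=False)
        summary["tallies"] = rows

        session_types = {s.session_type for s in dataset.sessions}
        if len(session_types) == 2 and len(tallies) >= 2:
            chi2, df, p = pop.chi_square_dependence(tallies)
            summary["chi_square"] = {"chi2": chi2, "df": df, "p": p}

            roc = pop.roc_analysis(results)
            pd.DataFrame(
                {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
            ).to_csv(out / "roc.csv", index=False)
            summary["roc"] = {
                "youden_optimal_threshold": roc.youden_optimal_threshold,
                "auc": roc.auc,
            }
            th0 = np.argmin(np.abs(roc.thresholds - 0.0))
            summary["roc"]["tpr_at_0"] = float(roc.tpr[th0])
            summary["roc"]["fpr_at_0"] = float(roc.fpr[th0])
    except TimedistError as exc:
        raise PipelineError("population_stats", str(exc)) from exc

    if len({s.session_type for s in dataset.sessions}) == 2 and len(dataset.sessions) >= 2:
        try:
            from .synth import derive_seed

            shuffle = pop.shuffle_test(
                dataset,
                n_shuffles=cfg.shuffle_n,
                horizon=cfg.shuffle_horizon,
                seed=derive_seed(cfg.seed, "shuffle"),
                config=det_cfg,
                alpha=cfg.alpha,
                distance_weight=cfg.distance_weight,
            )
        except TimedistError as exc:
            raise PipelineError("shuffle", str(exc)) from exc
        rows = []
        for m, dist in shuffle.null_distribution.items():
            for j, v in enumerate(dist):
                rows.append({"shuffle_index": j, "metric": m, "tdi_diff": v})
        pd.DataFrame(rows, columns=["shuffle_index", "metric", "tdi_diff"]).to_csv(
            out / "shuffle.csv", index=False
        )
        summary["shuffle"] = {
            "n_shuffles": shuffle.n_shuffles,
            "truncation_s": shuffle.truncation,
            "seed": shuffle.seed,
            "observed": shuffle.observed,
        }

    with open(out / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)
        fh.write("\n")
    return summary


def sweep(
    cfg: PipelineConfig,
    parameter: str,
    values: list,
    return_labels: bool = False,
):
    """Re-run detection+classification per setting of ``parameter``.

    ``parameter`` is ``"bin_width"`` or ``"anchor"``.  Returns a tidy per-setting
    tally table (and per-cell labels if ``return_labels``).
    """
    if parameter not in ("bin_width", "anchor"):
        raise ValidationError(f"sweep parameter must be bin_width or anchor, got {parameter!r}")
    if not values:
        raise ValidationError("sweep needs a nonempty value list")

    dataset = load_dataset(cfg)
    rows = []
    labels: dict[str, dict] = {}
    for value in values:
        setting = dataclasses.replace(cfg, **{parameter: value})
        det_cfg = _detection_config(setting)
        _, results = pop.classify_dataset(
            dataset,
            config=det_cfg,
            metric=setting.metric,
            alpha=setting.alpha,
            distance_weight=setting.distance_weight,
        )
        for t in pop.tally_results(results, metric=setting.metric):
            rows.append(
                {
                    parameter: value,
                    "group": "|".join(t.group_key),
                    "n_distance": t.n_distance,
                    "n_time": t.n_time,
                    "n_unclassified": t.n_unclassified,
                    "tdi": pop.compute_tdi(t),
                }
            )
        if return_labels:
            labels[str(value)] = {r.cell_id: r.label for r in results}
    table = pd.DataFrame(rows)
    return (table, labels) if return_labels else table
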