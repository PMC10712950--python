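"""Population-level statistics over per-cell encoding labels.

Aggregates classified cells into tallies per session type (or per animal ×
session type), and provides:

* the Time–Distance balance Index TDI = (#distance − #time)/(#distance + #time),
* Pearson's χ² test of independence between cell class and session type with
  expected counts from the pooled class proportions (df = 1), plus a
  goodness-of-fit fallback against global population proportions for groups
  recorded in a single session type,
* a ROC over CellType thresholds with the Youden-optimal threshold,
* the common-horizon truncation of sessions, and
* the session-label shuffle test of the TDI contrast.

Unclassified cells (metric value 0 or undefined) are excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import stats

from .detect import DetectionConfig, build_onset_table
from .io import (
    FIXED_DISTANCE,
    FIXED_TIME,
    Dataset,
    Run,
    Session,
    ValidationError,
)
from .metrics import EncodingResult, METRICS, classify_cell, label_from_value

__all__ = [
    "Tally",
    "RocCurve",
    "ShuffleResult",
    "tally_results",
    "compute_tdi",
    "chi_square_dependence",
    "roc_analysis",
    "truncate_sessions",
    "shuffle_test",
    "classify_dataset",
]


@dataclass
class Tally:
    group_key: tuple[str, ...]
    n_distance: int
    n_time: int
    n_unclassified: int

    @property
    def n_classified(self) -> int:
        return self.n_distance + self.n_time


def tally_results(
    results: list[EncodingResult],
    metric: str = "celltype",
    by: str = "session_type",
) -> list[Tally]:
    """Count distance/time/unclassified cells per group.

    ``by`` is ``"session_type"`` or ``"animal_session_type"``.
    Group order follows first appearance in ``results``.
    """
    if by not in ("session_type", "animal_session_type"):
        raise ValidationError(f"unknown grouping {by!r}")
    groups: dict[tuple[str, ...], list[int]] = {}
    for r in results:
        key = (
            (r.session_type,)
            if by == "session_type"
            else (r.animal_id, r.session_type)
        )
        counts = groups.setdefault(key, [0, 0, 0])
        lab = label_from_value(r.metric_value(metric))
        if lab == "distance":
            counts[0] += 1
        elif lab == "time":
            counts[1] += 1
        else:
            counts[2] += 1
    return [
        Tally(group_key=k, n_distance=c[0], n_time=c[1], n_unclassified=c[2])
        for k, c in groups.items()
    ]


def compute_tdi(tally: Tally) -> float | None:
    """(#distance − #time)/(#distance + #time); None when no cell is classified."""
    total = tally.n_distance + tally.n_time
    if total == 0:
        return None
    return (tally.n_distance - tally.n_time) / total


def chi_square_dependence(
    tallies: list[Tally],
    expected_source: str = "pooled",
    global_counts: tuple[int, int] | None = None,
) -> tuple[float, int, float]:
    """Pearson χ² of class (distance/time) against group.

    ``pooled``: expected counts from the pooled class proportions over the given
    tallies — the standard contingency expectation row·col/total; df = rows − 1.
    ``global_population``: for a single group (an animal recorded in one session
    type only), a goodness-of-fit χ² (df = 1) against ``global_counts`` =
    (n_distance, n_time) of the whole population.
    """
    if expected_source == "global_population":
        if len(tallies) != 1 or global_counts is None:
            raise ValidationError(
                "global_population expects a single tally and global_counts"
            )
        gd, gt = global_counts
        if gd + gt == 0:
            raise ValidationError("empty global population")
        tal = tallies[0]
        n = tal.n_classified
        expected = np.array([n * gd / (gd + gt), n * gt / (gd + gt)])
        if np.any(expected == 0):
            raise ValidationError("degenerate test: an expected count is zero")
        observed = np.array([tal.n_distance, tal.n_time], dtype=float)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        df = 1
        return chi2, df, float(stats.chi2.sf(chi2, df))

    if expected_source != "pooled":
        raise ValidationError(f"unknown expected_source {expected_source!r}")
    if len(tallies) < 2:
        raise ValidationError("pooled χ² needs at least two groups")
    observed = np.array(
        [[t.n_distance, t.n_time] for t in tallies], dtype=float
    )
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    if total == 0:
        raise ValidationError("no classified cells")
    expected = row @ col / total
    if np.any(expected == 0):
        raise ValidationError("degenerate test: an expected count is zero")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = observed.shape[0] - 1  # two class columns
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray  # fraction labelled distance among fixed-distance cells
    fpr: np.ndarray  # fraction labelled distance among fixed-time cells
    youden_optimal_threshold: float
    auc: float


def roc_analysis(results: list[EncodingResult]) -> RocCurve:
    """ROC of the CellType value over thresholds θ (label distance iff value < θ).

    Candidate thresholds are the midpoints between consecutive distinct values
    plus both extremes and θ = 0; the Youden-optimal threshold maximizes
    TPR − FPR, ties resolved toward the θ closest to 0.
    """
    vals_d = np.array(
        [r.celltype_value for r in results
         if r.session_type == FIXED_DISTANCE and r.label_by_celltype != "unclassified"]
    )
    vals_t = np.array(
        [r.celltype_value for r in results
         if r.session_type == FIXED_TIME and r.label_by_celltype != "unclassified"]
    )
    if vals_d.size == 0 or vals_t.size == 0:
        raise ValidationError("roc_analysis needs classified cells of both session types")

    values = np.unique(np.concatenate([vals_d, vals_t]))
    mids = (values[:-1] + values[1:]) / 2 if values.size > 1 else np.array([])
    cands = np.unique(
        np.concatenate([[values[0]], mids, [values[-1] + 1e-9], [0.0]])
    )
    tpr = np.array([(vals_d < th).mean() for th in cands])
    fpr = np.array([(vals_t < th).mean() for th in cands])
    youden = tpr - fpr
    best = youden.max()
    tied = np.isclose(youden, best, rtol=0, atol=1e-12)
    optimal = float(cands[tied][np.argmin(np.abs(cands[tied]))])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=cands, tpr=tpr, fpr=fpr,
        youden_optimal_threshold=optimal, auc=auc,
    )


def truncate_sessions(dataset: Dataset, horizon: float = 16.0) -> Dataset:
    """Cap every run's analysis window at ``horizon`` seconds after run start.

    Runs longer than the horizon lose their post-stop extension downstream;
    spikes beyond the cap are ignored by the binning stage.
    """
    if horizon <= 0:
        raise ValidationError("horizon must be > 0")
    sessions = [
        Session(
            session_id=s.session_id,
            animal_id=s.animal_id,
            session_type=s.session_type,
            runs=[dc_replace(r, analysis_cap=float(horizon)) for r in s.runs],
        )
        for s in dataset.sessions
    ]
    return Dataset(
        sessions=sessions,
        spike_trains=dataset.spike_trains,
        ground_truth=dataset.ground_truth,
    )


def classify_dataset(
    dataset: Dataset,
    config: DetectionConfig | None = None,
    metric: str = "celltype",
    alpha: float = 0.05,
    distance_weight: str = "inverse_square_velocity",
) -> tuple[list, list[EncodingResult]]:
    """Run detection + classification over every spike train.

    Returns (onset tables for all cells, encoding results for included cells).
    """
    config = config or DetectionConfig()
    tables = []
    results = []
    for train in dataset.spike_trains:
        session = dataset.session(train.session_id)
        table = build_onset_table(train, session, config)
        tables.append(table)
        if table.included:
            results.append(
                classify_cell(
                    table,
                    metric=metric,
                    anchor=config.anchor,
                    alpha=alpha,
                    distance_weight=distance_weight,
                )
            )
    return tables, results


@dataclass
class ShuffleResult:
    """Observed TDI contrast per metric plus its session-label shuffle null.

    The scalar compared against the null is
    TDI(fixed-distance group) − TDI(fixed-time group); p-values are empirical
    two-sided tail probabilities with the add-one rule (b+1)/(n+1).
    """

    observed: dict[str, dict[str, float | None]]
    null_distribution: dict[str, np.ndarray]
    n_shuffles: int
    truncation: float
    seed: int


def _tdi_contrast(
    class_by_cell: np.ndarray, session_idx: np.ndarray, types: list[str]
) -> float:
    """TDI(distance-labelled sessions) − TDI(time-labelled sessions).

    ``class_by_cell``: −1 distance / +1 time / 0 unclassified per cell;
    ``session_idx`` maps each cell to its session; ``types`` assigns a session
    type per session.  Empty groups contribute a TDI of 0.
    """
    type_arr = np.array(types)
    out = []
    for wanted in (FIXED_DISTANCE, FIXED_TIME):
        mask = type_arr[session_idx] == wanted
        cls = class_by_cell[mask]
        n_d = int((cls == -1).sum())
        n_t = int((cls == 1).sum())
        out.append(0.0 if n_d + n_t == 0 else (n_d - n_t) / (n_d + n_t))
    return out[0] - out[1]


def shuffle_test(
    dataset: Dataset,
    metrics: tuple[str, ...] = METRICS,
    n_shuffles: int = 1000,
    horizon: float = 16.0,
    seed: int = 0,
    config: DetectionConfig | None = None,
    alpha: float = 0.05,
    distance_weight: str = "inverse_square_velocity",
) -> ShuffleResult:
    """Session-type label shuffle of the TDI contrast, on truncated data.

    All sessions are truncated to a common ``horizon`` before detection, the
    session-type labels are then permuted across whole sessions (preserving the
    type counts) ``n_shuffles`` times, and the TDI contrast is recomputed per
    shuffle and per metric.  Reproducible under ``seed``.
    """
    types = [s.session_type for s in dataset.sessions]
    if len(set(types)) < 2:
        raise ValidationError("shuffle_test needs sessions of both types")
    for m in metrics:
        if m not in METRICS:
            raise ValidationError(f"unknown metric {m!r}")

    truncated = truncate_sessions(dataset, horizon)
    _, results = classify_dataset(
        truncated, config=config, alpha=alpha, distance_weight=distance_weight
    )
    if not results:
        raise ValidationError("no cells pass inclusion on the truncated data")

    sid_order = [s.session_id for s in dataset.sessions]
    sid_to_idx = {sid: i for i, sid in enumerate(sid_order)}
    session_idx = np.array([sid_to_idx[r.session_id] for r in results])

    class_by_metric: dict[str, np.ndarray] = {}
    for m in metrics:
        lab = [label_from_value(r.metric_value(m)) for r in results]
        class_by_metric[m] = np.array(
            [-1 if x == "distance" else (1 if x == "time" else 0) for x in lab]
        )

    rng = np.random.default_rng(seed)
    observed: dict[str, dict[str, float | None]] = {}
    null: dict[str, np.ndarray] = {m: np.empty(n_shuffles) for m in metrics}
    perms = [rng.permutation(len(types)) for _ in range(n_shuffles)]
    for m in metrics:
        cls = class_by_metric[m]
        obs = _tdi_contrast(cls, session_idx, types)
        for j, perm in enumerate(perms):
            shuffled = [types[i] for i in perm]
            null[m][j] = _tdi_contrast(cls, session_idx, shuffled)
        b = int(np.sum(np.abs(null[m]) >= abs(obs) - 1e-12))
        p = (b + 1) / (n_shuffles + 1)
        # per-type observed TDIs for reporting
        per_type: dict[str, float | None] = {}
        for wanted in (FIXED_DISTANCE, FIXED_TIME):
            mask = np.array(types)[session_idx] == wanted
            n_d = int((cls[mask] == -1).sum())
            n_t = int((cls[mask] == 1).sum())
            per_type[f"tdi_{wanted}"] = (
                None if n_d + n_t == 0 else (n_d - n_t) / (n_d + n_t)
            )
        observed[m] = {**per_type, "tdi_contrast": obs, "p_value": p}

    return ShuffleResult(
        observed=observed,
        null_distribution=null,
        n_shuffles=n_shuffles,
        truncation=horizon,
        seed=seed,
    )
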