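"""Velocity-regression fits and the three per-cell encoding metrics.

For each included cell the detected per-run onsets (T_i, s), velocities
(V_i, cm/s) and onset distances (S_i = V_i·T_i, cm) feed two ordinary
least-squares models,

    T_i = k·(1/V_i) + q          (time model;   k ≈ encoded distance, cm)
    S_i = m·V_i + n              (distance model; m ≈ encoded time, s)

and three classification metrics:

* **CellType** — normalized contrast of the onset-distance and onset-time
  variances, in [−1, 1]; positive ⇒ time cell, negative ⇒ distance cell.  By
  default the distance deviations are converted to time units, weighting each
  squared deviation by 1/V_i² so both variance terms carry units of s²; the
  unit-mismatched variant that multiplies by V_i instead is available as
  ``distance_weight="velocity"`` for sensitivity analysis.
* **FIT** — ternary verdict from the fitted slopes: a distance cell has
  k ≈ S̄ (so k/S̄ > 1/2) and m ≈ 0; a time cell has m ≈ T̄ and k ≈ 0.
* **P-Value** — ternary verdict from the slope F-tests at α = 0.05: an ideal
  distance cell has a significant T~1/V slope and a zero S~V slope; an ideal
  time cell the reverse.

Sign convention throughout: −1 ⇒ distance, +1 ⇒ time, 0 ⇒ unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detect import OnsetRecord, OnsetTable
from .io import DegenerateDesignError, ValidationError

__all__ = [
    "RegressionFit",
    "EncodingResult",
    "fit_time_model",
    "fit_distance_model",
    "celltype_metric",
    "fit_metric",
    "pvalue_metric",
    "classify_cell",
    "label_from_value",
    "results_to_frame",
    "METRICS",
    "DISTANCE_WEIGHTS",
]

METRICS = ("celltype", "fit", "pvalue")
DISTANCE_WEIGHTS = ("inverse_square_velocity", "velocity")


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n_points: int


def _ols_slope_ftest(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Simple OLS with an F-test of zero slope.

    Conventions for degenerate inputs: constant y (zero total SS) → slope 0,
    p = 1, R² = 0 (no evidence of any slope); an exact fit with nonzero slope →
    p = 0, R² = 1.  A single distinct x is a degenerate design and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError(f"regression needs >= 3 points, got {n}")
    if np.all(x == x[0]):
        raise DegenerateDesignError("all predictor values identical")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    if syy == 0.0:
        return RegressionFit(slope=slope, intercept=intercept, p_value=1.0,
                             r_squared=0.0, n_points=n)
    ss_model = slope * sxy
    ss_resid = max(syy - ss_model, 0.0)
    if ss_resid == 0.0:
        return RegressionFit(slope=slope, intercept=intercept, p_value=0.0,
                             r_squared=1.0, n_points=n)
    f_stat = ss_model / (ss_resid / (n - 2))
    p = float(stats.f.sf(f_stat, 1, n - 2))
    return RegressionFit(slope=slope, intercept=intercept, p_value=p,
                         r_squared=ss_model / syy, n_points=n)


def _arrays(records, anchor: str):
    recs = records.records if isinstance(records, OnsetTable) else list(records)
    v = np.array([r.velocity for r in recs], dtype=float)
    if anchor == "peak":
        t = np.array([r.peak_time for r in recs], dtype=float)
        s = v * t
    elif anchor == "onset":
        t = np.array([r.onset_time for r in recs], dtype=float)
        s = np.array([r.onset_distance for r in recs], dtype=float)
    else:
        raise ValidationError(f"anchor must be 'onset' or 'peak', got {anchor!r}")
    return v, t, s


def fit_time_model(records, anchor: str = "onset") -> RegressionFit:
    """OLS of onset time on reciprocal velocity: T_i = k/V_i + q (slope k, cm)."""
    v, t, _ = _arrays(records, anchor)
    return _ols_slope_ftest(1.0 / v, t)


def fit_distance_model(records, anchor: str = "onset") -> RegressionFit:
    """OLS of onset distance on velocity: S_i = m·V_i + n (slope m, s)."""
    v, _, s = _arrays(records, anchor)
    return _ols_slope_ftest(v, s)


def celltype_metric(
    records,
    distance_weight: str = "inverse_square_velocity",
    anchor: str = "onset",
) -> float:
    """Variance-contrast metric in [−1, 1]; NaN when both variance terms vanish.

    value = (D − T) / (D + T) with T = Σ(T_i−T̄)² and
    D = Σ(S_i−S̄)²/V_i² (default) or Σ V_i·(S_i−S̄)² (``"velocity"`` variant).
    """
    if distance_weight not in DISTANCE_WEIGHTS:
        raise ValidationError(f"unknown distance_weight {distance_weight!r}")
    v, t, s = _arrays(records, anchor)
    if v.size < 2:
        raise ValidationError("celltype_metric needs >= 2 records")
    t_term = float(np.sum((t - t.mean()) ** 2))
    dev2 = (s - s.mean()) ** 2
    if distance_weight == "velocity":
        d_term = float(np.sum(v * dev2))
    else:
        d_term = float(np.sum(dev2 / v**2))
    denom = d_term + t_term
    if denom == 0.0:
        return float("nan")
    return (d_term - t_term) / denom


def fit_metric(m: float, k: float, t_bar: float, s_bar: float) -> int:
    """Slope-ratio verdict: −1 distance (k/S̄ > ½, m/T̄ ≤ ½), +1 time (reverse), else 0."""
    if not (t_bar > 0 and s_bar > 0):
        raise ValidationError("fit_metric needs positive mean onset time and distance")
    r_time = m / t_bar     # ≈ 1 for a time cell (m ≈ T̄)
    r_dist = k / s_bar     # ≈ 1 for a distance cell (k ≈ S̄)
    if r_dist > 0.5 and r_time <= 0.5:
        return -1
    if r_time > 0.5 and r_dist <= 0.5:
        return 1
    return 0


def pvalue_metric(
    time_fit: RegressionFit, distance_fit: RegressionFit, alpha: float = 0.05
) -> int:
    """F-test verdict at level ``alpha``.

    A distance cell has onset time tracking 1/V (T~1/V slope significant) and a
    velocity-independent onset distance (S~V slope not significant); a time cell
    the reverse.  Both-or-neither significant → 0.
    """
    t_rejects = time_fit.p_value < alpha        # T ~ 1/V slope nonzero
    s_rejects = distance_fit.p_value < alpha    # S ~ V slope nonzero
    if t_rejects and not s_rejects:
        return -1
    if s_rejects and not t_rejects:
        return 1
    return 0


def label_from_value(value: float) -> str:
    """Map a metric value to its class label; 0 and NaN are unclassified."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "unclassified"
    if value > 0:
        return "time"
    if value < 0:
        return "distance"
    return "unclassified"


@dataclass
class EncodingResult:
    """Per-cell classification summary (all three metric values always filled)."""

    cell_id: str
    session_id: str
    session_type: str
    animal_id: str
    celltype_value: float
    fit_value: int
    pvalue_value: int
    label: str                 # label under the metric chosen at classification
    metric: str
    anchor: str
    mean_onset_time: float     # T̄, s
    mean_onset_distance: float  # S̄, cm
    n_runs: int

    @property
    def label_by_celltype(self) -> str:
        return label_from_value(self.celltype_value)

    def metric_value(self, metric: str) -> float:
        if metric == "celltype":
            return self.celltype_value
        if metric == "fit":
            return float(self.fit_value)
        if metric == "pvalue":
            return float(self.pvalue_value)
        raise ValidationError(f"unknown metric {metric!r}")


def classify_cell(
    table: OnsetTable,
    metric: str = "celltype",
    anchor: str = "onset",
    alpha: float = 0.05,
    distance_weight: str = "inverse_square_velocity",
) -> EncodingResult:
    """Compute all three metrics for an included cell; ``metric`` picks the label."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    if not table.included:
        raise ValidationError(
            f"cell {table.cell_id} is excluded ({table.exclusion_reason}); "
            "classify_cell requires an included onset table"
        )
    v, t, s = _arrays(table, anchor)
    t_bar, s_bar = float(t.mean()), float(s.mean())

    ct = celltype_metric(table, distance_weight=distance_weight, anchor=anchor)
    time_fit = fit_time_model(table, anchor=anchor)
    distance_fit = fit_distance_model(table, anchor=anchor)
    if t_bar > 0 and s_bar > 0:
        fv = fit_metric(distance_fit.slope, time_fit.slope, t_bar, s_bar)
    else:
        fv = 0  # all onsets at run start: slope ratios undefined, indeterminate
    pv = pvalue_metric(time_fit, distance_fit, alpha=alpha)

    chosen = {"celltype": ct, "fit": float(fv), "pvalue": float(pv)}[metric]
    return EncodingResult(
        cell_id=table.cell_id,
        session_id=table.session_id,
        session_type=table.session_type,
        animal_id=table.animal_id,
        celltype_value=ct,
        fit_value=fv,
        pvalue_value=pv,
        label=label_from_value(chosen),
        metric=metric,
        anchor=anchor,
        mean_onset_time=t_bar,
        mean_onset_distance=s_bar,
        n_runs=len(table.records),
    )


def results_to_frame(results: list[EncodingResult]) -> pd.DataFrame:
    """Export layout: one row per classified cell."""
    rows = [
        {
            "cell_id": r.cell_id,
            "session_id": r.session_id,
            "session_type": r.session_type,
            "celltype": r.celltype_value,
            "fit": r.fit_value,
            "pvalue": r.pvalue_value,
            "label": r.label,
            "mean_onset_time": r.mean_onset_time,
            "mean_onset_distance": r.mean_onset_distance,
            "n_runs": r.n_runs,
        }
        for r in results
    ]
    columns = [
        "cell_id", "session_id", "session_type", "celltype", "fit", "pvalue",
        "label", "mean_onset_time", "mean_onset_distance", "n_runs",
    ]
    return pd.DataFrame(rows, columns=columns)
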