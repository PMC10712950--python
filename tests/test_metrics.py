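"""Regression fits (vs statsmodels oracle) and the three encoding metrics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from timedist.detect import DetectionConfig, OnsetRecord, OnsetTable, build_onset_table
from timedist.io import DegenerateDesignError, FIXED_DISTANCE, FIXED_TIME, ValidationError
from timedist.metrics import (
    celltype_metric,
    classify_cell,
    fit_distance_model,
    fit_metric,
    fit_time_model,
    label_from_value,
    pvalue_metric,
)
from timedist.synth import CellParams, ScheduleParams, sample_runs, simulate_cell_spikes


def records_from(v, t, s=None):
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    s = v * t if s is None else np.asarray(s, dtype=float)
    return [
        OnsetRecord(run_index=i, velocity=vi, onset_time=ti, onset_distance=si,
                    peak_rate=10.0, peak_time=ti, peak_in_run=True)
        for i, (vi, ti, si) in enumerate(zip(v, t, s))
    ]


# -- regression fits --------------------------------------------------------

def test_time_model_exact_reciprocal_inversion():
    v = np.array([35.0, 42.0, 49.0])
    fit = fit_time_model(records_from(v, 200.0 / v))
    assert fit.slope == pytest.approx(200.0, abs=1e-9)
    assert fit.intercept == pytest.approx(0.0, abs=1e-9)


def test_time_model_constant_response_zero_slope_p_one():
    v = np.array([35.0, 40.0, 45.0, 49.0])
    fit = fit_time_model(records_from(v, np.full(4, 4.0)))
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.p_value == 1.0
    assert fit.r_squared == 0.0


def test_distance_model_exact_linear_inversion():
    v = np.array([35.0, 42.0, 49.0])
    fit = fit_distance_model(records_from(v, np.full(3, 4.0)))  # S = 4 V
    assert fit.slope == pytest.approx(4.0, abs=1e-9)
    assert fit.intercept == pytest.approx(0.0, abs=1e-7)


def test_distance_model_constant_distance_zero_slope():
    v = np.array([35.0, 42.0, 49.0])
    fit = fit_distance_model(records_from(v, 200.0 / v, s=np.full(3, 200.0)))
    assert fit.slope == pytest.approx(0.0, abs=1e-12)


def test_single_velocity_is_degenerate_design():
    with pytest.raises(DegenerateDesignError):
        fit_time_model(records_from([40.0, 40.0, 40.0], [1.0, 2.0, 3.0]))


def test_fits_match_statsmodels_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(123)
    for _ in range(200):
        n = rng.integers(5, 40)
        v = rng.uniform(35, 49, n)
        t = rng.uniform(0, 10) + rng.uniform(0, 300) / v + rng.normal(0, 0.7, n)
        fit = fit_time_model(records_from(v, t))
        res = sm.OLS(t, sm.add_constant(1.0 / v)).fit()
        assert fit.slope == pytest.approx(res.params[1], rel=1e-9)
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-9)
        assert fit.p_value == pytest.approx(res.pvalues[1], rel=1e-8, abs=1e-12)
        assert fit.r_squared == pytest.approx(res.rsquared, rel=1e-9)


# -- CellType ---------------------------------------------------------------

def test_celltype_ideal_time_cell_is_plus_one():
    v = np.array([35.0, 42.0, 49.0])
    assert celltype_metric(records_from(v, np.full(3, 4.0))) == 1.0


def test_celltype_ideal_distance_cell_is_minus_one():
    v = np.array([35.0, 42.0, 49.0])
    recs = records_from(v, 200.0 / v, s=np.full(3, 200.0))
    assert celltype_metric(recs) == -1.0
    assert celltype_metric(recs, distance_weight="velocity") == -1.0


def test_celltype_direct_formula_oracle():
    # independent direct evaluation, both weightings
    v = np.array([35.0, 49.0])
    t = np.array([3.0, 5.0])
    s = v * t
    recs = records_from(v, t, s)
    for weight in ("inverse_square_velocity", "velocity"):
        t_term = np.sum((t - t.mean()) ** 2)
        if weight == "velocity":
            d_term = np.sum(v * (s - s.mean()) ** 2)
        else:
            d_term = np.sum((s - s.mean()) ** 2 / v**2)
        want = (d_term - t_term) / (d_term + t_term)
        assert celltype_metric(recs, distance_weight=weight) == pytest.approx(
            want, rel=1e-12
        )


def test_celltype_undefined_when_both_variances_vanish():
    recs = records_from([40.0, 40.0], [4.0, 4.0])
    assert np.isnan(celltype_metric(recs))
    assert label_from_value(celltype_metric(recs)) == "unclassified"


def test_celltype_zero_is_unclassified():
    # equal velocities make both variance terms identical in time units
    recs = records_from([40.0, 40.0], [1.0, 2.0])
    assert celltype_metric(recs) == 0.0
    assert label_from_value(0.0) == "unclassified"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(35, 49), st.floats(0.1, 16.0)), min_size=2, max_size=30
    ),
    st.randoms(use_true_random=False),
)
def test_celltype_bounded_and_permutation_invariant(pairs, rnd):
    v = [p[0] for p in pairs]
    t = [p[1] for p in pairs]
    recs = records_from(v, t)
    value = celltype_metric(recs)
    if not np.isnan(value):
        assert -1.0 <= value <= 1.0
    shuffled = list(recs)
    rnd.shuffle(shuffled)
    other = celltype_metric(shuffled)
    assert (np.isnan(value) and np.isnan(other)) or value == pytest.approx(
        other, rel=1e-12, abs=1e-15
    )


# -- FIT --------------------------------------------------------------------

def test_fit_metric_ideal_cases_and_otherwise():
    # ideal distance cell: k ~ S-bar, m ~ 0
    assert fit_metric(m=0.02, k=195.0, t_bar=4.8, s_bar=200.0) == -1
    # ideal time cell: m ~ T-bar, k ~ 0
    assert fit_metric(m=3.9, k=6.0, t_bar=4.0, s_bar=170.0) == 1
    # both ratios small
    assert fit_metric(m=0.4, k=17.0, t_bar=4.0, s_bar=170.0) == 0
    # both ratios large -> indeterminate
    assert fit_metric(m=3.9, k=195.0, t_bar=4.0, s_bar=200.0) == 0


def test_fit_metric_requires_positive_means():
    with pytest.raises(ValidationError):
        fit_metric(m=1.0, k=1.0, t_bar=0.0, s_bar=100.0)


def test_fit_metric_from_ideal_fits():
    v = np.linspace(35, 49, 12)
    # distance cell records
    recs = records_from(v, 200.0 / v)
    tf, df_ = fit_time_model(recs), fit_distance_model(recs)
    t_bar = np.mean(200.0 / v)
    assert fit_metric(df_.slope, tf.slope, t_bar, 200.0) == -1
    # time cell records
    recs = records_from(v, np.full(12, 4.0))
    tf, df_ = fit_time_model(recs), fit_distance_model(recs)
    assert fit_metric(df_.slope, tf.slope, 4.0, float(np.mean(4.0 * v))) == 1


# -- P-Value ----------------------------------------------------------------

def test_pvalue_metric_on_near_ideal_cells():
    rng = np.random.default_rng(5)
    v = rng.uniform(35, 49, 30)
    # distance cell with tiny noise: T ~ 1/V significant, S ~ V flat
    t = 200.0 / v + rng.normal(0, 0.01, 30)
    tf, df_ = fit_time_model(records_from(v, t)), fit_distance_model(records_from(v, t))
    assert pvalue_metric(tf, df_) == -1
    # time cell with tiny noise
    t = 4.0 + rng.normal(0, 0.01, 30)
    tf, df_ = fit_time_model(records_from(v, t)), fit_distance_model(records_from(v, t))
    assert pvalue_metric(tf, df_) == 1


def test_pvalue_metric_indeterminate_cases():
    class F:
        def __init__(self, p):
            self.p_value = p

    assert pvalue_metric(F(0.5), F(0.5)) == 0   # neither
    assert pvalue_metric(F(0.01), F(0.01)) == 0  # both


# -- classify_cell ----------------------------------------------------------

def _simulated_table(label, seed, **cell_kw):
    stype = FIXED_TIME if label == "time" else FIXED_DISTANCE
    sess = sample_runs(ScheduleParams(n_runs=40, session_type=stype, seed=seed))
    cell = CellParams(label=label, peak_rate=200.0, baseline_rate=0.0,
                      onset_jitter_sd=0.0, field_width_time=0.1,
                      field_width_distance=4.0, **cell_kw)
    train = simulate_cell_spikes(sess, cell, seed=seed + 1)
    train.cell_id = f"{label}-cell"
    return build_onset_table(train, sess)


def test_noiseless_cells_agree_across_metrics_and_anchors():
    time_table = _simulated_table("time", 41, preferred_time=4.0)
    dist_table = _simulated_table("distance", 43, preferred_distance=200.0)
    for anchor in ("onset", "peak"):
        r = classify_cell(time_table, anchor=anchor)
        assert r.celltype_value > 0 and r.fit_value == 1 and r.pvalue_value == 1
        assert r.label == "time" and r.label_by_celltype == "time"
        r = classify_cell(dist_table, anchor=anchor)
        assert r.celltype_value < 0 and r.fit_value == -1 and r.pvalue_value == -1
        assert r.label == "distance"


def test_classify_rejects_excluded_tables():
    table = _simulated_table("time", 41, preferred_time=4.0)
    table.included = False
    table.exclusion_reason = "min-runs"
    with pytest.raises(ValidationError, match="excluded"):
        classify_cell(table)


def test_classify_label_follows_chosen_metric():
    table = _simulated_table("time", 41, preferred_time=4.0)
    for metric in ("celltype", "fit", "pvalue"):
        r = classify_cell(table, metric=metric)
        assert r.metric == metric and r.label == "time"
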