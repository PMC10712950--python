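"""Tallies, TDI, chi-square (vs scipy oracle), ROC (vs brute force), shuffle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from timedist.io import FIXED_DISTANCE, FIXED_TIME, ValidationError
from timedist.metrics import EncodingResult
from timedist.population import (
    Tally,
    chi_square_dependence,
    classify_dataset,
    compute_tdi,
    roc_analysis,
    shuffle_test,
    tally_results,
    truncate_sessions,
)


def make_result(celltype, session_type, cell_id="c", session_id="s", animal="a"):
    ternary = 0 if np.isnan(celltype) else int(np.sign(celltype))
    return EncodingResult(
        cell_id=cell_id, session_id=session_id, session_type=session_type,
        animal_id=animal, celltype_value=celltype,
        fit_value=ternary, pvalue_value=ternary,
        label="time" if celltype > 0 else ("distance" if celltype < 0 else "unclassified"),
        metric="celltype", anchor="onset", mean_onset_time=4.0,
        mean_onset_distance=170.0, n_runs=40,
    )


# -- TDI --------------------------------------------------------------------

def test_tdi_pure_groups_and_printed_tally():
    assert compute_tdi(Tally(("g",), 10, 0, 0)) == 1.0
    assert compute_tdi(Tally(("g",), 0, 10, 0)) == -1.0
    # 298 distance vs 146 time classified cells -> (298-146)/444
    assert compute_tdi(Tally(("g",), 298, 146, 0)) == pytest.approx(152 / 444)
    assert compute_tdi(Tally(("g",), 0, 0, 5)) is None


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 500), st.integers(0, 500))
def test_tdi_antisymmetry(nd, nt):
    if nd + nt == 0:
        return
    a = compute_tdi(Tally(("g",), nd, nt, 0))
    b = compute_tdi(Tally(("g",), nt, nd, 0))
    assert a == pytest.approx(-b)


# -- chi-square -------------------------------------------------------------

def test_chi_square_hand_evaluated_table():
    tallies = [Tally((FIXED_DISTANCE,), 30, 10, 0), Tally((FIXED_TIME,), 10, 30, 0)]
    chi2, df, p = chi_square_dependence(tallies)
    assert chi2 == pytest.approx(20.0)
    assert df == 1
    assert p == pytest.approx(7.744e-6, rel=1e-3)


def test_chi_square_zero_when_proportions_match():
    tallies = [Tally((FIXED_DISTANCE,), 30, 10, 0), Tally((FIXED_TIME,), 60, 20, 0)]
    chi2, _, p = chi_square_dependence(tallies)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_on_published_style_tallies():
    """The pooled-expected rule applied to the headline 2x2 split."""
    tallies = [Tally((FIXED_DISTANCE,), 298, 146, 0), Tally((FIXED_TIME,), 76, 159, 0)]
    chi2, df, p = chi_square_dependence(tallies)
    assert df == 1
    assert chi2 == pytest.approx(75.1, abs=0.05)
    assert p < 1e-10


def test_chi_square_matches_scipy_oracle():
    from scipy.stats import chi2_contingency

    rng = np.random.default_rng(77)
    for _ in range(300):
        table = rng.integers(1, 100, size=(2, 2))
        tallies = [
            Tally((FIXED_DISTANCE,), int(table[0, 0]), int(table[0, 1]), 0),
            Tally((FIXED_TIME,), int(table[1, 0]), int(table[1, 1]), 0),
        ]
        chi2, df, p = chi_square_dependence(tallies)
        ref = chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-9, abs=1e-12)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)


def test_chi_square_column_swap_invariance():
    tallies = [Tally((FIXED_DISTANCE,), 37, 12, 0), Tally((FIXED_TIME,), 9, 41, 0)]
    swapped = [Tally((FIXED_DISTANCE,), 12, 37, 0), Tally((FIXED_TIME,), 41, 9, 0)]
    assert chi_square_dependence(tallies)[0] == pytest.approx(
        chi_square_dependence(swapped)[0], rel=1e-12
    )


def test_chi_square_global_population_fallback():
    # animal recorded only in fixed-distance sessions, global split 374/305
    tal = Tally(("animalX", FIXED_DISTANCE), 40, 10, 0)
    chi2, df, p = chi_square_dependence(
        [tal], expected_source="global_population", global_counts=(374, 305)
    )
    n, p_d = 50, 374 / 679
    expected = np.array([n * p_d, n * (1 - p_d)])
    want = ((40 - expected[0]) ** 2 / expected[0]) + ((10 - expected[1]) ** 2 / expected[1])
    assert chi2 == pytest.approx(want, rel=1e-12)
    assert df == 1


def test_chi_square_single_group_needs_global_counts():
    with pytest.raises(ValidationError):
        chi_square_dependence([Tally((FIXED_DISTANCE,), 5, 5, 0)])


# -- tallies ----------------------------------------------------------------

def test_tally_excludes_unclassified():
    results = [
        make_result(-0.5, FIXED_DISTANCE), make_result(0.7, FIXED_DISTANCE),
        make_result(0.0, FIXED_DISTANCE), make_result(float("nan"), FIXED_TIME),
        make_result(0.2, FIXED_TIME),
    ]
    tallies = {t.group_key: t for t in tally_results(results)}
    td = tallies[(FIXED_DISTANCE,)]
    assert (td.n_distance, td.n_time, td.n_unclassified) == (1, 1, 1)
    tt = tallies[(FIXED_TIME,)]
    assert (tt.n_distance, tt.n_time, tt.n_unclassified) == (0, 1, 1)


# -- ROC --------------------------------------------------------------------

def test_roc_perfect_separation():
    results = [make_result(-0.5 - 0.01 * i, FIXED_DISTANCE) for i in range(10)]
    results += [make_result(0.5 + 0.01 * i, FIXED_TIME) for i in range(10)]
    roc = roc_analysis(results)
    j = roc.tpr - roc.fpr
    assert j.max() == pytest.approx(1.0)
    best = np.flatnonzero(np.isclose(j, 1.0))
    assert any(roc.tpr[i] == 1.0 and roc.fpr[i] == 0.0 for i in best)
    # threshold 0 separates, and ties resolve toward 0
    assert roc.youden_optimal_threshold == pytest.approx(0.0)


def test_roc_identical_distributions_no_discrimination():
    vals = [-0.6, -0.2, 0.3, 0.8]
    results = [make_result(v, FIXED_DISTANCE) for v in vals]
    results += [make_result(v, FIXED_TIME) for v in vals]
    roc = roc_analysis(results)
    assert (roc.tpr - roc.fpr).max() == pytest.approx(0.0, abs=1e-12)


def test_roc_endpoints_and_monotonicity():
    rng = np.random.default_rng(3)
    results = [make_result(v, FIXED_DISTANCE) for v in rng.uniform(-1, 1, 30)]
    results += [make_result(v, FIXED_TIME) for v in rng.uniform(-1, 1, 30)]
    roc = roc_analysis(results)
    assert roc.tpr[0] == 0.0 and roc.fpr[0] == 0.0
    assert roc.tpr[-1] == 1.0 and roc.fpr[-1] == 1.0
    assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)


def test_roc_matches_brute_force_enumeration():
    rng = np.random.default_rng(9)
    vals_d = rng.uniform(-1, 1, 25)
    vals_t = rng.uniform(-1, 1, 25)
    results = [make_result(v, FIXED_DISTANCE) for v in vals_d]
    results += [make_result(v, FIXED_TIME) for v in vals_t]
    roc = roc_analysis(results)
    # brute force over a dense threshold set
    cands = np.unique(np.concatenate(
        [vals_d, vals_t, vals_d + 1e-9, vals_t + 1e-9, [-2.0, 0.0, 2.0]]
    ))
    best = max(float((vals_d < th).mean() - (vals_t < th).mean()) for th in cands)
    got = float((roc.tpr - roc.fpr).max())
    assert got == pytest.approx(best, abs=1e-12)
    th = roc.youden_optimal_threshold
    assert (vals_d < th).mean() - (vals_t < th).mean() == pytest.approx(best)


def test_roc_requires_both_session_types():
    results = [make_result(-0.5, FIXED_DISTANCE)]
    with pytest.raises(ValidationError):
        roc_analysis(results)


# -- truncation -------------------------------------------------------------

def test_truncation_caps_only_long_runs(recovery_dataset):
    trunc = truncate_sessions(recovery_dataset, horizon=16.0)
    for sess, orig in zip(trunc.sessions, recovery_dataset.sessions):
        for run, run0 in zip(sess.runs, orig.runs):
            assert run.analysis_cap == 16.0
            assert run.duration == run0.duration  # schedule untouched
            if run0.duration <= 16.0:
                assert not run.capped
            else:
                assert run.capped and run.effective_duration == 16.0


def test_truncated_onsets_never_exceed_horizon(recovery_dataset):
    trunc = truncate_sessions(recovery_dataset, horizon=16.0)
    tables, _ = classify_dataset(trunc)
    for table in tables:
        for r in table.records:
            assert r.onset_time <= 16.0


# -- shuffle ----------------------------------------------------------------

def test_shuffle_deterministic_under_seed(multi_session_dataset):
    a = shuffle_test(multi_session_dataset, n_shuffles=30, seed=5)
    b = shuffle_test(multi_session_dataset, n_shuffles=30, seed=5)
    for m in a.null_distribution:
        np.testing.assert_array_equal(a.null_distribution[m], b.null_distribution[m])
    assert a.observed == b.observed


def test_shuffle_null_centered_when_exchangeable(untuned_dataset):
    res = shuffle_test(untuned_dataset, n_shuffles=200, seed=19)
    null = res.null_distribution["celltype"]
    se = null.std(ddof=1) / np.sqrt(len(null))
    assert abs(null.mean()) < 3 * se + 1e-9


def test_shuffle_rejects_single_type(recovery_dataset):
    from timedist.io import Dataset

    one_type = Dataset(
        sessions=[s for s in recovery_dataset.sessions if s.session_type == FIXED_TIME],
        spike_trains=[
            t for t in recovery_dataset.spike_trains
            if t.session_id.startswith("ft")
        ],
        ground_truth=None,
    )
    with pytest.raises(ValidationError):
        shuffle_test(one_type, n_shuffles=10, seed=1)
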