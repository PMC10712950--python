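# Methods

This note documents the statistical procedure `timedist` implements, the
choices made where the design was genuinely open, and what the synthetic data
do and do not establish.

## Data model

A *session* is an ordered, non-overlapping schedule of treadmill runs on an
absolute clock (t = 0 at session start; seconds). Each run has a constant belt
velocity (cm/s). Sessions are *fixed-time* (equal run durations) or
*fixed-distance* (equal duration × velocity); a 2% relative tolerance absorbs
treadmill control jitter. Violations are rejected, never repaired. Spike trains
are per-cell nondecreasing absolute times. If a source supplies a velocity
trace rather than a per-run constant, the run's time-average should be used —
the analysis treats velocity as a per-run scalar throughout.

## Onset detection

Per run, spikes are counted in half-open bins [e, e+w) aligned to run start
(default w = 100 ms; 50–500 ms supported for robustness sweeps), tiling the run
plus a 5 s post-stop extension so fields concentrated near treadmill stop are
not clipped — clipping would correlate with run duration and hence with session
type, biasing the classification. A trailing partial bin keeps its true width
for rate computation.

The run's *peak* is the earliest bin with the maximal count. Bins are grouped
into firing *episodes*: maximal series of active bins in which no silent gap
reaches ⌈silence/w⌉ consecutive zero bins (default silence 1 s). The pre-run
epoch counts as silence, so activity from bin 0 onsets at 0 — excluding such
runs would bias against short-latency cells. The onset Tᵢ is the start time of
the first bin of the episode containing the peak. Treating the 1 s silence as
the episode *delimiter* (rather than demanding a fully silent 1 s window
immediately before the peak's contiguous nonzero block) is essential in
practice: Poisson discreteness places zero bins and isolated rising-edge bins
inside any realistic firing field, and the stricter reading discards the
majority of runs for cells with ≥ 0.5 s fields. Ties at the peak take the
earliest bin (determinism). The peak-anchored variant substitutes the peak-bin
start time for the onset throughout and needs no silence rule.

Cell inclusion applies three conjunctive filters: (i) ≥ 10 runs yield an onset
with peak rate above 0.5 Hz; (ii) the mean per-run peak rate is ≥ 0.5 Hz
(note any single spike in a 100 ms bin is already 10 Hz, so this mainly removes
near-silent cells); (iii) the majority of detected peaks start before treadmill
stop — the "peak during the run" requirement is stated per cell, and majority
vote is the aggregation chosen here. Excluded cells carry a reason
(`min-runs`, `mean-peak-rate`, `peak-outside-run`, `no-records`), and the
pipeline log accounts for every input cell.

## Per-cell metrics

With onsets Tᵢ (s), velocities Vᵢ (cm/s) and onset distances Sᵢ = Vᵢ·Tᵢ (cm),
two ordinary least-squares fits are computed: Tᵢ = k·(1/Vᵢ) + q and
Sᵢ = m·Vᵢ + n. For an ideal distance cell encoding distance D: Tᵢ = D/Vᵢ, so
k ≈ D ≈ S̄ and m ≈ 0; for an ideal time cell encoding delay τ: Sᵢ = τ·Vᵢ, so
m ≈ τ ≈ T̄ and k ≈ 0. Slope significance uses the F-statistic with 1 and n−2
degrees of freedom. Conventions: a constant response (zero total sum of
squares) gives slope 0, p = 1, R² = 0 — no evidence of any slope; an exact fit
with nonzero slope gives p = 0; identical velocities are a degenerate design
and raise an error. No multiple-testing correction is applied across cells; the
per-cell level is α = 0.05.

**CellType** contrasts the two onset variances:
CellType = (D − T)/(D + T), T = Σᵢ(Tᵢ−T̄)², D = Σᵢ(Sᵢ−S̄)²/Vᵢ².
Dividing each squared distance deviation by Vᵢ² converts it to time units, so
both terms carry s² and the statistic is invariant to the choice of distance
and time units. The alternative weighting D = ΣᵢVᵢ(Sᵢ−S̄)² (units cm³/s) is
retained as `distance_weight="velocity"` for sensitivity analysis, but it is
not unit-balanced: at V ≈ 42 cm/s equal physical onset noise contributes ~V³
(≈ 7·10⁴) times more to the distance term, so under that weighting any cell
with more than ~2 ms of onset jitter classifies as a time cell. Both weightings
give exactly ±1 in the ideal-cell limits. If both variance terms vanish (only
possible at a single velocity) the value is undefined and the cell
unclassified. Positive values are labelled *time*, negative *distance*, exact 0
(or undefined) *unclassified*.

**FIT** compares the fitted slopes to half their ideal values: −1 (distance)
when k/S̄ > ½ and m/T̄ ≤ ½; +1 (time) when m/T̄ > ½ and k/S̄ ≤ ½; 0 otherwise,
including when both ratios exceed ½ (indeterminate). **P-Value** classifies
−1 (distance) when only the T~1/V slope test rejects at α, +1 (time) when only
the S~V test rejects, 0 otherwise. Both sign assignments follow the ideal-cell
algebra above, which is the only internally consistent mapping.

## Population statistics

Unclassified cells are excluded from all population statistics. Tallies are
formed per session type (or per animal × session type);
TDI = (#distance − #time)/(#distance + #time) ∈ [−1, 1].

Dependence of class on session type is tested by Pearson's χ² with two
categories and expected counts from the pooled class proportions over all
cells (the standard row·column/total expectation), df = 1. For an animal
recorded in only one session type, a goodness-of-fit χ² (df = 1) against the
global population proportions is used instead.

The ROC sweeps thresholds θ over [−1, 1] (label distance iff CellType < θ):
TPR is the distance-labelled fraction among fixed-distance cells, FPR the same
among fixed-time cells. Candidate thresholds are the midpoints between
consecutive observed values plus both extremes and θ = 0; the optimum maximizes
the Youden index TPR − FPR, ties resolved toward the θ nearest 0.

The shuffle test first truncates every run's analysis window to
min(duration + extension, horizon) with a 16 s horizon, so that no analysis
window — and no detected onset — extends past the common horizon; an extension
past an artificial cap would reintroduce the duration/session-type confound the
truncation removes. Session-type labels are then permuted across whole sessions
(preserving type counts) 1000 times by default; per shuffle and per metric the
scalar TDI(fixed-distance group) − TDI(fixed-time group) is recomputed. The
figure-style output shows per-group TDIs, but a scalar is needed for an
empirical p, and this contrast is stated in the output metadata. The two-sided
p uses the add-one rule (b+1)/(n+1), so it is never exactly zero. Note the
test's resolution is limited by the number of distinct label assignments: with
one session per type the null is {±observed} and the minimum attainable p is 1;
about five sessions per type are needed before p < 0.05 is reachable.

## Synthetic sessions

The generator emulates the study conditions: sessions of 31–57 runs (default
40), velocities i.i.d. uniform on [35, 49] cm/s (continuous — the sources give
a range, not a grid), fixed-time duration 16 s, fixed-distance 600 cm (chosen
so fixed-distance durations 12.2–17.1 s straddle the 16 s truncation horizon),
inter-run interval 10 s. Cells are inhomogeneous-Poisson units: Gaussian
tuning in time (σ default 0.5 s) or distance (σ default 20 cm), peak 20 Hz
over a 0.5 Hz baseline, per-run temporal jitter of the field center
(SD 0.2 s); conjunctive cells fire at baseline + min(time term, distance term),
which yields intermediate CellType values; untuned cells are homogeneous at
baseline. Tuned rates apply within the run, baseline elsewhere. Spikes are
drawn by thinning a homogeneous process at the peak rate — a constant envelope
that bounds every rate model exactly. All randomness flows from a single master
seed via stable per-(stage, entity) hashing, so a dataset, its portable export,
and the full pipeline are byte-reproducible.

What the generator does *not* emulate: theta modulation, bursting,
refractoriness, place fields outside the treadmill, drift across a session, or
velocity-trace fluctuations within a run. Passing tests therefore demonstrate
the pipeline's correctness and its statistical calibration under idealized
Poisson firing, not performance on every pathology of real recordings.

## Numerical and scale choices

Bin counts use ⌈window/width⌉ with a 10⁻⁹ guard against float artefacts
(21.0/0.1 → 210, not 211). Onset quantization is the bin width; the noiseless-
cell checks assert onset SD below one bin. The test-suite simulations are sized
for quick iteration — e.g. the recovery check uses 2 sessions × 40 runs × 60
cells and a 200-fold shuffle on a 10-session dataset; the shuffle check uses
10 sessions because session-label permutation over 2 sessions is degenerate
(see above). Statistical oracles in the tests are independent routes:
statsmodels OLS for the regressions, scipy's Pearson χ², brute-force
enumerators for the onset rule and the ROC.

## Known limitations

* The MAT reader handles one session per file and needs a caller-supplied
  `field_map`; archive-specific variable names must be filled in by inspecting
  the deposit.
* Empty spike trains have no row representation in the portable `spikes.csv`
  and vanish on a write/read round trip.
* The P-Value metric inherits the F-test's normality assumption on onset
  residuals; its per-test level is calibrated in the suite under Gaussian
  onset noise only.
* With `distance_weight="velocity"` the CellType statistic depends on the
  units of velocity and distance (see above); the default weighting avoids
  this.
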