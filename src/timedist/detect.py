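"""Per-run firing-onset detection and cell inclusion filtering.

Each run's spikes are counted in fixed-width bins (100 ms default, valid sweep
range 50–500 ms) tiling the run from treadmill start through 5 s past treadmill
stop.  The response onset of a run is the first bin of the contiguous block of
nonzero bins that contains the peak bin, provided that block is preceded by at
least 1 s of silent bins; the epoch before run start counts as silence.  Cells
enter the analysis only if (i) at least 10 runs yield an onset with peak rate
above 0.5 Hz, (ii) the average peak rate over detected runs is at least 0.5 Hz,
and (iii) the majority of detected peaks occur before treadmill stop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Run, Session, SpikeTrain, ValidationError

__all__ = [
    "BIN_WIDTH_RANGE",
    "DetectionConfig",
    "BinnedRun",
    "OnsetRecord",
    "OnsetTable",
    "bin_spikes",
    "detect_onset",
    "detect_anchor_peak",
    "build_onset_table",
    "onset_tables_to_frame",
]

BIN_WIDTH_RANGE = (0.05, 0.5)


@dataclass
class DetectionConfig:
    """Knobs of the onset-detection stage (defaults follow the analysis design)."""

    bin_width: float = 0.1       # s
    extension: float = 5.0       # s past treadmill stop
    silence: float = 1.0         # s of required pre-onset silence
    min_runs: int = 10           # qualifying runs for inclusion
    min_peak_rate: float = 0.5   # Hz
    anchor: str = "onset"        # "onset" | "peak"

    def __post_init__(self) -> None:
        lo, hi = BIN_WIDTH_RANGE
        if not (lo <= self.bin_width <= hi):
            raise ValidationError(
                f"response_detection: bin_width {self.bin_width} outside [{lo}, {hi}]"
            )
        if self.anchor not in ("onset", "peak"):
            raise ValidationError(f"anchor must be 'onset' or 'peak', got {self.anchor!r}")


@dataclass
class BinnedRun:
    """Spike counts/rates of one cell in one run, bins relative to run start."""

    run_index: int
    bin_width: float
    bin_edges: np.ndarray        # left edges, len n_bins
    bin_widths: np.ndarray       # true widths (last bin may be partial)
    counts: np.ndarray
    rates: np.ndarray            # counts / true width, Hz
    analysis_window_end: float   # s relative to run start


@dataclass
class OnsetRecord:
    """Detected response of one cell in one run."""

    run_index: int
    velocity: float        # V_i, cm/s
    onset_time: float      # T_i, s from run start
    onset_distance: float  # S_i = V_i * T_i, cm
    peak_rate: float       # Hz
    peak_time: float       # start of the peak bin, s from run start
    peak_in_run: bool      # peak bin starts before treadmill stop


@dataclass
class OnsetTable:
    """All detected onsets of one cell in one session plus the inclusion verdict."""

    cell_id: str
    session_id: str
    session_type: str
    animal_id: str
    records: list[OnsetRecord]
    included: bool
    exclusion_reason: str | None = None


def _n_bins(window: float, width: float) -> int:
    """ceil(window/width) robust to float artefacts like 21.0/0.1 = 210.0000...3."""
    ratio = window / width
    nearest = round(ratio)
    if abs(ratio - nearest) < 1e-9:
        return max(int(nearest), 1)
    return max(int(math.ceil(ratio)), 1)


def _effective_window(run: Run, extension: float) -> float:
    """Analysis window length after run start.

    Under a truncation cap the window never exceeds the common horizon —
    extending past it would reintroduce the duration/session-type confound the
    truncation removes — so the post-stop extension applies only as far as the
    horizon allows.
    """
    if run.analysis_cap is not None:
        return min(run.duration + extension, run.analysis_cap)
    return run.duration + extension


def bin_spikes(
    spikes: SpikeTrain | np.ndarray,
    run: Run,
    bin_width: float = 0.1,
    extension: float = 5.0,
) -> BinnedRun:
    """Count spikes in half-open bins [e, e+w) tiling [0, window) from run start."""
    lo, hi = BIN_WIDTH_RANGE
    if not (lo <= bin_width <= hi):
        raise ValidationError(
            f"response_detection: bin_width {bin_width} outside [{lo}, {hi}]"
        )
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    window = _effective_window(run, extension)
    n = _n_bins(window, bin_width)
    left = bin_width * np.arange(n)
    edges = np.append(left, window)
    widths = np.diff(edges)

    rel = times - run.start_time
    rel = rel[(rel >= 0.0) & (rel < window)]
    counts, _ = np.histogram(rel, bins=edges)
    rates = counts / widths
    return BinnedRun(
        run_index=run.run_index,
        bin_width=bin_width,
        bin_edges=left,
        bin_widths=widths,
        counts=counts,
        rates=rates,
        analysis_window_end=window,
    )


def detect_onset(
    binned: BinnedRun, silence: float = 1.0
) -> tuple[float, float, float] | None:
    """Apply the onset rule; returns (onset_time, peak_time, peak_rate) or None.

    Peak bin = earliest argmax of counts.  Bins are partitioned into firing
    *episodes*: maximal series of bins with activity in which no silent gap
    reaches ceil(silence / bin_width) consecutive zero bins; episodes are
    therefore separated by at least ``silence`` seconds of quiet, and the epoch
    before run start counts as silence.  The onset is the start time of the
    first (nonzero) bin of the episode that contains the peak.  All-zero counts
    yield no response.
    """
    counts = binned.counts
    if not counts.any():
        return None
    peak = int(np.argmax(counts))
    k = _n_bins(silence, binned.bin_width) if silence > 0 else 1
    # walk left from the peak; stop when a zero-gap of >= k bins separates the
    # next active bin from the episode
    first = peak
    i = peak - 1
    gap = 0
    while i >= 0:
        if counts[i] > 0:
            if gap >= k:
                break
            first = i
            gap = 0
        else:
            gap += 1
        i -= 1
    onset_time = float(binned.bin_edges[first])
    peak_time = float(binned.bin_edges[peak])
    peak_rate = float(binned.rates[peak])
    return onset_time, peak_time, peak_rate


def detect_anchor_peak(binned: BinnedRun) -> tuple[float, float] | None:
    """Peak-anchored variant: (start time of the earliest maximal bin, its rate)."""
    counts = binned.counts
    if not counts.any():
        return None
    peak = int(np.argmax(counts))
    return float(binned.bin_edges[peak]), float(binned.rates[peak])


def build_onset_table(
    spikes: SpikeTrain,
    session: Session,
    config: DetectionConfig | None = None,
) -> OnsetTable:
    """Detect a response in every run and apply the cell-inclusion filters.

    With ``config.anchor == "peak"`` the anchor time (start of the peak bin)
    stands in for the onset time throughout and no silence predicate applies.
    """
    config = config or DetectionConfig()
    records: list[OnsetRecord] = []
    for run in session.runs:
        binned = bin_spikes(spikes, run, config.bin_width, config.extension)
        if config.anchor == "peak":
            hit = detect_anchor_peak(binned)
            if hit is None:
                continue
            anchor_time, peak_rate = hit
            onset_time, peak_time = anchor_time, anchor_time
        else:
            hit = detect_onset(binned, config.silence)
            if hit is None:
                continue
            onset_time, peak_time, peak_rate = hit
        records.append(
            OnsetRecord(
                run_index=run.run_index,
                velocity=run.velocity,
                onset_time=onset_time,
                onset_distance=run.velocity * onset_time,
                peak_rate=peak_rate,
                peak_time=peak_time,
                peak_in_run=peak_time < run.effective_duration,
            )
        )

    included = True
    reason = None
    if not records:
        included, reason = False, "no-records"
    else:
        n_qualifying = sum(r.peak_rate > config.min_peak_rate for r in records)
        mean_peak = float(np.mean([r.peak_rate for r in records]))
        n_in_run = sum(r.peak_in_run for r in records)
        if n_qualifying < config.min_runs:
            included, reason = False, "min-runs"
        elif mean_peak < config.min_peak_rate:
            included, reason = False, "mean-peak-rate"
        elif 2 * n_in_run <= len(records):
            included, reason = False, "peak-outside-run"

    return OnsetTable(
        cell_id=spikes.cell_id,
        session_id=session.session_id,
        session_type=session.session_type,
        animal_id=session.animal_id,
        records=records,
        included=included,
        exclusion_reason=reason,
    )


def onset_tables_to_frame(tables: list[OnsetTable]) -> pd.DataFrame:
    """Flatten onset tables into the export layout (one row per detected run)."""
    rows = []
    for tab in tables:
        for r in tab.records:
            rows.append(
                {
                    "cell_id": tab.cell_id,
                    "session_id": tab.session_id,
                    "run_index": r.run_index,
                    "velocity": r.velocity,
                    "onset_time": r.onset_time,
                    "onset_distance": r.onset_distance,
                    "peak_rate": r.peak_rate,
                    "peak_time": r.peak_time,
                    "peak_in_run": r.peak_in_run,
                }
            )
    columns = [
        "cell_id", "session_id", "run_index", "velocity", "onset_time",
        "onset_distance", "peak_rate", "peak_time", "peak_in_run",
    ]
    return pd.DataFrame(rows, columns=columns)
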