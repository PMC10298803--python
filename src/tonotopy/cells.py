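"""Per-cell (hair cell / spiral ganglion neuron) event analysis.

Pairwise synchrony matrices with an 80th-percentile summary, assignment of
hair-cell transients to supporting-cell events, coupling regression, the
high-K⁺ viability filter for neurons, and before/after drug-wash rate
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ActivityEvent, RoiTraceSet


@dataclass
class CorrelationSummary:
    """Pairwise Pearson matrix plus its scalar synchrony summary.

    ``summary`` is, by default, the mean over ROIs of each ROI's 80th
    percentile pairwise correlation (self-pairs excluded); the "pooled" mode
    takes the 80th percentile of all off-diagonal entries instead.
    """

    matrix: np.ndarray
    summary: float
    mode: str


def correlation_summary(
    traces: RoiTraceSet | np.ndarray,
    percentile: float = 80.0,
    mode: str = "per_roi_mean",
) -> CorrelationSummary:
    """Pairwise Pearson correlations between every ROI pair.

    Zero-variance traces yield NaN rows/columns which are excluded from the
    summary. ``mode`` selects between per-ROI-percentile-then-mean (default)
    and a pooled percentile over all off-diagonal entries.
    """
    x = traces.traces if isinstance(traces, RoiTraceSet) else np.asarray(traces, float)
    n_rois, n_frames = x.shape
    if n_rois < 2 or n_frames < 3:
        raise ValueError("need at least 2 ROIs and 3 frames")

    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(x)
    mat[sd == 0, :] = np.nan
    mat[:, sd == 0] = np.nan
    np.fill_diagonal(mat, 1.0)

    off = mat.copy()
    np.fill_diagonal(off, np.nan)
    if mode == "per_roi_mean":
        per_roi = []
        for i in range(n_rois):
            vals = off[i][np.isfinite(off[i])]
            if vals.size:
                per_roi.append(np.percentile(vals, percentile))
        summary = float(np.mean(per_roi)) if per_roi else float("nan")
    elif mode == "pooled":
        vals = off[np.isfinite(off)]
        summary = float(np.percentile(vals, percentile)) if vals.size else float("nan")
    else:
        raise ValueError("mode must be 'per_roi_mean' or 'pooled'")
    return CorrelationSummary(matrix=mat, summary=summary, mode=mode)


@dataclass
class EventAssignment:
    """Hair cells assigned to each supporting-cell event.

    ``per_event`` lists, per event (in start-frame order), the ids of cells
    whose first qualifying peak falls in that event's window; a peak is
    consumed by the earliest-starting event containing it.
    """

    per_event: list[list[int]]
    counts: list[int]
    unassigned_peaks: int
    total_peaks: int


def assign_ihc_to_isc_events(
    cell_peaks: dict[int, list[int]],
    events: list[ActivityEvent],
) -> EventAssignment:
    """Count hair cells active during each supporting-cell event window.

    A cell is counted for an event when one of its peak frames lies in the
    inclusive window [start_frame, end_frame]. Where windows overlap, the
    peak goes to the earliest-starting event and is not reused.
    """
    order = sorted(range(len(events)), key=lambda i: (events[i].start_frame, events[i].end_frame))
    per_event_sorted: list[set[int]] = [set() for _ in events]
    assigned = 0
    total = 0
    for cid, peaks in cell_peaks.items():
        for p in peaks:
            total += 1
            for i in order:
                if events[i].start_frame <= p <= events[i].end_frame:
                    per_event_sorted[i].add(cid)
                    assigned += 1
                    break
    per_event = [sorted(s) for s in per_event_sorted]
    return EventAssignment(
        per_event=per_event,
        counts=[len(v) for v in per_event],
        unassigned_peaks=total - assigned,
        total_peaks=total,
    )


def isc_ihc_regression(
    n_isc_rois: np.ndarray, n_ihcs: np.ndarray
) -> tuple[float, float, float]:
    """Ordinary least squares of activated hair cells on activated grid ROIs.

    Returns (slope, intercept, r²). Degenerate x (single distinct value)
    raises.
    """
    x = np.asarray(n_isc_rois, float)
    y = np.asarray(n_ihcs, float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def filter_sgn_by_kcl(
    traces: RoiTraceSet | np.ndarray,
    kcl_window: tuple[int, int],
    min_response: float = 0.10,
) -> list[int]:
    """Keep neurons whose ΔF/F response to the high-K⁺ wash exceeds 10 %.

    ``kcl_window`` is a half-open frame range [start, stop); a neuron is
    included iff its maximum ΔF/F inside the window is strictly greater than
    ``min_response``.
    """
    x = traces.traces if isinstance(traces, RoiTraceSet) else np.atleast_2d(np.asarray(traces, float))
    ids = list(traces.roi_ids) if isinstance(traces, RoiTraceSet) else list(range(x.shape[0]))
    start, stop = kcl_window
    if not (0 <= start < stop <= x.shape[1]):
        raise ValueError("K+ window must be a nonempty frame range inside the recording")
    peak = x[:, start:stop].max(axis=1)
    return [ids[i] for i in np.nonzero(peak > min_response)[0]]


def pharmacology_window_compare(
    event_times_s: np.ndarray,
    drug_onset_s: float,
    recording_duration_s: float,
    washin_delay_s: float = 90.0,
) -> tuple[float, float, str | None]:
    """Event rates before drug onset and after wash-in.

    The pre window is [0, onset); the post window starts ``washin_delay_s``
    after onset (time for the drug to reach the bath) and runs to the end of
    the recording. Events inside the wash-in gap belong to neither window.
    Returns (rate_before_hz, rate_after_hz, warning).
    """
    t = np.asarray(event_times_s, float)
    post_start = drug_onset_s + washin_delay_s
    if drug_onset_s <= 0 or post_start >= recording_duration_s:
        raise ValueError("recording must span both analysis windows")
    pre_dur = drug_onset_s
    post_dur = recording_duration_s - post_start
    warning = "post window shorter than 60 s" if post_dur < 60.0 else None
    rate_before = float(np.sum(t < drug_onset_s)) / pre_dur
    rate_after = float(np.sum(t >= post_start)) / post_dur
    return rate_before, rate_after, warning
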