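"""Grid-ROI binarization and spatiotemporal event extraction for the
inner-supporting-cell sheet.

The sheet is tiled with square grid ROIs (default 10×10 px), each ROI trace
is ΔF/F-normalized and binarized as active when it exceeds its own
median + 3 SD, and events are connected components of active (frame, row, col)
voxels in 3D, filtered to ≥ 3 frames and ≥ 5 distinct ROIs. Merged events can
be split by k-means on their voxel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .trace import normalize_dff
from .types import ActivityEvent, CalciumMovie


@dataclass
class GridRoiSet:
    """Square-grid tiling of a region mask with one ΔF/F trace per tile.

    ``roi_index`` maps (row, col) grid coordinates to the flat trace row;
    ``roi_pixels`` maps (row, col) to the member-pixel boolean mask count.
    """

    grid_px: int
    roi_index: dict[tuple[int, int], int]
    roi_pixels: dict[tuple[int, int], np.ndarray]
    traces: np.ndarray  # (n_rois, n_frames), ΔF/F
    frame_rate_hz: float
    pixel_scale_um: float
    shape: tuple[int, int]  # (n_rows, n_cols) of the grid

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]


@dataclass
class EventMetrics:
    """Population summary: event frequency per 0.01 mm² per minute and means."""

    frequency_per_001mm2_per_min: float
    mean_duration_s: float | None
    mean_area_mm2: float | None
    n_events: int


def make_grid_rois(
    movie: CalciumMovie,
    region_mask: np.ndarray,
    grid_px: int = 10,
    min_fill: float = 0.5,
) -> GridRoiSet:
    """Overlay a square grid on the masked region and extract ΔF/F traces.

    Each grid ROI trace is the mean of its member pixels per frame, then
    normalized to its 10th percentile over time. Edge tiles covering less
    than ``min_fill`` of a full grid square are discarded.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != movie.data.shape[1:]:
        raise ValueError("region mask shape must match movie frame shape")
    if not region_mask.any():
        raise ValueError("region mask is empty")
    if grid_px < 2:
        raise ValueError("grid_px must be >= 2")

    rows = np.any(region_mask, axis=1).nonzero()[0]
    cols = np.any(region_mask, axis=0).nonzero()[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1

    roi_index: dict[tuple[int, int], int] = {}
    roi_pixels: dict[tuple[int, int], np.ndarray] = {}
    raw_traces = []
    n_rows = int(np.ceil((r1 - r0) / grid_px))
    n_cols = int(np.ceil((c1 - c0) / grid_px))
    min_px = min_fill * grid_px * grid_px
    for gr in range(n_rows):
        for gc in range(n_cols):
            ys = slice(r0 + gr * grid_px, min(r0 + (gr + 1) * grid_px, r1))
            xs = slice(c0 + gc * grid_px, min(c0 + (gc + 1) * grid_px, c1))
            tile = np.zeros_like(region_mask)
            tile[ys, xs] = True
            tile &= region_mask
            if tile.sum() < min_px:
                continue
            roi_index[(gr, gc)] = len(raw_traces)
            roi_pixels[(gr, gc)] = np.argwhere(tile)
            raw_traces.append(movie.data[:, tile].mean(axis=1))

    if not raw_traces:
        raise ValueError("no grid ROI meets the minimum-fill requirement")
    raw = np.asarray(raw_traces)
    dff = normalize_dff(raw, method="pixel_p10")
    return GridRoiSet(
        grid_px=grid_px,
        roi_index=roi_index,
        roi_pixels=roi_pixels,
        traces=dff.values,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_scale_um=movie.pixel_scale_um,
        shape=(n_rows, n_cols),
    )


def binarize_activity(grid: GridRoiSet, k_sd: float = 3.0) -> np.ndarray:
    """Binarize each ROI trace at its own median + ``k_sd``·SD (strict >).

    Returns a boolean raster of shape (n_frames, n_rows, n_cols); grid
    positions without an ROI are always inactive.
    """
    n_frames = grid.traces.shape[1]
    raster = np.zeros((n_frames, *grid.shape), dtype=bool)
    med = np.median(grid.traces, axis=1)
    sd = np.std(grid.traces, axis=1)
    thresh = med + k_sd * sd
    active = grid.traces > thresh[:, None]
    for (gr, gc), i in grid.roi_index.items():
        raster[:, gr, gc] = active[i]
    return raster


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def extract_events(
    raster: np.ndarray,
    min_frames: int = 3,
    min_rois: int = 5,
    connectivity: int = 26,
    frame_rate_hz: float = 2.0,
    roi_area_mm2: float = (10 * 425.1 / 512) ** 2 / 1e6,
    grid_traces: GridRoiSet | None = None,
) -> list[ActivityEvent]:
    """Extract events as 3D connected components of the active raster.

    Components spanning fewer than ``min_frames`` frames or fewer than
    ``min_rois`` distinct (row, col) ROIs are removed. Area is
    n_rois · roi_area_mm2; peak ΔF/F is filled from ``grid_traces`` when
    provided.
    """
    raster = np.asarray(raster, dtype=bool)
    labels, n = ndimage.label(raster, structure=_structure(connectivity))
    events: list[ActivityEvent] = []
    all_voxels = np.argwhere(labels > 0)
    lab_of = labels[tuple(all_voxels.T)]
    order = np.argsort(lab_of, kind="stable")
    all_voxels, lab_of = all_voxels[order], lab_of[order]
    boundaries = np.searchsorted(lab_of, np.arange(1, n + 2))
    for lab in range(1, n + 1):
        voxels = all_voxels[boundaries[lab - 1] : boundaries[lab]]
        frames = voxels[:, 0]
        start, end = int(frames.min()), int(frames.max())
        if end - start + 1 < min_frames:
            continue
        rois = {(int(r), int(c)) for r, c in voxels[:, 1:]}
        if len(rois) < min_rois:
            continue
        peak = float("nan")
        if grid_traces is not None:
            vals = [
                grid_traces.traces[grid_traces.roi_index[(r, c)], f]
                for f, r, c in voxels
                if (r, c) in grid_traces.roi_index
            ]
            if vals:
                peak = float(max(vals))
        events.append(
            ActivityEvent(
                voxels=voxels,
                start_frame=start,
                end_frame=end,
                n_rois=len(rois),
                duration_s=(end - start + 1) / frame_rate_hz,
                area_mm2=len(rois) * roi_area_mm2,
                peak_dff=peak,
            )
        )
    events.sort(key=lambda e: (e.start_frame, e.end_frame))
    return events


def split_overlapping_events(
    event: ActivityEvent,
    k: int,
    seed: int = 0,
    w_t: float = 1.0,
    min_frames: int = 3,
    min_rois: int = 5,
    frame_rate_hz: float = 2.0,
    roi_area_mm2: float = (10 * 425.1 / 512) ** 2 / 1e6,
) -> list[ActivityEvent]:
    """Split a merged event into ``k`` parts by k-means on voxel coordinates.

    Voxels are clustered on (frame·w_t, row, col); each part is re-checked
    against the duration and size filters, so split parts that fall below
    them are dropped. Deterministic for a given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return [event]
    if k > len(event.voxels):
        raise ValueError("k exceeds event voxel count")
    coords = event.voxels.astype(float).copy()
    coords[:, 0] *= w_t
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    parts: list[ActivityEvent] = []
    for lab in range(k):
        voxels = event.voxels[labels == lab]
        if len(voxels) == 0:
            continue
        frames = voxels[:, 0]
        start, end = int(frames.min()), int(frames.max())
        rois = {(int(r), int(c)) for r, c in voxels[:, 1:]}
        if end - start + 1 < min_frames or len(rois) < min_rois:
            continue
        parts.append(
            ActivityEvent(
                voxels=voxels,
                start_frame=start,
                end_frame=end,
                n_rois=len(rois),
                duration_s=(end - start + 1) / frame_rate_hz,
                area_mm2=len(rois) * roi_area_mm2,
                peak_dff=event.peak_dff,
            )
        )
    parts.sort(key=lambda e: (e.start_frame, e.end_frame))
    return parts


def suggest_split_k(
    event: ActivityEvent, trough_fraction: float = 0.30
) -> int:
    """Heuristic trigger for splitting temporally merged events.

    Builds the event's active-ROI-count time series and counts local maxima
    separated by a trough at least ``trough_fraction`` below the smaller
    flanking maximum; returns that count (1 = no split).
    """
    frames = event.voxels[:, 0]
    counts = np.bincount(frames - event.start_frame)
    peaks: list[int] = []
    for i in range(len(counts)):
        left = counts[i - 1] if i > 0 else -np.inf
        right = counts[i + 1] if i < len(counts) - 1 else -np.inf
        if counts[i] > left and counts[i] >= right:
            peaks.append(i)
    if len(peaks) < 2:
        return 1
    k = 1
    for a, b in zip(peaks[:-1], peaks[1:]):
        trough = counts[a : b + 1].min()
        if trough <= (1 - trough_fraction) * min(counts[a], counts[b]):
            k += 1
    return k


def summarize_events(
    events: list[ActivityEvent],
    recording_duration_s: float,
    region_area_mm2: float,
) -> EventMetrics:
    """Summarize an event list as frequency (per 0.01 mm² per minute) and
    mean duration/area; means are None when there are no events."""
    if recording_duration_s <= 0 or region_area_mm2 <= 0:
        raise ValueError("duration and area must be positive")
    n = len(events)
    freq = n / (region_area_mm2 / 0.01) / (recording_duration_s / 60.0)
    if n == 0:
        return EventMetrics(freq, None, None, 0)
    return EventMetrics(
        frequency_per_001mm2_per_min=freq,
        mean_duration_s=float(np.mean([e.duration_s for e in events])),
        mean_area_mm2=float(np.mean([e.area_mm2 for e in events])),
        n_events=n,
    )
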