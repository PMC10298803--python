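"""Shared domain containers.

Conventions used throughout the package: arrays are indexed (frame, row, col),
0-based, with half-open frame ranges written [start, end) only where a slice is
taken — event start/end frames are inclusive, matching how event durations are
counted (duration in frames = end − start + 1). Time is seconds from recording
start; fluorescence is either raw (arbitrary units, non-negative) or ΔF/F
(dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class CalciumMovie:
    """Fluorescence movie: ``data`` is (time, y, x) with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (T, Y, X)
        Raw or normalized fluorescence.
    frame_rate_hz : float
        Acquisition rate; must be positive.
    pixel_scale_um : float
        Microns per pixel; must be positive.
    """

    data: np.ndarray
    frame_rate_hz: float
    pixel_scale_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be 3D (time, y, x); got shape {self.data.shape}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class RoiTraceSet:
    """Per-ROI fluorescence time series with ROI geometry.

    ``traces`` is (n_rois, n_frames). ``roi_geometry`` maps roi id to either a
    pixel set (array of (row, col)) or an oval parameterization
    (center_y, center_x, semi_axis_y, semi_axis_x, angle_deg).
    """

    traces: np.ndarray
    frame_rate_hz: float
    roi_ids: Sequence[int] | None = None
    roi_geometry: dict | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.roi_ids is None:
            self.roi_ids = list(range(self.traces.shape[0]))
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi ids must be unique")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class DffTrace:
    """ΔF/F trace(s) with the baseline used to compute them.

    ``values`` has the same shape as the input fluorescence; ``baseline_f0``
    is the per-pixel / per-ROI F₀ (scalar, vector, or image depending on the
    normalization axis).
    """

    values: np.ndarray
    baseline_f0: np.ndarray
    baseline_method: str


@dataclass
class ActivityEvent:
    """One spatiotemporal calcium event on the supporting-cell grid.

    ``voxels`` is an (n, 3) integer array of (frame, row, col) grid
    coordinates; start/end frames are inclusive.
    """

    voxels: np.ndarray
    start_frame: int
    end_frame: int
    n_rois: int
    duration_s: float
    area_mm2: float
    peak_dff: float = float("nan")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def roi_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.voxels[:, 1:]}


@dataclass
class SynthConfig:
    """Parameters shared by the synthetic movie generators.

    Defaults emulate the confocal explant recordings the analyses were
    designed for: 2 Hz acquisition of a 512×512 px field covering
    425.1×425.1 µm over 10 minutes.
    """

    seed: int = 0
    duration_s: float = 600.0
    frame_rate_hz: float = 2.0
    image_shape: tuple[int, int] = (512, 512)
    pixel_scale_um: float = 425.1 / 512
    event_rate_per_min: float = 2.0
    event_footprint_um: float = 60.0
    event_amplitude_dff: float = 1.0
    noise_sd_dff: float = 0.05
    bleach_tau_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration and frame rate must be positive")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")
        if self.event_rate_per_min < 0 or self.noise_sd_dff < 0:
            raise ValueError("rates and noise SD must be non-negative")
        if self.bleach_tau_s < 0:
            raise ValueError("bleach_tau_s must be >= 0 (0 disables bleaching)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PlantedEvent:
    """Ground-truth record of one planted event.

    ``voxels`` spans the full trapezoidal time course; ``core_voxels`` only
    the full-amplitude plateau frames, which any supra-threshold detector is
    guaranteed to mark regardless of how the rise/decay frames interact with
    its per-ROI statistics.
    """

    start_frame: int
    end_frame: int
    members: np.ndarray  # pixel or (row,col)-ROI coordinates, (n, 2)
    peak_dff: float
    voxels: np.ndarray | None = None  # (frame,row,col) triples when gridded
    core_voxels: np.ndarray | None = None


@dataclass
class GroundTruth:
    """Planted parameters emitted by every synthetic generator."""

    events: list[PlantedEvent] = field(default_factory=list)
    per_cell_tuning: list[dict] | None = None
    planted_threshold_db: float | None = None
    crenation_regions: list[dict] | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class StimulusLog:
    """Tone-presentation log: one row per stimulus."""

    stim_id: np.ndarray
    freq_hz: np.ndarray
    level_db: np.ndarray
    onset_frame: np.ndarray

    def __post_init__(self) -> None:
        self.onset_frame = np.asarray(self.onset_frame, dtype=int)
        if np.any(np.diff(self.onset_frame) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset_frame)


NO_RESPONSE = float("inf")  # sentinel comparisons; ThresholdResult.censored is authoritative


@dataclass
class ThresholdResult:
    """Automated threshold with its interpolation provenance.

    When no level reaches criterion, ``threshold_db`` is one level step above
    the maximum tested level and ``censored`` is True (plot-at-detection-limit
    convention).
    """

    threshold_db: float
    criterion_value: float
    bracket_levels: tuple[float, float] | None
    censored: bool = False
    warning: str | None = None
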