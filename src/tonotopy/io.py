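"""File I/O and end-to-end orchestration.

Movies travel as multi-page TIFF with a JSON sidecar carrying frame rate and
pixel scale; traces and stimulus logs as CSV; ground truth, results and the
provenance manifest as JSON. ``run_pipeline`` ties generation, segmentation
and summarization into a reproducible seeded run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import segmentation
from .synth import gen_isc_ihc_movie, isc_region_mask
from .types import ActivityEvent, CalciumMovie, RoiTraceSet, StimulusLog, SynthConfig


def write_movie(movie: CalciumMovie, path: str | Path) -> None:
    """Multi-page TIFF plus a .json sidecar with acquisition metadata."""
    path = Path(path)
    tifffile.imwrite(path, movie.data, photometric="minisblack")
    sidecar = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_scale_um": movie.pixel_scale_um,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_movie(path: str | Path) -> CalciumMovie:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    return CalciumMovie(data, meta["frame_rate_hz"], meta["pixel_scale_um"])


def read_movie_traces(path: str | Path, pixel_masks: list[np.ndarray]) -> np.ndarray:
    """Mean-ROI traces from a TIFF without holding the full stack in memory
    (frames are streamed page by page)."""
    masks = [np.asarray(m, dtype=bool) for m in pixel_masks]
    out: list[list[float]] = [[] for _ in masks]
    with tifffile.TiffFile(Path(path)) as tif:
        for page in tif.pages:
            frame = page.asarray()
            for i, m in enumerate(masks):
                out[i].append(float(frame[m].mean()))
    return np.asarray(out)


def write_traces(traces: RoiTraceSet, path: str | Path) -> None:
    """Long-format CSV: roi_id, frame, value."""
    n_rois, n_frames = traces.traces.shape
    df = pd.DataFrame(
        {
            "roi_id": np.repeat(list(traces.roi_ids), n_frames),
            "frame": np.tile(np.arange(n_frames), n_rois),
            "value": traces.traces.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_traces(path: str | Path, frame_rate_hz: float) -> RoiTraceSet:
    df = pd.read_csv(path)
    required = {"roi_id", "frame", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing column(s): {sorted(missing)}")
    pivot = df.pivot(index="roi_id", columns="frame", values="value").sort_index()
    return RoiTraceSet(
        traces=pivot.to_numpy(),
        frame_rate_hz=frame_rate_hz,
        roi_ids=[int(i) for i in pivot.index],
    )


def write_stim_log(log: StimulusLog, path: str | Path) -> None:
    pd.DataFrame(
        {
            "stim_id": log.stim_id,
            "freq_hz": log.freq_hz,
            "level_db": log.level_db,
            "onset_frame": log.onset_frame,
        }
    ).to_csv(path, index=False)


def read_stim_log(path: str | Path) -> StimulusLog:
    df = pd.read_csv(path)
    required = {"stim_id", "freq_hz", "level_db", "onset_frame"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stimulus log missing column(s): {sorted(missing)}")
    return StimulusLog(
        stim_id=df["stim_id"].to_numpy(),
        freq_hz=df["freq_hz"].to_numpy(float),
        level_db=df["level_db"].to_numpy(float),
        onset_frame=df["onset_frame"].to_numpy(int),
    )


def write_events(events: list[ActivityEvent], path: str | Path) -> None:
    rows = [
        {
            "event": i,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
            "n_rois": e.n_rois,
            "duration_s": e.duration_s,
            "area_mm2": e.area_mm2,
            "peak_dff": e.peak_dff,
        }
        for i, e in enumerate(events)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end run parameters; defaults are the pipeline's canonical
    analysis constants (10-px grid, 3-frame/5-ROI filters, median + 3 SD
    binarization, per-minute frequency normalization)."""

    seed: int = 0
    out_dir: str = "results/run"
    synth: dict = field(default_factory=dict)
    grid_px: int = 10
    k_sd: float = 3.0
    min_frames: int = 3
    min_rois: int = 5
    connectivity: int = 26

    _KNOWN = {"seed", "out_dir", "synth", "grid_px", "k_sd", "min_frames", "min_rois", "connectivity"}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Synthesize a supporting-cell movie, segment it, and summarize events.

    Writes the event table, metrics and a provenance manifest (config hash,
    seed, array hashes) under ``config.out_dir``; reruns with the same
    config reproduce byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth_cfg = SynthConfig(seed=config.seed, **config.synth)
    movie, ihc_traces, gt = gen_isc_ihc_movie(synth_cfg, grid_px=config.grid_px)
    mask = isc_region_mask(synth_cfg.image_shape)
    grid = segmentation.make_grid_rois(movie, mask, grid_px=config.grid_px)
    raster = segmentation.binarize_activity(grid, k_sd=config.k_sd)
    roi_area_mm2 = (config.grid_px * movie.pixel_scale_um) ** 2 / 1e6
    events = segmentation.extract_events(
        raster,
        min_frames=config.min_frames,
        min_rois=config.min_rois,
        connectivity=config.connectivity,
        frame_rate_hz=movie.frame_rate_hz,
        roi_area_mm2=roi_area_mm2,
        grid_traces=grid,
    )
    region_area_mm2 = mask.sum() * movie.pixel_scale_um**2 / 1e6
    metrics = segmentation.summarize_events(events, movie.duration_s, region_area_mm2)

    write_events(events, out / "events.csv")
    metrics_d = asdict(metrics)
    (out / "metrics.json").write_text(json.dumps(metrics_d, indent=2))
    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "raster_sha256": hashlib.sha256(np.ascontiguousarray(raster)).hexdigest(),
        "movie_sha256": hashlib.sha256(
            np.ascontiguousarray(movie.data)
        ).hexdigest(),
        "n_events": len(events),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"events": events, "metrics": metrics, "manifest": manifest}
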