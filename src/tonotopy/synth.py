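"""Synthetic-data generators with planted ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — stochastic supporting-cell events on a grid with coupled hair-cell
transients, correlated neuron bursts with a high-K⁺ control, widefield
collicular band events with tonotopic structure, ABR waveform families,
DPOAE spectra, transmitted-light crenation movies, and two-photon tuning
tensors — and returns the planted parameters alongside the data. The ground
truth is always sufficient to predict the expected output of the downstream
analysis without re-running the generator (closure property).

Design choices baked in here: supporting-cell events are painted at
grid-tile granularity with a trapezoidal time course and are temporally
disjoint (real overlapping events are the job of the k-means splitter, which
is tested on purpose-built fused fixtures); audiometric ground-truth
thresholds are the analytic crossing of the planted response-growth curve
with the realized detection criterion, computed from the generator's own
draws by closed form, never by running the detector.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CalciumMovie,
    GroundTruth,
    PlantedEvent,
    RoiTraceSet,
    StimulusLog,
    SynthConfig,
)

BASELINE_F = 100.0  # arbitrary-unit resting fluorescence for all movies

# trapezoidal event time course: 1-frame rise, plateau at 1, 2-frame decay
RISE_FRACTION = 0.5
DECAY_FRACTIONS = (0.5, 0.25)


def _event_kernel(plateau_frames: int) -> np.ndarray:
    return np.array([RISE_FRACTION] + [1.0] * plateau_frames + list(DECAY_FRACTIONS))


def isc_region_mask(image_shape: tuple[int, int]) -> np.ndarray:
    """Supporting-cell region: the lower half of the frame."""
    mask = np.zeros(image_shape, dtype=bool)
    mask[image_shape[0] // 2 :, :] = True
    return mask


def _grid_tiles(
    image_shape: tuple[int, int], grid_px: int
) -> tuple[dict[tuple[int, int], tuple[slice, slice]], int, int]:
    """Full grid tiles of the supporting-cell region (same layout the
    segmentation grid produces for this mask)."""
    r0 = image_shape[0] // 2
    n_rows = (image_shape[0] - r0) // grid_px
    n_cols = image_shape[1] // grid_px
    tiles = {
        (gr, gc): (
            slice(r0 + gr * grid_px, r0 + (gr + 1) * grid_px),
            slice(gc * grid_px, (gc + 1) * grid_px),
        )
        for gr in range(n_rows)
        for gc in range(n_cols)
    }
    return tiles, n_rows, n_cols


def _disjoint_windows(
    rng: np.random.Generator, n: int, length_each: int, n_frames: int, gap: int = 2
) -> list[int]:
    """Draw up to ``n`` event start frames so windows never overlap."""
    starts: list[int] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(starts) < n and attempts < 50 * max(n, 1):
        attempts += 1
        s = int(rng.integers(1, max(2, n_frames - length_each - 1)))
        if all(s + length_each + gap <= a or s >= b + gap for a, b in occupied):
            starts.append(s)
            occupied.append((s, s + length_each))
    return sorted(starts)


def gen_isc_ihc_movie(
    config: SynthConfig,
    grid_px: int = 10,
    n_ihc: int = 20,
    plateau_frames: int = 3,
    ihc_coupling_amplitude: float = 0.5,
) -> tuple[CalciumMovie, RoiTraceSet, GroundTruth]:
    """Supporting-cell sheet movie with coupled hair-cell transients.

    Events are elliptical footprints painted on whole grid tiles of the
    supporting-cell region (lower half of the frame) with a trapezoidal time
    course; a row of ``n_ihc`` oval hair-cell ROIs sits just above the
    region border, and hair cells whose center falls inside an event's
    lateral extent receive a coupled transient. GroundTruth lists every
    event's (frame, grid_row, grid_col) voxels and its hair-cell members.
    """
    rng = config.rng()
    H, W = config.image_shape
    n_frames = config.n_frames
    tiles, n_rows, n_cols = _grid_tiles((H, W), grid_px)

    footprint_px = config.event_footprint_um / config.pixel_scale_um
    footprint_tiles = footprint_px / grid_px  # mean extent in grid units
    if footprint_tiles > min(n_rows, n_cols):
        raise ValueError("event footprint exceeds the supporting-cell region")

    kernel = _event_kernel(plateau_frames)
    n_events = int(rng.poisson(config.event_rate_per_min * config.duration_s / 60.0))
    starts = _disjoint_windows(rng, n_events, len(kernel), n_frames)

    dff = np.zeros((n_frames, H, W), dtype=np.float32)
    ihc_x = np.linspace(W / (n_ihc + 1), W - W / (n_ihc + 1), n_ihc)
    ihc_y = H // 2 - max(4, grid_px // 2)  # row of ovals just above the region
    ihc_dff = np.zeros((n_ihc, n_frames))

    events: list[PlantedEvent] = []
    for s in starts:
        cy = rng.uniform(1, n_rows - 1)
        cx = rng.uniform(1, n_cols - 1)
        ay = max(0.8, rng.normal(footprint_tiles / 2, footprint_tiles / 8))
        ax = max(0.8, rng.normal(footprint_tiles / 2, footprint_tiles / 8))
        members = [
            (gr, gc)
            for (gr, gc) in tiles
            if ((gr + 0.5 - cy) / ay) ** 2 + ((gc + 0.5 - cx) / ax) ** 2 <= 1.0
        ]
        if not members:
            continue
        amp = config.event_amplitude_dff
        end = s + len(kernel) - 1
        for gr, gc in members:
            ys, xs = tiles[(gr, gc)]
            for k, frac in enumerate(kernel):
                dff[s + k, ys, xs] += np.float32(amp * frac)
        # hair cells under the event's lateral footprint get a coupled transient
        x_lo = (cx - ax) * grid_px
        x_hi = (cx + ax) * grid_px
        member_ihcs = [i for i in range(n_ihc) if x_lo <= ihc_x[i] <= x_hi]
        for i in member_ihcs:
            for k, frac in enumerate(kernel):
                ihc_dff[i, s + k] += ihc_coupling_amplitude * frac
        voxels = np.array(
            [(s + k, gr, gc) for k in range(len(kernel)) for gr, gc in members], dtype=int
        )
        core = np.array(
            [
                (s + k, gr, gc)
                for k in range(len(kernel))
                if kernel[k] == 1.0
                for gr, gc in members
            ],
            dtype=int,
        )
        events.append(
            PlantedEvent(
                start_frame=s,
                end_frame=end,
                members=np.array(members, dtype=int),
                peak_dff=amp,
                voxels=voxels,
                core_voxels=core,
            )
        )
        events[-1].ihc_members = member_ihcs  # type: ignore[attr-defined]

    t = np.arange(n_frames, dtype=np.float32) / config.frame_rate_hz
    bleach = (
        np.exp(-t / config.bleach_tau_s, dtype=np.float32)
        if config.bleach_tau_s > 0
        else np.ones(n_frames, dtype=np.float32)
    )
    movie = BASELINE_F * (1.0 + dff) * bleach[:, None, None]
    if config.noise_sd_dff > 0:
        movie = movie + rng.normal(
            0.0, config.noise_sd_dff * BASELINE_F, size=movie.shape
        ).astype(np.float32)
        movie = np.clip(movie, 0.0, None)

    ihc_raw = BASELINE_F * (1.0 + ihc_dff) * bleach[None, :]
    if config.noise_sd_dff > 0:
        # oval-ROI traces average ~100 px, so trace noise is ~10x below pixel noise
        ihc_raw = ihc_raw + rng.normal(
            0.0, config.noise_sd_dff * BASELINE_F / 10.0, size=ihc_raw.shape
        )
    geometry = {
        i: (float(ihc_y), float(ihc_x[i]), 6.0, 3.0, 0.0) for i in range(n_ihc)
    }
    traces = RoiTraceSet(
        traces=ihc_raw,
        frame_rate_hz=config.frame_rate_hz,
        roi_ids=list(range(n_ihc)),
        roi_geometry=geometry,
    )
    gt = GroundTruth(
        events=events,
        extra={
            "grid_px": grid_px,
            "grid_shape": (n_rows, n_cols),
            "ihc_members": {ei: ev.ihc_members for ei, ev in enumerate(events)},  # type: ignore[attr-defined]
            "n_events_drawn": n_events,
        },
    )
    return CalciumMovie(movie, config.frame_rate_hz, config.pixel_scale_um), traces, gt


def gen_sgn_traces(
    config: SynthConfig,
    n_rois: int = 30,
    kcl_onset_s: float | None = None,
    responsive_fraction: float = 0.8,
    burst_rate_per_min: float = 3.0,
    burst_correlation: float = 0.8,
    burst_amplitude_dff: float = 0.4,
    kcl_amplitude_dff: float = 0.5,
    unresponsive_kcl_amplitude_dff: float = 0.05,
) -> tuple[RoiTraceSet, GroundTruth]:
    """Spiral-ganglion-neuron ΔF/F traces with correlated bursts and a
    terminal high-K⁺ wash response.

    A fraction of neurons is "responsive": they join population-wide burst
    events with probability ``burst_correlation`` and show a ramped response
    of ``kcl_amplitude_dff`` to the K⁺ wash; unresponsive neurons burst
    independently and respond only weakly to K⁺. GroundTruth flags the
    responsive set and records the K⁺ window.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    rng = config.rng()
    n_frames = config.n_frames
    if kcl_onset_s is None:
        kcl_onset_s = 0.8 * config.duration_s
    if not (0 < kcl_onset_s < config.duration_s):
        raise ValueError("K+ onset must lie within the recording")
    kcl_onset_f = int(kcl_onset_s * config.frame_rate_hz)

    responsive = np.zeros(n_rois, dtype=bool)
    responsive[: int(round(responsive_fraction * n_rois))] = True
    kernel = _event_kernel(2)

    dff = np.zeros((n_rois, n_frames))
    burst_window_frames = kcl_onset_f - len(kernel) - 1
    n_bursts = int(rng.poisson(burst_rate_per_min * (kcl_onset_s / 60.0)))
    burst_frames = sorted(rng.integers(1, max(2, burst_window_frames), size=n_bursts).tolist())
    for bf in burst_frames:
        participants = rng.random(n_rois) < burst_correlation
        participants &= responsive
        for i in np.nonzero(participants)[0]:
            seg = min(len(kernel), n_frames - bf)
            dff[i, bf : bf + seg] += burst_amplitude_dff * kernel[:seg]
    # independent bursts for unresponsive neurons
    for i in np.nonzero(~responsive)[0]:
        for bf in rng.integers(1, max(2, burst_window_frames), size=max(1, n_bursts)):
            seg = min(len(kernel), n_frames - bf)
            dff[i, bf : bf + seg] += burst_amplitude_dff * kernel[:seg]

    ramp = np.clip(
        (np.arange(n_frames) - kcl_onset_f) / (10.0 * config.frame_rate_hz), 0.0, 1.0
    )
    for i in range(n_rois):
        amp = kcl_amplitude_dff if responsive[i] else unresponsive_kcl_amplitude_dff
        dff[i] += amp * ramp
    if config.noise_sd_dff > 0:
        dff += rng.normal(0.0, config.noise_sd_dff, size=dff.shape)

    traces = RoiTraceSet(
        traces=dff, frame_rate_hz=config.frame_rate_hz, roi_ids=list(range(n_rois))
    )
    gt = GroundTruth(
        extra={
            "responsive": responsive,
            "kcl_window": (kcl_onset_f, n_frames),
            "burst_frames": burst_frames,
            "burst_correlation": burst_correlation,
        }
    )
    return traces, gt


def gen_widefield_ic(
    config: SynthConfig,
    band_angle_deg: float = 50.0,
    tone_schedule: StimulusLog | None = None,
    band_sigma_positions: float = 8.0,
    scan_length_px: int = 100,
    amplitude_sigma_ln: float = 0.4,
    evoked_threshold_db: float = 70.0,
    evoked_max_amplitude_dff: float = 0.10,
) -> tuple[CalciumMovie, StimulusLog | None, GroundTruth]:
    """Widefield inferior-colliculus movie with band-shaped events.

    Spontaneous mode (``tone_schedule`` None) plants events with a Gaussian
    cross-section across the tonotopic axis at drawn positions, with
    independent log-normal left/right amplitudes. Evoked mode plants one
    response band per stimulus whose position is linear in log₂ frequency
    and whose amplitude follows a saturating growth above the planted level
    threshold (zero below it). GroundTruth records, per event, the frame,
    line-scan position, width, and amplitudes; the tonotopic-axis geometry
    needed to place the line-scan rectangle is in ``extra``.
    """
    if not (0.0 <= band_angle_deg <= 90.0):
        raise ValueError("band angle must lie in [0, 90] degrees")
    rng = config.rng()
    H, W = config.image_shape
    n_frames = config.n_frames
    theta = np.deg2rad(band_angle_deg)
    axis_u = np.array([-np.sin(theta), np.cos(theta)])  # tonotopic axis direction

    centers = {"left": np.array([H / 2.0, W / 4.0]), "right": np.array([H / 2.0, 3 * W / 4.0])}
    radius = min(H, W) / 5.0
    yy, xx = np.mgrid[0:H, 0:W]
    region_masks = {}
    position_maps = {}
    for side, c in centers.items():
        region_masks[side] = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius**2
        # line-scan position of each pixel: projection on the axis, centered
        s = (yy - c[0]) * axis_u[0] + (xx - c[1]) * axis_u[1] + scan_length_px / 2.0
        position_maps[side] = s

    kernel_len = max(3, int(round(config.frame_rate_hz)))  # ~1 s triangular transient
    kernel = 1.0 - np.abs(np.linspace(-1, 1, 2 * kernel_len + 1))

    dff = np.zeros((n_frames, H, W), dtype=np.float32)
    events: list[dict] = []

    def paint(frame: int, pos: float, amp_l: float, amp_r: float) -> None:
        for side, amp in (("left", amp_l), ("right", amp_r)):
            if amp <= 0:
                continue
            prof = amp * np.exp(
                -((position_maps[side] - pos) ** 2) / (2 * band_sigma_positions**2)
            )
            prof = np.where(region_masks[side], prof, 0.0).astype(np.float32)
            for k, frac in enumerate(kernel):
                f = frame - kernel_len + k
                if 0 <= f < n_frames:
                    dff[f] += np.float32(frac) * prof

    if tone_schedule is None:
        n_events = int(rng.poisson(config.event_rate_per_min * config.duration_s / 60.0))
        frames = _disjoint_windows(rng, n_events, 2 * kernel_len + 1, n_frames, gap=2)
        for f in frames:
            pos = rng.uniform(0.2 * scan_length_px, 0.8 * scan_length_px)
            amp_l = config.event_amplitude_dff * rng.lognormal(0.0, amplitude_sigma_ln)
            amp_r = config.event_amplitude_dff * rng.lognormal(0.0, amplitude_sigma_ln)
            peak = f + kernel_len
            paint(peak, pos, amp_l, amp_r)
            events.append(
                {
                    "peak_frame": peak,
                    "position": pos,
                    "sigma_positions": band_sigma_positions,
                    "amp_left": amp_l,
                    "amp_right": amp_r,
                }
            )
    else:
        if np.any(tone_schedule.onset_frame + kernel_len >= n_frames):
            raise ValueError("tone schedule extends beyond the movie")
        freqs = np.asarray(tone_schedule.freq_hz, dtype=float)
        lo, hi = np.log2(freqs.min()), np.log2(max(freqs.max(), freqs.min() * 2))
        for i in range(len(tone_schedule)):
            f_hz = float(tone_schedule.freq_hz[i])
            level = float(tone_schedule.level_db[i])
            pos = (
                0.1 * scan_length_px
                + 0.8 * scan_length_px * (np.log2(f_hz) - lo) / (hi - lo)
            )
            amp = (
                evoked_max_amplitude_dff
                * (1.0 - np.exp(-(level - evoked_threshold_db) / 15.0))
                if level > evoked_threshold_db
                else 0.0
            )
            peak = int(tone_schedule.onset_frame[i]) + kernel_len // 2
            paint(peak, pos, 0.0, amp)  # contralateral (right) colliculus responds
            events.append(
                {
                    "peak_frame": peak,
                    "position": pos,
                    "freq_hz": f_hz,
                    "level_db": level,
                    "amp_right": amp,
                }
            )

    t = np.arange(n_frames, dtype=np.float32) / config.frame_rate_hz
    bleach = (
        np.exp(-t / config.bleach_tau_s, dtype=np.float32)
        if config.bleach_tau_s > 0
        else np.ones(n_frames, dtype=np.float32)
    )
    movie = BASELINE_F * (1.0 + dff) * bleach[:, None, None]
    if config.noise_sd_dff > 0:
        movie = movie + rng.normal(
            0.0, config.noise_sd_dff * BASELINE_F, size=movie.shape
        ).astype(np.float32)
        movie = np.clip(movie, 0.0, None)

    gt = GroundTruth(
        planted_threshold_db=(None if tone_schedule is None else evoked_threshold_db),
        extra={
            "band_events": events,
            "centers": centers,
            "radius": radius,
            "angle_deg": band_angle_deg,
            "scan_length_px": scan_length_px,
            "band_sigma_positions": band_sigma_positions,
            "evoked_max_amplitude_dff": evoked_max_amplitude_dff,
        },
    )
    return (
        CalciumMovie(movie, config.frame_rate_hz, config.pixel_scale_um),
        tone_schedule,
        gt,
    )


def _interp_crossing(levels: np.ndarray, values: np.ndarray, criterion: float) -> float:
    """Closed-form lowest crossing of a non-decreasing planted curve over a
    criterion (the generator-side counterpart of threshold interpolation)."""
    above = values > criterion
    if not above.any():
        return float("nan")
    idx = int(np.argmax(above))
    if idx == 0:
        return float(levels[0])
    lo, hi = idx - 1, idx
    frac = (criterion - values[lo]) / (values[hi] - values[lo])
    return float(levels[lo] + frac * (levels[hi] - levels[lo]))


def gen_abr_series(
    levels_db: np.ndarray | None = None,
    onset_level_db: float = 40.0,
    growth_uv_per_db: float = 0.1,
    background_pp_uv: float = 3.0,
    background_pp_sd_uv: float = 1.0,
    seed: int = 0,
    n_samples: int = 120,
    background_samples: int = 30,
):
    """ABR waveform family whose peak-to-peak grows above a planted onset.

    Each level's averaged waveform carries a background-window oscillation
    with peak-to-peak drawn as N(``background_pp_uv``, ``background_pp_sd_uv``)
    (floored at 0.05 µV) and a signal-window wave whose peak-to-peak is the
    expected noise floor plus max(0, growth·(level − onset)). The
    ground-truth threshold is the closed-form level at which that planted
    growth curve crosses the realized detection criterion
    (mean + 2 SD of the drawn background peak-to-peaks).

    Returns (AbrSeries, GroundTruth).
    """
    from .audiometry import AbrSeries

    if growth_uv_per_db <= 0:
        raise ValueError("growth must be positive")
    if levels_db is None:
        levels_db = np.arange(10.0, 101.0, 5.0)
    levels_db = np.asarray(levels_db, dtype=float)
    if np.any(np.diff(levels_db) <= 0):
        raise ValueError("levels must be sorted ascending")
    if not (levels_db[0] <= onset_level_db <= levels_db[-1]):
        raise ValueError("onset level must lie within the tested range")
    rng = np.random.default_rng(seed)

    bg_pp = np.maximum(
        rng.normal(background_pp_uv, background_pp_sd_uv, size=levels_db.size), 0.05
    )
    sig_pp = background_pp_uv + np.maximum(0.0, growth_uv_per_db * (levels_db - onset_level_db))

    n_bg = background_samples
    waveforms = np.zeros((levels_db.size, n_samples))
    # exact-p2p oscillations: alternating +/- half amplitude on a 4-sample cycle
    cycle = np.array([0.0, 0.5, 0.0, -0.5])
    bg_pattern = np.tile(cycle, n_bg // 4 + 1)[:n_bg]
    sig_pattern = np.tile(cycle, (n_samples - n_bg) // 4 + 1)[: n_samples - n_bg]
    for i in range(levels_db.size):
        waveforms[i, :n_bg] = bg_pp[i] * bg_pattern
        waveforms[i, n_bg:] = sig_pp[i] * sig_pattern

    criterion = float(bg_pp.mean() + 2.0 * bg_pp.std())
    planted = _interp_crossing(levels_db, sig_pp, criterion)
    censored = not np.isfinite(planted)
    series = AbrSeries(
        levels_db=levels_db,
        waveforms=waveforms,
        sample_rate_hz=24414.0,
        signal_window=slice(n_bg, n_samples),
        background_window=slice(0, n_bg),
    )
    gt = GroundTruth(
        planted_threshold_db=None if censored else planted,
        extra={
            "onset_level_db": onset_level_db,
            "criterion_uv": criterion,
            "background_pp_uv": bg_pp,
            "signal_pp_uv": sig_pp,
            "censored": censored,
        },
    )
    return series, gt


def gen_dpoae_spectra(
    fc_hz: float = 16000.0,
    levels_db: np.ndarray | None = None,
    onset_level_db: float = 40.0,
    growth_db_per_db: float = 1.0,
    noise_floor_db: float = -10.0,
    noise_sd_db: float = 0.0,
    dp_max_above_floor_db: float = 40.0,
    seed: int = 0,
    n_bins: int = 241,
):
    """DPOAE spectrum family with primaries and a growing 2F1−F2 component.

    Spectra cover 0.5–1.25·Fc; the distortion-product bin rises
    max(0, growth·(level − onset)) dB above the noise floor (capped at
    ``dp_max_above_floor_db``), primaries sit at F1 and F2. The ground-truth
    threshold is the closed-form crossing of the planted DP-above-floor
    curve over the realized mean + 2 SD adjacent-noise criterion.

    Returns (DpoaeSeries, GroundTruth).
    """
    from .audiometry import DpoaeSeries, dpoae_frequencies

    if not (200.0 <= fc_hz <= 100000.0):
        raise ValueError("center frequency outside the audio range")
    if levels_db is None:
        levels_db = np.arange(20.0, 91.0, 5.0)
    levels_db = np.asarray(levels_db, dtype=float)
    rng = np.random.default_rng(seed)
    f1, f2, fdp = dpoae_frequencies(fc_hz)
    freqs = np.linspace(0.5 * fc_hz, 1.25 * fc_hz, n_bins)

    spectra = np.full((levels_db.size, n_bins), noise_floor_db, dtype=float)
    if noise_sd_db > 0:
        spectra += rng.normal(0.0, noise_sd_db, size=spectra.shape)
    b1 = int(np.argmin(np.abs(freqs - f1)))
    b2 = int(np.argmin(np.abs(freqs - f2)))
    bdp = int(np.argmin(np.abs(freqs - fdp)))
    dp_above = np.minimum(
        np.maximum(0.0, growth_db_per_db * (levels_db - onset_level_db)),
        dp_max_above_floor_db,
    )
    for i, level in enumerate(levels_db):
        spectra[i, b1] = level - 10.0  # primaries dominate the spectrum
        spectra[i, b2] = level - 15.0
        spectra[i, bdp] = noise_floor_db + dp_above[i]

    series = DpoaeSeries(fc_hz=fc_hz, levels_db=levels_db, freqs_hz=freqs, spectra=spectra)

    # realized criterion in the detector's adjacent band (±10 bins minus ±2 guard)
    band = [
        b
        for b in range(max(0, bdp - 10), min(n_bins, bdp + 11))
        if abs(b - bdp) > 2 and b not in (b1, b2)
    ]
    noise_vals = spectra[:, band]
    crit = noise_vals.mean(axis=1) + 2.0 * noise_vals.std(axis=1)
    margin = (noise_floor_db + dp_above) - crit
    planted = _interp_crossing(levels_db, margin, 0.0)
    censored = not np.isfinite(planted)
    gt = GroundTruth(
        planted_threshold_db=None if censored else planted,
        extra={
            "onset_level_db": onset_level_db,
            "f1_hz": f1,
            "f2_hz": f2,
            "f_dp_hz": fdp,
            "censored": censored,
        },
    )
    return series, gt


def gen_crenation_movie(
    config: SynthConfig,
    n_regions: int = 3,
    region_area_um2: float = 2500.0,
    darkening_fraction: float = 0.25,
    ramp_s: float = 4.0,
    min_separation_px: int = 60,
) -> tuple[np.ndarray, GroundTruth]:
    """Transmitted-light movie with slowly darkening crenation patches.

    Square patches of the requested physical area appear at staggered onset
    frames and darken linearly over ``ramp_s`` seconds. Patches are placed
    with at least ``min_separation_px`` between edges; a configuration that
    cannot fit that many disjoint patches raises.
    """
    rng = config.rng()
    H, W = config.image_shape
    n_frames = config.n_frames
    side = int(round(np.sqrt(region_area_um2) / config.pixel_scale_um))
    if side < 2:
        raise ValueError("patch side below 2 px; increase area or resolution")

    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n_regions and attempts < 2000:
        attempts += 1
        r = int(rng.integers(10, max(11, H - side - 10)))
        c = int(rng.integers(10, max(11, W - side - 10)))
        if all(
            abs(r - pr) >= side + min_separation_px or abs(c - pc) >= side + min_separation_px
            for pr, pc in placed
        ):
            placed.append((r, c))
    if len(placed) < n_regions:
        raise ValueError("could not place disjoint crenation patches; reduce count or size")

    movie = np.full((n_frames, H, W), BASELINE_F, dtype=np.float32)
    ramp_frames = max(1, int(round(ramp_s * config.frame_rate_hz)))
    regions = []
    for i, (r, c) in enumerate(placed):
        onset = int(rng.integers(n_frames // 8, max(n_frames // 8 + 1, n_frames // 2)))
        depth = darkening_fraction * BASELINE_F
        for k in range(n_frames - onset):
            frac = min(1.0, k / ramp_frames)
            movie[onset + k, r : r + side, c : c + side] -= np.float32(frac * depth)
        pixels = np.array(
            [(rr, cc) for rr in range(r, r + side) for cc in range(c, c + side)], dtype=int
        )
        regions.append(
            {
                "pixels": pixels,
                "onset_frame": onset,
                "area_um2": side * side * config.pixel_scale_um**2,
            }
        )
    if config.noise_sd_dff > 0:
        movie = movie + rng.normal(
            0.0, config.noise_sd_dff * BASELINE_F, size=movie.shape
        ).astype(np.float32)
    gt = GroundTruth(crenation_regions=regions, extra={"patch_side_px": side})
    return movie, gt


def gen_2p_tuning(
    n_cells: int = 200,
    freqs_hz: np.ndarray | None = None,
    levels_db: np.ndarray | None = None,
    sigma_octaves: float = 0.5,
    threshold_db: float = 50.0,
    peak_amplitude_dff: float = 1.0,
    noise_sd_fraction: float = 0.05,
    archetypes: int = 1,
    seed: int = 0,
):
    """Two-photon tuning tensor: Gaussian frequency tuning × sigmoid of level.

    Per cell, the peak response at (frequency f, level L) is
    amplitude · exp(−(log₂f − log₂BF)²/(2σ²)) · s(L) + noise, with s a
    logistic function of level centered on the cell's threshold. Best
    frequencies are drawn from the interior tested frequencies. With
    ``archetypes=2``, cells split into two response archetypes (low-BF
    narrow/weak vs high-BF broad/strong) for cluster-separation tests.

    Returns (TuningTensor, GroundTruth).
    """
    from .tuning import TuningTensor

    if freqs_hz is None:
        freqs_hz = 4000.0 * 2.0 ** (0.5 * np.arange(9))  # 4–64 kHz, ½-octave steps
    if levels_db is None:
        levels_db = np.arange(30.0, 91.0, 20.0)  # 30–90 dB SPL
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    levels_db = np.asarray(levels_db, dtype=float)
    if freqs_hz.size < 2 or levels_db.size < 2:
        raise ValueError("need at least 2 frequencies and 2 levels")
    rng = np.random.default_rng(seed)
    x = np.log2(freqs_hz)

    per_cell = []
    responses = np.zeros((n_cells, freqs_hz.size, levels_db.size))
    for cell in range(n_cells):
        group = cell % archetypes
        if archetypes == 2 and group == 1:
            bf = freqs_hz[int(rng.integers(freqs_hz.size - 3, freqs_hz.size - 1))]
            sigma = sigma_octaves * 2.0
            amp = peak_amplitude_dff * 2.0
            thr = threshold_db - 10.0
        else:
            lo = 1 if archetypes == 2 else 1
            hi = 3 if archetypes == 2 else freqs_hz.size - 1
            bf = freqs_hz[int(rng.integers(lo, hi))]
            sigma = sigma_octaves
            amp = peak_amplitude_dff
            thr = threshold_db
        level_gain = 1.0 / (1.0 + np.exp(-(levels_db - thr) / 8.0))
        freq_gain = np.exp(-((x - np.log2(bf)) ** 2) / (2 * sigma**2))
        responses[cell] = amp * np.outer(freq_gain, level_gain)
        per_cell.append(
            {
                "best_frequency_hz": float(bf),
                "sigma_octaves": float(sigma),
                "threshold_db": float(thr),
                "amplitude_dff": float(amp),
                "archetype": int(group),
            }
        )
    if noise_sd_fraction > 0:
        responses += rng.normal(
            0.0, noise_sd_fraction * peak_amplitude_dff, size=responses.shape
        )
    tensor = TuningTensor(responses=responses, freqs_hz=freqs_hz, levels_db=levels_db)
    gt = GroundTruth(per_cell_tuning=per_cell)
    return tensor, gt
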