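"""In vivo widefield analysis of the inferior colliculus.

Spontaneous event detection with left/right dominance, tonotopic line scans
from a rotated rectangular ROI, band-shaped event detection by regional
maxima, band width above the 75th percentile of the peak, spatial integrals,
tone-evoked unmixing/averaging, response thresholds, and activated-area
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .audiometry import interpolate_threshold
from .trace import detect_peaks
from .types import StimulusLog, ThresholdResult

BAND_WIDTH_FACTOR = 2.0 * np.sqrt(2.0 * np.log(4.0 / 3.0))  # Gaussian σ → width above 0.75·peak


@dataclass
class IcEvent:
    """One spontaneous bilateral event in the inferior colliculus."""

    peak_frame: int
    left_amplitude: float
    right_amplitude: float
    dominant_side: str  # "left" | "right"
    half_width_s: float


def _fwhm_s(trace: np.ndarray, peak: int, frame_rate_hz: float) -> float:
    """Full width at half max of the transient around ``peak``, in seconds
    (linear interpolation at the half-max crossings)."""
    half = trace[peak] / 2.0
    left = peak
    while left > 0 and trace[left] > half:
        left -= 1
    right = peak
    n = len(trace)
    while right < n - 1 and trace[right] > half:
        right += 1
    # interpolate fractional crossings
    lf = left + (half - trace[left]) / (trace[left + 1] - trace[left]) if trace[left] <= half and peak > left else float(left)
    rf = right - (half - trace[right]) / (trace[right - 1] - trace[right]) if trace[right] <= half and right > peak else float(right)
    return float((rf - lf) / frame_rate_hz)


def detect_ic_events(
    left_trace: np.ndarray,
    right_trace: np.ndarray,
    frame_rate_hz: float,
    threshold: float = 0.01,
    min_amplitude: float = 0.01,
    match_window_s: float = 1.0,
) -> list[IcEvent]:
    """Detect spontaneous events on mean left/right collicular ΔF/F traces.

    Peaks on each side must exceed the fixed 1 % ΔF/F threshold and minimum
    amplitude; peaks on the two sides within ±``match_window_s`` are merged
    into one bilateral event whose dominant side carries the larger
    amplitude. Unmatched peaks become unilateral events (amplitude 0 on the
    silent side).
    """
    from scipy.signal import find_peaks

    left = np.asarray(left_trace, float)
    right = np.asarray(right_trace, float)
    height = np.nextafter(max(threshold, min_amplitude), np.inf)

    def _peaks(tr: np.ndarray) -> list[tuple[int, float]]:
        _, props = find_peaks(tr, height=height, plateau_size=(1, None))
        return [(int(i), float(tr[i])) for i in props["left_edges"]]

    lp = _peaks(left)
    rp = _peaks(right)

    window = int(round(match_window_s * frame_rate_hz))
    events: list[IcEvent] = []
    used_r: set[int] = set()
    for f, la in lp:
        match = None
        for j, (rf, ra) in enumerate(rp):
            if j not in used_r and abs(rf - f) <= window:
                match = (j, rf, ra)
                break
        if match is not None:
            j, rf, ra = match
            used_r.add(j)
            peak_frame = f if la >= ra else rf
            trace = left if la >= ra else right
            events.append(
                IcEvent(
                    peak_frame=int(peak_frame),
                    left_amplitude=float(la),
                    right_amplitude=float(ra),
                    dominant_side="left" if la >= ra else "right",
                    half_width_s=_fwhm_s(trace, peak_frame, frame_rate_hz),
                )
            )
        else:
            events.append(
                IcEvent(int(f), float(la), 0.0, "left", _fwhm_s(left, f, frame_rate_hz))
            )
    for j, (rf, ra) in enumerate(rp):
        if j not in used_r:
            events.append(
                IcEvent(int(rf), 0.0, float(ra), "right", _fwhm_s(right, rf, frame_rate_hz))
            )
    events.sort(key=lambda e: e.peak_frame)
    return events


@dataclass
class LineScanProfile:
    """Spatial profile along the tonotopic axis, one column per frame.

    ``profile`` is (positions, frames): each column is the rotated
    rectangle's short-axis average at one frame.
    """

    profile: np.ndarray
    rect_size_px: tuple[int, int]  # (short axis, long axis)
    angle_deg: float
    frame_rate_hz: float


def tonotopic_linescan(
    movie: np.ndarray,
    center_yx: tuple[float, float],
    length_px: int,
    width_px: int,
    angle_deg: float,
    frame_rate_hz: float = 10.0,
) -> LineScanProfile:
    """Average a rotated rectangular ROI across its short axis per frame.

    The rectangle is centered at ``center_yx``, its long axis of
    ``length_px`` positions rotated ``angle_deg`` degrees counterclockwise
    from the +x (column) direction. Pixels are sampled by bilinear
    interpolation; sampling outside the frame is an error.
    """
    movie = np.asarray(movie, dtype=float)
    T, H, W = movie.shape
    theta = np.deg2rad(angle_deg)
    u = np.array([-np.sin(theta), np.cos(theta)])  # long axis direction (dy, dx)
    v = np.array([np.cos(theta), np.sin(theta)])  # short axis direction
    s = np.arange(length_px) - (length_px - 1) / 2.0
    t = np.arange(width_px) - (width_px - 1) / 2.0
    yy = center_yx[0] + np.add.outer(s * u[0], t * v[0])  # (length, width)
    xx = center_yx[1] + np.add.outer(s * u[1], t * v[1])
    if yy.min() < 0 or xx.min() < 0 or yy.max() > H - 1 or xx.max() > W - 1:
        raise ValueError("rotated rectangle extends outside the frame")
    coords = np.stack([yy.ravel(), xx.ravel()])
    profile = np.empty((length_px, T))
    for f in range(T):
        samp = ndimage.map_coordinates(movie[f], coords, order=1, mode="nearest")
        profile[:, f] = samp.reshape(length_px, width_px).mean(axis=1)
    return LineScanProfile(
        profile=profile,
        rect_size_px=(width_px, length_px),
        angle_deg=angle_deg,
        frame_rate_hz=frame_rate_hz,
    )


def regional_maxima(image: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """8-connected regional maxima of a 2D image above ``threshold``.

    A plateau (connected set of equal values with no greater neighbor)
    counts as one maximum at its centroid (rounded to the nearest pixel).
    """
    img = np.asarray(image, dtype=float)
    if np.all(img == img.flat[0]):
        return []  # a flat field has no transient structure
    struct = np.ones((3, 3), dtype=bool)
    # candidate pixels equal the max of their 3x3 neighborhood (frame edges padded −inf)
    neigh_max = ndimage.maximum_filter(img, footprint=struct, mode="constant", cval=-np.inf)
    candidates = img >= neigh_max
    out: list[tuple[int, int]] = []
    plab, pn = ndimage.label(candidates, structure=struct)
    for lab in range(1, pn + 1):
        mask = plab == lab
        val = img[mask].max()
        if val <= threshold:
            continue
        mask = mask & (img == val)  # keep the top-valued plateau of the component
        grown = ndimage.binary_dilation(mask, structure=struct) & ~mask
        if grown.any() and img[grown].max() >= val:
            continue
        ys, xs = np.nonzero(mask)
        out.append((int(round(ys.mean())), int(round(xs.mean()))))
    out.sort()
    return out


def detect_band_events(
    profile: LineScanProfile, threshold: float = 0.02
) -> list[tuple[int, int]]:
    """Regional maxima of the (position × time) line-scan image above the
    fixed 2 % ΔF/F threshold; returns (frame, peak_position) pairs."""
    maxima = regional_maxima(profile.profile, threshold)
    return sorted((int(x), int(pos)) for pos, x in maxima)


def band_width(
    spatial_profile: np.ndarray,
    percentile_of_peak: float = 0.75,
    position_scale: float = 1.0,
) -> float:
    """Width of the tonotopic band above 75 % of its peak.

    The profile is normalized to its maximum and the width is the contiguous
    run of positions about the peak whose normalized value exceeds
    ``percentile_of_peak``, multiplied by ``position_scale``.
    """
    p = np.asarray(spatial_profile, dtype=float)
    peak_val = p.max()
    if peak_val <= 0:
        raise ValueError("profile peak must be positive")
    norm = p / peak_val
    peak = int(np.argmax(norm))
    left = peak
    while left > 0 and norm[left - 1] > percentile_of_peak:
        left -= 1
    right = peak
    while right < len(norm) - 1 and norm[right + 1] > percentile_of_peak:
        right += 1
    return float((right - left + 1) * position_scale)


def spatial_integral(spatial_profile: np.ndarray) -> float:
    """Trapezoidal integral of the profile at unit position spacing."""
    return float(np.trapezoid(np.asarray(spatial_profile, dtype=float)))


@dataclass
class ToneResponseMap:
    """Tone-aligned mean responses per (frequency, level).

    ``segments[(freq, level)]`` is the mean aligned movie/trace segment from
    1 s before to 3 s after tone onset; ``amplitudes`` is the summary
    response (post-onset peak of the mean ROI trace minus the 1-s pre-onset
    baseline mean); ``repeats`` counts presentations averaged.
    """

    segments: dict[tuple[float, float], np.ndarray]
    amplitudes: dict[tuple[float, float], float]
    repeats: dict[tuple[float, float], int]
    pre_s: float
    post_s: float


def unmix_tone_responses(
    dff: np.ndarray,
    log: StimulusLog,
    frame_rate_hz: float,
    pre_s: float = 1.0,
    post_s: float = 3.0,
) -> ToneResponseMap:
    """Separate a recording by stimulus, align around onsets, and average.

    ``dff`` is either a movie (T, Y, X) or a 1D ROI trace (T,). Windows run
    from ``pre_s`` before to ``post_s`` after each onset and must fit inside
    the recording and not overlap the next stimulus window.
    """
    dff = np.asarray(dff, dtype=float)
    n_frames = dff.shape[0]
    pre_f = int(round(pre_s * frame_rate_hz))
    post_f = int(round(post_s * frame_rate_hz))
    onsets = log.onset_frame
    if np.any(onsets - pre_f < 0) or np.any(onsets + post_f > n_frames):
        raise ValueError("aligned window extends outside the recording")
    if np.any(np.diff(onsets) < pre_f + post_f):
        raise ValueError("analysis windows of consecutive stimuli overlap")

    groups: dict[tuple[float, float], list[np.ndarray]] = {}
    for i in range(len(log)):
        key = (float(log.freq_hz[i]), float(log.level_db[i]))
        seg = dff[onsets[i] - pre_f : onsets[i] + post_f]
        groups.setdefault(key, []).append(seg)

    segments, amplitudes, repeats = {}, {}, {}
    for key, segs in groups.items():
        mean_seg = np.mean(segs, axis=0)
        trace = mean_seg if mean_seg.ndim == 1 else mean_seg.mean(axis=(1, 2))
        baseline = trace[:pre_f].mean()
        amplitudes[key] = float(trace[pre_f:].max() - baseline)
        segments[key] = mean_seg
        repeats[key] = len(segs)
    return ToneResponseMap(segments, amplitudes, repeats, pre_s, post_s)


def response_threshold(
    levels_db: np.ndarray,
    amplitudes: np.ndarray,
    baseline_mean: float = 0.0,
    baseline_sd: float = 0.0,
    k_sd: float = 2.0,
) -> ThresholdResult:
    """Tone-evoked response threshold, mirroring the ABR interpolation rule.

    Criterion = baseline mean + ``k_sd``·baseline SD; threshold is the
    interpolated lowest level whose summary amplitude exceeds it, or the
    censored sentinel when none does.
    """
    criterion = baseline_mean + k_sd * baseline_sd
    return interpolate_threshold(np.asarray(levels_db, float), np.asarray(amplitudes, float), criterion)


def activated_area(
    mean_response: np.ndarray, pixel_scale_um: float, threshold: float = 0.15
) -> float:
    """Total area (mm²) of pixels whose mean evoked ΔF/F exceeds 15 %."""
    img = np.asarray(mean_response, dtype=float)
    n = int(np.sum(img > threshold))
    return n * (pixel_scale_um / 1000.0) ** 2


def tonotopic_peak_shift(
    profiles: dict[float, np.ndarray],
) -> dict[str, dict[float, float]]:
    """Peak response location per tone frequency along the tonotopic axis.

    Returns the per-frequency argmax position plus shifts relative to the
    medial end (absolute position) and to the lowest tested frequency's
    peak. A tie at the maximum resolves to the first position.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    positions = {
        float(f): float(np.argmax(np.asarray(p, dtype=float))) for f, p in profiles.items()
    }
    f_lo = min(positions)
    return {
        "position": positions,
        "shift_vs_medial": dict(positions),
        "shift_vs_lowest_freq": {f: p - positions[f_lo] for f, p in positions.items()},
    }
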