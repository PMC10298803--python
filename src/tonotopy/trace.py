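"""Signal-conditioning primitives shared by every imaging analysis.

ΔF/F normalization (per-pixel 10th-percentile or per-ROI median baseline),
single-exponential photobleach correction, threshold-based peak detection, and
neuropil subtraction for two-photon somatic traces.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .types import DffTrace

BASELINE_METHODS = ("pixel_p10", "roi_median")


def normalize_dff(raw: np.ndarray, method: str = "pixel_p10") -> DffTrace:
    """Convert raw fluorescence to ΔF/F = (F − F₀)/F₀.

    Parameters
    ----------
    raw : ndarray
        1D trace (time,), 2D trace set (roi, time), or 3D movie (time, y, x).
        The time axis is axis 0 for 1D/3D input and axis 1 for 2D input.
    method : {"pixel_p10", "roi_median"}
        "pixel_p10": F₀ is the 10th percentile over time, per pixel/element
        (linear interpolation between order statistics).
        "roi_median": F₀ is the median over time.

    Returns
    -------
    DffTrace
        ΔF/F values of the same shape, with the F₀ used.

    Raises
    ------
    ValueError
        If any baseline F₀ ≤ 0 (the offending flat index is named) or the
        input is non-finite.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw fluorescence must be finite")
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline method {method!r}; use one of {BASELINE_METHODS}")

    time_axis = 1 if raw.ndim == 2 else 0
    if method == "pixel_p10":
        f0 = np.percentile(raw, 10, axis=time_axis)
    else:
        f0 = np.median(raw, axis=time_axis)

    bad = np.asarray(f0 <= 0)
    if bad.any():
        idx = np.argwhere(np.atleast_1d(bad))[0]
        raise ValueError(f"baseline F0 <= 0 at index {tuple(int(i) for i in idx)}")

    f0_b = np.expand_dims(f0, axis=time_axis) if np.ndim(f0) else f0
    values = (raw - f0_b) / f0_b
    return DffTrace(values=values, baseline_f0=np.asarray(f0), baseline_method=method)


def _exp_model(t: np.ndarray, a: float, tau: float, c: float) -> np.ndarray:
    return a * np.exp(-t / tau) + c


def correct_photobleach(
    trace: np.ndarray, frame_rate_hz: float = 1.0
) -> tuple[np.ndarray, dict]:
    """Remove a slow mono-exponential bleaching trend from a trace.

    Fits F(t) = a·exp(−t/τ) + c by least squares (initialized from a
    log-linear regression of the detrended positive part) and subtracts only
    the decaying a·exp(−t/τ) component — the offset c is retained, so the
    trace keeps its baseline level.

    Returns
    -------
    corrected : ndarray
        Trace minus the fitted exponential component.
    fit : dict
        Keys ``a``, ``tau_s``, ``c``, and ``converged``; on fit failure the
        input is returned unchanged with ``converged=False``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("correct_photobleach expects a 1D trace")
    if trace.size < 10:
        raise ValueError("trace must have at least 10 frames")
    t = np.arange(trace.size) / frame_rate_hz

    c0 = trace.min()
    resid0 = trace - c0 + 1e-12
    # log-linear init: log(F - c0) ~ log a - t/tau
    with np.errstate(divide="ignore"):
        coef = np.polyfit(t, np.log(resid0), 1)
    tau0 = -1.0 / coef[0] if coef[0] < 0 else t[-1]
    a0 = float(np.exp(coef[1]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _exp_model,
                t,
                trace,
                p0=(a0, max(tau0, 1e-3), c0),
                maxfev=5000,
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            )
        a, tau, c = popt
    except (RuntimeError, ValueError):
        return trace.copy(), {"a": np.nan, "tau_s": np.nan, "c": np.nan, "converged": False}

    corrected = trace - a * np.exp(-t / tau)
    return corrected, {"a": float(a), "tau_s": float(tau), "c": float(c), "converged": True}


def detect_peaks(
    trace: np.ndarray,
    k_sd: float = 3.0,
    min_amplitude: float = 0.10,
) -> list[tuple[int, float]]:
    """Find signal peaks exceeding a fixed statistical threshold.

    A frame is a peak when it is a strict local maximum (plateau ties resolve
    to the first frame), its value exceeds median + ``k_sd``·SD of the whole
    trace (single-pass SD, events included), and its value exceeds
    ``min_amplitude``.

    Returns a list of (peak_frame, amplitude) sorted by frame.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    threshold = float(np.median(trace) + k_sd * np.std(trace))
    height = max(threshold, min_amplitude)
    # strictly-greater criterion: nudge height up by the smallest representable step;
    # plateau ties resolve to the first frame of the plateau
    _, props = find_peaks(
        trace, height=np.nextafter(height, np.inf), plateau_size=(1, None)
    )
    idx = props["left_edges"]
    return [(int(i), float(trace[i])) for i in idx]


def subtract_neuropil(
    soma: np.ndarray, neuropil: np.ndarray, r: float = 0.7
) -> np.ndarray:
    """Return soma − r·neuropil, elementwise (default r = 0.7)."""
    soma = np.asarray(soma, dtype=float)
    neuropil = np.asarray(neuropil, dtype=float)
    if soma.shape != neuropil.shape:
        raise ValueError(f"length mismatch: soma {soma.shape} vs neuropil {neuropil.shape}")
    return soma - r * neuropil
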