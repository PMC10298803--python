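"""Automated ABR and DPOAE threshold detection.

ABR threshold: the lowest stimulus level, by linear interpolation of the
level/peak-to-peak curve, whose averaged-waveform peak-to-peak amplitude
exceeds mean + 2 SD of the background peak-to-peak signal. DPOAE threshold:
the analogous interpolated crossing of the 2F1−F2 spectral peak over the
mean + 2 SD of the noise floor adjacent to that frequency. Primaries follow
F1 = 0.909·Fc and F2 = 1.09·Fc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ThresholdResult

F1_FACTOR = 0.909
F2_FACTOR = 1.09


def dpoae_frequencies(fc_hz: float) -> tuple[float, float, float]:
    """Primary and distortion-product frequencies for a center frequency.

    Returns (f1, f2, f_dp) with f1 = 0.909·fc, f2 = 1.09·fc and
    f_dp = 2·f1 − f2.
    """
    if fc_hz <= 0:
        raise ValueError("center frequency must be positive")
    f1 = F1_FACTOR * fc_hz
    f2 = F2_FACTOR * fc_hz
    return f1, f2, 2 * f1 - f2


def abr_peak_to_peak(waveform: np.ndarray, window: slice | None = None) -> float:
    """Peak-to-peak amplitude (max − min) within the analysis window."""
    w = np.asarray(waveform, dtype=float)
    if window is not None:
        w = w[window]
    if w.size == 0:
        raise ValueError("analysis window is empty")
    return float(w.max() - w.min())


def interpolate_threshold(
    levels_db: np.ndarray,
    amplitudes: np.ndarray,
    criterion: float,
    level_step_db: float | None = None,
) -> ThresholdResult:
    """Lowest level whose response exceeds criterion, by linear interpolation.

    Finds the lowest level L such that the amplitude at L and at every higher
    level exceeds the criterion (a monotone crossing); the threshold is the
    linear interpolation of level against amplitude between L and the next
    lower level. If the lowest tested level already exceeds criterion the
    threshold clamps there; if no level ever exceeds it, the result is the
    censored sentinel one level step above the maximum tested level.
    Sub-criterion amplitudes above a crossing (non-monotone families) use the
    highest crossing and carry a warning.
    """
    levels = np.asarray(levels_db, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if levels.size < 2:
        raise ValueError("need at least 2 levels")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be strictly ascending")
    if level_step_db is None:
        level_step_db = float(np.diff(levels).max())

    above = amps > criterion
    if not above.any():
        return ThresholdResult(
            threshold_db=float(levels[-1] + level_step_db),
            criterion_value=float(criterion),
            bracket_levels=None,
            censored=True,
        )
    # lowest index from which all higher levels stay above criterion
    idx = len(above) - 1
    while idx > 0 and above[idx - 1]:
        idx -= 1
    warning = None
    if np.any(above[:idx]):
        warning = "non-monotone level series; used highest crossing"
    if idx == 0:
        return ThresholdResult(
            threshold_db=float(levels[0]),
            criterion_value=float(criterion),
            bracket_levels=(float(levels[0]), float(levels[0])),
            warning=warning,
        )
    lo, hi = idx - 1, idx
    frac = (criterion - amps[lo]) / (amps[hi] - amps[lo])
    thr = levels[lo] + frac * (levels[hi] - levels[lo])
    return ThresholdResult(
        threshold_db=float(thr),
        criterion_value=float(criterion),
        bracket_levels=(float(levels[lo]), float(levels[hi])),
        warning=warning,
    )


@dataclass
class AbrSeries:
    """Averaged ABR waveforms, one per stimulus level (ascending).

    ``waveforms`` is (n_levels, n_samples) in µV; ``signal_window`` and
    ``background_window`` are disjoint sample slices — by default background
    is the pre-stimulus segment at the start of each averaged trace.
    """

    levels_db: np.ndarray
    waveforms: np.ndarray
    sample_rate_hz: float
    signal_window: slice
    background_window: slice

    def __post_init__(self) -> None:
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if self.waveforms.shape[0] != self.levels_db.size:
            raise ValueError("one waveform per level required")
        if np.any(np.diff(self.levels_db) <= 0):
            raise ValueError("levels must be ascending")


def abr_threshold(series: AbrSeries, k_sd: float = 2.0) -> ThresholdResult:
    """Automated ABR threshold from a level series of averaged waveforms.

    The criterion is mean + ``k_sd``·SD of the per-level background
    peak-to-peak amplitudes; the threshold is the interpolated lowest level
    whose signal-window peak-to-peak exceeds it.
    """
    signal_pp = np.array(
        [abr_peak_to_peak(w, series.signal_window) for w in series.waveforms]
    )
    background_pp = np.array(
        [abr_peak_to_peak(w, series.background_window) for w in series.waveforms]
    )
    criterion = float(background_pp.mean() + k_sd * background_pp.std())
    return interpolate_threshold(series.levels_db, signal_pp, criterion)


@dataclass
class DpoaeSeries:
    """Per-level acoustic spectra bracketing the 2F1−F2 distortion product.

    ``spectra`` is (n_levels, n_bins) in dB SPL over ``freqs_hz``.
    """

    fc_hz: float
    levels_db: np.ndarray
    freqs_hz: np.ndarray
    spectra: np.ndarray

    def __post_init__(self) -> None:
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        f1, f2, fdp = dpoae_frequencies(self.fc_hz)
        if not (self.freqs_hz[0] <= fdp <= self.freqs_hz[-1]):
            raise ValueError("spectra must cover the distortion-product frequency")

    @property
    def f_dp_hz(self) -> float:
        return dpoae_frequencies(self.fc_hz)[2]


def dpoae_threshold(
    series: DpoaeSeries,
    k_sd: float = 2.0,
    noise_band_bins: int = 10,
    guard_bins: int = 2,
) -> ThresholdResult:
    """Automated DPOAE threshold from a family of per-level spectra.

    Per level, the distortion-product amplitude is the spectrum at the bin
    nearest 2F1−F2, and the noise criterion is mean + ``k_sd``·SD of the
    ±``noise_band_bins`` bins around it, excluding ±``guard_bins``. The
    threshold interpolates the lowest level whose margin (DP − criterion)
    crosses zero.
    """
    dp_bin = int(np.argmin(np.abs(series.freqs_hz - series.f_dp_hz)))
    n_bins = series.spectra.shape[1]
    band = [
        b
        for b in range(max(0, dp_bin - noise_band_bins), min(n_bins, dp_bin + noise_band_bins + 1))
        if abs(b - dp_bin) > guard_bins
    ]
    if not band:
        raise ValueError("no noise bins adjacent to the distortion product")
    dp_amp = series.spectra[:, dp_bin]
    noise = series.spectra[:, band]
    criterion = noise.mean(axis=1) + k_sd * noise.std(axis=1)
    # per-level criterion: interpolate on the margin crossing zero
    margin = dp_amp - criterion
    res = interpolate_threshold(series.levels_db, margin, 0.0)
    return ThresholdResult(
        threshold_db=res.threshold_db,
        criterion_value=float(np.mean(criterion)),
        bracket_levels=res.bracket_levels,
        censored=res.censored,
        warning=res.warning,
    )
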