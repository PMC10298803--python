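"""Two-photon single-neuron tuning analysis.

Best frequency (frequency of the largest response at any sound level),
single-term Gaussian bandwidth fits on the top-level frequency sweep,
responsiveness classification, PCA of flattened response surfaces, and
best-frequency histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.decomposition import PCA


@dataclass
class TuningTensor:
    """Max evoked ΔF/F per (cell, frequency, level).

    ``freqs_hz`` is log-spaced and strictly increasing; ``levels_db``
    strictly increasing.
    """

    responses: np.ndarray  # (n_cells, n_freqs, n_levels)
    freqs_hz: np.ndarray
    levels_db: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (cell, frequency, level)")
        if np.any(np.diff(self.freqs_hz) <= 0) or np.any(np.diff(self.levels_db) <= 0):
            raise ValueError("frequencies and levels must be strictly increasing")
        if self.responses.shape[1:] != (self.freqs_hz.size, self.levels_db.size):
            raise ValueError("tensor shape does not match freq/level axes")

    @property
    def n_cells(self) -> int:
        return self.responses.shape[0]


def best_frequency(tensor: TuningTensor, cell: int) -> float:
    """Frequency eliciting the cell's largest response at any sound level.

    Ties resolve to the lower frequency.
    """
    surface = tensor.responses[cell]
    if np.all(np.isnan(surface)):
        raise ValueError("cell has no finite responses")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_freq = np.nanmax(surface, axis=1)
    return float(tensor.freqs_hz[int(np.nanargmax(per_freq))])


def _gauss1(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-(((x - b) / c) ** 2))


def bandwidth_gaussian(
    amplitudes: np.ndarray,
    freqs_hz: np.ndarray,
    min_points: int = 4,
) -> float | None:
    """Gaussian tuning bandwidth σ (octaves) at one sound level.

    Fits a·exp(−((x−b)/c)²) over x = log₂(frequency) to the maximum evoked
    amplitudes per frequency and reports σ = c/√2 octaves. Returns None
    (excluded) when the fit cannot be made: fewer than ``min_points`` finite
    amplitudes, no curvature, non-convergence, or a fitted peak outside the
    tested frequency range.
    """
    amps = np.asarray(amplitudes, dtype=float)
    x = np.log2(np.asarray(freqs_hz, dtype=float))
    ok = np.isfinite(amps)
    if ok.sum() < min_points:
        return None
    amps, x = amps[ok], x[ok]
    if np.ptp(amps) == 0:
        return None
    a0 = float(amps.max())
    b0 = float(x[np.argmax(amps)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss1,
                x,
                amps,
                p0=(a0, b0, 1.0),
                bounds=([0, x.min(), 1e-3], [np.inf, x.max(), np.inf]),
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return None
    a, b, c = popt
    if a <= 0:
        return None
    return float(c / np.sqrt(2.0))


def is_responsive(
    tensor: TuningTensor,
    cell: int,
    baseline_mean: float = 0.0,
    baseline_sd: float = 0.0,
    k_sd: float = 3.0,
) -> bool:
    """A cell is responsive when any stimulus response exceeds
    baseline mean + ``k_sd``·baseline SD."""
    return bool(np.nanmax(tensor.responses[cell]) > baseline_mean + k_sd * baseline_sd)


def pca_response_features(
    tensor: TuningTensor, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of flattened (frequency × level) peak-response surfaces.

    Cells are observations; features are mean-centered raw amplitudes (no
    z-scoring). Returns (scores, explained_variance_ratio) with the top
    ``n_components`` components.
    """
    X = tensor.responses.reshape(tensor.n_cells, -1)
    if tensor.n_cells < 4:
        raise ValueError("need at least 4 cells for PCA")
    if np.allclose(X, X[0]):
        raise ValueError("constant feature matrix")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)  # sklearn mean-centers internally
    return scores, pca.explained_variance_ratio_


def best_frequency_histogram(
    tensor: TuningTensor,
    responsive: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Counts of responsive cells per best-frequency bin (tested frequencies).

    Returns (counts aligned with ``tensor.freqs_hz``, fraction responsive).
    Non-responsive cells are excluded from the counts.
    """
    if responsive is None:
        responsive = np.ones(tensor.n_cells, dtype=bool)
    responsive = np.asarray(responsive, dtype=bool)
    counts = np.zeros(tensor.freqs_hz.size, dtype=int)
    for cell in range(tensor.n_cells):
        if not responsive[cell]:
            continue
        bf = best_frequency(tensor, cell)
        counts[int(np.argmin(np.abs(tensor.freqs_hz - bf)))] += 1
    fraction = float(responsive.mean()) if tensor.n_cells else 0.0
    return counts, fraction
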