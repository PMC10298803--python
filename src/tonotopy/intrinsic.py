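"""Transmitted-light analysis: osmotic crenation detection and automated
hair-cell centroid counting.

Crenations are slow darkenings of the supporting-cell epithelium seen under
DIC optics. They are detected on difference movies (frame t+lag minus frame
t): each difference image is thresholded at its mean + 3 SD, the binary mask
is Gaussian-smoothed (σ = 12 px) and re-binarized at half max, and 2D
connected components become candidate regions, merged across successive
difference frames when they overlap the same physical patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class CrenationRegion:
    """One detected crenation: pixel set, onset frame, physical area."""

    pixels: np.ndarray  # (n, 2) row/col
    onset_frame: int
    area_um2: float

    @property
    def mask_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


def difference_movie(movie: np.ndarray, lag_frames: int = 5) -> np.ndarray:
    """diff[n] = frame[n + lag] − frame[n]; output has T − lag frames."""
    movie = np.asarray(movie, dtype=float)
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    if lag_frames >= movie.shape[0]:
        raise ValueError("lag must be shorter than the movie")
    return movie[lag_frames:] - movie[:-lag_frames]


def detect_crenations(
    diff_stack: np.ndarray,
    pixel_scale_um: float,
    k_sd: float = 3.0,
    gaussian_sigma: float = 12.0,
    merge_overlap: float = 0.25,
) -> list[CrenationRegion]:
    """Detect crenation regions on a difference-movie stack.

    Per frame: |diff| is thresholded at the frame's mean + ``k_sd``·SD, the
    binary mask is smoothed with a Gaussian (σ px) and re-binarized at 0.5 —
    half the plateau value of the 0/1 mask, so a solid patch keeps its
    borders while sparse noise pixels smooth away — and 2D connected
    components (8-neighborhood) are extracted. A
    component overlapping ≥ ``merge_overlap`` of an already-detected region
    is treated as the same physical crenation (onset keeps the first frame);
    otherwise it starts a new region.
    """
    diff_stack = np.asarray(diff_stack, dtype=float)
    if diff_stack.ndim != 3 or diff_stack.shape[0] == 0:
        raise ValueError("diff stack must be a nonempty (frames, y, x) array")
    regions: list[CrenationRegion] = []
    region_masks: list[set[tuple[int, int]]] = []
    struct8 = np.ones((3, 3), dtype=bool)
    for f in range(diff_stack.shape[0]):
        frame = np.abs(diff_stack[f])
        thresh = frame.mean() + k_sd * frame.std()
        binary = frame > thresh
        if not binary.any():
            continue
        smoothed = ndimage.gaussian_filter(binary.astype(float), gaussian_sigma)
        rebinarized = smoothed > 0.5
        if not rebinarized.any():
            continue
        labels, n = ndimage.label(rebinarized, structure=struct8)
        for lab in range(1, n + 1):
            pixels = np.argwhere(labels == lab)
            pset = {(int(r), int(c)) for r, c in pixels}
            matched = False
            for i, prev in enumerate(region_masks):
                inter = len(pset & prev)
                if inter >= merge_overlap * min(len(pset), len(prev)):
                    region_masks[i] = prev | pset
                    matched = True
                    break
            if not matched:
                regions.append(
                    CrenationRegion(
                        pixels=pixels,
                        onset_frame=f,
                        area_um2=len(pset) * pixel_scale_um**2,
                    )
                )
                region_masks.append(pset)
    # refresh pixel sets / areas after cross-frame merging
    for i, reg in enumerate(regions):
        pixels = np.array(sorted(region_masks[i]))
        regions[i] = CrenationRegion(
            pixels=pixels,
            onset_frame=reg.onset_frame,
            area_um2=len(region_masks[i]) * pixel_scale_um**2,
        )
    return regions


def count_centroids(
    image: np.ndarray,
    region_mask: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 10,
) -> int:
    """Count preserved-cell centroids inside a mask.

    The image is binarized (Otsu by default), restricted to the mask, and 2D
    connected components (8-neighborhood) at or above ``min_area_px`` pixels
    are counted. Touching cells merge into one count (no watershed).
    """
    image = np.asarray(image, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if image.shape != region_mask.shape:
        raise ValueError("mask must match image shape")
    if not region_mask.any():
        raise ValueError("region mask is empty")
    if threshold is None:
        if np.ptp(image) == 0:
            return 0
        threshold = threshold_otsu(image)
    binary = (image > threshold) & region_mask
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum(areas >= min_area_px))
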