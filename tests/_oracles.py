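"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid scipy/skimage labeling and the package's own code
paths: flood fill by explicit stack traversal, regional maxima by exhaustive
neighbor scan, percentiles by sort-and-index arithmetic.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(raster: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a 3D boolean raster by stack-based flood fill."""
    raster = np.asarray(raster, dtype=bool)
    if connectivity == 26:
        offsets = [
            (df, dr, dc)
            for df in (-1, 0, 1)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (df, dr, dc) != (0, 0, 0)
        ]
    elif connectivity == 6:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        ]
    else:
        raise ValueError("connectivity must be 6 or 26")
    visited = np.zeros_like(raster)
    comps: list[set] = []
    F, R, C = raster.shape
    for start in zip(*np.nonzero(raster)):
        if visited[start]:
            continue
        comp = set()
        stack = [start]
        visited[start] = True
        while stack:
            f, r, c = stack.pop()
            comp.add((f, r, c))
            for df, dr, dc in offsets:
                nf, nr, nc = f + df, r + dr, c + dc
                if 0 <= nf < F and 0 <= nr < R and 0 <= nc < C:
                    if raster[nf, nr, nc] and not visited[nf, nr, nc]:
                        visited[nf, nr, nc] = True
                        stack.append((nf, nr, nc))
        comps.append(comp)
    return comps


def filtered_flood_fill_events(
    raster: np.ndarray, min_frames: int = 3, min_rois: int = 5, connectivity: int = 26
) -> list[set]:
    """Flood-fill components surviving the duration and ROI-count filters."""
    out = []
    for comp in flood_fill_components(raster, connectivity):
        frames = {v[0] for v in comp}
        rois = {v[1:] for v in comp}
        if max(frames) - min(frames) + 1 >= min_frames and len(rois) >= min_rois:
            out.append(comp)
    return out


def exhaustive_regional_maxima(image: np.ndarray, threshold: float) -> set:
    """Regional maxima by all-neighbor scan with plateau flood fill.

    Returns the set of centroid pixels (rounded), matching the one-maximum-
    per-plateau convention.
    """
    img = np.asarray(image, dtype=float)
    R, C = img.shape
    seen = np.zeros((R, C), dtype=bool)
    out = set()
    for r in range(R):
        for c in range(C):
            if seen[r, c] or img[r, c] <= threshold:
                continue
            val = img[r, c]
            # flood the equal-valued plateau
            plateau = []
            stack = [(r, c)]
            seen[r, c] = True
            is_max = True
            while stack:
                pr, pc = stack.pop()
                plateau.append((pr, pc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        nr, nc = pr + dr, pc + dc
                        if not (0 <= nr < R and 0 <= nc < C):
                            continue
                        if img[nr, nc] > val:
                            is_max = False
                        elif img[nr, nc] == val and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            if is_max:
                ys = np.mean([p[0] for p in plateau])
                xs = np.mean([p[1] for p in plateau])
                out.add((int(round(ys)), int(round(xs))))
    return out


def percentile_sorted(values: np.ndarray, q: float) -> float:
    """Percentile by sort + linear interpolation between order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    pos = (q / 100.0) * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return float(v[lo] + frac * (v[hi] - v[lo]))


def trapezoid_sum(y: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    return float(sum((y[i] + y[i + 1]) / 2.0 for i in range(len(y) - 1)))
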