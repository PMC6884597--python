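"""Automatic ROI isolation from fluorescence movies.

Two-step variance-heatmap procedure: the temporal variance of every pixel
is mapped, smoothed with a 2-D Gaussian, and its local maxima seed
connected regions that each become one ROI.  The fluorescence trace of an
ROI is the time series of the single pixel nearest its mask's center of
mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max

from .synthetic import FluorescenceMovie, TraceSet

__all__ = [
    "VarianceHeatmap",
    "ROI",
    "compute_variance_heatmap",
    "smooth_heatmap",
    "detect_seeds",
    "segment_regions",
    "extract_traces",
    "extract_rois",
]


@dataclass(frozen=True)
class VarianceHeatmap:
    values: np.ndarray  # H x W, per-pixel temporal variance
    smoothed: bool = False
    sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("heatmap must be 2-D")
        if np.any(self.values < -1e-12):
            raise ValueError("variance heatmap must be non-negative")


@dataclass(frozen=True)
class ROI:
    id: int
    seed: tuple[int, int]
    mask: np.ndarray  # boolean H x W
    center_of_mass: tuple[float, float]
    trace_F: np.ndarray | None = None

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def compute_variance_heatmap(
    movie: FluorescenceMovie, ddof: int = 0
) -> VarianceHeatmap:
    """Per-pixel variance of brightness through time.

    Population convention (ddof=0) by default; set ddof=1 for the sample
    variance.
    """
    if movie.n_frames < 2:
        raise ValueError("variance needs at least 2 frames")
    values = movie.frames.var(axis=0, ddof=ddof)
    return VarianceHeatmap(values=np.maximum(values, 0.0))


def smooth_heatmap(hm: VarianceHeatmap, sigma_px: float = 2.0) -> VarianceHeatmap:
    """Convolve the heatmap with a 2-D Gaussian kernel (reflective edges)."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    smoothed = ndimage.gaussian_filter(hm.values, sigma=sigma_px, mode="reflect")
    return VarianceHeatmap(values=np.maximum(smoothed, 0.0),
                           smoothed=True, sigma_px=sigma_px)


def detect_seeds(
    hm: VarianceHeatmap,
    min_distance_px: int = 3,
    min_variance: float | None = None,
) -> list[tuple[int, int]]:
    """Local maxima of the (smoothed) heatmap, ordered by descending value.

    ``min_variance`` defaults to the 25th percentile of the heatmap, so
    flat background never seeds ROIs.  Plateau maxima count once.
    """
    if min_variance is None:
        min_variance = float(np.percentile(hm.values, 25))
    coords = peak_local_max(
        hm.values,
        min_distance=min_distance_px,
        threshold_abs=min_variance,
        exclude_border=False,
    )
    # peak_local_max keeps plateau pixels; reduce to one per plateau by
    # rejecting candidates whose value is not strictly above min_variance
    # when min_variance exceeds every pixel
    seeds = [(int(r), int(c)) for r, c in coords if hm.values[r, c] >= min_variance]
    seeds.sort(key=lambda rc: -hm.values[rc])
    return seeds


def segment_regions(
    hm: VarianceHeatmap,
    seeds: list[tuple[int, int]],
    rel_threshold: float = 0.5,
) -> list[np.ndarray]:
    """Grow one connected mask per seed by relative thresholding.

    A pixel belongs to seed i's candidate region when its heatmap value is
    >= rel_threshold x the seed value and it is 4-connected to the seed
    through such pixels.  A pixel claimed by several seeds goes to the
    nearest one (Euclidean), ties to the lower ROI id.
    """
    H, W = hm.values.shape
    candidate_masks: list[np.ndarray] = []
    for (sr, sc) in seeds:
        thr = rel_threshold * hm.values[sr, sc]
        above = hm.values >= thr
        labels, _ = ndimage.label(above)
        candidate_masks.append(labels == labels[sr, sc])

    # resolve contention: nearest seed wins, then lower id
    claim = np.full((H, W), -1, dtype=int)
    best_d2 = np.full((H, W), np.inf)
    for i, mask in enumerate(candidate_masks):
        rr, cc = np.nonzero(mask)
        d2 = (rr - seeds[i][0]) ** 2 + (cc - seeds[i][1]) ** 2
        better = d2 < best_d2[rr, cc]  # strict: ties stay with lower id
        claim[rr[better], cc[better]] = i
        best_d2[rr[better], cc[better]] = d2[better]

    final: list[np.ndarray] = []
    for i, (sr, sc) in enumerate(seeds):
        owned = claim == i
        # keep only the component still connected to the seed after contention
        if owned[sr, sc]:
            labels, _ = ndimage.label(owned)
            final.append(labels == labels[sr, sc])
        else:
            mask = np.zeros((H, W), dtype=bool)
            mask[sr, sc] = True
            final.append(mask)
    return final


def extract_traces(movie: FluorescenceMovie, rois: list[ROI]) -> TraceSet:
    """Single-pixel trace at each ROI's center of mass."""
    H, W = movie.frame_shape
    traces = np.empty((len(rois), movie.n_frames))
    for k, roi in enumerate(rois):
        r = int(round(roi.center_of_mass[0]))
        c = int(round(roi.center_of_mass[1]))
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"ROI {roi.id} center of mass outside the frame")
        traces[k] = movie.frames[:, r, c]
    return TraceSet(
        traces=traces,
        fs_hz=movie.fs_hz,
        roi_ids=np.array([roi.id for roi in rois], dtype=int),
    )


def extract_rois(
    movie: FluorescenceMovie,
    sigma_px: float = 2.0,
    min_distance_px: int = 3,
    min_variance: float | None = None,
    rel_threshold: float = 0.5,
) -> tuple[list[ROI], TraceSet]:
    """Full procedure: variance map -> smooth -> seeds -> regions -> traces."""
    hm = smooth_heatmap(compute_variance_heatmap(movie), sigma_px=sigma_px)
    seeds = detect_seeds(hm, min_distance_px=min_distance_px,
                         min_variance=min_variance)
    masks = segment_regions(hm, seeds)
    rois = []
    for i, (seed, mask) in enumerate(zip(seeds, masks)):
        com = ndimage.center_of_mass(mask)
        rois.append(ROI(id=i, seed=seed, mask=mask,
                        center_of_mass=(float(com[0]), float(com[1]))))
    traces = extract_traces(movie, rois)
    rois = [
        ROI(id=r.id, seed=r.seed, mask=r.mask, center_of_mass=r.center_of_mass,
            trace_F=traces.traces[k])
        for k, r in enumerate(rois)
    ]
    return rois, traces


def write_roi_table(rois: list[ROI], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "seed_row": r.seed[0],
            "seed_col": r.seed[1],
            "com_row": r.center_of_mass[0],
            "com_col": r.center_of_mass[1],
            "n_pixels": r.n_pixels,
        }
        for r in rois
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_label_image(rois: list[ROI], path: str | Path) -> None:
    if not rois:
        raise ValueError("no ROIs to write")
    labels = np.zeros(rois[0].mask.shape, dtype=np.uint16)
    for r in rois:
        labels[r.mask] = r.id + 1
    tifffile.imwrite(path, labels)
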