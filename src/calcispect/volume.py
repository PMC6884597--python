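"""Confocal-stack volume-fraction quantification.

Binarizes 3-D immunostain channel stacks (GFAP for astrocytes, beta-III
tubulin for neurons) and reports the fraction of the imaged volume each
marker covers, plus the astrocyte-to-neuron volume ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

__all__ = [
    "ConfocalStack",
    "binarize_stack",
    "volume_fraction",
    "astrocyte_neuron_ratio",
]


@dataclass(frozen=True)
class ConfocalStack:
    voxels: np.ndarray  # Z x H x W intensities
    channel: str = ""
    voxel_dims_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        v = self.voxels
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("stack must be Z x H x W with at least 1 plane")
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")

    @staticmethod
    def from_tiff(path: str | Path, channel: str = "") -> "ConfocalStack":
        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        return ConfocalStack(voxels=arr, channel=channel)


def binarize_stack(
    stack: ConfocalStack,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Binarize the whole stack: foreground = intensity >= threshold.

    ``method='otsu'`` picks the threshold that maximizes between-class
    variance over all planes jointly; an all-equal stack is degenerate and
    maps to all-background with a warning.  ``method='fixed'`` requires an
    explicit threshold.
    """
    v = stack.voxels
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        return v >= threshold
    if method != "otsu":
        raise ValueError(f"unknown binarization method: {method!r}")
    if v.min() == v.max():
        warnings.warn(
            "stack has a single intensity level; binarizing to all background",
            RuntimeWarning,
        )
        return np.zeros(v.shape, dtype=bool)
    thr = threshold_otsu(v.ravel())
    # threshold_otsu returns the last bin edge below the cut; >= keeps the
    # bright class entirely in the foreground
    return v > thr


def volume_fraction(binary: np.ndarray) -> float:
    """Positive voxels over total voxels, pooled across all planes."""
    binary = np.asarray(binary)
    if binary.size == 0:
        raise ValueError("empty stack")
    return float(binary.sum()) / binary.size


def astrocyte_neuron_ratio(
    gfap_binary: np.ndarray, tubulin_binary: np.ndarray
) -> float:
    """GFAP volume fraction divided by beta-III tubulin volume fraction."""
    if gfap_binary.shape != tubulin_binary.shape:
        raise ValueError("channel stacks must have the same shape")
    neuron = volume_fraction(tubulin_binary)
    if neuron == 0:
        raise ValueError("zero neuron volume; ratio undefined")
    return volume_fraction(gfap_binary) / neuron
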