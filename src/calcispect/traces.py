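"""Raw fluorescence to smoothed dF/F.

The baseline F0 at each time point is the mean of the samples lying
strictly below the 80th percentile of a +/- 15 s sliding window (clipped
at the trace boundaries); dF/F = (F - F0)/F0.  A second-order
Savitzky-Golay filter then removes high-frequency noise while preserving
the sub-3 Hz band the downstream spectral analysis targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .synthetic import TraceSet

__all__ = ["DFFTrace", "compute_dff", "smooth_dff", "process_traceset"]


@dataclass(frozen=True)
class DFFTrace:
    dff: np.ndarray
    fs_hz: float
    baseline_F0: np.ndarray
    roi_id: int = 0

    def __post_init__(self) -> None:
        if self.dff.shape != self.baseline_F0.shape:
            raise ValueError("dff and baseline must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.dff.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def _sliding_percentile_baseline(
    trace: np.ndarray,
    half_window: int,
    percentile: float,
    strict: bool,
) -> np.ndarray:
    n = trace.size
    f0 = np.empty(n)
    for t in range(n):
        lo = max(0, t - half_window)
        hi = min(n, t + half_window + 1)
        window = trace[lo:hi]
        cut = np.percentile(window, percentile)
        sub = window[window < cut] if strict else window[window <= cut]
        if not sub.size:
            # discrete/near-constant window: strictly-below set empty;
            # fall back to <= the percentile, then to the window mean
            sub = window[window <= cut]
        f0[t] = sub.mean() if sub.size else window.mean()
    return f0


def compute_dff(
    trace_F: np.ndarray,
    fs_hz: float,
    half_window_s: float = 15.0,
    percentile: float = 80.0,
    strict: bool = True,
    global_baseline: bool = False,
    roi_id: int = 0,
) -> DFFTrace:
    """Relative fluorescence change with a sliding sub-percentile baseline.

    Parameters
    ----------
    trace_F
        Raw fluorescence samples (finite, baseline must be positive).
    fs_hz
        Sampling rate.
    half_window_s
        Half-width of the sliding baseline window in seconds.
    percentile
        Only samples below this window percentile enter the baseline mean;
        robust to sparse transients riding on the baseline.
    strict
        Use samples strictly below the percentile (default) or <=.
    global_baseline
        Estimate a single F0 from the whole trace instead of per window.
    """
    trace_F = np.asarray(trace_F, dtype=float)
    if trace_F.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    if not np.all(np.isfinite(trace_F)):
        raise ValueError("trace contains non-finite values")
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")

    half_window = int(round(half_window_s * fs_hz))
    if half_window < 1:
        raise ValueError("baseline window must span at least 2 samples")

    if global_baseline:
        cut = np.percentile(trace_F, percentile)
        sub = trace_F[trace_F < cut] if strict else trace_F[trace_F <= cut]
        if not sub.size:
            sub = trace_F[trace_F <= cut]
        value = sub.mean() if sub.size else trace_F.mean()
        f0 = np.full(trace_F.size, value)
    else:
        f0 = _sliding_percentile_baseline(trace_F, half_window, percentile, strict)

    if np.any(f0 <= 0):
        raise ValueError(
            f"ROI {roi_id}: baseline F0 is non-positive; dF/F undefined"
        )
    return DFFTrace(dff=(trace_F - f0) / f0, fs_hz=fs_hz,
                    baseline_F0=f0, roi_id=roi_id)


def smooth_dff(
    dff: DFFTrace, window_frames: int = 11, poly_order: int = 2
) -> DFFTrace:
    """Savitzky-Golay smoothing of the dF/F signal.

    Exactly reproduces any polynomial of degree <= poly_order, so baseline
    trends survive while broadband noise is attenuated.
    """
    if window_frames % 2 == 0 or window_frames <= poly_order:
        raise ValueError("window_frames must be odd and exceed poly_order")
    if window_frames > dff.n_samples:
        raise ValueError("smoothing window longer than the trace")
    smoothed = savgol_filter(dff.dff, window_frames, poly_order)
    return DFFTrace(dff=smoothed, fs_hz=dff.fs_hz,
                    baseline_F0=dff.baseline_F0, roi_id=dff.roi_id)


def process_traceset(
    traces: TraceSet,
    half_window_s: float = 15.0,
    percentile: float = 80.0,
    smooth_window_frames: int = 11,
    smooth_poly_order: int = 2,
    smooth: bool = True,
) -> list[DFFTrace]:
    """dF/F + smoothing for every trace in a set."""
    out = []
    for k in range(traces.n_rois):
        d = compute_dff(
            traces.traces[k],
            traces.fs_hz,
            half_window_s=half_window_s,
            percentile=percentile,
            roi_id=int(traces.roi_ids[k]),
        )
        if smooth:
            d = smooth_dff(d, smooth_window_frames, smooth_poly_order)
        out.append(d)
    return out
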