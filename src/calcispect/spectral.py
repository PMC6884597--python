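"""Frequency-domain quantification of dF/F activity.

Pipeline per ROI: Welch PSD (8 s windows, 2 s overlap) -> removal of the
aperiodic 1/f power-law component by subtracting a least-squares line from
the log-log spectrum over 0.2-8 Hz -> spectral peaks exceeding 3 standard
deviations of the detrended spectrum.  Peaks from all ROIs are then pooled
and only those in the top 75% of the pooled height distribution count as
significant oscillations; the surviving peak frequencies summarize the
periodicity of the spontaneous activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .traces import DFFTrace

__all__ = [
    "SpectralResult",
    "OscillationSummary",
    "welch_psd",
    "detrend_psd",
    "detect_peaks",
    "pool_and_call_oscillations",
    "band_power",
    "fit_frequency_distribution",
    "analyze_traces",
]

#: default aperiodic fit band, Hz
FIT_BAND = (0.2, 8.0)
#: default oscillation band for total power, Hz
POWER_BAND = (0.2, 3.0)


@dataclass
class SpectralResult:
    roi_id: int
    freqs_hz: np.ndarray
    psd: np.ndarray
    log_psd: np.ndarray | None = None
    detrended_psd: np.ndarray | None = None
    fit_band: tuple[float, float] = FIT_BAND
    peaks: list[tuple[float, float]] = field(default_factory=list)  # (f, height)
    band_power_0p2_3: float | None = None
    has_significant_oscillation: bool = False
    oscillation_freq_hz: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.psd < 0):
            raise ValueError("PSD must be non-negative")


@dataclass(frozen=True)
class OscillationSummary:
    group: str
    n_rois: int
    n_oscillating: int
    normal_fit: tuple[float, float] | None  # (mean_hz, sd_hz)

    @property
    def percent_oscillating(self) -> float:
        return 100.0 * self.n_oscillating / self.n_rois if self.n_rois else 0.0


def welch_psd(
    dff: DFFTrace, window_s: float = 8.0, overlap_s: float = 2.0
) -> SpectralResult:
    """Welch power spectral density of a dF/F trace.

    Hann taper, one-sided density scaling, per-segment constant detrend.
    Frequency resolution is 1/window_s.
    """
    nperseg = int(round(window_s * dff.fs_hz))
    noverlap = int(round(overlap_s * dff.fs_hz))
    if dff.n_samples < nperseg:
        raise ValueError(
            f"trace of {dff.duration_s:.1f} s shorter than one {window_s} s window"
        )
    freqs, psd = sps.welch(
        dff.dff,
        fs=dff.fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    return SpectralResult(roi_id=dff.roi_id, freqs_hz=freqs, psd=psd)


def detrend_psd(
    sr: SpectralResult, fit_band: tuple[float, float] = FIT_BAND
) -> SpectralResult:
    """Remove the aperiodic 1/f component from the log-10 PSD.

    A least-squares line is fitted to log10(PSD) against log10(frequency)
    over ``fit_band`` — a pure power law c*f^(-chi) is exactly linear
    there — and subtracted.  Outside the band the detrended spectrum is
    NaN.
    """
    lo, hi = fit_band
    in_band = (sr.freqs_hz >= lo) & (sr.freqs_hz <= hi)
    if in_band.sum() < 3:
        raise ValueError("fit band contains fewer than 3 frequency bins")
    # floor keeps exactly-zero bins finite; a uniformly floored spectrum
    # detrends to zero, so silence yields no peaks
    log_psd = np.log10(np.maximum(sr.psd, 1e-300))
    logf = np.log10(sr.freqs_hz[in_band])
    slope, intercept = np.polyfit(logf, log_psd[in_band], 1)
    detrended = np.full_like(log_psd, np.nan)
    detrended[in_band] = log_psd[in_band] - (slope * logf + intercept)
    return replace(sr, log_psd=log_psd, detrended_psd=detrended, fit_band=fit_band)


def detect_peaks(sr: SpectralResult, k_sd: float = 3.0) -> SpectralResult:
    """Spectral peaks above ``k_sd`` standard deviations of the detrended PSD.

    Peaks are strict local maxima of the detrended spectrum inside the fit
    band; the threshold SD is computed per ROI over the same band.
    """
    if sr.detrended_psd is None:
        raise ValueError("detrend the PSD before peak detection")
    in_band = np.isfinite(sr.detrended_psd)
    d = sr.detrended_psd[in_band]
    f = sr.freqs_hz[in_band]
    sd = d.std()
    if sd < 1e-10:  # flat to numerical precision: no structure, no peaks
        return replace(sr, peaks=[])
    threshold = k_sd * sd
    idx, _ = sps.find_peaks(d, height=threshold)
    peaks = [(float(f[i]), float(d[i])) for i in idx if d[i] > threshold]
    return replace(sr, peaks=peaks)


def pool_and_call_oscillations(
    results: list[SpectralResult], keep_top_percent: float = 75.0
) -> list[SpectralResult]:
    """Pool peaks across ROIs and keep the top fraction by height.

    The pooled height distribution sets a single cutoff (its
    ``100 - keep_top_percent`` percentile); an ROI oscillates iff at least
    one of its peaks survives, at the frequency of its tallest survivor.
    """
    heights = np.array([h for sr in results for (_, h) in sr.peaks])
    if heights.size == 0:
        return [
            replace(sr, has_significant_oscillation=False, oscillation_freq_hz=None)
            for sr in results
        ]
    cutoff = np.percentile(heights, 100.0 - keep_top_percent)
    out = []
    for sr in results:
        kept = [(f, h) for (f, h) in sr.peaks if h >= cutoff]
        if kept:
            best_f = max(kept, key=lambda fh: fh[1])[0]
            out.append(
                replace(sr, has_significant_oscillation=True,
                        oscillation_freq_hz=best_f)
            )
        else:
            out.append(
                replace(sr, has_significant_oscillation=False,
                        oscillation_freq_hz=None)
            )
    return out


def band_power(
    sr: SpectralResult, band: tuple[float, float] = POWER_BAND
) -> float:
    """Trapezoidal integral of the linear PSD over a closed frequency band.

    Band edges falling between Welch bins are linearly interpolated so the
    integral covers exactly [band_low, band_high].
    """
    lo, hi = band
    f, p = sr.freqs_hz, sr.psd
    if lo < f[0] or hi > f[-1]:
        raise ValueError("band extends beyond the frequency grid")
    inside = (f > lo) & (f < hi)
    grid = np.concatenate(([lo], f[inside], [hi]))
    vals = np.concatenate(([np.interp(lo, f, p)], p[inside], [np.interp(hi, f, p)]))
    return float(np.trapezoid(vals, grid))


def fit_frequency_distribution(freqs_hz: np.ndarray) -> tuple[float, float]:
    """Gaussian maximum-likelihood fit (sample mean, population SD)."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.size < 2:
        raise ValueError("need at least 2 frequencies to fit a distribution")
    return float(freqs_hz.mean()), float(freqs_hz.std(ddof=0))


def analyze_traces(
    dffs: list[DFFTrace],
    window_s: float = 8.0,
    overlap_s: float = 2.0,
    fit_band: tuple[float, float] = FIT_BAND,
    k_sd: float = 3.0,
    keep_top_percent: float = 75.0,
    power_band: tuple[float, float] = POWER_BAND,
    pool: bool = True,
) -> list[SpectralResult]:
    """Full spectral pipeline over a cohort of dF/F traces.

    When ``pool`` is true the oscillation call uses the pooled-percentile
    rule across every trace passed in one invocation (one pool per call);
    otherwise peaks are kept as detected.
    """
    results = []
    for dff in dffs:
        sr = welch_psd(dff, window_s=window_s, overlap_s=overlap_s)
        # cap the fit band at Nyquist for short/slow recordings
        hi = min(fit_band[1], float(sr.freqs_hz[-1]))
        sr = detrend_psd(sr, fit_band=(fit_band[0], hi))
        sr = detect_peaks(sr, k_sd=k_sd)
        sr.band_power_0p2_3 = band_power(sr, band=power_band)
        results.append(sr)
    if pool:
        pooled = pool_and_call_oscillations(results, keep_top_percent)
        for sr, old in zip(pooled, results):
            sr.band_power_0p2_3 = old.band_power_0p2_3
        return pooled
    return results


def summarize_group(
    results: list[SpectralResult], group: str = ""
) -> OscillationSummary:
    osc_freqs = [
        sr.oscillation_freq_hz for sr in results if sr.has_significant_oscillation
    ]
    fit = (
        fit_frequency_distribution(np.array(osc_freqs)) if len(osc_freqs) >= 2 else None
    )
    return OscillationSummary(
        group=group,
        n_rois=len(results),
        n_oscillating=len(osc_freqs),
        normal_fit=fit,
    )
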