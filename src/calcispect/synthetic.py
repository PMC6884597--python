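"""Synthetic fluorescence data with planted ground truth.

Generates single-pixel fluorescence traces and full time-lapse movies that
mimic spontaneous calcium activity in 3-D neural cultures: sparse
GECI-shaped transients and periodic oscillations (default 0.5-3 Hz) riding
on a slowly drifting baseline with an aperiodic 1/f background and
shot-like noise.  Every quantity the downstream analysis estimates (ROI
position, activity class, oscillation frequency, cluster membership) is
recorded as machine-readable ground truth, so recovery can be scored
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SimulationConfig",
    "GroundTruthRecord",
    "GroundTruth",
    "TraceSet",
    "FluorescenceMovie",
    "simulate_traces",
    "simulate_movie",
]

#: activity classes a planted unit can belong to
CLASS_OSCILLATORY = "oscillatory"
CLASS_TRANSIENT = "transient-only"
CLASS_SILENT = "silent"

#: cluster label assigned to each activity class (oscillatory units form
#: the "active" cluster; transient-only and silent units the "quiescent" one)
_CLASS_TO_CLUSTER = {CLASS_OSCILLATORY: 1, CLASS_TRANSIENT: 0, CLASS_SILENT: 0}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic culture.

    Amplitudes (``signal_amplitude``, ``noise_sd``, ``drift_amplitude``)
    are expressed relative to ``baseline_intensity``, i.e. they are the
    size of the corresponding dF/F excursion.
    """

    image_height_px: int = 64
    image_width_px: int = 64
    n_frames: int = 1200
    frame_interval_s: float = 0.05
    n_rois: int = 10
    roi_radius_px: float = 4.0
    fraction_oscillatory: float = 0.5
    fraction_transient: float | None = None  # None -> half the remainder
    oscillation_freq_range_hz: tuple[float, float] = (0.5, 3.0)
    transient_rate_hz: float = 0.2
    transient_tau_rise_s: float = 0.05
    transient_tau_decay_s: float = 0.5
    baseline_intensity: float = 100.0
    signal_amplitude: float = 0.5
    noise_sd: float = 0.05
    aperiodic_exponent: float = 1.0
    aperiodic_amplitude: float = 0.05
    drift_amplitude: float = 0.02
    drift_period_s: float = 120.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not 0.0 <= self.fraction_oscillatory <= 1.0:
            raise ValueError("fraction_oscillatory must lie in [0, 1]")
        if self.fraction_transient is not None and not (
            0.0 <= self.fraction_transient <= 1.0 - self.fraction_oscillatory
        ):
            raise ValueError(
                "fraction_transient must lie in [0, 1 - fraction_oscillatory]"
            )
        lo, hi = self.oscillation_freq_range_hz
        nyquist = 0.5 / self.frame_interval_s
        if not (0.0 < lo <= hi):
            raise ValueError("oscillation frequency range must satisfy 0 < low <= high")
        if hi > nyquist:
            raise ValueError(
                f"oscillation frequency {hi} Hz above Nyquist {nyquist} Hz"
            )
        for name in (
            "signal_amplitude",
            "noise_sd",
            "drift_amplitude",
            "aperiodic_amplitude",
            "transient_rate_hz",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def fs_hz(self) -> float:
        return 1.0 / self.frame_interval_s

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass(frozen=True)
class GroundTruthRecord:
    roi_id: int
    center: tuple[float, float]  # (row, col), px
    activity_class: str
    oscillation_freq_hz: float | None
    cluster_label: int
    clean_trace: np.ndarray  # noiseless, drift-free fluorescence


@dataclass(frozen=True)
class GroundTruth:
    records: list[GroundTruthRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            has_f = r.oscillation_freq_hz is not None
            if has_f != (r.activity_class == CLASS_OSCILLATORY):
                raise ValueError(
                    "oscillation_freq_hz must be set iff the unit is oscillatory"
                )

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "roi_id": r.roi_id,
                "center_row": r.center[0],
                "center_col": r.center[1],
                "activity_class": r.activity_class,
                "oscillation_freq_hz": r.oscillation_freq_hz,
                "cluster_label": r.cluster_label,
            }
            for r in self.records
        ]
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class TraceSet:
    """Raw fluorescence traces, one column per unit."""

    traces: np.ndarray  # (n_rois, n_frames)
    fs_hz: float
    roi_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.roi_ids is None:
            object.__setattr__(
                self, "roi_ids", np.arange(self.traces.shape[0], dtype=int)
            )

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.traces.T, columns=[f"roi_{i}" for i in self.roi_ids]
        )
        df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path, fs_hz: float) -> "TraceSet":
        df = pd.read_csv(path)
        ids = np.array(
            [int(c.split("_")[-1]) if "_" in c else i for i, c in enumerate(df.columns)]
        )
        return TraceSet(traces=df.to_numpy().T, fs_hz=fs_hz, roi_ids=ids)


@dataclass(frozen=True)
class FluorescenceMovie:
    """T x H x W intensity array with its frame interval."""

    frames: np.ndarray
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def fs_hz(self) -> float:
        return 1.0 / self.frame_interval_s

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))

    @staticmethod
    def from_tiff(path: str | Path, frame_interval_s: float) -> "FluorescenceMovie":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        return FluorescenceMovie(frames=np.asarray(arr, dtype=float),
                                 frame_interval_s=frame_interval_s)


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def _transient_kernel(cfg: SimulationConfig) -> np.ndarray:
    """Difference-of-exponentials calcium impulse, unit peak."""
    dt = cfg.frame_interval_s
    length = int(np.ceil((cfg.transient_tau_rise_s + 6 * cfg.transient_tau_decay_s) / dt))
    t = np.arange(max(length, 2)) * dt
    k = np.exp(-t / cfg.transient_tau_decay_s) - np.exp(-t / cfg.transient_tau_rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """White noise shaped to a 1/f^(chi/2) amplitude spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC power
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_rois
    n_osc = int(round(cfg.fraction_oscillatory * n))
    remainder = n - n_osc
    if cfg.fraction_transient is None:
        n_tr = remainder // 2
    else:
        n_tr = int(round(cfg.fraction_transient * n))
        n_tr = min(n_tr, remainder)
    classes = (
        [CLASS_OSCILLATORY] * n_osc
        + [CLASS_TRANSIENT] * n_tr
        + [CLASS_SILENT] * (remainder - n_tr)
    )
    rng.shuffle(classes)
    return classes


def _clean_signal(
    cfg: SimulationConfig, activity_class: str, rng: np.random.Generator
) -> tuple[np.ndarray, float | None]:
    """Noise-free dF/F-scale signal s(t) for one unit and its frequency."""
    t = np.arange(cfg.n_frames) * cfg.frame_interval_s
    if activity_class == CLASS_OSCILLATORY:
        lo, hi = cfg.oscillation_freq_range_hz
        f0 = float(rng.uniform(lo, hi))
        phase = rng.uniform(0, 2 * np.pi)
        return cfg.signal_amplitude * np.sin(2 * np.pi * f0 * t + phase), f0
    if activity_class == CLASS_TRANSIENT:
        p_event = min(cfg.transient_rate_hz * cfg.frame_interval_s, 1.0)
        events = (rng.random(cfg.n_frames) < p_event).astype(float)
        kernel = _transient_kernel(cfg)
        sig = np.convolve(events, kernel)[: cfg.n_frames]
        return cfg.signal_amplitude * sig, None
    return np.zeros(cfg.n_frames), None


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_traces(cfg: SimulationConfig) -> tuple[TraceSet, GroundTruth]:
    """Generate raw fluorescence traces with planted activity.

    Each unit's trace is ``F(t) = B * (1 + s(t)) + B * drift(t) + noise``
    where ``B`` is the baseline intensity and ``s`` the clean dF/F-scale
    signal determined by the unit's activity class.  The ground-truth
    ``clean_trace`` is ``B * (1 + s(t))`` (no noise, no drift), so with
    ``noise_sd = 0`` and ``drift_amplitude = 0`` the returned trace equals
    it exactly.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    classes = _assign_classes(cfg, rng)
    # trace-level simulation renders nothing, so centers are nominal grid
    # positions; spatial placement constraints apply only to movies
    side = int(np.ceil(np.sqrt(max(cfg.n_rois, 1))))
    centers = [
        (
            (i // side + 0.5) * cfg.image_height_px / side,
            (i % side + 0.5) * cfg.image_width_px / side,
        )
        for i in range(cfg.n_rois)
    ]
    t = np.arange(cfg.n_frames) * cfg.frame_interval_s

    traces = np.empty((cfg.n_rois, cfg.n_frames))
    records: list[GroundTruthRecord] = []
    for i, cls in enumerate(classes):
        s, f0 = _clean_signal(cfg, cls, rng)
        clean = cfg.baseline_intensity * (1.0 + s)
        tr = clean.copy()
        if cfg.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            tr = tr + cfg.baseline_intensity * cfg.drift_amplitude * np.sin(
                2 * np.pi * t / cfg.drift_period_s + phase
            )
        if cfg.aperiodic_amplitude > 0:
            tr = tr + (
                cfg.baseline_intensity
                * cfg.aperiodic_amplitude
                * _one_over_f_noise(cfg.n_frames, cfg.aperiodic_exponent, rng)
            )
        if cfg.noise_sd > 0:
            tr = tr + cfg.baseline_intensity * cfg.noise_sd * rng.standard_normal(
                cfg.n_frames
            )
        traces[i] = tr
        records.append(
            GroundTruthRecord(
                roi_id=i,
                center=centers[i],
                activity_class=cls,
                oscillation_freq_hz=f0,
                cluster_label=_CLASS_TO_CLUSTER[cls],
                clean_trace=clean,
            )
        )
    return TraceSet(traces=traces, fs_hz=cfg.fs_hz), GroundTruth(records=records)


def _place_centers(
    cfg: SimulationConfig, rng: np.random.Generator, max_tries: int = 10_000
) -> list[tuple[float, float]]:
    """Rejection-sample ROI centers so discs of roi_radius_px never overlap."""
    margin = cfg.roi_radius_px
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < cfg.n_rois:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_rois} non-overlapping ROIs "
                f"in a {cfg.image_height_px}x{cfg.image_width_px} frame "
                f"within {max_tries} attempts"
            )
        tries += 1
        r = rng.uniform(margin, cfg.image_height_px - 1 - margin)
        c = rng.uniform(margin, cfg.image_width_px - 1 - margin)
        if all(
            (r - rr) ** 2 + (c - cc) ** 2 >= (2 * cfg.roi_radius_px) ** 2
            for rr, cc in centers
        ):
            centers.append((r, c))
    return centers


def simulate_movie(cfg: SimulationConfig) -> tuple[FluorescenceMovie, GroundTruth]:
    """Render planted units as Gaussian spots modulated by their traces.

    Spot profile is an isotropic Gaussian with sigma = roi_radius_px / 3,
    truncated at 3 sigma (i.e. at roi_radius_px), so non-overlapping discs
    guarantee non-overlapping photometric footprints.  Pixel model:
    ``I(x, t) = B * (1 + s_i(t) * G_i(x)) + noise`` inside spot i and
    ``I = B + noise`` elsewhere, with per-pixel iid Gaussian noise.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    classes = _assign_classes(cfg, rng)
    centers = _place_centers(cfg, rng)

    H, W = cfg.image_height_px, cfg.image_width_px
    frames = np.full((cfg.n_frames, H, W), cfg.baseline_intensity, dtype=float)
    t = np.arange(cfg.n_frames) * cfg.frame_interval_s

    sigma = cfg.roi_radius_px / 3.0
    records: list[GroundTruthRecord] = []
    for i, cls in enumerate(classes):
        s, f0 = _clean_signal(cfg, cls, rng)
        if cfg.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            s = s + cfg.drift_amplitude * np.sin(
                2 * np.pi * t / cfg.drift_period_s + phase
            )
        cr, cc = centers[i]
        r0, r1 = int(np.floor(cr - 3 * sigma)), int(np.ceil(cr + 3 * sigma)) + 1
        c0, c1 = int(np.floor(cc - 3 * sigma)), int(np.ceil(cc + 3 * sigma)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, H), min(c1, W)
        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        d2 = (rows[:, None] - cr) ** 2 + (cols[None, :] - cc) ** 2
        profile = np.exp(-d2 / (2 * sigma**2))
        profile[d2 > (3 * sigma) ** 2] = 0.0
        frames[:, r0:r1, c0:c1] += (
            cfg.baseline_intensity * s[:, None, None] * profile[None]
        )
        records.append(
            GroundTruthRecord(
                roi_id=i,
                center=(cr, cc),
                activity_class=cls,
                oscillation_freq_hz=f0,
                cluster_label=_CLASS_TO_CLUSTER[cls],
                clean_trace=cfg.baseline_intensity * (1.0 + s),
            )
        )

    if cfg.noise_sd > 0:
        frames += cfg.baseline_intensity * cfg.noise_sd * rng.standard_normal(
            frames.shape
        )
    movie = FluorescenceMovie(frames=frames, frame_interval_s=cfg.frame_interval_s)
    return movie, GroundTruth(records=records)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["oscillation_freq_range_hz"] = list(d["oscillation_freq_range_hz"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "oscillation_freq_range_hz" in d:
        d["oscillation_freq_range_hz"] = tuple(d["oscillation_freq_range_hz"])
    return SimulationConfig(**d)
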