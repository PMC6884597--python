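"""End-to-end orchestration: simulate/load -> ROIs -> dF/F -> spectra ->
clustering -> group report.

A single master seed determines every stage sub-seed, so a rerun with the
same configuration reproduces all stochastic stages exactly.  Every run
writes a manifest (configuration hash, parameters, seeds, package version)
next to its artifacts.  Group comparison applies a two-way ANOVA with
Tukey post-hoc tests (time point x construct type) on per-ROI band power,
and a one-way Tukey-Kramer variant for per-cluster comparisons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, roi, spectral, synthetic, traces
from .synthetic import FluorescenceMovie, SimulationConfig, TraceSet

__all__ = ["GroupSpec", "RunConfig", "GroupReport", "run_pipeline", "compare_groups",
           "compare_clusters"]

log = logging.getLogger("calcispect")
ALPHA = 0.01  # significance level for group comparisons


@dataclass(frozen=True)
class GroupSpec:
    """One experimental cell: a construct type at a time point."""

    name: str
    time_point: str
    construct: str
    n_cultures: int = 3
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    movie_paths: tuple[str, ...] = ()
    trace_paths: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    groups: tuple[GroupSpec, ...]
    master_seed: int = 0
    out_dir: str | None = None
    # stage parameters (defaults match the analysis conventions)
    roi_sigma_px: float = 2.0
    roi_min_distance_px: int = 3
    dff_half_window_s: float = 15.0
    dff_percentile: float = 80.0
    sg_window_frames: int = 11
    sg_poly_order: int = 2
    welch_window_s: float = 8.0
    welch_overlap_s: float = 2.0
    peak_k_sd: float = 3.0
    keep_top_percent: float = 75.0
    louvain_runs: int = 100
    consensus_tau: float = 0.5
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    alpha: float = ALPHA


@dataclass(frozen=True)
class GroupReport:
    per_roi: pd.DataFrame  # group, culture, roi, band_power, oscillation call
    per_group: pd.DataFrame  # N, n_osc, percent_oscillating, power mean/SEM, MI, DI
    cluster_partitions: dict[str, clustering.ClusterPartition]
    anova: pd.DataFrame | None
    tukey: pd.DataFrame | None
    manifest: dict


def _config_hash(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    d.pop("out_dir", None)  # hash identifies the analysis, not its location
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _group_traces(
    spec: GroupSpec, cfg: RunConfig, rng_seeds: list[int]
) -> list[TraceSet]:
    """Per-culture raw trace sets: simulated, extracted from movies, or read."""
    out: list[TraceSet] = []
    if spec.trace_paths:
        fs = 1.0 / SimulationConfig(**spec.simulation).frame_interval_s \
            if spec.simulation else 20.0
        for p in spec.trace_paths:
            out.append(TraceSet.from_csv(p, fs_hz=fs))
        return out
    if spec.movie_paths:
        dt = SimulationConfig(**spec.simulation).frame_interval_s \
            if spec.simulation else 0.05
        for p in spec.movie_paths:
            movie = FluorescenceMovie.from_tiff(p, frame_interval_s=dt)
            _, ts = roi.extract_rois(
                movie, sigma_px=cfg.roi_sigma_px,
                min_distance_px=cfg.roi_min_distance_px,
            )
            out.append(ts)
        return out
    sim_dict = dict(spec.simulation)
    simulate_movies = sim_dict.pop("_render_movie", False)
    for k in range(spec.n_cultures):
        sim_cfg = synthetic.config_from_dict(
            {**sim_dict, "rng_seed": rng_seeds[k]}
        )
        if simulate_movies:
            movie, _ = synthetic.simulate_movie(sim_cfg)
            _, ts = roi.extract_rois(
                movie, sigma_px=cfg.roi_sigma_px,
                min_distance_px=cfg.roi_min_distance_px,
            )
        else:
            ts, _ = synthetic.simulate_traces(sim_cfg)
        out.append(ts)
    return out


def run_pipeline(cfg: RunConfig) -> GroupReport:
    """Execute every stage for every group and assemble the report.

    Peak pooling for the oscillation call spans all ROIs of the run (every
    construct, time point and culture together); clustering is per group,
    matching how the source experiments were analyzed.
    """
    ss = np.random.SeedSequence(cfg.master_seed)
    group_seeds = ss.spawn(len(cfg.groups))
    cluster_seed, embed_seed = (int(s) for s in ss.generate_state(2) % (2**31))

    all_dffs: list[traces.DFFTrace] = []
    meta: list[dict] = []
    for g_idx, spec in enumerate(cfg.groups):
        culture_seeds = [
            int(s) for s in group_seeds[g_idx].generate_state(spec.n_cultures)
            % (2**31)
        ]
        log.info("group %s: preparing %d cultures", spec.name, spec.n_cultures)
        for c_idx, ts in enumerate(_group_traces(spec, cfg, culture_seeds)):
            dffs = traces.process_traceset(
                ts,
                half_window_s=cfg.dff_half_window_s,
                percentile=cfg.dff_percentile,
                smooth_window_frames=cfg.sg_window_frames,
                smooth_poly_order=cfg.sg_poly_order,
            )
            for d in dffs:
                meta.append(
                    {"group": spec.name, "time_point": spec.time_point,
                     "construct": spec.construct, "culture": c_idx,
                     "roi_id": d.roi_id}
                )
            all_dffs.extend(dffs)

    log.info("spectral analysis of %d ROIs (pooled oscillation call)",
             len(all_dffs))
    results = spectral.analyze_traces(
        all_dffs,
        window_s=cfg.welch_window_s,
        overlap_s=cfg.welch_overlap_s,
        k_sd=cfg.peak_k_sd,
        keep_top_percent=cfg.keep_top_percent,
    )

    per_roi = pd.DataFrame(meta)
    per_roi["band_power"] = [sr.band_power_0p2_3 for sr in results]
    per_roi["has_oscillation"] = [sr.has_significant_oscillation for sr in results]
    per_roi["oscillation_freq_hz"] = [sr.oscillation_freq_hz for sr in results]
    per_roi["n_peaks"] = [len(sr.peaks) for sr in results]

    partitions: dict[str, clustering.ClusterPartition] = {}
    group_rows = []
    for spec in cfg.groups:
        sel = per_roi["group"] == spec.name
        idx = np.flatnonzero(sel.to_numpy())
        feats = [
            clustering.compute_features(all_dffs[i], results[i]) for i in idx
        ]
        part = None
        if len(feats) >= 2:
            log.info("clustering group %s (%d ROIs)", spec.name, len(feats))
            part = clustering.cluster_rois(
                feats, n_runs=cfg.louvain_runs, tau=cfg.consensus_tau,
                seed=cluster_seed, n_neighbors=cfg.umap_n_neighbors,
                min_dist=cfg.umap_min_dist,
            )
            partitions[spec.name] = part
        summ = spectral.summarize_group([results[i] for i in idx], spec.name)
        bp = per_roi.loc[sel, "band_power"].to_numpy()
        group_rows.append(
            {
                "group": spec.name,
                "time_point": spec.time_point,
                "construct": spec.construct,
                "N": summ.n_rois,
                "n_oscillating": summ.n_oscillating,
                "percent_oscillating": summ.percent_oscillating,
                "freq_mean_hz": summ.normal_fit[0] if summ.normal_fit else np.nan,
                "freq_sd_hz": summ.normal_fit[1] if summ.normal_fit else np.nan,
                "band_power_mean": bp.mean() if bp.size else np.nan,
                "band_power_sem": bp.std(ddof=1) / np.sqrt(bp.size)
                if bp.size > 1 else np.nan,
                "modularity": part.modularity if part else np.nan,
                "dunn_index": part.dunn if part else np.nan,
                "n_clusters": part.n_clusters if part else 0,
            }
        )
    per_group = pd.DataFrame(group_rows)

    anova = tukey = None
    tp_levels = per_roi["time_point"].nunique()
    ct_levels = per_roi["construct"].nunique()
    if tp_levels >= 2 and ct_levels >= 2:
        anova, tukey = compare_groups(per_roi, alpha=cfg.alpha)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "master_seed": cfg.master_seed,
        "n_rois_total": int(len(all_dffs)),
        "package": "calcispect",
    }
    report = GroupReport(
        per_roi=per_roi, per_group=per_group, cluster_partitions=partitions,
        anova=anova, tukey=tukey, manifest=manifest,
    )
    if cfg.out_dir is not None:
        _write_artifacts(report, Path(cfg.out_dir))
    return report


def _write_artifacts(report: GroupReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.per_roi.to_csv(out_dir / "per_roi.csv", index=False)
    report.per_group.to_csv(out_dir / "per_group.csv", index=False)
    for name, part in report.cluster_partitions.items():
        pd.DataFrame(
            {"roi_index": np.arange(part.labels.size), "cluster": part.labels}
        ).to_csv(out_dir / f"partition_{name}.csv", index=False)
        if part.embedding is not None:
            pd.DataFrame(part.embedding, columns=["umap_1", "umap_2"]).to_csv(
                out_dir / f"embedding_{name}.csv", index=False
            )
    if report.anova is not None:
        report.anova.to_csv(out_dir / "anova.csv")
    if report.tukey is not None:
        report.tukey.to_csv(out_dir / "tukey.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=1, default=str)
    )


# ---------------------------------------------------------------------------
# group statistics (thin wrappers over statsmodels)
# ---------------------------------------------------------------------------

def compare_groups(
    per_roi: pd.DataFrame,
    value: str = "band_power",
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (time point x construct) with Tukey HSD post-hoc."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    counts = per_roi.groupby(["time_point", "construct"]).size()
    if per_roi["time_point"].nunique() < 2 or per_roi["construct"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    full = (
        per_roi["time_point"].nunique() * per_roi["construct"].nunique()
    )
    if len(counts) < full:
        raise ValueError("empty factor cells; two-way ANOVA undefined")
    if (counts < 2).any():
        raise ValueError("each cell needs at least 2 observations")

    df = per_roi.rename(columns={value: "y"})
    model = ols("y ~ C(time_point) * C(construct)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    cell = df["time_point"].astype(str) + ":" + df["construct"].astype(str)
    tk = pairwise_tukeyhsd(df["y"], cell, alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return anova, tukey


def compare_clusters(
    values: np.ndarray, labels: np.ndarray, alpha: float = ALPHA
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA with Tukey-Kramer post-hoc across clusters."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({"y": values, "cluster": labels.astype(str)})
    if df["cluster"].nunique() < 2:
        raise ValueError("need at least 2 clusters")
    if (df.groupby("cluster").size() < 2).any():
        raise ValueError("each cluster needs at least 2 observations")
    model = ols("y ~ C(cluster)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    tk = pairwise_tukeyhsd(df["y"], df["cluster"], alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return anova, tukey
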