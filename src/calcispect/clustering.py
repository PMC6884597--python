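"""Feature-graph consensus clustering of ROI activity.

Each ROI is summarized by an 8-feature time-frequency vector; ROIs become
nodes of a complete graph weighted by the reciprocal of the L2 distance
between standardized feature vectors; communities are found by maximizing
modularity with the Louvain algorithm, stabilized by a co-assignment
consensus over many runs.  Cluster separation is scored with Dunn's index
on a 2-D UMAP embedding of the feature vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import skew

from .spectral import SpectralResult
from .traces import DFFTrace

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "SimilarityGraph",
    "ClusterPartition",
    "compute_features",
    "build_graph",
    "louvain_consensus",
    "embed_features",
    "dunn_index",
]

#: distance floor before taking reciprocals; identical feature vectors get
#: weight 1/EPS instead of infinity
EPS = 1e-9

FEATURE_NAMES = (
    "mean_dff",
    "sd_dff",
    "skew_dff",
    "transients_per_min",
    "mean_transient_amplitude",
    "band_power_0p2_3",
    "dominant_freq_hz",
    "spectral_entropy",
)


@dataclass(frozen=True)
class FeatureVector:
    roi_id: int
    values: np.ndarray  # 8 finite entries, ordered as FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


@dataclass(frozen=True)
class SimilarityGraph:
    connectivity: np.ndarray  # N x N symmetric, non-negative, zero diagonal
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        C = self.connectivity
        if not np.allclose(C, C.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(C < 0) or np.any(np.diag(C) != 0):
            raise ValueError("weights must be non-negative with zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.connectivity.shape[0]


@dataclass(frozen=True)
class ClusterPartition:
    labels: np.ndarray
    n_clusters: int
    modularity: float  # MI of the consensus labels on the original graph
    mean_run_modularity: float
    dunn: float | None
    embedding: np.ndarray | None
    n_runs: int
    consensus_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _transient_stats(
    dff: np.ndarray, fs_hz: float, k_sd: float = 2.0
) -> tuple[float, float]:
    """Count threshold crossings and their mean peak amplitude.

    An event starts at an upward crossing of median + k_sd * SD and ends
    when the signal falls back below; its amplitude is the epoch maximum.
    """
    sd = dff.std()
    if sd == 0:
        return 0.0, 0.0
    threshold = np.median(dff) + k_sd * sd
    above = dff > threshold
    starts = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if starts.size == 0:
        return 0.0, 0.0
    ends = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    amps = []
    for s in starts:
        e_candidates = ends[ends > s]
        e = e_candidates[0] if e_candidates.size else dff.size
        amps.append(dff[s:e].max())
    per_min = starts.size / (dff.size / fs_hz / 60.0)
    return float(per_min), float(np.mean(amps))


def compute_features(dff: DFFTrace, sr: SpectralResult) -> FeatureVector:
    """8-feature time-frequency characterization of one ROI.

    Amplitude moments of dF/F, transient statistics from threshold
    crossings, total power in [0.2, 3] Hz, the dominant frequency and the
    spectral (Shannon) entropy over [0.2, 8] Hz.  Non-finite features
    (e.g. skewness of a constant trace) fall back to 0.
    """
    x = dff.dff
    mean, sd = float(x.mean()), float(x.std())
    sk = float(skew(x)) if sd > 0 else 0.0
    if not np.isfinite(sk):
        sk = 0.0
    per_min, amp = _transient_stats(x, dff.fs_hz)

    lo, hi = sr.fit_band
    in_band = (sr.freqs_hz >= lo) & (sr.freqs_hz <= hi)
    p = sr.psd[in_band]
    f = sr.freqs_hz[in_band]
    if p.sum() > 0:
        dominant = float(f[np.argmax(p)])
        q = p / p.sum()
        nz = q > 0
        entropy = float(-(q[nz] * np.log2(q[nz])).sum())
    else:
        dominant, entropy = 0.0, 0.0
    bp = sr.band_power_0p2_3 if sr.band_power_0p2_3 is not None else 0.0
    values = np.array([mean, sd, sk, per_min, amp, bp, dominant, entropy])
    return FeatureVector(roi_id=dff.roi_id, values=values)


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------

def feature_matrix(features: list[FeatureVector]) -> np.ndarray:
    return np.vstack([fv.values for fv in features])


def standardize(X: np.ndarray) -> np.ndarray:
    """Z-score each feature across ROIs; zero-variance features map to 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def build_graph(
    features: list[FeatureVector], standardize_features: bool = True
) -> SimilarityGraph:
    """Complete graph weighted by reciprocal L2 feature distance.

    w_ij = 1 / (||z_i - z_j||_2 + eps): similar ROIs are strongly
    connected, dissimilar ones weakly.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 ROIs to build a graph")
    X = feature_matrix(features)
    if standardize_features:
        X = standardize(X)
    D = squareform(pdist(X, metric="euclidean"))
    C = 1.0 / (D + EPS)
    np.fill_diagonal(C, 0.0)
    ids = np.array([fv.roi_id for fv in features])
    return SimilarityGraph(connectivity=C, roi_ids=ids)


# ---------------------------------------------------------------------------
# Louvain consensus
# ---------------------------------------------------------------------------

def _louvain_once(G: nx.Graph, seed: int) -> tuple[np.ndarray, float]:
    comms = nx.community.louvain_communities(G, weight="weight", seed=int(seed))
    labels = np.empty(G.number_of_nodes(), dtype=int)
    for k, members in enumerate(comms):
        for node in members:
            labels[node] = k
    mod = nx.community.modularity(G, comms, weight="weight")
    return labels, float(mod)


def _graph_from_matrix(C: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    n = C.shape[0]
    G.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    w = C[iu, ju]
    nz = w > 0
    G.add_weighted_edges_from(zip(iu[nz].tolist(), ju[nz].tolist(), w[nz].tolist()))
    return G


def _all_identical(runs: np.ndarray) -> bool:
    first = runs[0]
    return all(_same_partition(first, r) for r in runs[1:])


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    # identical up to relabeling: co-membership matrices agree
    return np.array_equal(
        a[:, None] == a[None, :], b[:, None] == b[None, :]
    )


def louvain_consensus(
    graph: SimilarityGraph,
    n_runs: int = 100,
    tau: float = 0.5,
    seed: int = 0,
    max_iterations: int = 10,
) -> ClusterPartition:
    """Consensus community detection over repeated Louvain optimizations.

    Louvain is run ``n_runs`` times with distinct sub-seeds; the
    co-assignment matrix D (fraction of runs placing each pair together)
    is thresholded at ``tau`` and re-clustered, iterating until every run
    agrees or ``max_iterations`` is reached.  The reported modularity is
    that of the consensus labels on the original graph.
    """
    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s) for s in ss.generate_state(n_runs * max_iterations) % (2**31)]
    seed_iter = iter(sub_seeds)

    G0 = _graph_from_matrix(graph.connectivity)
    n = graph.n_nodes

    runs = np.empty((n_runs, n), dtype=int)
    mods = np.empty(n_runs)
    for r in range(n_runs):
        runs[r], mods[r] = _louvain_once(G0, next(seed_iter))
    mean_run_modularity = float(mods.mean())

    iterations = 0
    converged = _all_identical(runs)
    while not converged and iterations < max_iterations:
        iterations += 1
        D = np.zeros((n, n))
        for r in range(n_runs):
            D += runs[r][:, None] == runs[r][None, :]
        D /= n_runs
        D[D < tau] = 0.0
        np.fill_diagonal(D, 0.0)
        Gc = _graph_from_matrix(D)
        for r in range(n_runs):
            runs[r], _ = _louvain_once(Gc, next(seed_iter))
        converged = _all_identical(runs)

    if not converged:
        warnings.warn(
            f"consensus did not converge within {max_iterations} iterations; "
            "returning the current majority partition",
            RuntimeWarning,
        )
    labels = _canonical_labels(runs[0])
    comms = [set(np.flatnonzero(labels == k)) for k in range(labels.max() + 1)]
    modularity = float(
        nx.community.modularity(G0, comms, weight="weight")
    ) if len(comms) > 1 else 0.0
    return ClusterPartition(
        labels=labels,
        n_clusters=len(comms),
        modularity=modularity,
        mean_run_modularity=mean_run_modularity,
        dunn=None,
        embedding=None,
        n_runs=n_runs,
        consensus_iterations=iterations,
        converged=converged,
    )


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# embedding and validity
# ---------------------------------------------------------------------------

def embed_features(
    features: list[FeatureVector],
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    standardize_features: bool = True,
) -> np.ndarray:
    """2-D UMAP embedding of the feature vectors, deterministic given seed.

    Falls back to the first two principal components (with a warning) when
    the cohort is too small for the neighbor graph.
    """
    X = feature_matrix(features)
    if standardize_features:
        X = standardize(X)
    n = X.shape[0]
    if n <= n_neighbors:
        warnings.warn(
            f"N={n} too small for n_neighbors={n_neighbors}; "
            "falling back to PCA",
            RuntimeWarning,
        )
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        return Xc @ vt[:2].T
    import umap  # deferred: heavy import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Classical Dunn's index on a point set.

    DI = (minimum single-linkage inter-cluster distance) /
    (maximum intra-cluster diameter); diameters below ``EPS`` are floored
    so coincident clusters yield DI = 0 rather than a division error.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn's index requires at least 2 clusters")
    if any((labels == u).sum() == 0 for u in uniq):
        raise ValueError("every cluster must be non-empty")
    D = squareform(pdist(points, metric="euclidean"))
    min_inter = np.inf
    max_diam = 0.0
    for a_idx, a in enumerate(uniq):
        ia = labels == a
        sub = D[np.ix_(ia, ia)]
        if ia.sum() > 1:
            max_diam = max(max_diam, float(sub.max()))
        for b in uniq[a_idx + 1:]:
            ib = labels == b
            min_inter = min(min_inter, float(D[np.ix_(ia, ib)].min()))
    return min_inter / max(max_diam, EPS)


def cluster_rois(
    features: list[FeatureVector],
    n_runs: int = 100,
    tau: float = 0.5,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> ClusterPartition:
    """Graph construction, consensus clustering, embedding and validity."""
    graph = build_graph(features)
    part = louvain_consensus(graph, n_runs=n_runs, tau=tau, seed=seed)
    emb = embed_features(features, seed=seed, n_neighbors=n_neighbors,
                         min_dist=min_dist)
    di = (
        dunn_index(emb, part.labels) if part.n_clusters >= 2 else None
    )
    return ClusterPartition(
        labels=part.labels,
        n_clusters=part.n_clusters,
        modularity=part.modularity,
        mean_run_modularity=part.mean_run_modularity,
        dunn=di,
        embedding=emb,
        n_runs=part.n_runs,
        consensus_iterations=part.consensus_iterations,
        converged=part.converged,
    )
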