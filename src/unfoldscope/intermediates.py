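"""Unfolding-intermediate detection by clustering in (RMSD, H-bond) space.

Trajectory frames are embedded in a two-dimensional reaction-coordinate
plane — Cα RMSD to the native reference (tertiary structure, nm) and the
main-chain hydrogen-bond count (secondary structure) — and partitioned
with k-means. Silhouette widths validate the partition, and persistent,
temporally contiguous clusters are read as unfolding intermediates.

Features are used raw (nm and counts, no standardisation) so that cluster
centres are directly interpretable in those units; pass
``standardize=True`` to cluster on z-scores instead (centroids are always
reported back in raw units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from unfoldscope.secondary_structure import count_mainchain_hbonds
from unfoldscope.structure_io import Frame, Trajectory
from unfoldscope.trajectory_metrics import rmsd_series

__all__ = [
    "FeatureMatrix", "ClusterResult", "build_features", "kmeans",
    "silhouette", "cluster_trajectory", "plateau_detect",
    "silhouette_over_k",
]


@dataclass
class FeatureMatrix:
    """n×2 reaction coordinates (RMSD nm, H-bond count) with frame times (ps)."""

    points: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be n×2")
        if len(self.times) != len(self.points):
            raise ValueError("times and points disagree in length")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("features contain missing values")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ClusterResult:
    """A k-means partition with optional silhouette validation."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int
    silhouettes: np.ndarray | None = None
    time_spans: list[tuple[int, float, float]] = field(default_factory=list)
    # (cluster, start ps, end ps) intervals dominated by each cluster

    @property
    def mean_silhouette(self) -> float:
        if self.silhouettes is None:
            raise ValueError("silhouettes not computed")
        return float(np.mean(self.silhouettes))


def build_features(traj: Trajectory, reference: Frame) -> FeatureMatrix:
    """Column-bind the RMSD series and the per-frame H-bond counts."""
    rmsd = rmsd_series(traj, reference)
    hbonds = np.array([count_mainchain_hbonds(f) for f in traj.frames], dtype=float)
    return FeatureMatrix(np.column_stack([rmsd, hbonds]), traj.times)


def kmeans(points: np.ndarray, k: int, seed: int = 0,
           standardize: bool = False) -> ClusterResult:
    """k-means with k-means++ seeding, 10 restarts, Lloyd iterations.

    Squared-Euclidean assignment; the best-inertia run of 10 seeded
    restarts is kept, so the result is deterministic given *seed*.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be 2-D")
    n = len(points)
    if not 1 <= k <= n:
        raise ValueError(f"need n ≥ k ≥ 1, got n={n}, k={k}")
    if k > 1 and np.allclose(points, points[0]):
        raise ValueError("all points identical: clustering with k > 1 is degenerate")
    X = points
    mu = sigma = None
    if standardize:
        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        sigma[sigma == 0] = 1.0
        X = (X - mu) / sigma
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, algorithm="lloyd",
                random_state=seed).fit(X)
    centroids = km.cluster_centers_
    if standardize:
        centroids = centroids * sigma + mu
    return ClusterResult(k, km.labels_.astype(int), centroids,
                         float(km.inertia_), seed)


def silhouette(points: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point silhouette widths s(i) = (b−a)/max(a,b) and their mean.

    Euclidean distances; singleton clusters score 0. Requires at least
    two non-empty clusters.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    vals = silhouette_samples(points, labels, metric="euclidean")
    return vals, float(vals.mean())


def _dominant_spans(labels: np.ndarray, times: np.ndarray,
                    window: int = 5) -> list[tuple[int, float, float]]:
    """Maximal contiguous intervals dominated (majority within *window*) by one cluster."""
    n = len(labels)
    half = window // 2
    smoothed = np.empty(n, dtype=int)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        best = counts.max()
        smoothed[i] = min(v for v, c in zip(vals, counts) if c == best)
    spans = []
    start = 0
    for i in range(1, n + 1):
        if i == n or smoothed[i] != smoothed[start]:
            spans.append((int(smoothed[start]), float(times[start]),
                          float(times[i - 1])))
            start = i
    return spans


def cluster_trajectory(traj: Trajectory, reference: Frame, k: int = 3,
                       seed: int = 0, standardize: bool = False) -> ClusterResult:
    """Cluster a trajectory in the (RMSD, H-bond) plane and time-resolve the result.

    Runs :func:`kmeans` and :func:`silhouette` on :func:`build_features`
    and reports the contiguous time intervals dominated by each cluster
    (majority label within a 5-frame window).
    """
    feats = build_features(traj, reference)
    result = kmeans(feats.points, k, seed=seed, standardize=standardize)
    if k >= 2:
        result.silhouettes, _ = silhouette(feats.points, result.labels)
    result.time_spans = _dominant_spans(result.labels, feats.times)
    return result


def silhouette_over_k(points: np.ndarray, k_range=range(2, 7),
                      seed: int = 0) -> pd.DataFrame:
    """Mean silhouette for each candidate k (simple model-selection scan)."""
    rows = []
    for k in k_range:
        res = kmeans(points, k, seed=seed)
        _, mean = silhouette(points, res.labels)
        rows.append({"k": k, "mean_silhouette": mean, "inertia": res.inertia})
    return pd.DataFrame(rows)


def plateau_detect(times_ps: np.ndarray, values: np.ndarray,
                   window_ns: float = 1.0,
                   slope_tol: float = 0.1) -> list[tuple[float, float]]:
    """Maximal flat intervals of a time series.

    A point is *flat* when the least-squares slope of the series within a
    centred window of *window_ns* has magnitude ≤ slope_tol × (global
    range / global duration). Maximal runs of flat points are returned as
    (start ps, end ps) intervals. Constant series yield one full-span
    plateau.
    """
    t = np.asarray(times_ps, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) != len(y) or len(t) < 2:
        raise ValueError("need matching series of length ≥ 2")
    window_ps = window_ns * 1000.0
    duration = t[-1] - t[0]
    if duration < 2 * window_ps:
        raise ValueError("window larger than half the series span")
    rng = np.ptp(y)
    if rng == 0:
        return [(float(t[0]), float(t[-1]))]
    tol = slope_tol * rng / duration
    flat = np.zeros(len(t), dtype=bool)
    for i in range(len(t)):
        mask = np.abs(t - t[i]) <= window_ps / 2
        if np.count_nonzero(mask) < 2:
            continue
        tm, ym = t[mask], y[mask]
        slope = np.polyfit(tm, ym, 1)[0]
        flat[i] = abs(slope) <= tol
    plateaus = []
    start = None
    for i, f in enumerate(flat):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if t[i - 1] > t[start]:
                plateaus.append((float(t[start]), float(t[i - 1])))
            start = None
    if start is not None and t[-1] > t[start]:
        plateaus.append((float(t[start]), float(t[-1])))
    return plateaus
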