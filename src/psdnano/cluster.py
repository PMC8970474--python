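"""Nanocluster detection and bracelet-ring geometry for localization data.

Nanoclusters are detected with DBSCAN (epsilon = 20 nm, minimum 5 points,
the point itself counted toward its own neighbourhood — the original
algorithm's convention).  Cluster size is reported as the longest axis
(maximum pairwise member distance).  Ring ("bracelet") arrangements of
peripheral nanoclusters around a central reference are quantified with an
algebraic least-squares circle fit through cluster centroids and a sector
occupancy score that classifies a synapse as bracelet-like or not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

NOISE = -1


@dataclass
class ClusterParams:
    epsilon: float = 20.0   # nm
    min_points: int = 5     # includes the point itself

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class ClusterSet:
    """Labelled partition of localizations into nanoclusters.

    ``labels`` assigns each localization a cluster id or -1 for noise.
    ``clusters`` has one row per cluster: id, centroid coordinates, member
    count ``n``, and ``longest_axis`` (nm).
    """

    labels: np.ndarray
    clusters: pd.DataFrame
    coords: np.ndarray

    def __len__(self) -> int:
        return len(self.clusters)

    def members(self, cluster_id: int) -> np.ndarray:
        return self.coords[self.labels == cluster_id]

    @property
    def centroids(self) -> np.ndarray:
        cols = [c for c in ("cx", "cy", "cz") if c in self.clusters.columns]
        return self.clusters[cols].to_numpy()


def _coords_from_table(table: pd.DataFrame) -> np.ndarray:
    cols = ["x", "y"] + (["z"] if "z" in table.columns and table["z"].notna().all() else [])
    return table[cols].to_numpy(dtype=float)


def detect_clusters_dbscan(table: pd.DataFrame, params: ClusterParams | None = None) -> ClusterSet:
    """Partition a localization table into nanoclusters via DBSCAN.

    Euclidean metric in nm; 2D or 3D handled uniformly.  Border points are
    assigned deterministically given input order.  An empty table yields an
    empty ClusterSet.
    """
    params = params or ClusterParams()
    coords = _coords_from_table(table) if len(table) else np.empty((0, 2))
    if len(coords) == 0:
        empty = pd.DataFrame(columns=["cluster", "cx", "cy", "n", "longest_axis"])
        return ClusterSet(labels=np.empty(0, dtype=int), clusters=empty, coords=coords)
    if not np.all(np.isfinite(coords)):
        raise ValueError("localization coordinates must be finite")
    labels = DBSCAN(eps=params.epsilon, min_samples=params.min_points).fit_predict(coords)
    rows = []
    dim_cols = ["cx", "cy", "cz"][: coords.shape[1]]
    for cid in np.unique(labels):
        if cid == NOISE:
            continue
        members = coords[labels == cid]
        row = {"cluster": int(cid)}
        row.update(dict(zip(dim_cols, members.mean(axis=0))))
        row["n"] = len(members)
        row["longest_axis"] = cluster_longest_axis(members)
        rows.append(row)
    clusters = pd.DataFrame(rows, columns=["cluster", *dim_cols, "n", "longest_axis"])
    return ClusterSet(labels=labels, clusters=clusters, coords=coords)


def cluster_longest_axis(points: np.ndarray) -> float:
    """Longest axis of a cluster: the maximum pairwise member distance (nm).

    Exact; for large clusters the convex hull prunes the pair search.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    if len(pts) == 1:
        return 0.0
    if len(pts) > 400 and pts.shape[1] in (2, 3):
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (collinear) input: fall back to all pairs
    return float(pdist(pts).max())


def size_histogram(
    values: np.ndarray,
    bin_width: float = 15.0,
    overflow_cap: float | None = 400.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of cluster sizes with half-open bins and an overflow bin.

    Bins are ``[k*w, (k+1)*w)``; values ``>= overflow_cap`` pool into a
    terminal bin.  Returns (edges, counts); total count is conserved.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError("sizes must be non-negative")
    if overflow_cap is not None:
        n_bins = int(math.ceil(overflow_cap / bin_width))
        edges = np.arange(n_bins + 1) * bin_width
        counts = np.histogram(vals[vals < overflow_cap], bins=edges)[0]
        counts = np.append(counts, int((vals >= overflow_cap).sum()))
        edges = np.append(edges, np.inf)
        return edges, counts
    if len(vals) == 0:
        return np.array([0.0, bin_width]), np.zeros(1, dtype=int)
    n_bins = int(vals.max() // bin_width) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.histogram(vals, bins=edges)[0]
    return edges, counts


@dataclass
class RingEstimate:
    """Least-squares circle fit through peripheral cluster centroids."""

    centre: tuple[float, float] | None
    diameter: float | None
    residual: float | None      # RMS radial residual, nm
    n_support: int
    defined: bool


def estimate_ring_diameter(centroids: np.ndarray, min_support: int = 3) -> RingEstimate:
    """Fit a circle to cluster centroids and return its diameter.

    Algebraic (Kasa) fit: least squares on x^2 + y^2 = 2ax + 2by + c, which
    is exact on noiseless circles for any >= 3 non-collinear points.
    Under-supported or collinear inputs yield an undefined, flagged
    estimate.
    """
    pts = np.asarray(centroids, dtype=float)[:, :2]
    n = len(pts)
    if n < min_support:
        return RingEstimate(None, None, None, n, False)
    x, y = pts[:, 0], pts[:, 1]
    a_mat = np.column_stack([2.0 * x, 2.0 * y, np.ones(n)])
    b_vec = x ** 2 + y ** 2
    sol, _, rank, _ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    if rank < 3:
        return RingEstimate(None, None, None, n, False)
    cx, cy, c = sol
    r2 = c + cx ** 2 + cy ** 2
    if r2 <= 0:
        return RingEstimate(None, None, None, n, False)
    radius = math.sqrt(r2)
    radial = np.hypot(x - cx, y - cy)
    residual = float(np.sqrt(np.mean((radial - radius) ** 2)))
    return RingEstimate((float(cx), float(cy)), 2.0 * radius, residual, n, True)


@dataclass
class BraceletScore:
    score: float
    is_bracelet: bool
    occupied_sectors: int
    central_violation_ratio: float


def classify_bracelet(
    peripheral_centroids: np.ndarray,
    centre: tuple[float, float],
    n_sectors: int = 8,
    void_radius: float = 250.0,
    threshold: float = 0.5,
) -> BraceletScore:
    """Score the ring-likeness of peripheral nanoclusters around a centre.

    score = (fraction of ``n_sectors`` angular sectors occupied by at least
    one peripheral cluster centroid) x (1 - central-void violation ratio),
    where the violation ratio is the fraction of centroids falling inside
    ``void_radius`` of the centre (a bracelet leaves the PSD interior
    empty).  Classified bracelet when score >= ``threshold``.  No peripheral
    clusters at all scores 0.
    """
    pts = np.asarray(peripheral_centroids, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return BraceletScore(0.0, False, 0, 0.0)
    rel = pts - np.asarray(centre, dtype=float)
    r = np.hypot(rel[:, 0], rel[:, 1])
    violation = float(np.mean(r < void_radius))
    outer = rel[r >= void_radius]
    if len(outer) == 0:
        return BraceletScore(0.0, False, 0, violation)
    ang = np.mod(np.arctan2(outer[:, 1], outer[:, 0]), 2.0 * math.pi)
    sectors = np.unique((ang / (2.0 * math.pi / n_sectors)).astype(int))
    occupied = int(len(sectors))
    score = (occupied / n_sectors) * (1.0 - violation)
    return BraceletScore(float(score), bool(score >= threshold), occupied, violation)


def combined_peripheral_centroids(*cluster_sets: ClusterSet) -> np.ndarray:
    """Stack the 2D centroids of several ClusterSets (e.g. both ring species)."""
    parts = [cs.centroids[:, :2] for cs in cluster_sets if len(cs)]
    if not parts:
        return np.empty((0, 2))
    return np.vstack(parts)
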