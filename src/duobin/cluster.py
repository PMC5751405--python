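"""Primary binning: density-based clustering in GC-log(coverage) space.

Coverage separates organisms of different abundance even when their
composition is similar, so the first tier clusters contigs on just two axes:
GC fraction and log coverage. DBSCAN is used because it infers the number of
clusters from the data, makes no shape assumption, and flags low-density
outliers as noise rather than forcing them into a bin.

The two axes have incommensurate units (GC in [0,1], log-coverage roughly
0-5.7 for coverages 1-300), so each axis is standardised to zero mean / unit
variance before Euclidean distances are taken. The neighbourhood radius
``eps``, if not supplied, is chosen from the k-distance curve
(k = ``min_points``) at the knee, located as the point of maximum distance to
the chord joining the curve's endpoints.

The DBSCAN implementation here is intentionally self-contained: a brute-force
O(n^2) neighbour search and the classic core/border/noise expansion with a
fixed, documented scan order (input order), so border points join the cluster
that discovers them first and runs are deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import UNCLASSIFIED

#: minimum eps returned by the knee heuristic (guards all-duplicate input)
EPSILON_FLOOR = 1e-6

#: classic heuristic for 2-D data
DEFAULT_MIN_POINTS = 4


def scale_features(points: np.ndarray) -> np.ndarray:
    """Standardise each axis to zero mean, unit (population) variance.

    A constant axis is mapped to all-zeros with a warning. Requires at least
    two points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("scale_features: need at least 2 points (2-D array)")
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0)  # population sd (ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"scale_features: {int(constant.sum())} constant axis/axes mapped "
            "to zeros",
            stacklevel=2,
        )
        sd = np.where(constant, 1.0, sd)
    return (pts - mean) / sd


def select_epsilon(
    points: np.ndarray,
    min_points: int = DEFAULT_MIN_POINTS,
    epsilon: float | None = None,
) -> float:
    """Choose DBSCAN's eps from the k-distance curve, unless overridden.

    With k = ``min_points``, the distance from every point to its k-th
    nearest neighbour (self included) is sorted ascending; eps is the value
    at the knee — the point of maximum perpendicular distance to the chord
    joining the curve's endpoints — floored at :data:`EPSILON_FLOOR`.
    A user-supplied ``epsilon`` is returned unchanged.
    """
    if epsilon is not None:
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        return float(epsilon)
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < min_points + 1:
        raise ValueError(
            f"select_epsilon: need at least min_points+1={min_points + 1} "
            f"points, got {n}"
        )
    dmat = squareform(pdist(pts))
    # distance to the (min_points-1)-th nearest *other* point, so that a core
    # point's eps-neighbourhood holds min_points points including itself
    kdist = np.sort(np.sort(dmat, axis=1)[:, min_points - 1])
    x = np.arange(n, dtype=float)
    x0, y0 = x[0], kdist[0]
    x1, y1 = x[-1], kdist[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    if chord == 0:
        return EPSILON_FLOOR
    # perpendicular distance from each curve point to the chord
    dist = np.abs((y1 - y0) * x - (x1 - x0) * kdist + x1 * y0 - y1 * x0) / chord
    knee = int(np.argmax(dist))
    return max(float(kdist[knee]), EPSILON_FLOOR)


class DBSCANClusterer(BaseEstimator, ClusterMixin):
    """Density-based clustering with noise detection (DBSCAN).

    Parameters
    ----------
    eps : float, optional
        Neighbourhood radius. If None, chosen by :func:`select_epsilon`.
    min_points : int, default 4
        Minimum number of points (the point itself included) within ``eps``
        for a point to be a core point.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster label per point; noise points get ``UNCLASSIFIED`` (-1).
        Cluster labels are contiguous integers starting at 0, numbered in
        order of discovery.
    core_sample_indices_ : ndarray
        Indices of core points.
    eps_ : float
        The radius actually used.
    n_clusters_ : int
    """

    def __init__(self, eps: float | None = None, min_points: int = DEFAULT_MIN_POINTS):
        self.eps = eps
        self.min_points = min_points

    def fit(self, X: np.ndarray, y=None) -> "DBSCANClusterer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("DBSCANClusterer: X must be a nonempty 2-D array")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        n = X.shape[0]
        eps = self.eps if self.eps is not None else select_epsilon(X, self.min_points)
        dmat = cdist(X, X)
        neighbors = [np.flatnonzero(dmat[i] <= eps) for i in range(n)]
        core = np.array([len(nb) >= self.min_points for nb in neighbors])

        UNDEFINED = -2
        labels = np.full(n, UNDEFINED, dtype=int)
        cid = 0
        for p in range(n):
            if labels[p] != UNDEFINED:
                continue
            if not core[p]:
                labels[p] = UNCLASSIFIED
                continue
            labels[p] = cid
            seeds: list[int] = list(neighbors[p])
            i = 0
            while i < len(seeds):
                q = seeds[i]
                i += 1
                if labels[q] == UNCLASSIFIED:
                    labels[q] = cid  # border point, discovered first by cid
                if labels[q] != UNDEFINED:
                    continue
                labels[q] = cid
                if core[q]:
                    seeds.extend(neighbors[q])
            cid += 1

        self.labels_ = labels
        self.core_sample_indices_ = np.flatnonzero(core)
        self.eps_ = float(eps)
        self.n_clusters_ = cid
        return self


def dbscan(
    points: np.ndarray,
    eps: float | None = None,
    min_points: int = DEFAULT_MIN_POINTS,
) -> np.ndarray:
    """Functional wrapper over :class:`DBSCANClusterer`; returns labels."""
    return DBSCANClusterer(eps=eps, min_points=min_points).fit(points).labels_


def primary_bin(
    features: pd.DataFrame,
    epsilon: float | None = None,
    min_points: int = DEFAULT_MIN_POINTS,
) -> pd.Series:
    """Cluster contigs in scaled GC-log(coverage) space with DBSCAN.

    Parameters
    ----------
    features : DataFrame
        Feature table with ``gc`` and ``log_coverage`` columns (see
        :func:`duobin.features.build_feature_table`).

    Returns
    -------
    Series
        Bin label per contig id; noise contigs get ``UNCLASSIFIED``.
    """
    if len(features) == 0:
        raise ValueError("primary_bin: empty feature table")
    pts = features[["gc", "log_coverage"]].to_numpy(dtype=float)
    scaled = scale_features(pts)
    labels = dbscan(scaled, eps=epsilon, min_points=min_points)
    return pd.Series(labels, index=features.index, name="primary_bin")
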