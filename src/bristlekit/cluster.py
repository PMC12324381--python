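"""Deterministic DBSCAN with silhouette-based parameter selection.

Bristle precursor cells are spaced by lateral inhibition but still show
local density differences; DBSCAN turns those differences into clusters,
boundary points and outliers without assuming convex cluster shapes.
This module owns the algorithm end to end so that its tie-breaking is
fully specified:

* the ε-ball is the *closed* disk of radius ``eps`` and a point counts
  itself among its neighbours, so ``min_pts = 1`` makes every point core
  (the inclusive convention of the original DBSCAN formulation);
* clusters are the connected components of the graph on core points with
  an edge where the pairwise distance is ≤ ε, numbered 0..K−1 in order
  of each component's lowest point index;
* a boundary point joins the cluster of the lowest-index core point
  within ε of it (classic DBSCAN leaves this order-dependent; here it is
  pinned down so a labeling is a pure function of the point sequence);
* everything else is an outlier, labelled :data:`OUTLIER`.

Clustering quality is scored by the mean per-point silhouette (the
"pattern silhouette score"), and ``(ε, MinPts)`` are chosen per pattern
by maximising that score over a grid. Distances are Euclidean throughout
and the O(n²) distance matrix is used directly — patterns hold on the
order of 10² points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "OUTLIER",
    "ROLE_CORE",
    "ROLE_BOUNDARY",
    "ROLE_OUTLIER",
    "ClusteringParams",
    "ClusterLabeling",
    "SilhouetteBreakdown",
    "DeterministicDBSCAN",
    "SilhouetteTunedDBSCAN",
    "dbscan",
    "silhouette",
    "pattern_silhouette",
    "optimize_params",
    "default_eps_grid",
    "DEFAULT_MINPTS_GRID",
]

#: Label assigned to points that belong to no cluster.
OUTLIER = -1

# Per-point role codes.
ROLE_OUTLIER = 0
ROLE_BOUNDARY = 1
ROLE_CORE = 2

#: Default MinPts candidates for parameter selection.
DEFAULT_MINPTS_GRID = (3, 4, 5, 6)


@dataclass(frozen=True)
class ClusteringParams:
    """DBSCAN parameters: ε-ball radius (μm) and the core-point threshold."""

    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if not (self.eps > 0):
            raise ValueError(f"eps must be > 0, got {self.eps!r}")
        if not (int(self.min_pts) == self.min_pts and self.min_pts >= 1):
            raise ValueError(f"min_pts must be a positive integer, got {self.min_pts!r}")


@dataclass
class ClusterLabeling:
    """Per-point cluster assignment and role for one parameter pair.

    ``labels[i]`` is the cluster index in ``0..k-1`` or :data:`OUTLIER`;
    ``roles[i]`` is one of the ``ROLE_*`` codes. Cluster indices are
    contiguous and ordered by each cluster's first core point.
    """

    labels: np.ndarray
    roles: np.ndarray
    k: int
    params: ClusteringParams

    def cluster_sizes(self) -> np.ndarray:
        """Occupancy η_i of each cluster (boundary points included)."""
        if self.k == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels[self.labels != OUTLIER], minlength=self.k)

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == OUTLIER))


@dataclass
class SilhouetteBreakdown:
    """Per-point silhouette components.

    ``a`` is the mean distance to the *other* members of the point's own
    cluster, ``b`` the smallest mean distance to any other cluster, and
    ``s = (b − a) / max(a, b)``. Outliers and members of singleton
    clusters have no defined silhouette: they carry ``valid = False``
    and ``s = 0``. No point is valid unless at least two clusters exist.
    """

    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    valid: np.ndarray


def _as_points(points: Sequence | np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D coordinate array")
    return pts


def _distance_matrix(points: np.ndarray) -> np.ndarray:
    n = points.shape[0]
    if n < 2:
        return np.zeros((n, n))
    return squareform(pdist(points))


class DeterministicDBSCAN:
    """DBSCAN clusterer with fully specified, order-deterministic output.

    Parameters
    ----------
    eps : float
        Radius of the closed ε-ball, in the units of the coordinates (μm
        for bristle patterns).
    min_pts : int
        Minimum number of points (the point itself included) inside the
        ε-ball for a point to be core.

    Attributes set by :meth:`fit`
    -----------------------------
    labels_ : (n,) int array — cluster index or :data:`OUTLIER`.
    roles_ : (n,) int array of ``ROLE_*`` codes.
    n_clusters_ : int — number of clusters K.
    labeling_ : :class:`ClusterLabeling` — the bundled result.
    """

    def __init__(self, eps: float = 1.0, min_pts: int = 4):
        self.eps = eps
        self.min_pts = min_pts

    def get_params(self, deep: bool = True) -> dict:
        return {"eps": self.eps, "min_pts": self.min_pts}

    def set_params(self, **params) -> "DeterministicDBSCAN":
        for k, v in params.items():
            if k not in ("eps", "min_pts"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence | np.ndarray, y=None, *, dist: np.ndarray | None = None):
        params = ClusteringParams(eps=float(self.eps), min_pts=int(self.min_pts))
        pts = _as_points(X)
        n = pts.shape[0]
        if n == 0:
            self.labels_ = np.zeros(0, dtype=int)
            self.roles_ = np.zeros(0, dtype=int)
            self.n_clusters_ = 0
            self.labeling_ = ClusterLabeling(self.labels_, self.roles_, 0, params)
            return self
        D = _distance_matrix(pts) if dist is None else dist
        within = D <= params.eps  # closed ball; diagonal True → self counted
        counts = within.sum(axis=1)
        core = counts >= params.min_pts

        labels = np.full(n, OUTLIER, dtype=int)
        roles = np.full(n, ROLE_OUTLIER, dtype=int)
        core_idx = np.flatnonzero(core)
        k = 0
        if core_idx.size:
            sub = within[np.ix_(core_idx, core_idx)]
            # BFS over the boolean core graph; scanning seeds in index
            # order numbers components by their lowest core point
            m = core_idx.size
            comp = np.full(m, -1, dtype=int)
            k = 0
            for seed in range(m):
                if comp[seed] != -1:
                    continue
                comp[seed] = k
                frontier = [seed]
                while frontier:
                    j = frontier.pop()
                    nbrs = np.flatnonzero(sub[j] & (comp == -1))
                    comp[nbrs] = k
                    frontier.extend(nbrs.tolist())
                k += 1
            labels[core_idx] = comp
            roles[core_idx] = ROLE_CORE

            # boundary: non-core within eps of a core point; ties go to
            # the lowest-index core neighbour
            non_core = np.flatnonzero(~core)
            if non_core.size:
                reach = within[np.ix_(non_core, core_idx)]
                has_core = reach.any(axis=1)
                first_core = reach.argmax(axis=1)  # first True = lowest index
                hit = non_core[has_core]
                labels[hit] = labels[core_idx[first_core[has_core]]]
                roles[hit] = ROLE_BOUNDARY

        self.labels_ = labels
        self.roles_ = roles
        self.n_clusters_ = int(k)
        self.labeling_ = ClusterLabeling(labels, roles, int(k), params)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def dbscan(points, params: ClusteringParams, *, dist: np.ndarray | None = None) -> ClusterLabeling:
    """Functional wrapper: cluster *points* under *params*."""
    est = DeterministicDBSCAN(eps=params.eps, min_pts=params.min_pts)
    return est.fit(points, dist=dist).labeling_


def silhouette(
    points,
    labeling: ClusterLabeling,
    *,
    dist: np.ndarray | None = None,
) -> SilhouetteBreakdown:
    """Per-point silhouette components for a labeling.

    For point i in cluster C with |C| = m: a_i averages the distances to
    the other m−1 members; b_i is the minimum over other clusters of the
    mean distance to all their members; s_i = (b_i − a_i)/max(a_i, b_i).
    With coincident points both means can be zero, in which case s_i = 0.
    Outliers and singleton-cluster members are invalid (s = 0), and no
    point is valid when fewer than two clusters exist.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    labels = labeling.labels
    if labels.shape[0] != n:
        raise ValueError("labeling does not match the point sequence")
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    k = labeling.k
    if k < 2 or n == 0:
        return SilhouetteBreakdown(a, b, s, valid)

    D = _distance_matrix(pts) if dist is None else dist
    member = np.zeros((n, k), dtype=float)
    clustered = labels != OUTLIER
    member[np.arange(n)[clustered], labels[clustered]] = 1.0
    sizes = member.sum(axis=0)  # η_i including boundary points
    sums = D @ member  # (n, k): total distance from each point to each cluster

    idx = np.flatnonzero(clustered)
    own = labels[idx]
    ok = sizes[own] >= 2  # singleton-cluster members stay invalid
    idx = idx[ok]
    own = own[ok]
    if idx.size:
        a_v = sums[idx, own] / (sizes[own] - 1)
        mean_to = sums[idx] / sizes  # (m, k) mean distance to each cluster
        mean_to[np.arange(idx.size), own] = np.inf  # mask own cluster
        b_v = mean_to.min(axis=1)
        denom = np.maximum(a_v, b_v)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_v = np.where(denom > 0, (b_v - a_v) / denom, 0.0)
        a[idx] = a_v
        b[idx] = b_v
        s[idx] = s_v
        valid[idx] = True
    return SilhouetteBreakdown(a, b, s, valid)


def pattern_silhouette(
    breakdown: SilhouetteBreakdown,
    *,
    cq_outliers: str = "zero",
) -> float:
    """Pattern silhouette score CQ: the mean per-point silhouette.

    ``cq_outliers="zero"`` (default) averages over every point, counting
    invalid ones (outliers and singleton-cluster members) as 0 — the
    mean over all N points of the pattern; ``"exclude"`` averages over
    valid points only. Returns NaN when no point has a defined
    silhouette — CQ is then missing for the pattern.
    """
    if cq_outliers not in ("exclude", "zero"):
        raise ValueError(f"cq_outliers must be 'exclude' or 'zero', got {cq_outliers!r}")
    if not breakdown.valid.any():
        return float("nan")
    if cq_outliers == "exclude":
        return float(breakdown.s[breakdown.valid].mean())
    return float(breakdown.s.mean())


def default_eps_grid(points, n: int = 15) -> np.ndarray:
    """ε candidates tied to the pattern's own distance scale.

    Log-spaced between the 5th percentile of nearest-neighbour distances
    and 4× their 95th percentile, which brackets both within-cluster
    spacing and between-cluster gaps without any absolute length scale.
    """
    pts = _as_points(points)
    if pts.shape[0] < 2:
        return np.geomspace(1.0, 10.0, n)
    D = _distance_matrix(pts)
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    lo = max(float(np.percentile(nn, 5)), 1e-9)
    hi = max(4.0 * float(np.percentile(nn, 95)), lo * (1.0 + 1e-9))
    return np.geomspace(lo, hi, n)


class SilhouetteTunedDBSCAN:
    """DBSCAN whose (ε, MinPts) maximise the pattern silhouette score.

    Every pair on ``eps_grid × min_pts_grid`` is evaluated. Pairs that
    produce fewer than two clusters (or no point with a defined
    silhouette) are invalid and score −∞. Ties break toward smaller ε,
    then smaller MinPts, so the selection is independent of grid order.
    If every pair is invalid the pair giving the most clusters (ties →
    smaller ε, then MinPts) is returned with ``cq_`` = NaN.

    Parameters default to the scale-free grid of :func:`default_eps_grid`
    and MinPts ∈ {3, 4, 5, 6}.
    """

    def __init__(
        self,
        eps_grid: Sequence[float] | None = None,
        min_pts_grid: Sequence[int] | None = DEFAULT_MINPTS_GRID,
        cq_outliers: str = "zero",
    ):
        self.eps_grid = eps_grid
        self.min_pts_grid = min_pts_grid
        self.cq_outliers = cq_outliers

    def get_params(self, deep: bool = True) -> dict:
        return {
            "eps_grid": self.eps_grid,
            "min_pts_grid": self.min_pts_grid,
            "cq_outliers": self.cq_outliers,
        }

    def set_params(self, **params) -> "SilhouetteTunedDBSCAN":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        pts = _as_points(X)
        eps_grid = (
            default_eps_grid(pts) if self.eps_grid is None
            else np.asarray(list(self.eps_grid), dtype=float)
        )
        minpts_grid = np.asarray(
            list(self.min_pts_grid if self.min_pts_grid is not None else DEFAULT_MINPTS_GRID),
            dtype=int,
        )
        if eps_grid.size == 0 or minpts_grid.size == 0:
            raise ValueError("parameter grids must be non-empty")
        # sorted scan makes the tie-break (smaller eps, then min_pts) a
        # strict-improvement test
        eps_grid = np.sort(eps_grid)
        minpts_grid = np.sort(minpts_grid)

        D = _distance_matrix(pts)
        best_cq = -np.inf
        best: tuple[ClusteringParams, ClusterLabeling] | None = None
        fallback: tuple[int, ClusteringParams, ClusterLabeling] | None = None
        for eps in eps_grid:
            for mp in minpts_grid:
                params = ClusteringParams(eps=float(eps), min_pts=int(mp))
                lab = dbscan(pts, params, dist=D)
                if fallback is None or lab.k > fallback[0]:
                    fallback = (lab.k, params, lab)
                if lab.k < 2:
                    continue
                cq = pattern_silhouette(
                    silhouette(pts, lab, dist=D), cq_outliers=self.cq_outliers
                )
                if np.isnan(cq):
                    continue
                if cq > best_cq:
                    best_cq = cq
                    best = (params, lab)

        if best is None:
            assert fallback is not None
            _, params, lab = fallback
            self.cq_ = float("nan")
        else:
            params, lab = best
            self.cq_ = float(best_cq)
        self.eps_ = params.eps
        self.min_pts_ = params.min_pts
        self.params_ = params
        self.labeling_ = lab
        self.labels_ = lab.labels
        self.n_clusters_ = lab.k
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def optimize_params(
    points,
    eps_grid: Sequence[float] | None = None,
    minpts_grid: Sequence[int] | None = None,
    *,
    cq_outliers: str = "zero",
) -> tuple[ClusteringParams, ClusterLabeling, float]:
    """Functional wrapper around :class:`SilhouetteTunedDBSCAN`."""
    est = SilhouetteTunedDBSCAN(
        eps_grid=eps_grid,
        min_pts_grid=minpts_grid if minpts_grid is not None else DEFAULT_MINPTS_GRID,
        cq_outliers=cq_outliers,
    ).fit(points)
    return est.params_, est.labeling_, est.cq_
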