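"""Global features of a bristle spot pattern.

Five numbers summarise one tissue:

* RSA — relative sensory area, ``n_cells × cell_area / tissue_area``.
  The default single-cell apical area is 24.5 μm² (measured on
  control-White bristle cells at 24 h after pupariation) and is
  overridable per cohort.
* CN — number of DBSCAN clusters at the tissue's optimal (ε, MinPts).
* OP — outlier prevalence, the fraction of points left unclustered.
* CQ — cluster quality, the pattern silhouette score; missing (NaN)
  when no parameter pair yields a valid two-cluster labeling.
* CSV — cluster size variance, ``(1/(K−1)) Σ ((η_i − η̄)/N)²``; the
  N-scaling makes it comparable across patterns of different size.

``PatternFeaturizer`` maps a sequence of patterns to the cohort feature
table used by the statistics and classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cluster import (
    DEFAULT_MINPTS_GRID,
    ClusterLabeling,
    SilhouetteTunedDBSCAN,
)
from .io import FEATURE_TABLE_COLUMNS, PointPattern

__all__ = [
    "DEFAULT_CELL_AREA",
    "FEATURE_NAMES",
    "FeatureVector",
    "compute_rsa",
    "compute_op",
    "compute_csv",
    "compute_features",
    "PatternFeaturizer",
]

#: Mean apical area of a single bristle precursor cell, μm².
DEFAULT_CELL_AREA = 24.5

#: The five global features, in reporting order.
FEATURE_NAMES = ["RSA", "CN", "OP", "CQ", "CSV"]


@dataclass
class FeatureVector:
    """The five global features of one pattern plus bookkeeping fields."""

    rsa: float
    cn: int
    op: float
    cq: float  # NaN when no valid clustering exists
    csv: float
    n_points: int
    eps_opt: float
    minpts_opt: int


def compute_rsa(
    n_cells: int,
    tissue_area: float,
    cell_area: float = DEFAULT_CELL_AREA,
) -> float:
    """Relative sensory area: total sensory area over tissue area."""
    if not (tissue_area > 0):
        raise ValueError(f"tissue_area must be > 0, got {tissue_area!r}")
    if not (cell_area > 0):
        raise ValueError(f"cell_area must be > 0, got {cell_area!r}")
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    return n_cells * cell_area / tissue_area


def compute_op(labeling: ClusterLabeling, n_points: int) -> float:
    """Outlier prevalence: fraction of the pattern's points left unclustered."""
    if n_points < 1:
        raise ValueError("OP is undefined for an empty pattern")
    return labeling.n_outliers / n_points


def compute_csv(
    labeling: ClusterLabeling,
    n_points: int,
    *,
    count_outliers_in_n: bool = True,
) -> float:
    """Cluster size variance, scaled by the pattern's point count.

    With cluster occupancies η_1..η_K and mean η̄, returns
    ``(1/(K−1)) Σ ((η_i − η̄)/N)²``. K ≤ 1 gives 0 by convention — a
    single cluster (or none) has no between-cluster size heterogeneity.
    N defaults to all pattern points including outliers; set
    ``count_outliers_in_n=False`` to scale by clustered points only.
    """
    if n_points < 1:
        raise ValueError("CSV is undefined for an empty pattern")
    k = labeling.k
    if k <= 1:
        return 0.0
    sizes = labeling.cluster_sizes().astype(float)
    n = n_points if count_outliers_in_n else int(sizes.sum())
    dev = (sizes - sizes.mean()) / n
    return float(np.sum(dev**2) / (k - 1))


def compute_features(
    pattern: PointPattern,
    eps_grid: Sequence[float] | None = None,
    minpts_grid: Sequence[int] | None = None,
    cell_area: float = DEFAULT_CELL_AREA,
    *,
    cq_outliers: str = "zero",
    csv_count_outliers: bool = True,
) -> FeatureVector:
    """Optimal clustering plus the five global features for one pattern."""
    n = pattern.n_points
    if n == 0:
        raise ValueError(f"pattern {pattern.pattern_id!r} has no points")
    tuner = SilhouetteTunedDBSCAN(
        eps_grid=eps_grid,
        min_pts_grid=minpts_grid if minpts_grid is not None else DEFAULT_MINPTS_GRID,
        cq_outliers=cq_outliers,
    ).fit(pattern.points)
    lab = tuner.labeling_
    return FeatureVector(
        rsa=compute_rsa(n, pattern.tissue_area, cell_area),
        cn=lab.k,
        op=compute_op(lab, n),
        cq=tuner.cq_,
        csv=compute_csv(lab, n, count_outliers_in_n=csv_count_outliers),
        n_points=n,
        eps_opt=tuner.eps_,
        minpts_opt=tuner.min_pts_,
    )


class PatternFeaturizer:
    """Transformer from point patterns to the cohort feature table.

    ``transform`` accepts an iterable of :class:`PointPattern` and
    returns a DataFrame with one row per pattern and the standard
    feature-table columns. All parameters mirror
    :func:`compute_features`.
    """

    def __init__(
        self,
        eps_grid: Sequence[float] | None = None,
        minpts_grid: Sequence[int] | None = None,
        cell_area: float = DEFAULT_CELL_AREA,
        cq_outliers: str = "zero",
        csv_count_outliers: bool = True,
    ):
        self.eps_grid = eps_grid
        self.minpts_grid = minpts_grid
        self.cell_area = cell_area
        self.cq_outliers = cq_outliers
        self.csv_count_outliers = csv_count_outliers

    def get_params(self, deep: bool = True) -> dict:
        return {
            "eps_grid": self.eps_grid,
            "minpts_grid": self.minpts_grid,
            "cell_area": self.cell_area,
            "cq_outliers": self.cq_outliers,
            "csv_count_outliers": self.csv_count_outliers,
        }

    def set_params(self, **params) -> "PatternFeaturizer":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "PatternFeaturizer":
        return self  # stateless: nothing to learn

    def transform(self, patterns: Iterable[PointPattern]) -> pd.DataFrame:
        rows = []
        for p in patterns:
            fv = compute_features(
                p,
                eps_grid=self.eps_grid,
                minpts_grid=self.minpts_grid,
                cell_area=self.cell_area,
                cq_outliers=self.cq_outliers,
                csv_count_outliers=self.csv_count_outliers,
            )
            rows.append(
                {
                    "pattern_id": p.pattern_id,
                    "group": p.group,
                    "n_points": fv.n_points,
                    "eps_opt": fv.eps_opt,
                    "minpts_opt": fv.minpts_opt,
                    "RSA": fv.rsa,
                    "CN": fv.cn,
                    "OP": fv.op,
                    "CQ": fv.cq,
                    "CSV": fv.csv,
                }
            )
        return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)

    def fit_transform(self, patterns: Iterable[PointPattern], y=None) -> pd.DataFrame:
        return self.fit().transform(patterns)
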