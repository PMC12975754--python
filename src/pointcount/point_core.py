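"""Point-set geometry shared by losses, decoding and evaluation.

Coordinates are 0-based continuous pixel coordinates, origin at the top-left,
x rightward and y downward, with annotations at pixel centers.  A point set is
stored as an (N, 2) float array of (x, y) rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("Point2D coordinates must be finite")


@dataclass
class PointSet:
    """Ordered set of 2-D centroids for one image, as an (N, 2) (x, y) array."""

    points: np.ndarray
    image_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (N, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __iter__(self):
        for x, y in self.points:
            yield Point2D(float(x), float(y))


def as_points(obj) -> np.ndarray:
    """Coerce a PointSet / array-like / list of Point2D to an (N, 2) array."""
    if isinstance(obj, PointSet):
        return obj.points
    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], Point2D):
        return np.array([[p.x, p.y] for p in obj], dtype=float)
    arr = np.asarray(obj, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    return arr.reshape(-1, 2)


@dataclass
class MatchResult:
    """One-to-one assignment between a prediction set and a ground-truth set."""

    pairs: list  # (prediction index, ground-truth index)
    unmatched_pred: list
    unmatched_gt: list
    total_cost: float = 0.0


def pairwise_distances(a, b) -> np.ndarray:
    """Euclidean distance matrix between two point sets, shape (|a|, |b|)."""
    pa, pb = as_points(a), as_points(b)
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        return np.zeros((pa.shape[0], pb.shape[0]))
    return cdist(pa, pb)


def hungarian_match(cost: np.ndarray) -> MatchResult:
    """Minimum-cost one-to-one assignment of size min(rows, cols).

    Rectangular matrices are handled by leaving the |rows - cols| surplus
    items unmatched.  Only ``total_cost`` is contractual when ties exist.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if np.isnan(cost).any():
        raise ValueError("cost matrix contains NaN")
    if cost.shape[0] == 0 or cost.shape[1] == 0:
        return MatchResult([], list(range(cost.shape[0])), list(range(cost.shape[1])), 0.0)
    rows, cols = linear_sum_assignment(cost)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    total = float(cost[rows, cols].sum())
    unmatched_pred = sorted(set(range(cost.shape[0])) - set(rows.tolist()))
    unmatched_gt = sorted(set(range(cost.shape[1])) - set(cols.tolist()))
    return MatchResult(pairs, unmatched_pred, unmatched_gt, total)


# Density stratification: quantile-based seed-count strata used for
# stratified evaluation (sparse <= 37 < medium <= 63 < dense).

@dataclass(frozen=True)
class DensityStratum:
    label: str
    lower: int
    upper: int  # inclusive; upper bound of Dense is unbounded


SPARSE = DensityStratum("Sparse", 0, 37)
MEDIUM = DensityStratum("Medium", 38, 63)
DENSE = DensityStratum("Dense", 64, np.iinfo(np.int64).max)
STRATA = (SPARSE, MEDIUM, DENSE)


def density_stratum(count: int) -> str:
    """Stratum label for a per-image seed count."""
    count = int(count)
    if count < 0:
        raise ValueError("count must be nonnegative")
    for s in STRATA:
        if s.lower <= count <= s.upper:
            return s.label
    raise AssertionError("strata must partition the nonnegative integers")
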