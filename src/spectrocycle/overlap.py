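"""Standard-deviation ellipses and their intersection-over-union statistic.

Each 2-D cluster is summarised by the Mahalanobis-distance-1 contour of its
population covariance (the "1-SD ellipse", ~39% of the mass for a Gaussian;
a scale factor k generalises to k-SD contours).  The overlap of two
clusters is quantified by IoU = 100 * intersection / union, ranging from 0%
for fully separated ellipses to 100% for coincident ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SDEllipse", "IoUResult", "fit_sd_ellipse", "ellipse_area",
           "intersection_area", "iou"]


@dataclass(frozen=True)
class SDEllipse:
    """Ellipse {z : (z - centre)' cov^-1 (z - centre) <= 1}."""

    centre: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2) symmetric positive definite

    def __post_init__(self) -> None:
        c = np.asarray(self.centre, dtype=float).reshape(2)
        cov = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        evals = np.linalg.eigvalsh(cov)
        if np.any(evals <= 1e-12):
            raise ValueError("collinear cluster: degenerate covariance")
        object.__setattr__(self, "centre", c)
        object.__setattr__(self, "covariance", cov)

    @property
    def area(self) -> float:
        return math.pi * math.sqrt(float(np.linalg.det(self.covariance)))

    @property
    def max_radius(self) -> float:
        """Largest semi-axis (square root of the leading eigenvalue)."""
        return math.sqrt(float(np.linalg.eigvalsh(self.covariance)[-1]))

    def x_extent(self) -> tuple[float, float]:
        r = math.sqrt(self.covariance[0, 0])
        return self.centre[0] - r, self.centre[0] + r

    def y_interval(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """y-range [lo, hi] of the ellipse at abscissae x (NaN outside)."""
        a = np.linalg.inv(self.covariance)
        dx = np.asarray(x, dtype=float) - self.centre[0]
        # a11 y'^2 + 2 a01 dx y' + a00 dx^2 - 1 <= 0 with y' = y - cy
        disc = (a[0, 1] * dx) ** 2 - a[1, 1] * (a[0, 0] * dx**2 - 1.0)
        with np.errstate(invalid="ignore"):
            root = np.sqrt(disc)
        mid = -a[0, 1] * dx / a[1, 1]
        lo = self.centre[1] + mid - root / a[1, 1]
        hi = self.centre[1] + mid + root / a[1, 1]
        lo[disc < 0] = np.nan
        hi[disc < 0] = np.nan
        return lo, hi


@dataclass(frozen=True)
class IoUResult:
    intersection_area: float
    union_area: float
    iou_percent: float


def fit_sd_ellipse(points: np.ndarray, scale: float = 1.0) -> SDEllipse:
    """Fit the k-SD ellipse of a point cloud (centre = mean, population cov).

    ``scale`` k draws the Mahalanobis-distance-k contour (default 1).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    centre = pts.mean(axis=0)
    d = pts - centre
    cov = d.T @ d / pts.shape[0]
    return SDEllipse(centre, cov * scale**2)


def ellipse_area(e: SDEllipse) -> float:
    return e.area


def intersection_area(e1: SDEllipse, e2: SDEllipse, rel_tol: float = 1e-4) -> float:
    """Area of the set intersection of two ellipses.

    Integrates the overlap of the two per-abscissa y-intervals on a
    refined x grid (midpoint rule, grid doubled until the estimate moves by
    less than ``rel_tol`` relative).  Symmetric in its arguments.
    """
    min_area = min(e1.area, e2.area)
    if (np.array_equal(e1.centre, e2.centre)
            and np.array_equal(e1.covariance, e2.covariance)):
        return min_area
    lo1, hi1 = e1.x_extent()
    lo2, hi2 = e2.x_extent()
    lo, hi = max(lo1, lo2), min(hi1, hi2)
    if hi <= lo:
        return 0.0
    # quick reject on centre distance
    if np.linalg.norm(e1.centre - e2.centre) > e1.max_radius + e2.max_radius:
        return 0.0

    prev = None
    n = 512
    while True:
        x = lo + (hi - lo) * (np.arange(n) + 0.5) / n
        lo_a, hi_a = e1.y_interval(x)
        lo_b, hi_b = e2.y_interval(x)
        overlap = np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b)
        overlap = np.where(np.isnan(overlap), 0.0, np.clip(overlap, 0.0, None))
        est = min(float(overlap.sum() * (hi - lo) / n), min_area)
        if prev is not None:
            if est == prev == 0.0:
                return 0.0
            if abs(est - prev) <= rel_tol * max(abs(est), 1e-300):
                return est
        if n >= 2**17:
            return est
        prev = est
        n *= 2


def iou(e1: SDEllipse, e2: SDEllipse, rel_tol: float = 1e-4) -> IoUResult:
    """Intersection-over-union percentage of two SD ellipses."""
    inter = intersection_area(e1, e2, rel_tol)
    union = e1.area + e2.area - inter
    return IoUResult(inter, union, 100.0 * inter / union)
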