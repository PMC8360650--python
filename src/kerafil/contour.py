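"""Contours: ordered 2D point lists with arc-length parameterization.

A :class:`Contour` is unit-agnostic — persistence analysis uses nm,
segment picking uses pixels — callers keep track of the unit.  Points are
(x, y) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate

__all__ = ["Contour", "resample_spline", "tangent_angles"]


@dataclass
class Contour:
    """Ordered 2D points with cumulative arc length ``arc_s``."""

    points: np.ndarray  # (N, 2) of (x, y)
    arc_s: np.ndarray   # (N,) cumulative arc length, arc_s[0] == 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.arc_s = np.asarray(self.arc_s, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("Contour points must be an (N, 2) array")
        if self.arc_s.shape != (len(self.points),):
            raise ValueError("arc_s length must match points")
        if len(self.points) >= 2 and not np.all(np.diff(self.arc_s) > 0):
            raise ValueError("arc_s must be strictly increasing")

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Contour":
        points = np.asarray(points, dtype=np.float64)
        d = np.linalg.norm(np.diff(points, axis=0), axis=1)
        return cls(points, np.concatenate([[0.0], np.cumsum(d)]))

    @property
    def length(self) -> float:
        return float(self.arc_s[-1])

    def __len__(self) -> int:
        return len(self.points)

    def reversed(self) -> "Contour":
        return Contour.from_points(self.points[::-1])

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.points + np.array([dx, dy]), self.arc_s.copy())

    def rotated(self, angle_rad: float) -> "Contour":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return Contour(self.points @ rot.T, self.arc_s.copy())


def _is_collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    if len(points) < 3:
        return True
    v = points[-1] - points[0]
    n = np.linalg.norm(v)
    if n == 0:
        return False
    v = v / n
    rel = points - points[0]
    cross = np.abs(rel[:, 0] * v[1] - rel[:, 1] * v[0])
    return bool(np.max(cross) < tol * max(n, 1.0))


def resample_spline(points: np.ndarray, step: float, smoothing: float = 0.0
                    ) -> Contour:
    """Fit a (smoothing) spline through traced points and resample it at a
    uniform arc-length step.

    Parameters
    ----------
    points : (N, 2) array, N >= 3 (N >= 2 for exactly collinear traces)
    step : resampling interval in the unit of ``points``
    smoothing : spline smoothing factor (0 = interpolating spline),
        passed to the parametric spline fit
    """
    points = np.asarray(points, dtype=np.float64)
    if step <= 0:
        raise ValueError("step must be positive")
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("degenerate contour: repeated consecutive points")

    if len(points) == 2 or _is_collinear(points):
        # a straight trace needs no spline; sample the chord directly
        total = float(np.sum(seg))
        n = max(int(np.floor(total / step)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)
        direction = (points[-1] - points[0]) / np.linalg.norm(points[-1] - points[0])
        pts = points[0] + np.outer(t * total, direction)
        return Contour.from_points(pts)

    k = min(3, len(points) - 1)
    u_chord = np.concatenate([[0.0], np.cumsum(seg)]) / np.sum(seg)
    tck, _ = interpolate.splprep(points.T, u=u_chord, s=smoothing, k=k)

    # dense evaluation to build the arc-length table of the fitted spline
    u_dense = np.linspace(0.0, 1.0, max(20 * len(points), 1000))
    xy = np.column_stack(interpolate.splev(u_dense, tck))
    s_dense = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))]
    )
    total = s_dense[-1]
    n = int(np.floor(total / step)) + 1
    s_targets = np.arange(n) * step
    u_targets = np.interp(s_targets, s_dense, u_dense)
    pts = np.column_stack(interpolate.splev(u_targets, tck))
    return Contour.from_points(pts)


def tangent_angles(contour: Contour) -> np.ndarray:
    """Unwrapped tangent direction (radians) at each contour point.

    Central differences in the interior, one-sided at the ends; the result
    is unwrapped so that a smooth turn accumulates angle without 2π jumps.
    """
    pts = contour.points
    if len(pts) < 3:
        raise ValueError("need at least 3 points for tangent estimation")
    d = np.empty_like(pts)
    d[1:-1] = pts[2:] - pts[:-2]
    d[0] = pts[1] - pts[0]
    d[-1] = pts[-1] - pts[-2]
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    # one-sided endpoint differences lag by half a step; linear
    # extrapolation restores the full turn of, e.g., an exact quarter arc
    if len(theta) >= 3:
        theta[0] = 2 * theta[1] - theta[2]
        theta[-1] = 2 * theta[-2] - theta[-3]
    return theta
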