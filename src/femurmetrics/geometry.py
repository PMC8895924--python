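"""Pure 3D geometric primitives.

Every primitive here is deterministic and has a brute-force or closed-form
oracle in the test suite.  Nothing in this module knows about femurs except
:func:`mirror_x`, which operates on a whole specimen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .constants import (
    COLLINEARITY_AREA_TOL_MM2,
    PARALLEL_TOL_RAD,
    PROJECTION_EPS_MM,
)
from .errors import CollinearityError, DegeneracyError
from .model import Axis, FemurSpecimen

__all__ = [
    "SphereFit",
    "SkewResult",
    "MaxDeviation",
    "Circumcircle",
    "fit_sphere",
    "fit_line",
    "skew_distance",
    "angle_between",
    "projected_angle",
    "circumradius",
    "max_deviation_point",
    "mirror_x",
    "rotate_about",
]


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass
class SkewResult:
    distance: float
    point_on_line1: np.ndarray
    point_on_line2: np.ndarray
    parallel_flag: bool


@dataclass
class MaxDeviation:
    index: int
    point: np.ndarray
    deviation: float


@dataclass
class Circumcircle:
    radius: float
    center: np.ndarray


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n < PROJECTION_EPS_MM:
        raise DegeneracyError(f"zero-length {what}")
    return v / n


def fit_sphere(points) -> SphereFit:
    """Least-squares algebraic sphere fit (linear in center and |c|^2 - r^2).

    Exact for noise-free spherical samples.  Raises
    :class:`DegeneracyError` for coplanar or otherwise rank-deficient input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 5:
        raise DegeneracyError("fit_sphere needs at least 5 points of shape (n, 3)")
    # shift to centroid for conditioning
    mu = pts.mean(axis=0)
    q = pts - mu
    A = np.column_stack([2.0 * q, np.ones(len(q))])
    b = np.einsum("ij,ij->i", q, q)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegeneracyError("points are coplanar or degenerate; sphere fit undefined")
    center = sol[:3] + mu
    r2 = sol[3] + float(sol[:3] @ sol[:3])
    if r2 <= 0:
        raise DegeneracyError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(center=center, radius=radius, rms_residual=float(np.sqrt(np.mean(resid**2))))


def fit_line(points) -> Axis:
    """Total-least-squares 3D line: first principal direction through the centroid.

    The direction sign points from the LAST input point toward the FIRST,
    so that proximal->distal ordered stations yield a proximally oriented axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise DegeneracyError("fit_line needs at least 2 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    if float(np.abs(q).max(initial=0.0)) < PROJECTION_EPS_MM:
        raise DegeneracyError("all points coincide; line fit undefined")
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    direction = vt[0]
    if float(direction @ (pts[0] - pts[-1])) < 0:
        direction = -direction
    return Axis(point=centroid, direction=direction / np.linalg.norm(direction))


def skew_distance(a: Axis, b: Axis, parallel_tol: float = PARALLEL_TOL_RAD) -> SkewResult:
    """Common-perpendicular distance and mutually closest points of two lines.

    If the angle between directions is below ``parallel_tol`` the lines are
    treated as parallel: the distance is the perpendicular distance between
    them and the reported points are ``a.point`` and its projection onto b.
    """
    da, db = a.direction, b.direction
    cross = np.cross(da, db)
    sin_angle = float(np.linalg.norm(cross))  # both directions are unit
    w0 = a.point - b.point
    if min(sin_angle, 1.0) < np.sin(parallel_tol) or sin_angle == 0.0:
        perp = w0 - float(w0 @ db) * db
        proj = b.point + float((a.point - b.point) @ db) * db
        return SkewResult(
            distance=float(np.linalg.norm(perp)),
            point_on_line1=a.point.copy(),
            point_on_line2=proj,
            parallel_flag=True,
        )
    d_ab = float(da @ db)
    d_aw = float(da @ w0)
    d_bw = float(db @ w0)
    denom = 1.0 - d_ab * d_ab
    s = (d_ab * d_bw - d_aw) / denom
    t = (d_bw - d_ab * d_aw) / denom
    p1 = a.point + s * da
    p2 = b.point + t * db
    return SkewResult(
        distance=float(np.linalg.norm(p1 - p2)),
        point_on_line1=p1,
        point_on_line2=p2,
        parallel_flag=False,
    )


def angle_between(u, v) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    un = _unit(u, "vector u")
    vn = _unit(v, "vector v")
    return float(np.degrees(np.arccos(np.clip(un @ vn, -1.0, 1.0))))


def projected_angle(u, v, plane_normal, signed_about) -> float:
    """Signed angle from v to u after projecting both onto the plane ⟂ plane_normal.

    Sign follows the right-hand rule about ``signed_about``; result in
    (-180, 180] degrees.  Raises :class:`DegeneracyError` if either
    projection is shorter than ``PROJECTION_EPS_MM``.
    """
    n = _unit(plane_normal, "plane normal")
    s = _unit(signed_about, "sign axis")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    up = u - float(u @ n) * n
    vp = v - float(v @ n) * n
    if np.linalg.norm(up) < PROJECTION_EPS_MM or np.linalg.norm(vp) < PROJECTION_EPS_MM:
        raise DegeneracyError("vector projection onto plane is degenerate")
    c = np.cross(vp, up)
    ang = float(np.degrees(np.arctan2(np.linalg.norm(c), float(vp @ up))))
    if float(c @ s) < 0:
        ang = -ang
    return ang


def circumradius(p1, p2, p3) -> Circumcircle:
    """Radius and center of the circle through three non-collinear 3D points.

    radius = |p1p2| |p2p3| |p1p3| / (4 * area).  Raises
    :class:`CollinearityError` when the triangle area is below tolerance
    (curvature unresolvable / radius effectively infinite).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = float(np.linalg.norm(p2 - p3))  # side opposite p1
    b = float(np.linalg.norm(p1 - p3))  # side opposite p2
    c = float(np.linalg.norm(p1 - p2))  # side opposite p3
    area = 0.5 * float(np.linalg.norm(np.cross(p2 - p1, p3 - p1)))
    if area <= COLLINEARITY_AREA_TOL_MM2:
        raise CollinearityError("points are collinear; circumradius undefined")
    radius = (a * b * c) / (4.0 * area)
    # barycentric circumcenter
    wa = a * a * (b * b + c * c - a * a)
    wb = b * b * (c * c + a * a - b * b)
    wc = c * c * (a * a + b * b - c * c)
    center = (wa * p1 + wb * p2 + wc * p3) / (wa + wb + wc)
    return Circumcircle(radius=radius, center=center)


def max_deviation_point(points, chord_start, chord_end) -> MaxDeviation:
    """Input point with maximal perpendicular distance to the chord line.

    Ties are broken by the smallest index (noisy arcs can tie).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegeneracyError("max_deviation_point needs at least 3 points")
    start = np.asarray(chord_start, dtype=float)
    d = _unit(np.asarray(chord_end, dtype=float) - start, "chord")
    rel = pts - start
    dev = np.linalg.norm(np.cross(rel, d), axis=1)
    idx = int(np.argmax(dev))  # argmax returns the first maximal index
    return MaxDeviation(index=idx, point=pts[idx].copy(), deviation=float(dev[idx]))


def rotate_about(vec, axis_unit, angle_rad) -> np.ndarray:
    """Rodrigues rotation of ``vec`` about the unit vector ``axis_unit``."""
    v = np.asarray(vec, dtype=float)
    k = np.asarray(axis_unit, dtype=float)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(k, v) * s + k * float(k @ v) * (1.0 - c)


def mirror_x(specimen: FemurSpecimen) -> FemurSpecimen:
    """Negate all x-coordinates and flip the side label (L <-> R)."""
    def flip(arr: np.ndarray) -> np.ndarray:
        out = np.array(arr, dtype=float, copy=True)
        out[..., 0] = -out[..., 0]
        return out

    return dataclasses.replace(
        specimen,
        side="L" if specimen.side == "R" else "R",
        head_surface=flip(specimen.head_surface),
        neck_station_centroids=flip(specimen.neck_station_centroids),
        canal_centroids=flip(specimen.canal_centroids),
        gt_tip=flip(specimen.gt_tip),
        neck_lateral_entry=flip(specimen.neck_lateral_entry),
        dicn=flip(specimen.dicn),
        condyle_post_medial=flip(specimen.condyle_post_medial),
        condyle_post_lateral=flip(specimen.condyle_post_lateral),
    )
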