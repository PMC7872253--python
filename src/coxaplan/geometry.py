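"""Coordinate-free geometric primitives and least-squares fitting.

All coordinates live in a right-handed patient-based frame, in millimetres.
Angles are returned in degrees; internal math is in radians.  These
primitives are the shared substrate for osteotomy planning (planes through
anatomic landmarks), morphometry (best-fit sphere for the femoral head,
best-fit cylinder axis for the diaphysis) and plan/outcome comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Plane",
    "Line",
    "Sphere",
    "DegenerateInputError",
    "plane_from_points",
    "fit_sphere",
    "fit_axis",
    "closest_approach",
    "projected_angle",
    "unit",
]

_UNIT_TOL = 1e-9


class DegenerateInputError(ValueError):
    """Raised when input geometry is degenerate for the requested operation."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


def unit(v) -> np.ndarray:
    """Return v normalized to unit length; raise on (near-)zero vectors."""
    v = _as_point(v)
    n = np.linalg.norm(v)
    if n < _UNIT_TOL:
        raise DegenerateInputError("cannot normalize a near-zero vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_point(self.point))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, p) -> np.ndarray:
        """Signed distance(s) of point(s) ``p``; positive on the normal side."""
        p = np.asarray(p, dtype=float)
        return (p - self.point) @ self.normal

    def contains(self, p, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.signed_distance(p)) < tol))


@dataclass(frozen=True)
class Line:
    """Infinite line given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_point(self.point))
        object.__setattr__(self, "direction", unit(self.direction))

    def at(self, t: float) -> np.ndarray:
        return self.point + np.asarray(t)[..., None] * self.direction if np.ndim(t) else self.point + t * self.direction

    def distance_to_point(self, p) -> float:
        p = _as_point(p)
        d = p - self.point
        return float(np.linalg.norm(d - (d @ self.direction) * self.direction))


@dataclass(frozen=True)
class Sphere:
    """Sphere with center (mm) and radius (mm > 0)."""

    center: np.ndarray
    radius: float
    rms_residual: float = field(default=0.0, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center))
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three points; normal by right-hand rule on (p2−p1, p3−p1).

    Collinearity is tested against ``1e-8 ×`` the maximum pairwise distance.
    """
    p1, p2, p3 = _as_point(p1), _as_point(p2), _as_point(p3)
    pts = np.stack([p1, p2, p3])
    scale = max(
        np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), np.linalg.norm(p3 - p2)
    )
    if scale == 0.0:
        raise DegenerateInputError(f"duplicate points: {pts.tolist()}")
    n = np.cross(p2 - p1, p3 - p1)
    if np.linalg.norm(n) < 1e-8 * scale**2:
        raise DegenerateInputError(
            f"collinear or duplicate points, cannot define a plane: {pts.tolist()}"
        )
    return Plane(point=p1, normal=n / np.linalg.norm(n))


def _algebraic_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    # linear least squares on |p|^2 = 2 c·p + (r^2 - |c|^2)
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateInputError("algebraic sphere fit collapsed (r^2 <= 0)")
    return center, float(np.sqrt(r2))


def fit_sphere(points, *, geometric: bool = True, max_iter: int = 100,
               tol: float = 1e-10) -> Sphere:
    """Best-fit sphere to ≥ 4 non-coplanar points.

    Algebraic (linear) initialization, optionally refined by orthogonal-distance
    (geometric) least squares, which is the default criterion.  The RMS of
    orthogonal residuals is reported on the result.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise DegenerateInputError(f"sphere fit needs >= 4 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateInputError("points are coplanar; sphere is not determined")

    center, radius = _algebraic_sphere(pts)
    if geometric:
        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        res = least_squares(
            resid, np.r_[center, radius], method="lm",
            max_nfev=max_iter * 5, xtol=tol, ftol=tol, gtol=tol,
        )
        center, radius = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return Sphere(center=center, radius=abs(radius), rms_residual=rms)


def fit_axis(points, *, proximal_hint=None) -> Line:
    """Central axis of an elongated point cloud (best-fit cylinder axis).

    PCA through the centroid initializes the axis; a least-squares refinement
    then minimizes the spread of radial distances about their mean (the
    orthogonal cylinder criterion with the radius profiled out).  The cloud
    must be dominantly elongated: largest principal extent at least twice the
    second largest, otherwise the axis is not meaningful.

    Direction sign: along ``proximal_hint`` when given; otherwise positive dot
    with +z, ties broken toward +x.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 6:
        raise DegenerateInputError(f"axis fit needs >= 6 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # principal extents via SVD of the centered cloud
    u_, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 2.0 * s[1]:
        raise DegenerateInputError(
            f"point cloud not elongated enough for an axis "
            f"(anisotropy ratio {s[0] / s[1]:.2f} < 2)"
        )
    d0 = vt[0]
    e1 = np.cross(d0, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(d0, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d0, e1)

    def resid(x):
        # direction tilted by (a, b); anchor point offset in the normal plane
        a, b, ox, oy = x
        d = _tilt(d0, a, b)
        rel = centered - (ox * e1 + oy * e2)
        r = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
        return r - r.mean()

    res = least_squares(resid, np.zeros(4), method="lm", xtol=1e-14, ftol=1e-14)
    d = _tilt(d0, *res.x[:2])
    centroid = centroid + res.x[2] * e1 + res.x[3] * e2

    if proximal_hint is not None:
        if d @ _as_point(proximal_hint) < 0:
            d = -d
    else:
        if d[2] < 0 or (d[2] == 0 and d[0] < 0):
            d = -d
    return Line(point=centroid, direction=d)


def _tilt(d0: np.ndarray, a: float, b: float) -> np.ndarray:
    """Unit vector obtained by tilting d0 by small angles along two orthogonals."""
    e1 = np.cross(d0, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(d0, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d0, e1)
    v = d0 + a * e1 + b * e2
    return v / np.linalg.norm(v)


class ParallelLinesError(DegenerateInputError):
    pass


def closest_approach(a: Line, b: Line) -> tuple[np.ndarray, np.ndarray, float]:
    """Closest points between two non-parallel lines and their distance.

    Returns ``(point_on_a, point_on_b, distance)``; distance is zero iff the
    lines intersect.
    """
    da, db = a.direction, b.direction
    cross = np.cross(da, db)
    denom = cross @ cross
    if np.sqrt(denom) < 1e-9:
        raise ParallelLinesError("lines are parallel; no unique closest approach")
    w = b.point - a.point
    ta = np.cross(w, db) @ cross / denom
    tb = np.cross(w, da) @ cross / denom
    pa = a.point + ta * da
    pb = b.point + tb * db
    return pa, pb, float(np.linalg.norm(pb - pa))


def projected_angle(v, ref, plane_normal) -> float:
    """Signed angle in degrees from ``ref`` to ``v`` measured in the plane.

    Both vectors are projected onto the plane with unit normal
    ``plane_normal``; the sign follows the right-hand rule about that normal.
    Result lies in (−180, 180].
    """
    n = unit(plane_normal)
    v = _as_point(v)
    ref = _as_point(ref)
    vp = v - (v @ n) * n
    rp = ref - (ref @ n) * n
    if np.linalg.norm(vp) < 1e-9 or np.linalg.norm(rp) < 1e-9:
        raise DegenerateInputError(
            "vector is (near-)parallel to the plane normal; projected angle undefined"
        )
    ang = np.degrees(np.arctan2(np.cross(rp, vp) @ n, rp @ vp))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)
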