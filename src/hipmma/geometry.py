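"""Low-level 3D vector geometry for moment-arm analysis.

Everything here operates on plain ``numpy`` arrays of shape ``(3,)`` (or
``(n, 3)`` for point clouds), in millimetres.  Angles cross the public
interface in degrees and are converted to radians internally.

The module provides the four geometric primitives the rest of the package
is built from:

* least-squares sphere fitting (joint-center estimation from femoral-head
  surface samples),
* nearest point on a segment or infinite line (the moment-arm query),
* Rodrigues rotation about an arbitrary axis (rigid joint posing),
* projection of a vector onto a plane (flexion--extension projection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Sphere",
    "RigidTransform",
    "fit_sphere",
    "nearest_point_on_segment",
    "closest_point_on_triangles",
    "rotate_about_axis",
    "rotation_about_axis_matrix",
    "project_vector_onto_plane",
    "unit",
]

#: tolerance used for orthonormality / unit-norm invariants
_UNIT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when an input configuration has no well-defined answer.

    Examples: fewer than four or coplanar points passed to the sphere fit,
    or a zero-length segment passed to the nearest-point query.
    """


def _as_point(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must have shape (3,), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite coordinates: {a}")
    return a


def unit(v) -> np.ndarray:
    """Return ``v`` scaled to unit Euclidean norm.

    Raises
    ------
    DegenerateGeometryError
        If ``v`` has (numerically) zero length.
    """
    a = _as_point(v, "vector")
    n = float(np.linalg.norm(a))
    if n < 1e-12:
        raise DegenerateGeometryError("cannot normalise a zero-length vector")
    return a / n


@dataclass(frozen=True)
class Sphere:
    """A sphere in model space: ``center`` (mm) and ``radius`` (mm, > 0)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center, "center"))
        if not (self.radius > 0 and np.isfinite(self.radius)):
            raise ValueError(f"sphere radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t``.

    ``rotation`` must be orthonormal with determinant +1 (no reflections:
    anatomy is chiral).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = _as_point(self.translation, "translation")
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points) -> np.ndarray:
        """Apply the transform to one point ``(3,)`` or a stack ``(n, 3)``."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def fit_sphere(points) -> Sphere:
    """Fit a sphere to >= 4 points by linear (algebraic) least squares.

    Minimises ``sum_i (|p_i - c|^2 - r^2)^2``, which is linear in the
    unknowns ``(2c, r^2 - |c|^2)``: each point contributes one row of the
    overdetermined system ``2 p_i . c + k = |p_i|^2``.  For points lying
    exactly on a sphere the fit is exact to machine precision; under
    isotropic noise it is a close, initialisation-free approximation to the
    geometric (orthogonal-distance) fit.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 4 points or a coplanar/degenerate configuration
        (rank-deficient normal system), where center and radius are not
        identifiable.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"points must have shape (n, 3), got {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValueError("points contain non-finite coordinates")
    n = P.shape[0]
    if n < 4:
        raise DegenerateGeometryError(f"sphere fit needs >= 4 points, got {n}")

    # Shift to the centroid for conditioning; the fit is translation-equivariant.
    mean = P.mean(axis=0)
    Q = P - mean
    A = np.hstack([2.0 * Q, np.ones((n, 1))])
    b = np.einsum("ij,ij->i", Q, Q)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "degenerate point configuration (coplanar or coincident): "
            "sphere parameters are not identifiable"
        )
    c_local, k = sol[:3], sol[3]
    r_sq = k + float(c_local @ c_local)
    if r_sq <= 0:
        raise DegenerateGeometryError("sphere fit collapsed to non-positive radius")
    return Sphere(center=c_local + mean, radius=float(np.sqrt(r_sq)))


def nearest_point_on_segment(a, b, q, clamp: bool = True):
    """Nearest point to ``q`` on the segment ``a``--``b`` (or its line).

    With ``clamp=True`` (default) the answer is constrained to the segment,
    mirroring a nearest-point-on-curve query against a finite muscle line of
    action; with ``clamp=False`` the infinite line through ``a`` and ``b``
    is used, which is the textbook perpendicular moment-arm distance.

    Returns
    -------
    (point, distance)
        The closest point (mm) and its Euclidean distance to ``q`` (mm).
    """
    a = _as_point(a, "a")
    b = _as_point(b, "b")
    q = _as_point(q, "q")
    d = b - a
    dd = float(d @ d)
    if dd < 1e-24:
        raise DegenerateGeometryError("segment endpoints coincide")
    t = float((q - a) @ d) / dd
    if clamp:
        t = min(1.0, max(0.0, t))
    p = a + t * d
    return p, float(np.linalg.norm(q - p))


def rotation_about_axis_matrix(axis_dir, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (unit) axis direction, in degrees."""
    n = unit(axis_dir)
    th = np.deg2rad(angle_deg)
    K = np.array(
        [
            [0.0, -n[2], n[1]],
            [n[2], 0.0, -n[0]],
            [-n[1], n[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)


def rotate_about_axis(p, axis_point, axis_dir, angle_deg: float) -> np.ndarray:
    """Rotate point(s) ``p`` about the axis through ``axis_point`` along
    ``axis_dir`` by ``angle_deg`` degrees (right-hand rule).

    A zero angle returns the input bitwise unchanged, so the reference pose
    of a sweep is exactly the stored geometry.
    """
    c = _as_point(axis_point, "axis_point")
    pts = np.asarray(p, dtype=float)
    if angle_deg == 0.0:
        return pts.copy()
    R = rotation_about_axis_matrix(axis_dir, angle_deg)
    return (pts - c) @ R.T + c


def axis_rotation_transform(axis_point, axis_dir, angle_deg: float) -> RigidTransform:
    """The :class:`RigidTransform` equivalent of :func:`rotate_about_axis`."""
    c = _as_point(axis_point, "axis_point")
    R = rotation_about_axis_matrix(axis_dir, angle_deg)
    return RigidTransform(rotation=R, translation=c - R @ c)


def closest_point_on_triangles(triangles: np.ndarray, q) -> Tuple[np.ndarray, float]:
    """Closest point to ``q`` over a stack of triangles ``(n, 3, 3)``.

    Vectorised barycentric-region clamping (exact, no spatial index); at the
    mesh sizes used here a brute-force scan over all triangles is fast.
    Returns the closest point and its distance.
    """
    tri = np.asarray(triangles, dtype=float)
    if tri.ndim != 3 or tri.shape[1:] != (3, 3):
        raise ValueError(f"triangles must have shape (n, 3, 3), got {tri.shape}")
    q = _as_point(q, "q")

    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, aq = b - a, c - a, q - a
    d1 = np.einsum("ij,ij->i", ab, aq)
    d2 = np.einsum("ij,ij->i", ac, aq)
    bq = q - b
    d3 = np.einsum("ij,ij->i", ab, bq)
    d4 = np.einsum("ij,ij->i", ac, bq)
    cq = q - c
    d5 = np.einsum("ij,ij->i", ab, cq)
    d6 = np.einsum("ij,ij->i", ac, cq)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        # interior point via barycentric coordinates
        denom = va + vb + vc
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
        p = a + v[:, None] * ab + w[:, None] * ac
        # edge AB
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0.0, 1.0)
        # edge AC
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0.0, 1.0)
        # edge BC
        num_bc = d4 - d3
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.clip(np.where(den_bc != 0, num_bc / den_bc, 0.0), 0.0, 1.0)

    # region tests, following the standard closest-point-on-triangle cases
    p = np.where((d1 <= 0)[:, None] & (d2 <= 0)[:, None], a, p)
    p = np.where((d3 >= 0)[:, None] & (d4 <= d3)[:, None], b, p)
    p = np.where((d6 >= 0)[:, None] & (d5 <= d6)[:, None], c, p)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    p = np.where(on_ab[:, None], a + t_ab[:, None] * ab, p)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    p = np.where(on_ac[:, None], a + t_ac[:, None] * ac, p)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    p = np.where(on_bc[:, None], b + t_bc[:, None] * (c - b), p)

    d = np.linalg.norm(p - q, axis=1)
    k = int(np.argmin(d))
    return p[k], float(d[k])


def project_vector_onto_plane(v, normal):
    """Remove the component of ``v`` along the plane normal.

    Returns the in-plane vector ``v - (v . n) n`` and its norm.  Projection
    is idempotent and never increases the norm.
    """
    a = _as_point(v, "vector")
    n = unit(normal)
    w = a - (a @ n) * n
    return w, float(np.linalg.norm(w))
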