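"""Least-squares geometric primitives for 3D morphometry.

Planes, 3D lines and spheres fitted to point clouds (coordinates in mm),
plus the projection, signed-angle and spherical-cap helpers the anatomical
measurements are assembled from.

Fitting conventions
-------------------
* Plane: total least squares — the normal is the direction of minimum
  total squared orthogonal distance (smallest principal direction of the
  centered points), plane anchored at the centroid.
* Line: total least squares — direction of maximum variance (largest
  principal direction), anchored at the centroid.
* Sphere: algebraic (linearized) least squares followed by a damped
  Gauss-Newton refinement of the geometric residuals ``|p - c| - r``.
  Steps are only accepted when they reduce the residual, so the refined
  fit is never worse than the algebraic seed.

Eigenvector signs are arbitrary, so fitted normals/directions are flipped
deterministically: the largest-magnitude component is made positive.
Anatomical orientation (lateral/medial, anterior/posterior) is imposed
later by the frame builder, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Plane",
    "Line3",
    "Sphere",
    "SphereFitDiagnostics",
    "fit_plane_least_squares",
    "fit_line_least_squares",
    "fit_sphere",
    "fit_sphere_detailed",
    "spherical_cap_volume_fraction",
    "project_onto_plane",
    "signed_angle_in_plane",
    "orient_deterministic",
]

_UNIT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """The input points do not determine the requested primitive."""


def _as_points(points, min_points: int, what: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{what}: expected an (N, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{what}: points contain non-finite coordinates")
    if len(pts) < min_points:
        raise DegenerateGeometryError(
            f"{what}: need at least {min_points} points, got {len(pts)}"
        )
    return pts


def _unit(v, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what} has (near-)zero length")
    return v / n


def orient_deterministic(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its largest-magnitude component is positive."""
    v = np.asarray(v, dtype=float)
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


@dataclass
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = _unit(self.normal, "plane normal")

    def signed_distance(self, points) -> np.ndarray | float:
        """Signed distance of point(s) along the normal, in mm."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.point) @ self.normal


@dataclass
class Line3:
    """A 3D line given by a point on it and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = _unit(self.direction, "line direction")

    def distance(self, points) -> np.ndarray | float:
        """Orthogonal point-line distance(s), in mm."""
        pts = np.asarray(points, dtype=float)
        rel = pts - self.point
        return np.linalg.norm(np.cross(rel, self.direction), axis=-1)


@dataclass
class Sphere:
    """A sphere with center (mm) and radius (mm > 0)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.radius = float(self.radius)
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass
class SphereFitDiagnostics:
    """Sphere fit with convergence / conditioning metadata."""

    sphere: Sphere
    algebraic_sphere: Sphere
    rms_residual: float
    algebraic_rms_residual: float
    converged: bool
    iterations: int
    cap_coverage_deg: float
    ill_conditioned: bool
    flags: list = field(default_factory=list)


def fit_plane_least_squares(points) -> Plane:
    """Total-least-squares plane through a point cloud.

    Returns the plane through the centroid whose normal is the smallest
    principal direction of the centered points.  Raises
    :class:`DegenerateGeometryError` for < 3 points or (near-)collinear
    input.
    """
    pts = _as_points(points, 3, "plane fit")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear (or coincident) points: no unique in-plane second direction
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("plane fit: points are (near-)collinear")
    return Plane(centroid, orient_deterministic(vt[2]))


def fit_line_least_squares(points) -> Line3:
    """Total-least-squares 3D line through a point cloud.

    Line through the centroid along the largest principal direction, i.e.
    the direction minimizing the summed squared orthogonal point-line
    distances.
    """
    pts = _as_points(points, 2, "line fit")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12 * max(1.0, float(np.abs(pts).max())):
        raise DegenerateGeometryError("line fit: fewer than 2 distinct points")
    return Line3(centroid, orient_deterministic(vt[0]))


def _algebraic_sphere(pts: np.ndarray) -> Sphere:
    # Linearized system: |p|^2 = 2 p.c + (r^2 - |c|^2)
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, sv = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4 or sv[-1] <= 1e-10 * sv[0]:
        raise DegenerateGeometryError(
            "sphere fit: points are coplanar or otherwise under-determined"
        )
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit: non-positive squared radius")
    return Sphere(center, float(np.sqrt(r2)))


def _sphere_ssq(pts: np.ndarray, center: np.ndarray, radius: float) -> float:
    return float(((np.linalg.norm(pts - center, axis=1) - radius) ** 2).sum())


def _cap_coverage_deg(pts: np.ndarray, sphere: Sphere) -> float:
    """Angular extent (deg) of the point directions seen from the center.

    Twice the maximum angle between a point-center direction and their
    mean direction — roughly the full opening angle of the sampled cap.
    """
    rel = pts - sphere.center
    norms = np.linalg.norm(rel, axis=1)
    norms[norms < 1e-12] = 1e-12
    dirs = rel / norms[:, None]
    mean_dir = dirs.mean(axis=0)
    mn = np.linalg.norm(mean_dir)
    if mn < 1e-12:  # directions wrap the whole sphere
        return 360.0
    mean_dir /= mn
    cosang = np.clip(dirs @ mean_dir, -1.0, 1.0)
    return float(2.0 * np.degrees(np.arccos(cosang.min())))


def fit_sphere_detailed(
    points,
    *,
    max_iter: int = 100,
    step_tol: float = 1e-10,
    coverage_min_deg: float = 20.0,
) -> SphereFitDiagnostics:
    """Algebraic sphere fit plus damped Gauss-Newton geometric refinement.

    Parameters
    ----------
    points
        (N, 3) array-like, N >= 4, not all coplanar.
    max_iter, step_tol
        Gauss-Newton iteration cap and parameter-step convergence
        threshold (mm).
    coverage_min_deg
        Caps sampled over less than this angular extent are flagged
        ``ill_conditioned`` (shallow patches barely constrain the radius)
        but still returned.
    """
    pts = _as_points(points, 4, "sphere fit")
    algebraic = _algebraic_sphere(pts)
    n = len(pts)

    params = np.append(algebraic.center, algebraic.radius)
    ssq = _sphere_ssq(pts, params[:3], params[3])
    converged = ssq <= n * 1e-24
    iterations = 0
    flags: list = []
    for iterations in range(1, max_iter + 1):
        if converged:
            break
        rel = pts - params[:3]
        dist = np.linalg.norm(rel, axis=1)
        dist[dist < 1e-12] = 1e-12
        f = dist - params[3]
        jac = np.column_stack([-rel / dist[:, None], -np.ones(n)])
        step, *_ = np.linalg.lstsq(jac, -f, rcond=None)
        # step halving: only accept a residual decrease (keeps the refined
        # fit no worse than the algebraic seed on any input)
        t = 1.0
        accepted = False
        for _ in range(25):
            cand = params + t * step
            if cand[3] > 0:
                cand_ssq = _sphere_ssq(pts, cand[:3], cand[3])
                if cand_ssq <= ssq:
                    params, ssq = cand, cand_ssq
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
        if np.linalg.norm(t * step) < step_tol:
            converged = True
    if not converged:
        flags.append("sphere_refinement_not_converged")

    sphere = Sphere(params[:3], params[3])
    coverage = _cap_coverage_deg(pts, sphere)
    ill = coverage < coverage_min_deg
    if ill:
        flags.append("sphere_cap_ill_conditioned")
    return SphereFitDiagnostics(
        sphere=sphere,
        algebraic_sphere=algebraic,
        rms_residual=float(np.sqrt(ssq / n)),
        algebraic_rms_residual=float(
            np.sqrt(_sphere_ssq(pts, algebraic.center, algebraic.radius) / n)
        ),
        converged=converged,
        iterations=iterations,
        cap_coverage_deg=coverage,
        ill_conditioned=ill,
        flags=flags,
    )


def fit_sphere(points, **kwargs) -> Sphere:
    """Best-fit sphere (see :func:`fit_sphere_detailed` for diagnostics)."""
    return fit_sphere_detailed(points, **kwargs).sphere


def spherical_cap_volume_fraction(sphere: Sphere, plane: Plane, side: int = 1) -> float:
    """Fraction of the ball's volume on one side of a plane.

    ``side=+1`` selects the half-space the plane normal points into,
    ``side=-1`` the opposite one.  With ``d`` the signed distance of the
    center toward the selected side and ``h = clip(R + d, 0, 2R)`` the cap
    height, the fraction is ``h^2 (3R - h) / (4 R^3)``; clamping makes
    every geometry valid (0 when the ball is entirely outside, 1 when
    entirely inside).
    """
    if side not in (1, -1):
        raise ValueError(f"side must be +1 or -1, got {side!r}")
    r = sphere.radius
    d = side * float(plane.signed_distance(sphere.center))
    h = float(np.clip(r + d, 0.0, 2.0 * r))
    return h * h * (3.0 * r - h) / (4.0 * r**3)


def project_onto_plane(v, plane_normal) -> np.ndarray:
    """Orthogonal projection of ``v`` onto the plane with unit normal."""
    v = np.asarray(v, dtype=float)
    n = _unit(plane_normal, "plane normal")
    return v - (v @ n) * n


def signed_angle_in_plane(u, v, plane_normal) -> float:
    """Signed angle (degrees, in (-180, 180]) from u to v within a plane.

    Both vectors are projected onto the plane first; the sign follows the
    right-hand rule about ``plane_normal``.
    """
    n = _unit(plane_normal, "plane normal")
    up = project_onto_plane(u, n)
    vp = project_onto_plane(v, n)
    if np.linalg.norm(up) < 1e-12 or np.linalg.norm(vp) < 1e-12:
        raise DegenerateGeometryError(
            "signed angle: a vector projects to (near-)zero in the plane"
        )
    ang = float(np.degrees(np.arctan2(np.cross(up, vp) @ n, up @ vp)))
    if ang <= -180.0:
        ang = 180.0
    return ang
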