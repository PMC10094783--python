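"""The measurement pipeline: scapular frame, glenoid fits, and angles.

Given labeled point clouds of one shoulder (scapular blade, trigonum
ridge, glenoid surface, humeral head), this module

1. fits the scapular plane and the transverse axis and assembles a
   right-handed anatomical frame (x lateral->medial, y inferior->superior,
   z posterior->anterior);
2. fits the glenoid best-fit sphere (averaging paleo-/neoglenoid fits for
   biconcave glenoids) and derives the glenoid centerline;
3. reports signed glenoid version (retroversion negative), signed glenoid
   inclination (superior positive) and humeral-head subluxation (percent
   of humeral-head volume posterior to the glenoid midcoronal plane).

Two transverse-axis variants are supported, mirroring a software update
whose axis redefinition shifts inclination: the legacy axis fitted to the
lateral two thirds of the ridge points only, and the newer axis fitted to
the entire curved ridge up to the trigonum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    Line3,
    Plane,
    Sphere,
    fit_line_least_squares,
    fit_plane_least_squares,
    fit_sphere_detailed,
    spherical_cap_volume_fraction,
)

__all__ = [
    "AxisVariant",
    "ScapularFrame",
    "MorphometryResult",
    "select_ridge_subset",
    "build_scapular_frame",
    "glenoid_centerline",
    "measure_version",
    "measure_inclination",
    "measure_subluxation",
    "run_pipeline",
    "REQUIRED_LABELS",
]

REQUIRED_LABELS = ("glenoid", "blade", "ridge", "humeral_head")

_LATERAL_FRACTION = 2.0 / 3.0


class AxisVariant(enum.Enum):
    """Which ridge points feed the transverse-axis fit."""

    TIME_ZERO_LATERAL_TWO_THIRDS = "time-zero"
    FULL_CURVE_2020 = "2020"

    @classmethod
    def from_label(cls, label: "str | AxisVariant") -> "AxisVariant":
        if isinstance(label, cls):
            return label
        for variant in cls:
            if variant.value == label or variant.name == label:
                return variant
        raise ValueError(f"unknown axis variant {label!r}")


@dataclass
class ScapularFrame:
    """Right-handed anatomical coordinate system of one scapula."""

    origin: np.ndarray  # glenoid-surface barycenter
    x_transverse: np.ndarray  # lateral -> medial
    y_superoinferior: np.ndarray  # inferior -> superior
    z_anteroposterior: np.ndarray  # posterior -> anterior
    scapular_plane: Plane
    transverse_axis: Line3

    def components(self, v: np.ndarray) -> tuple[float, float, float]:
        """Coordinates of a vector in the (x, y, z) frame axes."""
        v = np.asarray(v, dtype=float)
        return (
            float(v @ self.x_transverse),
            float(v @ self.y_superoinferior),
            float(v @ self.z_anteroposterior),
        )


@dataclass
class MorphometryResult:
    """One software-variant measurement of one shoulder."""

    version: float  # degrees, retroversion negative
    inclination: float  # degrees, superior positive
    subluxation: float  # percent posterior
    glenoid_sphere: Sphere
    humeral_sphere: Sphere
    frame: ScapularFrame
    variant: AxisVariant
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "version_deg": self.version,
            "inclination_deg": self.inclination,
            "subluxation_pct": self.subluxation,
            "glenoid_sphere": {
                "center": self.glenoid_sphere.center.tolist(),
                "radius": self.glenoid_sphere.radius,
            },
            "humeral_sphere": {
                "center": self.humeral_sphere.center.tolist(),
                "radius": self.humeral_sphere.radius,
            },
            "flags": list(self.flags),
        }


def select_ridge_subset(
    ridge_points,
    variant: AxisVariant,
    lateral_reference: np.ndarray | None = None,
) -> np.ndarray:
    """Ridge points feeding the transverse-axis fit for one variant.

    ``FULL_CURVE_2020`` returns all points.  The legacy variant orders
    the points by arc length along their principal direction, identifies
    the lateral end as the end nearer ``lateral_reference`` (typically
    the glenoid barycenter), and keeps the lateral two thirds by
    arc-length fraction: every point strictly inside the first 2/3 of the
    arc plus the boundary point at or just past the cut.
    """
    variant = AxisVariant.from_label(variant)
    pts = np.asarray(ridge_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("ridge points must be an (N, 3) array")
    if variant is AxisVariant.FULL_CURVE_2020:
        if len(pts) < 2:
            raise DegenerateGeometryError("ridge: need >= 2 points")
        return pts
    if len(pts) < 3:
        raise DegenerateGeometryError("ridge: need >= 3 points for the lateral subset")
    if lateral_reference is None:
        raise ValueError(
            "lateral_reference (e.g. the glenoid barycenter) is required for "
            "the lateral-two-thirds variant"
        )
    line = fit_line_least_squares(pts)
    t = (pts - line.point) @ line.direction
    order = np.argsort(t, kind="stable")
    ordered = pts[order]
    ref = np.asarray(lateral_reference, dtype=float)
    if np.linalg.norm(ordered[-1] - ref) < np.linalg.norm(ordered[0] - ref):
        ordered = ordered[::-1]
    seg = np.linalg.norm(np.diff(ordered, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise DegenerateGeometryError("ridge: points are coincident")
    frac = arclen / total
    inside = frac < _LATERAL_FRACTION - 1e-12
    k = int(inside.sum())
    k = min(k + 1, len(ordered))  # boundary point at/just past the 2/3 cut
    subset = ordered[:k]
    if len(subset) < 2:
        raise DegenerateGeometryError("ridge: lateral subset has fewer than 2 points")
    return subset


def _reflect_across_plane(points: np.ndarray, plane: Plane) -> np.ndarray:
    d = plane.signed_distance(points)
    return points - 2.0 * np.outer(d, plane.normal)


def _plane_points(blade: np.ndarray, glenoid: np.ndarray, include_glenoid: bool) -> np.ndarray:
    return np.vstack([blade, glenoid]) if include_glenoid else blade


def build_scapular_frame(
    blade_points,
    ridge_points,
    glenoid_points,
    variant: AxisVariant,
    side: str = "right",
    *,
    include_glenoid_in_plane: bool = False,
    min_axis_plane_angle_deg: float = 5.0,
) -> ScapularFrame:
    """Assemble the anatomical frame from the fitted plane and axis.

    The plane normal is taken as the most reliable direction, so the
    orthogonalization order is z (normal) -> y (z x raw transverse) -> x
    (y x z): the transverse azimuth within the plane is preserved while
    the triad becomes exactly orthonormal.

    Orientation is landmark free: x points from the glenoid barycenter
    toward the ridge (lateral -> medial); the superior hint is the
    blade-centroid -> ridge-centroid direction (the spine sits on the
    superior border of the blade); z is signed so the triad matches
    right-shoulder anatomy.  For ``side="left"`` the clouds are mirrored
    across the fitted scapular plane first, turning the shoulder into its
    right-handed twin so the signed conventions carry over unchanged.
    """
    blade = np.asarray(blade_points, dtype=float)
    ridge = np.asarray(ridge_points, dtype=float)
    glenoid = np.asarray(glenoid_points, dtype=float)
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    if side == "left":
        plane0 = fit_plane_least_squares(_plane_points(blade, glenoid, include_glenoid_in_plane))
        blade = _reflect_across_plane(blade, plane0)
        ridge = _reflect_across_plane(ridge, plane0)
        glenoid = _reflect_across_plane(glenoid, plane0)

    plane = fit_plane_least_squares(_plane_points(blade, glenoid, include_glenoid_in_plane))
    glenoid_barycenter = glenoid.mean(axis=0)
    subset = select_ridge_subset(ridge, variant, lateral_reference=glenoid_barycenter)
    axis = fit_line_least_squares(subset)

    x_raw = axis.direction
    if x_raw @ (ridge.mean(axis=0) - glenoid_barycenter) < 0:
        x_raw = -x_raw

    # transverse axis nearly parallel to the plane normal: no usable frame
    axis_plane_angle = np.degrees(np.arccos(np.clip(abs(x_raw @ plane.normal), 0.0, 1.0)))
    if axis_plane_angle < min_axis_plane_angle_deg:
        raise DegenerateGeometryError(
            "transverse axis within "
            f"{min_axis_plane_angle_deg} degrees of the scapular-plane normal"
        )

    y_hint = ridge.mean(axis=0) - blade.mean(axis=0)
    y_hint = y_hint - (y_hint @ x_raw) * x_raw
    if np.linalg.norm(y_hint) < 1e-9:
        raise DegenerateGeometryError("cannot orient the superoinferior axis")
    y_hint /= np.linalg.norm(y_hint)

    z = plane.normal if plane.normal @ np.cross(x_raw, y_hint) > 0 else -plane.normal
    y = np.cross(z, x_raw)
    y /= np.linalg.norm(y)
    x = np.cross(y, z)

    return ScapularFrame(
        origin=glenoid_barycenter,
        x_transverse=x,
        y_superoinferior=y,
        z_anteroposterior=z,
        scapular_plane=Plane(plane.point, z),
        transverse_axis=Line3(axis.point, x_raw),
    )


def glenoid_centerline(
    glenoid_points,
    sublabels: np.ndarray | None = None,
    *,
    sphere_kwargs: dict | None = None,
) -> tuple[Line3, Sphere, list]:
    """Glenoid best-fit sphere and the outward centerline through it.

    For biconcave glenoids (``sublabels`` holding ``paleoglenoid`` /
    ``neoglenoid`` per point) the two surfaces are fitted separately and
    the centers and radii averaged arithmetically; a sublabeled subset
    with fewer than 4 points falls back to the single-sphere fit with a
    warning flag.

    The centerline runs from the glenoid-surface barycenter through the
    sphere center.  The glenoid is a concave cup, so its center of
    curvature sits on the open (lateral) side of the surface and the
    barycenter->center direction points outward, laterally.
    """
    pts = np.asarray(glenoid_points, dtype=float)
    kw = sphere_kwargs or {}
    flags: list = []

    fits = None
    if sublabels is not None:
        sub = np.asarray(sublabels)
        paleo = pts[sub == "paleoglenoid"]
        neo = pts[sub == "neoglenoid"]
        if len(paleo) >= 4 and len(neo) >= 4:
            fits = [fit_sphere_detailed(paleo, **kw), fit_sphere_detailed(neo, **kw)]
        else:
            flags.append("biconcave_subset_too_small_single_fit")
    if fits is not None:
        for f in fits:
            flags.extend(f.flags)
        sphere = Sphere(
            0.5 * (fits[0].sphere.center + fits[1].sphere.center),
            0.5 * (fits[0].sphere.radius + fits[1].sphere.radius),
        )
    else:
        fit = fit_sphere_detailed(pts, **kw)
        flags.extend(fit.flags)
        sphere = fit.sphere

    barycenter = pts.mean(axis=0)
    outward = sphere.center - barycenter
    norm = np.linalg.norm(outward)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "glenoid centerline: sphere center coincides with the surface barycenter"
        )
    return Line3(barycenter, outward / norm), sphere, flags


def _azimuth(vx: float, other: float, what: str) -> float:
    # angle of (lateral-component, other-component) from the lateral axis;
    # lateral component is -vx in frame coordinates
    lateral = -vx
    if np.hypot(lateral, other) < 1e-12:
        raise DegenerateGeometryError(f"{what}: centerline projects to zero")
    if lateral <= 0:
        raise DegenerateGeometryError(
            f"{what}: glenoid centerline points medially; angle outside (-90, 90)"
        )
    return float(np.degrees(np.arctan2(other, lateral)))


def measure_version(centerline: Line3, frame: ScapularFrame) -> float:
    """Signed glenoid version in degrees; retroversion (posterior) negative.

    The outward centerline is projected onto the transverse plane
    (spanned by x and z) and measured from the lateral direction (-x);
    a posterior-facing glenoid (component along -z) yields a negative
    angle.
    """
    vx, _, vz = frame.components(centerline.direction)
    return _azimuth(vx, vz, "version")


def measure_inclination(centerline: Line3, frame: ScapularFrame) -> float:
    """Signed glenoid inclination in degrees; superior tilt positive.

    The outward centerline is projected onto the scapular plane (spanned
    by x and y) and measured from the lateral direction (-x) with
    superior tilt (+y) positive — i.e. the in-plane angle taken about the
    posterior-pointing normal, so the printed sign convention holds.
    """
    vx, vy, _ = frame.components(centerline.direction)
    return _azimuth(vx, vy, "inclination")


def measure_subluxation(
    humeral_points,
    glenoid_sphere: Sphere,
    frame: ScapularFrame,
    *,
    sphere_kwargs: dict | None = None,
) -> tuple[float, Sphere, list]:
    """Humeral-head posterior subluxation in percent.

    Fits the humeral-head sphere and returns 100x the fraction of its
    volume posterior to the glenoid midcoronal plane (the plane through
    the glenoid-sphere center normal to the anteroposterior axis).
    """
    fit = fit_sphere_detailed(humeral_points, **(sphere_kwargs or {}))
    midcoronal = Plane(glenoid_sphere.center, frame.z_anteroposterior)
    fraction = spherical_cap_volume_fraction(fit.sphere, midcoronal, side=-1)
    return 100.0 * fraction, fit.sphere, list(fit.flags)


def run_pipeline(
    clouds: dict,
    variant: AxisVariant | str,
    side: str = "right",
    glenoid_sublabels: np.ndarray | None = None,
    *,
    include_glenoid_in_plane: bool = False,
    min_axis_plane_angle_deg: float = 5.0,
    sphere_kwargs: dict | None = None,
) -> MorphometryResult:
    """Measure one shoulder end to end with one axis variant.

    ``clouds`` maps labels to (N, 3) mm arrays.  The glenoid may be given
    either as one ``glenoid`` cloud (optionally with ``glenoid_sublabels``)
    or as separate ``paleoglenoid`` / ``neoglenoid`` clouds.
    """
    variant = AxisVariant.from_label(variant)
    clouds = {k: np.asarray(v, dtype=float) for k, v in clouds.items()}
    if "glenoid" not in clouds and {"paleoglenoid", "neoglenoid"} <= clouds.keys():
        glenoid_sublabels = np.array(
            ["paleoglenoid"] * len(clouds["paleoglenoid"])
            + ["neoglenoid"] * len(clouds["neoglenoid"])
        )
        clouds["glenoid"] = np.vstack([clouds["paleoglenoid"], clouds["neoglenoid"]])
    for label in REQUIRED_LABELS:
        if label not in clouds:
            raise ValueError(f"missing required point-cloud label {label!r}")

    blade, ridge = clouds["blade"], clouds["ridge"]
    glenoid, humeral = clouds["glenoid"], clouds["humeral_head"]

    if side == "left":
        # mirror into the right-handed twin; the scapular plane is (to
        # first order) the symmetry plane, so reflecting across it flips
        # only the anteroposterior sense
        plane0 = fit_plane_least_squares(
            _plane_points(blade, glenoid, include_glenoid_in_plane)
        )
        blade = _reflect_across_plane(blade, plane0)
        ridge = _reflect_across_plane(ridge, plane0)
        glenoid = _reflect_across_plane(glenoid, plane0)
        humeral = _reflect_across_plane(humeral, plane0)
        side = "right"

    frame = build_scapular_frame(
        blade,
        ridge,
        glenoid,
        variant,
        side,
        include_glenoid_in_plane=include_glenoid_in_plane,
        min_axis_plane_angle_deg=min_axis_plane_angle_deg,
    )
    centerline, glenoid_sphere, flags = glenoid_centerline(
        glenoid, glenoid_sublabels, sphere_kwargs=sphere_kwargs
    )
    version = measure_version(centerline, frame)
    inclination = measure_inclination(centerline, frame)
    subluxation, humeral_sphere, sub_flags = measure_subluxation(
        humeral, glenoid_sphere, frame, sphere_kwargs=sphere_kwargs
    )
    return MorphometryResult(
        version=version,
        inclination=inclination,
        subluxation=subluxation,
        glenoid_sphere=glenoid_sphere,
        humeral_sphere=humeral_sphere,
        frame=frame,
        variant=variant,
        flags=flags + sub_flags,
    )
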