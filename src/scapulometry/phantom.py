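"""Parametric scapula + humerus phantoms with known ground truth.

Generates labeled point clouds emulating the structures the automated
morphometry pipeline consumes: a curved scapular-blade sheet, the curved
trigonum-ridge arc along the scapular spine, a spherical-cap glenoid
patch (optionally biconcave: paleo- plus neoglenoid), and a humeral-head
sphere.  True version, inclination and subluxation are inputs, so the
phantoms serve as ground truth for validating the measurement pipeline.

Canonical right-shoulder frame used for construction:

* ``x`` — transverse axis, lateral -> medial
* ``y`` — superoinferior, inferior -> superior
* ``z`` — anteroposterior, posterior -> anterior

The glenoid outward centerline is ``(-1, tan(inclination), tan(version))``
normalized, so that its transverse-plane azimuth equals the version and
its scapular-plane elevation equals the inclination *exactly*: a
noiseless phantom with a straight ridge is recovered to numerical
precision by the pipeline (inverse consistency).  Retroversion is
negative (glenoid facing posteriorly), superior inclination positive.

Noiseless structures are sampled on symmetric layouts (full azimuthal
rings on the glenoid cap, an x-symmetric rectangular grid for the blade,
a symmetric circular arc for the ridge) so the fitted plane/line/sphere
coincide with the constructions exactly before noise is added.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Plane, Sphere, spherical_cap_volume_fraction

__all__ = [
    "BiconcaveParams",
    "PhantomParams",
    "ScapulaPhantom",
    "generate_phantom",
    "generate_cohort",
    "solve_subluxation_offset",
    "DEFAULT_COHORT_RANGES",
]


@dataclass
class BiconcaveParams:
    """Biconcave (B2-like) glenoid: a second, posteriorly eroded surface.

    The neoglenoid cap shares the cup floor with the paleoglenoid but has
    its own radius and an additional version offset (degrees, negative =
    more retroverted).  ``neo_fraction`` of the glenoid points are
    assigned to the neoglenoid.
    """

    neo_radius: float = 12.5
    neo_version_offset_deg: float = -10.0
    neo_fraction: float = 0.5

    def validate(self) -> None:
        if not self.neo_radius > 0:
            raise ValueError("neo_radius must be > 0")
        if not 0.0 < self.neo_fraction < 1.0:
            raise ValueError("neo_fraction must be in (0, 1)")


@dataclass
class PhantomParams:
    """Ground-truth parameters of one synthetic shoulder.

    Angles in degrees (retroversion negative, superior inclination
    positive), lengths in mm, subluxation in percent of humeral-head
    volume posterior to the glenoid midcoronal plane.
    """

    true_version: float = -9.4
    true_inclination: float = 8.1
    true_subluxation: float = 60.1
    glenoid_radius: float = 12.5
    glenoid_cap_half_angle: float = 60.0
    humeral_radius: float = 24.0
    blade_extent: float = 100.0
    blade_curvature: float = 0.01  # 1/mm about the superoinferior axis; 0 = flat
    ridge_length: float = 100.0
    ridge_bow: float = 6.0  # mid-arc sag from the chord, in the scapular plane
    glenoid_points: int = 400
    blade_points: int = 800
    ridge_points: int = 40
    humeral_points: int = 500
    noise_sd: float = 0.3
    biconcave: BiconcaveParams | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (self.glenoid_radius > 0 and self.humeral_radius > 0):
            raise ValueError("radii must be > 0")
        if not 0.0 < self.glenoid_cap_half_angle < 90.0:
            raise ValueError("glenoid_cap_half_angle must be in (0, 90) degrees")
        if not 0.0 <= self.true_subluxation <= 100.0:
            raise ValueError("true_subluxation must be in [0, 100] percent")
        if not -90.0 < self.true_version < 90.0:
            raise ValueError("true_version must be in (-90, 90) degrees")
        if not -90.0 < self.true_inclination < 90.0:
            raise ValueError("true_inclination must be in (-90, 90) degrees")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.blade_extent <= 0 or self.ridge_length <= 0:
            raise ValueError("blade_extent and ridge_length must be > 0")
        if self.blade_curvature < 0:
            raise ValueError("blade_curvature must be >= 0")
        if self.blade_curvature * self.blade_extent / 2.0 >= 1.0:
            raise ValueError("blade_curvature too large for blade_extent")
        if self.ridge_bow < 0:
            raise ValueError("ridge_bow must be >= 0")
        if self.ridge_bow >= self.ridge_length / 2.0:
            raise ValueError("ridge_bow must be < ridge_length / 2")
        if self.glenoid_points < 4 or self.blade_points < 3 or self.ridge_points < 2:
            raise ValueError("too few points for the downstream fits")
        if self.humeral_points < 4:
            raise ValueError("humeral_points must be >= 4")
        if self.biconcave is not None:
            self.biconcave.validate()


@dataclass
class GroundTruth:
    """Exact construction values of a phantom, in the canonical frame."""

    params: PhantomParams
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    glenoid_center: np.ndarray
    glenoid_outward: np.ndarray
    humeral_center: np.ndarray
    humeral_posterior_offset: float  # signed distance of humeral center toward -z

    def to_dict(self) -> dict:
        p = dataclasses.asdict(self.params)
        return {
            "params": p,
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
            "glenoid_center": self.glenoid_center.tolist(),
            "glenoid_outward": self.glenoid_outward.tolist(),
            "humeral_center": self.humeral_center.tolist(),
            "humeral_posterior_offset": self.humeral_posterior_offset,
        }


@dataclass
class ScapulaPhantom:
    """Labeled point clouds plus the ground truth they were built from."""

    clouds: dict[str, np.ndarray]
    glenoid_sublabels: np.ndarray | None  # 'paleoglenoid'/'neoglenoid' per glenoid row
    ground_truth: GroundTruth

    def write_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth.to_dict(), indent=1))


def solve_subluxation_offset(subluxation_pct: float, radius: float, *, tol: float = 1e-10) -> float:
    """Signed posterior offset d of a sphere center so that the posterior
    cap holds ``subluxation_pct`` percent of the volume.

    Solves ``h^2 (3R - h) / (4R^3) = pct/100`` with ``h = R + d`` by
    bisection on ``[-R, R]`` (the fraction is monotone in d).
    """
    if not 0.0 <= subluxation_pct <= 100.0:
        raise ValueError("subluxation must be in [0, 100] percent")
    target = subluxation_pct / 100.0
    r = float(radius)

    def frac(d: float) -> float:
        h = r + d
        return h * h * (3.0 * r - h) / (4.0 * r**3)

    lo, hi = -r, r
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _rotation_from_z(target: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +z to the unit vector ``target``."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(z @ target)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, target)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def _cap_directions(n: int, half_angle_rad: float) -> np.ndarray:
    """~n unit vectors on a spherical cap about +z, in full azimuthal rings.

    Full rings make the direction barycenter lie exactly on the cap axis,
    which keeps noiseless phantoms exactly inverse-consistent.
    """
    n_rings = max(2, int(round(np.sqrt(n / 3.0))))
    thetas = half_angle_rad * (np.arange(1, n_rings + 1) / n_rings)
    weights = np.sin(thetas)
    counts = np.maximum(3, np.round(weights / weights.sum() * (n - 1)).astype(int))
    dirs = [np.array([[0.0, 0.0, 1.0]])]  # apex point, on the axis
    for theta, k in zip(thetas, counts):
        phi = 2.0 * np.pi * np.arange(k) / k
        dirs.append(
            np.column_stack(
                [
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.full(k, np.cos(theta)),
                ]
            )
        )
    return np.vstack(dirs)


def _arc_points(length: float, bow: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Planar circular arc of given arc length and mid-arc sag (bow).

    Returns (x, y) with the chord along x centered at 0 and the mid-arc
    bowing toward +y (superiorly, within the scapular plane); ``bow=0``
    degenerates to a straight chord.  Points are equally spaced in arc
    length, endpoints included.
    """
    if bow <= 0:
        x = np.linspace(-length / 2.0, length / 2.0, n)
        return x, np.zeros(n)
    # solve (1 - cos(phi)) / (2 phi) = bow / length for the half-angle phi
    ratio = bow / length
    lo, hi = 1e-12, np.pi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (1.0 - np.cos(mid)) / (2.0 * mid) < ratio:
            lo = mid
        else:
            hi = mid
    phi = 0.5 * (lo + hi)
    rho = length / (2.0 * phi)
    theta = np.linspace(-phi, phi, n)
    x = rho * np.sin(theta)
    y = rho * np.cos(theta) - rho * np.cos(phi)
    return x, y


def _glenoid_outward(version_deg: float, inclination_deg: float) -> np.ndarray:
    v = np.array(
        [
            -1.0,
            np.tan(np.radians(inclination_deg)),
            np.tan(np.radians(version_deg)),
        ]
    )
    return v / np.linalg.norm(v)


def _glenoid_cap(
    center: np.ndarray, radius: float, outward: np.ndarray, half_angle_deg: float, n: int
) -> np.ndarray:
    # concave cup opening along `outward`: surface directions cluster
    # around -outward as seen from the sphere center
    rot = _rotation_from_z(-outward)
    dirs = _cap_directions(n, np.radians(half_angle_deg)) @ rot.T
    return center + radius * dirs


def generate_phantom(params: PhantomParams) -> ScapulaPhantom:
    """Build one labeled phantom; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    x_axis = np.array([1.0, 0.0, 0.0])
    y_axis = np.array([0.0, 1.0, 0.0])
    z_axis = np.array([0.0, 0.0, 1.0])

    # --- glenoid cap(s); sphere center at the origin --------------------
    glenoid_center = np.zeros(3)
    outward = _glenoid_outward(params.true_version, params.true_inclination)
    sublabels: np.ndarray | None = None
    if params.biconcave is None:
        glenoid = _glenoid_cap(
            glenoid_center,
            params.glenoid_radius,
            outward,
            params.glenoid_cap_half_angle,
            params.glenoid_points,
        )
    else:
        bc = params.biconcave
        n_neo = int(round(bc.neo_fraction * params.glenoid_points))
        n_neo = min(max(n_neo, 4), params.glenoid_points - 4)
        neo_outward = _glenoid_outward(
            params.true_version + bc.neo_version_offset_deg, params.true_inclination
        )
        # neoglenoid sphere anchored at the paleoglenoid cup floor
        apex = glenoid_center - params.glenoid_radius * outward
        neo_center = apex + bc.neo_radius * neo_outward
        paleo = _glenoid_cap(
            glenoid_center,
            params.glenoid_radius,
            outward,
            params.glenoid_cap_half_angle,
            params.glenoid_points - n_neo,
        )
        neo = _glenoid_cap(
            neo_center,
            bc.neo_radius,
            neo_outward,
            params.glenoid_cap_half_angle,
            n_neo,
        )
        glenoid = np.vstack([paleo, neo])
        sublabels = np.array(
            ["paleoglenoid"] * len(paleo) + ["neoglenoid"] * len(neo)
        )

    glenoid_barycenter = glenoid.mean(axis=0)

    # --- blade: x-symmetric rectangular sheet, cylindrically curved -----
    x0 = glenoid_barycenter[0] + 12.0  # sheet starts just medial of the glenoid
    height = 0.7 * params.blade_extent
    nx = max(3, int(round(np.sqrt(params.blade_points * params.blade_extent / height))))
    ny = max(3, int(np.ceil(params.blade_points / nx)))
    gx = np.linspace(x0, x0 + params.blade_extent, nx)
    gy = np.linspace(-height, 0.0, ny)
    bx, by = np.meshgrid(gx, gy)
    bx, by = bx.ravel(), by.ravel()
    if params.blade_curvature > 0:
        rho = 1.0 / params.blade_curvature
        xc = x0 + params.blade_extent / 2.0
        bz = rho - np.sqrt(rho**2 - (bx - xc) ** 2)
    else:
        bz = np.zeros_like(bx)
    blade = np.column_stack([bx, by, bz])

    # --- ridge: circular arc along the spine, sag within the plane ------
    rx, ry = _arc_points(params.ridge_length, params.ridge_bow, params.ridge_points)
    ridge_x0 = glenoid_barycenter[0] + 15.0  # lateral end, nearest the glenoid
    ridge = np.column_stack(
        [rx - rx[0] + ridge_x0, ry, np.zeros_like(rx)]
    )

    # --- humeral head: full sphere offset posteriorly --------------------
    d = solve_subluxation_offset(params.true_subluxation, params.humeral_radius)
    humeral_center = glenoid_center - d * z_axis  # d > 0 => center posterior
    hdirs = rng.normal(size=(params.humeral_points, 3))
    hdirs /= np.linalg.norm(hdirs, axis=1)[:, None]
    humeral = humeral_center + params.humeral_radius * hdirs

    clouds = {
        "glenoid": glenoid,
        "blade": blade,
        "ridge": ridge,
        "humeral_head": humeral,
    }
    if params.noise_sd > 0:
        for label in ("glenoid", "blade", "ridge", "humeral_head"):
            clouds[label] = clouds[label] + rng.normal(
                scale=params.noise_sd, size=clouds[label].shape
            )

    gt = GroundTruth(
        params=params,
        x_axis=x_axis,
        y_axis=y_axis,
        z_axis=z_axis,
        glenoid_center=glenoid_center,
        glenoid_outward=outward,
        humeral_center=humeral_center,
        humeral_posterior_offset=d,
    )
    return ScapulaPhantom(clouds=clouds, glenoid_sublabels=sublabels, ground_truth=gt)


#: Cohort parameter ranges emulating an arthroplasty-bound population:
#: mostly retroverted, superiorly inclined, posteriorly subluxated shoulders.
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "true_version": (-25.0, 5.0),
    "true_inclination": (-5.0, 20.0),
    "true_subluxation": (40.0, 80.0),
    "glenoid_radius": (11.0, 15.0),
    "humeral_radius": (21.0, 26.0),
}


def generate_cohort(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base: PhantomParams | None = None,
) -> list[ScapulaPhantom]:
    """n phantoms with parameters drawn uniformly from per-field ranges.

    Fields absent from ``ranges`` keep the value in ``base`` (default
    :class:`PhantomParams`).  Per-phantom seeds are derived from the
    master ``seed``, so reruns are identical.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ranges = DEFAULT_COHORT_RANGES if ranges is None else ranges
    base = PhantomParams() if base is None else base
    valid_fields = {f.name for f in dataclasses.fields(PhantomParams)}
    int_fields = {"glenoid_points", "blade_points", "ridge_points", "humeral_points", "seed"}
    for name, (lo, hi) in ranges.items():
        if name not in valid_fields:
            raise ValueError(f"unknown phantom parameter {name!r}")
        if lo > hi:
            raise ValueError(f"invalid range for {name!r}: {lo} > {hi}")
    rng = np.random.default_rng(seed)
    phantoms = []
    for _ in range(n):
        draws = {
            name: rng.uniform(lo, hi) for name, (lo, hi) in ranges.items()
        }
        for name in list(draws):
            if name in int_fields:
                draws[name] = int(round(draws[name]))
        child_seed = int(rng.integers(2**31))
        params = dataclasses.replace(base, seed=child_seed, **draws)
        phantoms.append(generate_phantom(params))
    return phantoms


def _check_cap_solver_consistency(sphere: Sphere, d: float) -> float:
    """Posterior volume fraction implied by an offset; test/debug helper."""
    plane = Plane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    shifted = Sphere(np.array([0.0, 0.0, -d]), sphere.radius)
    return spherical_cap_volume_fraction(shifted, plane, side=-1)
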