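"""Analytic magnetometer lead fields for a spherical volume conductor.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has a closed-form solution (the classical spherical-conductor
formula). Its key structural properties are exploited throughout the
package: a purely radial dipole moment is externally silent, the field is
linear in the moment, and sensor-space amplitude decays steeply with
source depth — the regime that makes hippocampal and amygdalar generators
hard to see at the helmet.

Geometry is in meters, dipole moments in A·m, fields in femtotesla (fT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU0_OVER_4PI = 1e-7  # T·m/A
T_TO_FT = 1e15

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Sphere:
    """Conductor sphere: center (m) and radius (m)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.09

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class SensorArray:
    """Magnetometer positions and unit orientations (the measured component)."""

    positions: np.ndarray  # (n_sensors, 3) m
    orientations: np.ndarray  # (n_sensors, 3) unit vectors

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must have equal shapes")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("sensor orientations must be unit vectors")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class DipoleSource:
    """Current dipole: position inside the conductor, moment in A·m."""

    position: tuple[float, float, float]
    moment: tuple[float, float, float]


@dataclass
class LeadField:
    """Gains of 3 orthogonal unit dipoles per grid point, in fT per A·m.

    ``gain`` has shape (n_grid, 3, n_sensors); the moment triplet is the
    Cartesian basis. Because radial moments are silent in a sphere, each
    3-column gain block has effective rank 2.
    """

    grid: np.ndarray  # (n_grid, 3) m
    gain: np.ndarray  # (n_grid, 3, n_sensors) fT / (A·m)
    sphere: Sphere
    spacing: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_grid(self) -> int:
        return self.grid.shape[0]


def _check_inside(positions: np.ndarray, sphere: Sphere, what: str) -> None:
    rel = np.atleast_2d(positions) - sphere.center_arr
    radii = np.linalg.norm(rel, axis=1)
    bad = np.nonzero(radii >= sphere.radius)[0]
    if bad.size:
        raise ValueError(f"{what} outside the conductor sphere at index {bad[0]}")
    center = np.nonzero(radii < 1e-9)[0]
    if center.size:
        raise ValueError(f"{what} at the sphere center at index {center[0]} (silent)")


def _sarvas_matrix(r0: np.ndarray, sensors: SensorArray, sphere: Sphere) -> np.ndarray:
    """Field of the three Cartesian unit dipoles at ``r0``.

    Returns (3, n_sensors): row m is the measured field (fT) of a 1 A·m
    dipole along axis m, projected on each sensor's orientation.
    """
    center = sphere.center_arr
    r = sensors.positions - center  # (S, 3)
    rmag = np.linalg.norm(r, axis=1)
    if np.any(rmag <= sphere.radius):
        raise ValueError("all sensors must lie outside the conductor sphere")
    p = r0 - center  # dipole position, center-relative
    a_vec = r - p  # (S, 3)
    amag = np.linalg.norm(a_vec, axis=1)
    ar = np.einsum("sj,sj->s", a_vec, r)
    p_dot_r = r @ p
    F = amag * (rmag * amag + rmag**2 - p_dot_r)  # (S,)
    grad_coeff_r = amag**2 / rmag + ar / amag + 2.0 * amag + 2.0 * rmag
    grad_coeff_p = amag + 2.0 * rmag + ar / amag
    gradF = grad_coeff_r[:, None] * r - grad_coeff_p[:, None] * p[None, :]  # (S, 3)

    eye = np.eye(3)
    cross = np.cross(eye, p[None, :])  # (3, 3): Q_m x p
    cr = cross @ r.T  # (3, S): (Q_m x p) · r
    # B_m(s) = mu0/(4 pi F^2) * (F * (Q_m x p) - ((Q_m x p)·r) gradF)
    B = (
        MU0_OVER_4PI
        / F[None, :, None] ** 2
        * (F[None, :, None] * cross[:, None, :] - cr[:, :, None] * gradF[None, :, :])
    )  # (3, S, 3)
    projected = np.einsum("msj,sj->ms", B, sensors.orientations)
    return projected * T_TO_FT


def dipole_field(
    dipole: DipoleSource, sensors: SensorArray, sphere: Sphere
) -> np.ndarray:
    """Measured field (fT per sensor) of a current dipole in the sphere."""
    pos = np.asarray(dipole.position, dtype=float)
    _check_inside(pos, sphere, "dipole")
    gain = _sarvas_matrix(pos, sensors, sphere)  # (3, S)
    return np.asarray(dipole.moment, dtype=float) @ gain


def compute_leadfield(
    grid: np.ndarray, sensors: SensorArray, sphere: Sphere, spacing: float | None = None
) -> LeadField:
    """Lead field of a Cartesian unit-dipole triplet at each grid point."""
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    _check_inside(grid, sphere, "grid point")
    gain = np.empty((grid.shape[0], 3, sensors.n_sensors))
    for g, point in enumerate(grid):
        gain[g] = _sarvas_matrix(point, sensors, sphere)
    if not np.all(np.isfinite(gain)):
        raise FloatingPointError("non-finite gain encountered")
    return LeadField(grid=grid, gain=gain, sphere=sphere, spacing=spacing)


def make_grid(
    sphere: Sphere,
    spacing: float = 0.0075,
    max_radius_fraction: float = 0.9,
) -> np.ndarray:
    """Regular isotropic grid inside the sphere.

    The grid is offset by half a spacing so no point coincides with the
    (silent) sphere center; points beyond ``max_radius_fraction * radius``
    are excluded to keep sources away from the conductor boundary.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    r = sphere.radius * max_radius_fraction
    axis = np.arange(-r, r + spacing, spacing) + spacing / 2.0
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= r]
    return pts + sphere.center_arr


def make_helmet(
    n_sensors: int = 248,
    radius: float = 0.105,
    cap_angle: float = 2.0,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SensorArray:
    """Quasi-uniform radially oriented magnetometers on a spherical cap.

    A Fibonacci lattice on the cap of half-angle ``cap_angle`` (radians,
    measured from the +z apex) emulates a whole-head magnetometer helmet.
    """
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    if not (0.0 < cap_angle <= np.pi):
        raise ValueError("cap_angle must lie in (0, pi]")
    center = np.asarray(center, dtype=float)
    if n_sensors == 1:
        directions = np.array([[0.0, 0.0, 1.0]])
    else:
        i = np.arange(n_sensors)
        z = 1.0 - (1.0 - np.cos(cap_angle)) * (i + 0.5) / n_sensors
        phi = i * _GOLDEN_ANGLE
        sin_theta = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        directions = np.column_stack(
            [sin_theta * np.cos(phi), sin_theta * np.sin(phi), z]
        )
    positions = center + radius * directions
    return SensorArray(positions=positions, orientations=directions)


def write_sensors(sensors: SensorArray, path) -> None:
    """Sensor geometry as JSON (positions/orientations in meters)."""
    import json
    from pathlib import Path

    Path(path).write_text(
        json.dumps(
            {
                "positions_m": sensors.positions.tolist(),
                "orientations": sensors.orientations.tolist(),
            }
        )
    )


def read_sensors(path) -> SensorArray:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    return SensorArray(np.asarray(d["positions_m"]), np.asarray(d["orientations"]))


def write_leadfield(leadfield: LeadField, prefix) -> None:
    """Lead-field archive: gain array + JSON sidecar with grid and sphere."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), leadfield.gain)
    prefix.with_suffix(".json").write_text(
        json.dumps(
            {
                "grid_m": leadfield.grid.tolist(),
                "sphere": {"center": list(leadfield.sphere.center),
                           "radius": leadfield.sphere.radius},
                "spacing": leadfield.spacing,
                "units": "fT per A*m",
            }
        )
    )


def read_leadfield(prefix) -> LeadField:
    import json
    from pathlib import Path

    prefix = Path(prefix)
    gain = np.load(prefix.with_suffix(".npy"))
    d = json.loads(prefix.with_suffix(".json").read_text())
    return LeadField(
        grid=np.asarray(d["grid_m"]),
        gain=gain,
        sphere=Sphere(tuple(d["sphere"]["center"]), d["sphere"]["radius"]),
        spacing=d.get("spacing"),
    )


def tangential_unit(position: np.ndarray, sphere: Sphere | None = None) -> np.ndarray:
    """A deterministic unit vector tangential to the sphere at ``position``."""
    center = sphere.center_arr if sphere is not None else np.zeros(3)
    radial = np.asarray(position, dtype=float) - center
    nrm = np.linalg.norm(radial)
    if nrm < 1e-12:
        raise ValueError("position coincides with the sphere center")
    radial = radial / nrm
    ref = np.array([0.0, 0.0, 1.0])
    if abs(radial @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    tang = np.cross(radial, ref)
    return tang / np.linalg.norm(tang)
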