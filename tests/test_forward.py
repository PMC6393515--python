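"""Spherical-conductor forward model: silence, symmetry, linearity, decay."""

import numpy as np
import pytest

from deepmeg.forward import (
    DipoleSource,
    SensorArray,
    Sphere,
    compute_leadfield,
    dipole_field,
    make_grid,
    make_helmet,
    tangential_unit,
)


@pytest.fixture(scope="module")
def helmet():
    return make_helmet(n_sensors=100)


@pytest.fixture(scope="module")
def sph():
    return Sphere()


def _random_positions(rng, n, radius=0.06):
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * rng.uniform(0.01, radius, (n, 1))


class TestDipoleField:
    def test_radial_dipoles_are_silent(self, helmet, sph):
        rng = np.random.default_rng(0)
        worst = 0.0
        for pos in _random_positions(rng, 1000):
            radial = pos / np.linalg.norm(pos)
            silent = dipole_field(DipoleSource(tuple(pos), tuple(2e-8 * radial)), helmet, sph)
            loud = dipole_field(
                DipoleSource(tuple(pos), tuple(2e-8 * tangential_unit(pos, sph))),
                helmet,
                sph,
            )
            worst = max(worst, np.abs(silent).max() / np.abs(loud).max())
        assert worst <= 1e-10

    def test_linearity_and_superposition(self, helmet, sph):
        rng = np.random.default_rng(1)
        pos = (0.02, 0.01, 0.03)
        q1, q2 = rng.standard_normal(3) * 1e-8, rng.standard_normal(3) * 1e-8
        f1 = dipole_field(DipoleSource(pos, tuple(q1)), helmet, sph)
        f2 = dipole_field(DipoleSource(pos, tuple(q2)), helmet, sph)
        f12 = dipole_field(DipoleSource(pos, tuple(q1 + q2)), helmet, sph)
        np.testing.assert_allclose(f12, f1 + f2, rtol=1e-12, atol=1e-12)
        fdouble = dipole_field(DipoleSource(pos, tuple(2 * q1)), helmet, sph)
        np.testing.assert_allclose(fdouble, 2 * f1, rtol=1e-12)

    def test_mirror_antisymmetry(self, sph):
        # dipole on the z-axis with moment along x: the radial field is
        # antisymmetric under reflection across the xz-plane (y -> -y)
        pos_s = np.array([[0.05, 0.04, 0.08], [0.05, -0.04, 0.08]])
        ori = pos_s / np.linalg.norm(pos_s, axis=1, keepdims=True)
        sensors = SensorArray(pos_s, ori)
        f = dipole_field(DipoleSource((0.0, 0.0, 0.04), (2e-8, 0.0, 0.0)), sensors, sph)
        assert f[0] == pytest.approx(-f[1], rel=1e-12)

    def test_radial_projection_matches_biot_savart(self, helmet, sph):
        # volume currents contribute no radial field in a sphere, so the
        # radial (sensor-oriented) component must equal the bare current
        # dipole's Biot-Savart field -- an independent closed form.
        pos = np.array([0.02, 0.01, 0.03])
        q = 2e-8 * tangential_unit(pos, sph)
        measured = dipole_field(DipoleSource(tuple(pos), tuple(q)), helmet, sph)
        a = helmet.positions - pos
        b_primary = (
            1e-7 * np.cross(q, a) / np.linalg.norm(a, axis=1, keepdims=True) ** 3 * 1e15
        )
        oracle = np.einsum("sj,sj->s", b_primary, helmet.orientations)
        np.testing.assert_allclose(
            measured, oracle, rtol=1e-10, atol=np.abs(oracle).max() * 1e-12
        )

    def test_depth_attenuation(self, helmet, sph):
        direction = np.array([0.6, 0.3, 0.2])
        direction /= np.linalg.norm(direction)
        rms = []
        for radius in np.linspace(0.06, 0.01, 8):
            pos = direction * radius
            q = 2e-8 * tangential_unit(pos, sph)
            f = dipole_field(DipoleSource(tuple(pos), tuple(q)), helmet, sph)
            rms.append(np.sqrt(np.mean(f**2)))
        assert np.all(np.diff(rms) < 0)

    def test_invalid_dipole_positions(self, helmet, sph):
        with pytest.raises(ValueError, match="outside"):
            dipole_field(DipoleSource((0.2, 0.0, 0.0), (0.0, 1e-8, 0.0)), helmet, sph)
        with pytest.raises(ValueError, match="center"):
            dipole_field(DipoleSource((0.0, 0.0, 0.0), (0.0, 1e-8, 0.0)), helmet, sph)


class TestLeadField:
    def test_consistency_with_dipole_field(self, helmet, sph):
        point = np.array([0.01, 0.02, 0.03])
        lf = compute_leadfield(point[None, :], helmet, sph)
        for m, unit in enumerate(np.eye(3)):
            direct = dipole_field(DipoleSource(tuple(point), tuple(unit)), helmet, sph)
            np.testing.assert_allclose(lf.gain[0, m], direct, rtol=1e-12)

    def test_grid_point_outside_rejected_with_index(self, helmet, sph):
        grid = np.array([[0.0, 0.0, 0.03], [0.0, 0.0, 0.095]])
        with pytest.raises(ValueError, match="index 1"):
            compute_leadfield(grid, helmet, sph)

    def test_gain_finite(self, helmet, sph):
        grid = make_grid(sph, spacing=0.03)
        lf = compute_leadfield(grid, helmet, sph)
        assert np.all(np.isfinite(lf.gain))

    def test_grid_avoids_center_and_boundary(self, sph):
        grid = make_grid(sph, spacing=0.0075)
        radii = np.linalg.norm(grid, axis=1)
        assert radii.min() > 1e-4
        assert radii.max() <= 0.9 * sph.radius + 1e-12


class TestHelmet:
    def test_full_count_and_radial_orientation(self):
        helmet = make_helmet(n_sensors=248, radius=0.105)
        assert helmet.n_sensors == 248
        np.testing.assert_allclose(np.linalg.norm(helmet.orientations, axis=1), 1.0)
        np.testing.assert_allclose(
            helmet.positions, 0.105 * helmet.orientations, atol=1e-12
        )

    def test_single_sensor_at_apex(self):
        helmet = make_helmet(n_sensors=1, radius=0.1)
        np.testing.assert_allclose(helmet.positions, [[0.0, 0.0, 0.1]])

    def test_positive_minimum_angular_spacing(self):
        helmet = make_helmet(n_sensors=248)
        dots = helmet.orientations @ helmet.orientations.T
        np.fill_diagonal(dots, -1.0)
        min_angle = np.arccos(np.clip(dots.max(), -1, 1))
        assert min_angle > np.deg2rad(1.0)

    def test_invalid_cap_angle(self):
        with pytest.raises(ValueError, match="cap_angle"):
            make_helmet(n_sensors=10, cap_angle=4.0)


class TestForwardIO:
    def test_sensor_and_leadfield_roundtrip(self, tmp_path, sph):
        from deepmeg.forward import (
            compute_leadfield,
            make_grid,
            make_helmet,
            read_leadfield,
            read_sensors,
            write_leadfield,
            write_sensors,
        )

        sensors = make_helmet(16)
        write_sensors(sensors, tmp_path / "sensors.json")
        back = read_sensors(tmp_path / "sensors.json")
        np.testing.assert_allclose(back.positions, sensors.positions)
        grid = make_grid(sph, spacing=0.04)
        lf = compute_leadfield(grid, sensors, sph, spacing=0.04)
        write_leadfield(lf, tmp_path / "lf")
        lf2 = read_leadfield(tmp_path / "lf")
        np.testing.assert_allclose(lf2.gain, lf.gain)
        np.testing.assert_allclose(lf2.grid, lf.grid)
        assert lf2.sphere.radius == sph.radius
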