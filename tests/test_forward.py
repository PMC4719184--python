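"""Forward-model correctness: closed-form oracle, series, sampling, I/O."""

import numpy as np
import pytest

from neuroref.exceptions import ValidationError
from neuroref.forward import (
    Dipole,
    HeadModel,
    SourceGrid,
    build_leadfield,
    make_source_grid,
    potential_sphere1,
    potential_sphere3,
    read_leadfield,
    sample_dipoles,
    write_leadfield,
)


class TestHomogeneousSphere:
    def test_central_dipole_cosine_field(self, mon71, sphere1):
        """A central z-dipole produces a field proportional to cos(theta),
        equal in magnitude and opposite in sign at antipodal latitudes."""
        d = Dipole([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        v = potential_sphere1(d, mon71, sphere1)
        pos = mon71.positions
        cos_theta = pos[:, 2] / np.linalg.norm(pos, axis=1)
        expected = 3.0 * cos_theta / (4.0 * np.pi * 92.0**2)
        np.testing.assert_allclose(v, expected, rtol=1e-12)

    def test_linearity_in_moment(self, mon21, sphere1, rng):
        p = rng.standard_normal(3)
        pos = [10.0, -20.0, 30.0]
        v1 = potential_sphere1(Dipole(pos, p), mon21, sphere1)
        v2 = potential_sphere1(Dipole(pos, 2.0 * p), mon21, sphere1)
        np.testing.assert_allclose(v2, 2.0 * v1, rtol=1e-12)

    def test_dipole_outside_rejected(self, mon21, sphere1):
        with pytest.raises(ValidationError, match="outside"):
            potential_sphere1(Dipole([0, 0, 93.0], [1, 0, 0]), mon21, sphere1)


class TestShellSeries:
    def test_equal_conductivities_reduce_to_closed_form(
        self, mon71, sphere1, sphere3_equal, rng
    ):
        """The layered series with equal conductivities must match the
        homogeneous closed form (independent oracle) to < 1e-6 relative."""
        for _ in range(5):
            pos = rng.standard_normal(3)
            pos *= rng.uniform(0.0, 70.0) / np.linalg.norm(pos)
            d = Dipole(pos, rng.standard_normal(3))
            v_closed = potential_sphere1(d, mon71, sphere1)
            v_series = potential_sphere3(d, mon71, sphere3_equal, n_terms=150)
            rel = np.linalg.norm(v_series - v_closed) / np.linalg.norm(v_closed)
            assert rel < 1e-6

    def test_series_convergence_mid_depth(self, mon71, sphere3):
        d = Dipole([0.0, 0.5 * sphere3.brain_radius_mm, 0.0], [1.0, 0.5, 0.2])
        v60 = potential_sphere3(d, mon71, sphere3, n_terms=60)
        v120 = potential_sphere3(d, mon71, sphere3, n_terms=120)
        assert np.linalg.norm(v60 - v120) / np.linalg.norm(v120) < 1e-8

    def test_resistive_skull_attenuates_scalp_potential(
        self, mon71, sphere3, sphere3_equal
    ):
        d = Dipole([0.0, 30.0, 20.0], [1.0, 0.5, 0.3])
        v_skull = potential_sphere3(d, mon71, sphere3)
        v_equal = potential_sphere3(d, mon71, sphere3_equal)
        assert np.abs(v_skull).max() < np.abs(v_equal).max()

    def test_rotation_invariance(self, sphere3, mon256, rng):
        """Rotating dipole and montage together leaves potentials unchanged
        (isotropy of the spherical conductor)."""
        ang = 0.7
        rot = np.array(
            [[np.cos(ang), 0, np.sin(ang)], [0, 1, 0], [-np.sin(ang), 0, np.cos(ang)]]
        )
        pos = np.array([15.0, -25.0, 35.0])
        mom = np.array([0.3, -1.1, 0.6])
        v = potential_sphere3(Dipole(pos, mom), mon256, sphere3)
        mon_rot = mon256.with_positions(mon256.positions @ rot.T)
        v_rot = potential_sphere3(Dipole(rot @ pos, rot @ mom), mon_rot, sphere3)
        np.testing.assert_allclose(v_rot, v, rtol=1e-9, atol=1e-15)


class TestLeadfield:
    def test_single_source_shape_and_columns(self, mon21, sphere3):
        grid = SourceGrid(positions=np.array([[0.0, 20.0, 30.0]]), spacing_mm=0.0)
        lf = build_leadfield(sphere3, mon21, grid)
        assert lf.gain.shape == (21, 3)
        for k, axis in enumerate(np.eye(3)):
            v = potential_sphere3(Dipole(grid.positions[0], axis), mon21, sphere3)
            np.testing.assert_allclose(lf.gain[:, k], v, rtol=1e-10)

    def test_superposition(self, lf128_coarse, rng):
        s1 = rng.standard_normal(lf128_coarse.gain.shape[1])
        s2 = rng.standard_normal(lf128_coarse.gain.shape[1])
        lhs = lf128_coarse.gain @ (s1 + s2)
        rhs = lf128_coarse.gain @ s1 + lf128_coarse.gain @ s2
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-18)

    def test_round_trip(self, tmp_path, lf128_coarse):
        path = tmp_path / "lf.tsv"
        write_leadfield(lf128_coarse, path)
        back = read_leadfield(path)
        np.testing.assert_array_equal(back.gain, lf128_coarse.gain)
        assert back.channel_labels == lf128_coarse.channel_labels
        assert back.model_ref == lf128_coarse.model_ref

    def test_missing_sidecar_and_shape_mismatch(self, tmp_path, lf128_coarse):
        path = tmp_path / "lf.tsv"
        write_leadfield(lf128_coarse, path)
        import json

        sidecar = tmp_path / "lf.json"
        meta = json.loads(sidecar.read_text())
        sidecar.unlink()
        with pytest.raises(ValidationError, match="regenerate"):
            read_leadfield(path)
        meta["n_sources"] += 1
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValidationError, match="shape"):
            read_leadfield(path)


class TestSourceSampling:
    def test_sample_count_margin_and_determinism(self, sphere3):
        a = sample_dipoles(sphere3, 100, seed=4)
        b = sample_dipoles(sphere3, 100, seed=4)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (100, 3)
        rmax = sphere3.brain_radius_mm * 0.9
        assert np.all(np.linalg.norm(a, axis=1) < rmax + 1e-12)

    def test_uniformity_mean_radius(self, sphere3):
        """For a uniform ball the mean radius is 3/4 of the maximum."""
        pts = sample_dipoles(sphere3, 100_000, seed=9)
        rmax = sphere3.brain_radius_mm * 0.9
        mean_r = np.linalg.norm(pts, axis=1).mean()
        assert abs(mean_r - 0.75 * rmax) / (0.75 * rmax) < 0.01

    def test_margin_validation(self, sphere3):
        with pytest.raises(ValidationError):
            sample_dipoles(sphere3, 5, seed=0, depth_margin_mm=1000.0)

    def test_grid_inside_brain(self, sphere3):
        grid = make_source_grid(sphere3, spacing_mm=10.0)
        assert grid.n_sources > 100
        assert np.all(
            np.linalg.norm(grid.positions, axis=1) <= 0.9 * sphere3.brain_radius_mm
        )
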