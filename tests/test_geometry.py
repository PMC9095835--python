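"""Toy head geometry and the analytic sphere forward model."""

import numpy as np
import pytest

from tcdeeg.geometry import (GeometryError, SphereModel, build_toy_mesh,
                             compute_lead_field, load_mesh_obj,
                             load_montage_sfp, mesh_adjacency,
                             place_electrodes, save_mesh_obj,
                             save_montage_sfp, _sphere_dipole_potential)


def legendre_series_potential(dip_pos, dip_mom, elec_pos, radius,
                              conductivity, nmax=400):
    """Independent oracle: truncated Legendre-series solution of the
    homogeneous-sphere Neumann problem, summed term by term."""
    out = np.zeros((len(elec_pos), len(dip_pos)))
    for j, (r0, m) in enumerate(zip(dip_pos, dip_mom)):
        b = np.linalg.norm(r0)
        r0h = r0 / b
        for i, e in enumerate(elec_pos):
            eh = e / np.linalg.norm(e)
            x = float(eh @ r0h)
            mr = float(m @ r0h)
            me = float(m @ eh)
            tot = 0.0
            p_prev, p_cur = 1.0, x            # P_0, P_1
            dp_prev, dp_cur = 0.0, 1.0        # P_0', P_1'
            f = b / radius
            fpow = 1.0                        # f ** (n - 1)
            for n in range(1, nmax + 1):
                coef = (2 * n + 1) / n * fpow / radius ** 2
                tot += coef * (n * mr * p_cur + (me - x * mr) * dp_cur)
                fpow *= f
                p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
                dp_next = dp_prev + (2 * n + 1) * p_cur
                p_prev, p_cur = p_cur, p_next
                dp_prev, dp_cur = dp_cur, dp_next
            out[i, j] = tot / (4 * np.pi * conductivity)
    return out


class TestToyMesh:
    @pytest.mark.parametrize("level,n_vertices,n_faces",
                             [(0, 12, 20), (1, 42, 80), (3, 642, 1280)])
    def test_icosphere_combinatorics(self, level, n_vertices, n_faces):
        m = build_toy_mesh(level, 70.0)
        assert m.n_vertices == n_vertices
        assert len(m.faces) == n_faces

    @pytest.mark.parametrize("level", [0, 1, 2, 3])
    def test_euler_characteristic_of_closed_surface(self, level):
        m = build_toy_mesh(level, 70.0)
        edges = np.vstack([m.faces[:, [0, 1]], m.faces[:, [1, 2]],
                           m.faces[:, [2, 0]]])
        n_edges = len(np.unique(np.sort(edges, axis=1), axis=0))
        assert m.n_vertices - n_edges + len(m.faces) == 2

    def test_vertices_on_requested_radius_with_unit_normals(self, mesh):
        assert np.allclose(mesh.eccentricity, 70.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(mesh.vertex_normals, axis=1),
                           1.0, atol=1e-9)

    def test_radial_modulation_varies_eccentricity(self):
        m = build_toy_mesh(2, 70.0, radial_modulation=0.2)
        assert np.ptp(m.eccentricity) > 5.0

    def test_invalid_level_rejected(self):
        with pytest.raises(GeometryError):
            build_toy_mesh(6, 70.0)


class TestMontage:
    def test_positions_on_scalp_sphere(self):
        mo = place_electrodes(32, 90.0)
        assert np.allclose(np.linalg.norm(mo.positions, axis=1), 90.0,
                           atol=1e-6)

    def test_deterministic(self):
        a = place_electrodes(32, 90.0)
        b = place_electrodes(32, 90.0)
        assert a.labels == b.labels
        assert np.array_equal(a.positions, b.positions)

    def test_no_coincident_electrodes_at_128(self):
        mo = place_electrodes(128, 90.0)
        u = mo.positions / 90.0
        cosang = np.clip(u @ u.T, -1, 1)
        np.fill_diagonal(cosang, -1)
        min_angle = np.arccos(cosang.max())
        assert min_angle > 0

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(GeometryError):
            place_electrodes(7, 90.0)


class TestLeadField:
    def test_average_reference_columns(self, leadfield):
        assert np.abs(leadfield.gain.sum(axis=0)).max() < 1e-9

    def test_linearity_and_superposition(self, rng):
        R, sigma = 0.09, 0.33
        pos = rng.uniform(-0.05, 0.05, (2, 3))
        mom = rng.normal(0, 1e-12, (2, 3))
        elec = rng.standard_normal((12, 3))
        elec = elec / np.linalg.norm(elec, axis=1, keepdims=True) * R
        v = _sphere_dipole_potential(pos, mom, elec, R, sigma)
        v2 = _sphere_dipole_potential(pos, 2 * mom, elec, R, sigma)
        assert np.allclose(v2, 2 * v, rtol=1e-12)
        both = _sphere_dipole_potential(pos, mom, elec, R, sigma).sum(axis=1)
        assert np.allclose(both, v[:, 0] + v[:, 1], rtol=1e-12)

    def test_closed_form_matches_series_oracle(self, rng):
        R, sigma = 0.09, 0.33
        pos = rng.uniform(-0.045, 0.045, (5, 3))
        mom = rng.normal(0, 1e-12, (5, 3))
        elec = rng.standard_normal((8, 3))
        elec = elec / np.linalg.norm(elec, axis=1, keepdims=True) * R
        got = _sphere_dipole_potential(pos, mom, elec, R, sigma)
        want = legendre_series_potential(pos, mom, elec, R, sigma)
        rel = np.abs(got - want).max() / np.abs(want).max()
        assert rel < 1e-3

    def test_depth_attenuation_along_radial_line(self):
        # same orientation, same radial line: deeper source is weaker
        R, sigma = 0.09, 0.33
        direction = np.array([0.3, 0.5, 0.81])
        direction /= np.linalg.norm(direction)
        mom = np.array([[0.0, 1e-12, 0.0]] * 2)
        elec = place_electrodes(64, 90.0).positions * 1e-3
        norms = []
        for depth in (0.070, 0.050, 0.030):
            v = _sphere_dipole_potential(direction[None] * depth, mom[:1],
                                         elec, R, sigma)
            v = v - v.mean(axis=0, keepdims=True)
            norms.append(np.linalg.norm(v))
        assert norms[0] > norms[1] > norms[2]

    def test_rotation_equivariance(self, rng):
        from scipy.spatial.transform import Rotation
        R, sigma = 0.09, 0.33
        rot = Rotation.from_rotvec([0.3, -0.7, 1.1]).as_matrix()
        pos = rng.uniform(-0.05, 0.05, (3, 3))
        mom = rng.normal(0, 1e-12, (3, 3))
        elec = rng.standard_normal((10, 3))
        elec = elec / np.linalg.norm(elec, axis=1, keepdims=True) * R
        v = _sphere_dipole_potential(pos, mom, elec, R, sigma)
        v_rot = _sphere_dipole_potential(pos @ rot.T, mom @ rot.T,
                                         elec @ rot.T, R, sigma)
        assert np.allclose(v, v_rot, atol=1e-9 * np.abs(v).max())

    def test_vertex_outside_sphere_rejected(self, montage):
        m = build_toy_mesh(0, 95.0)
        with pytest.raises(GeometryError):
            compute_lead_field(m, montage, SphereModel(scalp_radius=90.0))


class TestIO:
    def test_mesh_obj_roundtrip(self, tmp_path):
        m = build_toy_mesh(1, 70.0)
        path = tmp_path / "mesh.obj"
        save_mesh_obj(m, path)
        m2 = load_mesh_obj(path)
        assert np.allclose(m.vertex_positions, m2.vertex_positions, atol=1e-6)
        assert np.array_equal(m.faces, m2.faces)
        assert np.allclose(m.vertex_normals, m2.vertex_normals, atol=1e-6)

    def test_montage_sfp_roundtrip(self, tmp_path):
        mo = place_electrodes(16, 90.0)
        path = tmp_path / "montage.sfp"
        save_montage_sfp(mo, path)
        mo2 = load_montage_sfp(path)
        assert mo.labels == mo2.labels
        assert np.allclose(mo.positions, mo2.positions, atol=1e-6)


def test_mesh_adjacency_symmetric(mesh):
    nbrs = mesh_adjacency(mesh)
    for i, s in enumerate(nbrs):
        assert i not in s
        for j in s:
            assert i in nbrs[j]
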