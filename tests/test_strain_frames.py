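"""Regional frames, spontaneous-strain tensors and rest-length programming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapeprog.strain_frames import (REGION_DVB, REGION_OUTDVB_D, REGION_OUTDVB_V,
                                     assemble_strain_tensor,
                                     assign_regions_and_frames, field_from_profile,
                                     preset_patterns, ramped_rest_length,
                                     spring_strain, target_rest_lengths)


@pytest.fixture(scope="module")
def radial_frame(cap_f5):
    return assign_regions_and_frames(cap_f5, w_DV=0.0)


@pytest.fixture(scope="module")
def band_frame(cap_f5):
    return assign_regions_and_frames(cap_f5, w_DV=15.0)


class TestFrames:
    def test_orthonormal_basis(self, radial_frame):
        B = radial_frame.basis()
        gram = np.einsum("nij,nik->njk", B, B)
        assert np.abs(gram - np.eye(3)).max() < 1e-10

    def test_normal_is_radial(self, cap_f5, radial_frame):
        u = cap_f5.vertices / np.linalg.norm(cap_f5.vertices, axis=1, keepdims=True)
        assert np.abs(radial_frame.e3 - u).max() < 1e-12

    def test_radial_mode_coordinate(self, cap_f5, radial_frame):
        """With w_DV = 0 the coordinate reduces to theta / theta_M."""
        theta = np.arccos(cap_f5.vertices[:, 2] / np.linalg.norm(cap_f5.vertices, axis=1))
        expected = theta / theta.max()
        assert np.abs(radial_frame.coord - expected).max() < 1e-9

    def test_e1_points_along_increasing_theta_on_meridian(self, cap_f5, radial_frame):
        """On the x-z meridian the radial axis is the polar tangent."""
        x = cap_f5.vertices
        on_meridian = (np.abs(x[:, 1]) < 1e-9) & (x[:, 0] > 1.0)
        assert on_meridian.sum() > 0
        theta = np.arccos(x[on_meridian, 2] / np.linalg.norm(x[on_meridian], axis=1))
        tangent = np.column_stack([np.cos(theta), np.zeros_like(theta), -np.sin(theta)])
        dots = np.einsum("ij,ij->i", radial_frame.e1[on_meridian], tangent)
        assert np.all(dots > 1 - 1e-9)

    def test_band_regions_partition(self, cap_f5, band_frame):
        counts = {r: int(np.sum(band_frame.region == r))
                  for r in (REGION_OUTDVB_D, REGION_OUTDVB_V, REGION_DVB)}
        assert sum(counts.values()) == cap_f5.n_vertices
        assert counts[REGION_DVB] > 0
        # the band holds the vertices near the dividing plane x = 0
        u = cap_f5.vertices / np.linalg.norm(cap_f5.vertices, axis=1, keepdims=True)
        band_dist = np.abs(np.arcsin(u[:, 0])) * cap_f5.R
        in_band = band_frame.region == REGION_DVB
        assert band_dist[in_band].max() <= 7.5 + 1e-9
        assert band_dist[~in_band].min() > 7.5 - 1e-9

    def test_coordinates_normalised(self, band_frame):
        assert band_frame.coord.min() >= 0.0
        assert band_frame.coord.max() <= 1.0 + 1e-12

    def test_band_too_wide_rejected(self, cap_f5):
        with pytest.raises(ValueError):
            assign_regions_and_frames(cap_f5, w_DV=2 * cap_f5.R * cap_f5.theta_M)


class TestStrainTensor:
    def test_identity(self, radial_frame):
        f = assemble_strain_tensor(1.0, 1.0, radial_frame)
        assert np.abs(f.tensor - np.eye(3)).max() < 1e-12

    def test_in_frame_components(self, radial_frame):
        f = assemble_strain_tensor(1.1, 1.2, radial_frame)
        e1, e2, e3 = radial_frame.e1, radial_frame.e2, radial_frame.e3
        t11 = np.einsum("ni,nij,nj->n", e1, f.tensor, e1)
        t22 = np.einsum("ni,nij,nj->n", e2, f.tensor, e2)
        t33 = np.einsum("ni,nij,nj->n", e3, f.tensor, e3)
        reg = ~radial_frame.singular
        assert np.abs(t11[reg] - 1.32).max() < 1e-12
        assert np.abs(t22[reg] - 1.1 / 1.2).max() < 1e-12
        assert np.abs(t33 - 1.0).max() < 1e-12

    @given(lam=st.floats(0.5, 2.0), lam_t=st.floats(0.5, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_inplane_determinant_and_spd(self, cap_f5, lam, lam_t):
        frame = assign_regions_and_frames(cap_f5, w_DV=0.0)
        f = assemble_strain_tensor(lam, lam_t, frame)
        # determinant of the full tensor equals the in-plane determinant lam^2
        assert np.abs(np.linalg.det(f.tensor) - lam**2).max() < 1e-8
        eig = np.linalg.eigvalsh(0.5 * (f.tensor + f.tensor.transpose(0, 2, 1)))
        assert eig.min() > 0

    def test_nonpositive_factors_rejected(self, radial_frame):
        with pytest.raises(ValueError):
            assemble_strain_tensor(-1.0, 1.0, radial_frame)


class TestSpringProgramming:
    def test_spring_tensor_is_endpoint_mean(self, cap_f5, radial_frame):
        f = assemble_strain_tensor(1.0 + radial_frame.coord, 1.0, radial_frame)
        Ta = spring_strain(f, cap_f5.springs)
        s0 = cap_f5.springs[0]
        assert np.allclose(Ta[0], 0.5 * (f.tensor[s0[0]] + f.tensor[s0[1]]))

    def test_lab_frame_averaging_differs_from_componentwise(self, cap_f5, radial_frame):
        """On a curved pair the endpoint frames differ, so averaging in lab
        coordinates is not the same as averaging local components."""
        f = assemble_strain_tensor(1.0, 1.3, radial_frame)
        # find a spring whose endpoint frames differ appreciably
        s = cap_f5.springs
        d = np.linalg.norm(radial_frame.e1[s[:, 0]] - radial_frame.e1[s[:, 1]], axis=1)
        a = int(np.argmax(d))
        lab_mean = 0.5 * (f.tensor[s[a, 0]] + f.tensor[s[a, 1]])
        naive = np.zeros((3, 3))
        for v in s[a]:
            e1, e2, e3 = radial_frame.e1[v], radial_frame.e2[v], radial_frame.e3[v]
        naive = 1.3 * np.outer(e1, e1) + (1 / 1.3) * np.outer(e2, e2) + np.outer(e3, e3)
        assert not np.allclose(lab_mean, naive, atol=1e-6)

    def test_identity_field_keeps_rest_lengths(self, cap_f5, radial_frame):
        f = assemble_strain_tensor(1.0, 1.0, radial_frame)
        assert np.array_equal(target_rest_lengths(cap_f5, f), cap_f5.rest_lengths)

    def test_uniform_isotropic_scaling_exact_on_flat_sheet(self):
        """On a flat sheet every in-layer spring scales exactly by c (the
        thickness-wise factor is 1, so vertical springs stay put); on a cap
        the chord sag makes the in-layer ratio approximate."""
        from shapeprog.cap_lattice import TriMesh, build_from_surface

        n = 6
        xx, yy = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
        faces = []
        for j in range(n - 1):
            for i in range(n - 1):
                a = j * n + i
                faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
        sheet = build_from_surface(TriMesh(verts, np.array(faces)), 0.5,
                                   normals=np.tile([0.0, 0.0, 1.0], (n * n, 1)))
        frame = type(self)._flat_frame(sheet)
        c = 1.4
        f = assemble_strain_tensor(c, 1.0, frame)
        delta = target_rest_lengths(sheet, f)
        in_layer = sheet.kinds != 2
        ratio = delta[in_layer] / sheet.rest_lengths[in_layer]
        assert np.abs(ratio - c).max() < 1e-12
        vertical = (sheet.kinds == 2) & (
            np.abs(sheet.reference[sheet.springs[:, 0], 2]
                   - sheet.reference[sheet.springs[:, 1], 2]) > 0.49)
        flat_vertical = vertical & (np.linalg.norm(
            sheet.reference[sheet.springs[:, 0], :2]
            - sheet.reference[sheet.springs[:, 1], :2], axis=1) < 1e-12)
        assert np.abs(delta[flat_vertical] - sheet.rest_lengths[flat_vertical]).max() < 1e-12

    @staticmethod
    def _flat_frame(sheet):
        from shapeprog.strain_frames import RegionalFrame

        n = sheet.n_vertices
        return RegionalFrame(
            region=np.zeros(n, dtype=int),
            e1=np.tile([1.0, 0.0, 0.0], (n, 1)),
            e2=np.tile([0.0, 1.0, 0.0], (n, 1)),
            e3=np.tile([0.0, 0.0, 1.0], (n, 1)),
            coord=np.zeros(n),
            origin_D=np.zeros(3), origin_V=np.zeros(3),
        )

    def test_uniform_isotropic_on_cap_within_chord_sag(self, cap_f5, radial_frame):
        c = 1.4
        f = assemble_strain_tensor(c, 1.0, radial_frame)
        delta = target_rest_lengths(cap_f5, f)
        in_layer = cap_f5.kinds != 2
        ratio = delta[in_layer] / cap_f5.rest_lengths[in_layer]
        assert np.abs(ratio - c).max() < c * 0.01

    def test_oblique_spring_matrix_norm_oracle(self):
        """|T . dX| for a 45-degree in-plane spring against direct arithmetic."""
        T = np.diag([1.2, 1 / 1.2, 1.0])
        dX = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        expected = np.linalg.norm(T @ dX)
        assert expected == pytest.approx(np.sqrt((1.2**2 + 1.2**-2) / 2))

    @pytest.mark.parametrize("T, T_F, frac", [(0, 5, 0.0), (5, 5, 1.0), (2, 5, 0.4)])
    def test_linear_ramp(self, T, T_F, frac):
        assert ramped_rest_length(1.0, 3.0, T, T_F) == pytest.approx(1.0 + 2.0 * frac)

    def test_ramp_bounds(self):
        with pytest.raises(ValueError):
            ramped_rest_length(1.0, 2.0, 1, 0)


class TestPresetsAndProfiles:
    def test_uniform_preset(self, radial_frame):
        f = preset_patterns("uniform", radial_frame, lam=1.05)
        assert np.allclose(f.lam, 1.05)
        assert np.allclose(f.lam_t, 1.0)

    def test_iso_gradient_monotone(self, radial_frame):
        f = preset_patterns("iso_gradient", radial_frame, a=0.2)
        order = np.argsort(radial_frame.coord)
        assert np.all(np.diff(f.lam[order]) >= -1e-12)

    def test_tangential_preset_contracts_e1(self, radial_frame):
        f = preset_patterns("aniso_tangential", radial_frame, a=0.5)
        e1 = radial_frame.e1
        t11 = np.einsum("ni,nij,nj->n", e1, f.tensor, e1)
        reg = ~radial_frame.singular & (radial_frame.coord < 0.9)
        assert np.all(t11[reg] < 1.0)

    def test_unknown_preset(self, radial_frame):
        with pytest.raises(ValueError):
            preset_patterns("nope", radial_frame)

    def test_profile_interpolation_roundtrip(self, radial_frame, tmp_path):
        table = pd.DataFrame({
            "region": "outDVB",
            "coordinate": [0.0, 0.5, 1.0],
            "lambda_iso": [1.0, 1.1, 1.2],
            "lambda_aniso": [1.0, 1.0, 1.0],
        })
        f = field_from_profile(table, radial_frame)
        expected = np.interp(radial_frame.coord, [0, 0.5, 1], [1.0, 1.1, 1.2])
        assert np.abs(f.lam - expected).max() < 1e-12
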