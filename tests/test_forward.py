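"""Forward models: SSNP pair propagation, BPM, first Born."""

import math

import numpy as np
import pytest

from ltomo.core import (
    ComplexField2D,
    OpticalGrid,
    RIVolume,
    incident_field_values,
    incident_pair,
    propagating_mask,
    snap_illumination,
    transverse_frequency_grid,
)
from ltomo.bpm import (
    bpm_diffraction_step,
    bpm_phase_step,
    bpm_propagate,
    first_born_predict,
)
from ltomo.ssnp import (
    field_to_pair,
    make_pair_propagator,
    pair_to_forward_field,
    propagate_pair,
    scatter_update,
    ssnp_propagate,
)


class TestPairPropagator:
    def test_zero_step_is_identity(self, grid2d):
        ker = make_pair_propagator(grid2d, 0.0)
        np.testing.assert_array_equal(ker.A, 1.0)
        np.testing.assert_array_equal(ker.B, 0.0)
        np.testing.assert_array_equal(ker.C, 0.0)
        np.testing.assert_array_equal(ker.D, 1.0)

    def test_unit_determinant_on_propagating_disk(self, grid2d):
        ker = make_pair_propagator(grid2d, 0.17)
        mask = propagating_mask(grid2d)
        det = ker.A * ker.D - ker.B * ker.C
        np.testing.assert_allclose(det[mask], 1.0, atol=1e-12)

    def test_grazing_limit_series(self):
        # at kz = 0 the propagator tends to A=1, B=dz, C=0, D=1
        g = OpticalGrid(nx=4, ny=1, nz=1, dx=0.15, dz=0.15, wavelength=0.6)
        kx, _, _ = transverse_frequency_grid(g)
        lam = 2 * math.pi / abs(kx[1, 0])
        g2 = OpticalGrid(nx=4, ny=1, nz=1, dx=0.15, dz=0.15, wavelength=lam)
        ker = make_pair_propagator(g2, 0.15)
        assert ker.A[1, 0] == pytest.approx(1.0, abs=1e-12)
        assert ker.B[1, 0] == pytest.approx(0.15, abs=1e-9)
        assert abs(ker.C[1, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_plane_wave_eigenvector(self, grid2d):
        """Applying the kernel to (1, i kz) multiplies by exp(i kz dz)."""
        il = snap_illumination(grid2d, 0.25 * grid2d.k_med, 0.0)
        dz = 0.21
        pair = incident_pair(il, grid2d, 0.0)
        out = propagate_pair(pair, dz)
        expect = pair.u.values * np.exp(1j * il.kz * dz)
        np.testing.assert_allclose(out.u.values, expect, rtol=1e-12)
        np.testing.assert_allclose(out.dudz.values, 1j * il.kz * expect, rtol=1e-12)

    def test_composition_semigroup(self, grid2d, rng):
        u = rng.normal(size=grid2d.shape_transverse) + 1j * rng.normal(
            size=grid2d.shape_transverse
        )
        pair = field_to_pair(ComplexField2D(u, z=0.0, grid=grid2d))
        twice = propagate_pair(propagate_pair(pair, 0.1), 0.1)
        once = propagate_pair(pair, 0.2)
        np.testing.assert_allclose(twice.u.values, once.u.values, atol=1e-12)
        np.testing.assert_allclose(twice.dudz.values, once.dudz.values, atol=1e-11)

    def test_energy_conserved_by_homogeneous_propagation(self, grid2d, rng):
        from scipy import fft as sfft

        u = rng.normal(size=grid2d.shape_transverse) + 1j * rng.normal(
            size=grid2d.shape_transverse
        )
        pair = field_to_pair(ComplexField2D(u, z=0.0, grid=grid2d))
        mask = propagating_mask(grid2d)
        before = np.abs(sfft.fft2(pair_to_forward_field(pair).values)[mask]) ** 2
        after_pair = propagate_pair(pair, 1.3)
        after = np.abs(sfft.fft2(pair_to_forward_field(after_pair).values)[mask]) ** 2
        np.testing.assert_allclose(after.sum(), before.sum(), rtol=1e-10)


class TestScatterUpdate:
    def test_homogeneous_slice_is_identity(self, grid2d):
        il = snap_illumination(grid2d, 0.0, 0.0)
        pair = incident_pair(il, grid2d, 0.0)
        n_slice = np.full(grid2d.shape_transverse, grid2d.n0)
        out = scatter_update(pair, n_slice, grid2d, grid2d.dz)
        np.testing.assert_array_equal(out.dudz.values, pair.dudz.values)

    def test_linearity_in_scattering_potential(self, grid2d, rng):
        il = snap_illumination(grid2d, 0.2 * grid2d.k_med, 0.0)
        pair = incident_pair(il, grid2d, 0.0)
        base = np.full(grid2d.shape_transverse, grid2d.n0**2)
        d1 = 0.01 * rng.random(grid2d.shape_transverse)
        n1 = np.sqrt(base + d1)
        n2 = np.sqrt(base + 2 * d1)  # doubled n^2 - n0^2
        inc1 = scatter_update(pair, n1, grid2d, 0.15).dudz.values - pair.dudz.values
        inc2 = scatter_update(pair, n2, grid2d, 0.15).dudz.values - pair.dudz.values
        np.testing.assert_allclose(inc2, 2 * inc1, rtol=1e-10)

    def test_shape_mismatch_rejected(self, grid2d):
        pair = incident_pair(snap_illumination(grid2d, 0.0, 0.0), grid2d, 0.0)
        with pytest.raises(ValueError):
            scatter_update(pair, np.ones((3, 3)), grid2d, 0.15)


class TestSsnpPropagate:
    @pytest.mark.parametrize("deg", [0.0, 20.0, 45.0])
    def test_homogeneous_volume_exact_phase_advance(self, deg):
        g = OpticalGrid(nx=64, ny=1, nz=16, dx=0.15, dz=0.15, wavelength=0.6)
        il = snap_illumination(g, g.k_med * math.sin(math.radians(deg)), 0.0)
        pair = ssnp_propagate(RIVolume.homogeneous(g), il)
        expect = incident_field_values(il, g, g.exit_z)
        np.testing.assert_allclose(pair.u.values, expect, atol=1e-13)
        np.testing.assert_allclose(pair.dudz.values, 1j * il.kz * expect, atol=1e-12)

    def test_weak_single_slice_matches_first_born(self, rng):
        g = OpticalGrid(nx=64, ny=1, nz=1, dx=0.15, dz=0.15, wavelength=0.6)
        il = snap_illumination(g, 0.3 * g.k_med, 0.0)
        x = 1e-4 * rng.random(g.shape_volume)
        vol = RIVolume.from_contrast(x, g)
        u_ssnp = pair_to_forward_field(ssnp_propagate(vol, il)).values
        u_born = first_born_predict(vol, il).values
        scat = u_born - incident_field_values(il, g, g.exit_z)
        rel = np.linalg.norm(u_ssnp - u_born) / np.linalg.norm(scat)
        assert rel < 1e-6

    def test_slice_reversal_symmetry_at_normal_incidence(self, rng):
        """Reversing an axially symmetric volume leaves exit intensity unchanged."""
        g = OpticalGrid(nx=32, ny=1, nz=10, dx=0.15, dz=0.15, wavelength=0.6)
        half = 0.03 * rng.random((g.nx, 1, 5))
        x = np.concatenate([half, half[:, :, ::-1]], axis=2)
        il = snap_illumination(g, 0.0, 0.0)
        a = ssnp_propagate(RIVolume.from_contrast(x, g), il)
        b = ssnp_propagate(RIVolume.from_contrast(x[:, :, ::-1], g), il)
        np.testing.assert_allclose(
            np.abs(a.u.values), np.abs(b.u.values), rtol=1e-10
        )


class TestPairFieldConversions:
    def test_forward_plane_wave_recovered_exactly(self, grid2d):
        il = snap_illumination(grid2d, 0.25 * grid2d.k_med, 0.0)
        pair = incident_pair(il, grid2d, 0.0)
        np.testing.assert_allclose(
            pair_to_forward_field(pair).values, pair.u.values, atol=1e-12
        )

    def test_backward_plane_wave_maps_to_zero(self, grid2d):
        il = snap_illumination(grid2d, 0.25 * grid2d.k_med, 0.0)
        u = incident_field_values(il, grid2d, 0.0)
        pair = field_to_pair(ComplexField2D(u, z=0.0, grid=grid2d))
        backward = ComplexField2D(-pair.dudz.values, z=0.0, grid=grid2d)
        from ltomo.core import FieldPair

        bw = FieldPair(u=pair.u, dudz=backward)
        np.testing.assert_allclose(
            pair_to_forward_field(bw).values, 0.0, atol=1e-12
        )

    def test_forward_backward_mixture_keeps_forward_half(self, grid2d):
        from ltomo.core import FieldPair

        il = snap_illumination(grid2d, 0.25 * grid2d.k_med, 0.0)
        u = incident_field_values(il, grid2d, 0.0)
        mix = FieldPair(
            u=ComplexField2D(2 * u, z=0.0, grid=grid2d),
            dudz=ComplexField2D(1j * il.kz * u - 1j * il.kz * u, z=0.0, grid=grid2d),
        )  # u_fwd = u_bwd = u
        np.testing.assert_allclose(pair_to_forward_field(mix).values, u, atol=1e-12)

    def test_roundtrip_identity_for_band_limited_fields(self, grid2d, rng):
        u = rng.normal(size=grid2d.shape_transverse) + 1j * rng.normal(
            size=grid2d.shape_transverse
        )
        from scipy import fft as sfft

        mask = propagating_mask(grid2d)
        u = sfft.ifft2(np.where(mask, sfft.fft2(u), 0.0))
        f = ComplexField2D(u, z=0.0, grid=grid2d)
        rt = pair_to_forward_field(field_to_pair(f))
        np.testing.assert_allclose(rt.values, f.values, atol=1e-12)

    def test_derivative_spectrum_is_ikz_times_input(self, grid2d, rng):
        from scipy import fft as sfft

        u = rng.normal(size=grid2d.shape_transverse) + 1j * rng.normal(
            size=grid2d.shape_transverse
        )
        pair = field_to_pair(ComplexField2D(u, z=0.0, grid=grid2d))
        _, _, kz = transverse_frequency_grid(grid2d)
        mask = propagating_mask(grid2d)
        duh = sfft.fft2(pair.dudz.values)
        uh = sfft.fft2(u)
        np.testing.assert_allclose(
            duh[mask], (1j * kz.real * uh)[mask], atol=1e-10
        )


class TestBpm:
    def test_diffraction_plane_wave_phase_advance(self, grid2d):
        il = snap_illumination(grid2d, 0.25 * grid2d.k_med, 0.0)
        u = incident_field_values(il, grid2d, 0.0)
        f = ComplexField2D(u, z=0.0, grid=grid2d)
        out = bpm_diffraction_step(f, grid2d, 0.3)
        np.testing.assert_allclose(
            out.values, u * np.exp(1j * il.kz * 0.3), rtol=1e-12
        )

    def test_diffraction_zero_step_identity(self, grid2d, rng):
        u = rng.normal(size=grid2d.shape_transverse) + 0j
        f = ComplexField2D(u, z=0.0, grid=grid2d)
        np.testing.assert_allclose(
            bpm_diffraction_step(f, grid2d, 0.0).values, u, atol=1e-13
        )

    def test_diffraction_semigroup(self, grid2d, rng):
        u = rng.normal(size=grid2d.shape_transverse) + 1j * rng.normal(
            size=grid2d.shape_transverse
        )
        f = ComplexField2D(u, z=0.0, grid=grid2d)
        twice = bpm_diffraction_step(
            bpm_diffraction_step(f, grid2d, 0.1), grid2d, 0.1
        )
        once = bpm_diffraction_step(f, grid2d, 0.2)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_phase_step_closed_form(self):
        # k0 * 0.05 * 0.15 at lambda = 0.6 um -> 0.0785 rad
        g = OpticalGrid(nx=8, ny=1, nz=1, dx=0.15, dz=0.15, wavelength=0.6)
        il = snap_illumination(g, 0.0, 0.0)
        f = ComplexField2D(np.ones(g.shape_transverse, complex), z=0.0, grid=g)
        n_slice = np.full(g.shape_transverse, 1.05)
        out = bpm_phase_step(f, n_slice, g, 0.15, il)
        phase = np.angle(out.values[0, 0])
        assert phase == pytest.approx(2 * math.pi / 0.6 * 0.05 * 0.15, rel=1e-12)
        assert phase == pytest.approx(0.0785, abs=2e-4)

    def test_oblique_path_cosine_law(self):
        g = OpticalGrid(nx=64, ny=1, nz=1, dx=0.15, dz=0.15, wavelength=0.6)
        il60 = snap_illumination(g, g.k_med * math.sin(math.radians(60)), 0.0)
        # snapping shifts the angle slightly; use the snapped cos(theta)
        f = ComplexField2D(np.ones(g.shape_transverse, complex), z=0.0, grid=g)
        n_slice = np.full(g.shape_transverse, 1.02)
        il0 = snap_illumination(g, 0.0, 0.0)
        p0 = np.angle(bpm_phase_step(f, n_slice, g, 0.15, il0).values[0, 0])
        p60 = np.angle(bpm_phase_step(f, n_slice, g, 0.15, il60).values[0, 0])
        assert p60 / p0 == pytest.approx(1.0 / il60.cos_theta, rel=1e-12)

    def test_homogeneous_volume_free_space(self, grid2d):
        il = snap_illumination(grid2d, 0.2 * grid2d.k_med, 0.0)
        out = bpm_propagate(RIVolume.homogeneous(grid2d), il)
        np.testing.assert_allclose(
            out.values, incident_field_values(il, grid2d, grid2d.exit_z), atol=1e-12
        )

    def test_weak_thin_object_matches_ssnp(self, rng):
        g = OpticalGrid(nx=64, ny=1, nz=1, dx=0.15, dz=0.15, wavelength=0.6)
        il = snap_illumination(g, 0.0, 0.0)
        x = 1e-4 * rng.random(g.shape_volume)
        vol = RIVolume.from_contrast(x, g)
        u_bpm = bpm_propagate(vol, il).values
        u_ssnp = pair_to_forward_field(ssnp_propagate(vol, il)).values
        rel = np.linalg.norm(u_bpm - u_ssnp) / np.linalg.norm(u_bpm)
        assert rel < 1e-4


class TestFirstBorn:
    def test_zero_contrast_returns_incident(self, grid3d):
        il = snap_illumination(grid3d, 0.2 * grid3d.k_med, 0.0)
        out = first_born_predict(RIVolume.homogeneous(grid3d), il)
        np.testing.assert_allclose(
            out.values,
            incident_field_values(il, grid3d, grid3d.exit_z),
            atol=1e-12,
        )

    def test_scattered_field_linear_in_potential(self, grid3d, rng):
        il = snap_illumination(grid3d, 0.0, 0.0)
        u_inc = incident_field_values(il, grid3d, grid3d.exit_z)
        base = grid3d.n0**2
        d = 0.01 * rng.random(grid3d.shape_volume)
        v1 = RIVolume(np.sqrt(base + d), grid3d)
        v2 = RIVolume(np.sqrt(base + 2 * d), grid3d)
        s1 = first_born_predict(v1, il).values - u_inc
        s2 = first_born_predict(v2, il).values - u_inc
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-10)

    def test_superposition_over_random_volumes(self, grid3d, rng):
        il = snap_illumination(grid3d, 0.15 * grid3d.k_med, 0.1 * grid3d.k_med)
        u_inc = incident_field_values(il, grid3d, grid3d.exit_z)
        base = grid3d.n0**2
        da = 0.01 * rng.random(grid3d.shape_volume)
        db = 0.01 * rng.random(grid3d.shape_volume)
        sa = first_born_predict(RIVolume(np.sqrt(base + da), grid3d), il).values - u_inc
        sb = first_born_predict(RIVolume(np.sqrt(base + db), grid3d), il).values - u_inc
        sab = (
            first_born_predict(RIVolume(np.sqrt(base + da + db), grid3d), il).values
            - u_inc
        )
        np.testing.assert_allclose(sab, sa + sb, rtol=1e-9)

    def test_single_voxel_matches_greens_function_sum(self):
        """One isolated weak voxel reproduces the brute-force Green's sum.

        The model is transversely periodic, so the oracle is the direct sum
        of the free-space 2D Green's function over the voxel and its lattice
        images; the voxel sits far enough from the exit plane that the
        (dropped) evanescent content is negligible.
        """
        from scipy.special import hankel1

        g = OpticalGrid(nx=192, ny=1, nz=96, dx=0.14, dz=0.14, wavelength=0.6)
        L = g.nx * g.dx
        il = snap_illumination(g, 0.0, 0.0)
        x = np.zeros(g.shape_volume)
        iz = 16
        x[g.nx // 2, 0, iz] = 1e-4
        vol = RIVolume.from_contrast(x, g)
        scat = (
            first_born_predict(vol, il).values
            - incident_field_values(il, g, g.exit_z)
        )[:, 0]
        f_val = g.k0**2 * ((g.n0 + 1e-4) ** 2 - g.n0**2)
        src_z = (iz + 0.5) * g.dz
        src_x = g.x_coords()[g.nx // 2, 0]
        xs = g.x_coords()[:, 0]
        zp = g.exit_z - src_z
        oracle = np.zeros(g.nx, dtype=complex)
        M = 20000
        for chunk in np.array_split(np.arange(-M, M + 1), 60):
            R = np.sqrt((xs[:, None] - src_x - chunk[None, :] * L) ** 2 + zp**2)
            oracle += (0.25j * hankel1(0, g.k_med * R)).sum(axis=1)
        oracle *= f_val * np.exp(1j * il.kz * src_z) * g.dx * g.dz
        rel = np.linalg.norm(scat - oracle) / np.linalg.norm(oracle)
        assert rel < 0.01
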