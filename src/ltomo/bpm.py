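"""Baseline forward models: beam propagation method (BPM) and first Born.

The BPM alternates non-paraxial angular-spectrum diffraction with a thin
phase screen.  Diffraction uses the homogeneous kernel exp(i kz dz) (the
total field, not an envelope); the screen approximates the sample term as
k0 n(x,y,z) ~ k0 n0 and modulates the phase by the oblique path
k0 (n - n0) dz / cos(theta), where cos(theta) = kz/k_med is a single scalar
of the current illumination, fixed for the whole volume.  That fixed oblique
path is precisely the BPM's limitation for multiply-scattering samples and is
deliberately kept.

The first-Born model is the single-scattering linearization used by "linear
tomography": each slice contributes its scattering potential
f = k0^2 (n^2 - n0^2) times the *incident* field, propagated to the exit
plane with the homogeneous kernel and the i/(2 kz) obliquity factor of the
scalar Green's function.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

from .core import (
    ComplexField2D,
    OpticalGrid,
    PlaneWaveIllumination,
    RIVolume,
    incident_field_values,
    propagating_mask,
    transverse_frequency_grid,
)


def _diffraction_kernel(grid: OpticalGrid, dz: float) -> np.ndarray:
    """exp(i kz dz): oscillatory on the propagating disk, decaying outside."""
    _, _, kz = transverse_frequency_grid(grid)
    return np.exp(1j * kz * dz)


def bpm_diffraction_step(
    field: ComplexField2D, grid: OpticalGrid | None = None, dz: float | None = None
) -> ComplexField2D:
    """Angular-spectrum free-space propagation over dz.

    Evanescent frequencies are attenuated by exp(-kappa dz).
    """
    grid = grid or field.grid
    dz = grid.dz if dz is None else dz
    ker = _diffraction_kernel(grid, dz)
    out = sfft.ifft2(ker * sfft.fft2(field.values))
    return ComplexField2D(out, z=field.z + dz, grid=grid)


def bpm_phase_step(
    field: ComplexField2D,
    n_slice: np.ndarray,
    grid: OpticalGrid,
    dz: float,
    illum: PlaneWaveIllumination,
) -> ComplexField2D:
    """Thin phase screen exp(i k0 (n - n0) dz / cos(theta))."""
    cos_theta = illum.cos_theta
    if cos_theta <= 0:
        raise ValueError("cos(theta) must be positive")
    n_slice = np.asarray(n_slice, dtype=float)
    if n_slice.shape != grid.shape_transverse:
        raise ValueError("slice shape does not match grid")
    phase = grid.k0 * (n_slice - grid.n0) * dz / cos_theta
    return ComplexField2D(field.values * np.exp(1j * phase), z=field.z, grid=grid)


def bpm_propagate(
    volume: RIVolume,
    illum: PlaneWaveIllumination,
    return_states: bool = False,
):
    """Run the BPM through ``volume``; returns the exit-plane field.

    Diffraction and phase screens alternate symmetrically (half-step
    diffraction at the entrance and exit) so each slice's screen acts at
    its center plane z = (k + 0.5) dz, mirroring the SSNP arrangement.

    With ``return_states=True`` additionally returns the slice-center
    (pre-screen) fields for the adjoint sweep.
    """
    grid = volume.grid
    ker_half = _diffraction_kernel(grid, grid.dz / 2.0)
    ker_full = _diffraction_kernel(grid, grid.dz)
    u = incident_field_values(illum, grid, 0.0)
    scale = grid.k0 * grid.dz / illum.cos_theta
    states = [] if return_states else None
    u = sfft.ifft2(ker_half * sfft.fft2(u))
    for k in range(grid.nz):
        if return_states:
            states.append(u)
        u = u * np.exp(1j * scale * (volume.n[:, :, k] - grid.n0))
        if k < grid.nz - 1:
            u = sfft.ifft2(ker_full * sfft.fft2(u))
    u = sfft.ifft2(ker_half * sfft.fft2(u))
    field = ComplexField2D(u, z=grid.exit_z, grid=grid)
    if return_states:
        return field, states
    return field


# angular-aperture margin for the Born obliquity factor: frequencies with
# kz <= margin*k_med are dropped so 1/(2 kz) stays bounded
_BORN_KZ_MARGIN = 0.02


def _born_slice_kernels(grid: OpticalGrid) -> tuple[np.ndarray, np.ndarray]:
    """Apertured propagating mask and i/(2 kz) obliquity factor on it."""
    _, _, kz = transverse_frequency_grid(grid)
    mask = propagating_mask(grid, margin=_BORN_KZ_MARGIN)
    kzr = np.where(mask, kz.real, 1.0)
    obliquity = np.where(mask, 1j / (2.0 * kzr), 0.0)
    return mask, obliquity


def first_born_predict(
    volume: RIVolume,
    illum: PlaneWaveIllumination,
    grid: OpticalGrid | None = None,
) -> ComplexField2D:
    """Single-scattering prediction of the exit-plane field.

    u = u_inc + u_s with, per slice k (scattering event on the slice-center
    plane z = (k + 0.5) dz, consistent with the symmetric multislice
    arrangement),

        u_s_hat += exp(i kz (nz-k-0.5) dz) * (i/(2 kz)) * FFT[f_k u_inc,k] * dz

    where f = k0^2 (n^2 - n0^2).  Contributions are accumulated in the
    frequency domain; evanescent frequencies are dropped.
    """
    grid = grid or volume.grid
    _, _, kz = transverse_frequency_grid(grid)
    mask, obliquity = _born_slice_kernels(grid)
    kzr_phase = np.where(mask, kz.real, 0.0)
    k0sq = grid.k0**2
    n0sq = grid.n0**2
    dz = grid.dz
    acc = np.zeros(grid.shape_transverse, dtype=complex)
    for k in range(grid.nz):
        z_k = (k + 0.5) * dz
        u_inc_k = incident_field_values(illum, grid, z_k)
        f_k = k0sq * (volume.n[:, :, k] ** 2 - n0sq)
        src = sfft.fft2(f_k * u_inc_k)
        acc += np.exp(1j * kzr_phase * (grid.nz - k - 0.5) * dz) * obliquity * src * dz
    u_s = sfft.ifft2(np.where(mask, acc, 0.0))
    u_inc = incident_field_values(illum, grid, grid.exit_z)
    return ComplexField2D(u_inc + u_s, z=grid.exit_z, grid=grid)


__all__ = [
    "bpm_diffraction_step",
    "bpm_phase_step",
    "bpm_propagate",
    "first_born_predict",
]
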