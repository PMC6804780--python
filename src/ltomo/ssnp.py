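"""Split-step non-paraxial (SSNP) multislice forward model.

SSNP propagates the pair state v = (u, du/dz) through the sample.  Writing
the Helmholtz equation as a first-order system dv/dz = H v, H splits exactly
into a homogeneous part (diffraction, diagonal in the transverse FFT basis)
and a scattering part k0^2 (n^2 - n0^2) that only updates the derivative
component.  Unlike the BPM, no approximation of the refractive-index term is
needed: the phase modulation enters the derivative and takes effect in the
next diffraction step.

The homogeneous system per transverse frequency is

    d/dz [u; u'] = [[0, 1], [-kz^2, 0]] [u; u'],   kz^2 = k_med^2 - kx^2 - ky^2

whose exact propagator over a step dz is

    [[cos(kz dz),        sin(kz dz)/kz],
     [-kz sin(kz dz),    cos(kz dz)  ]].

For evanescent frequencies (kz = i*kappa) the analytic continuation
cosh/sinh contains a growing exponential e^{+kappa dz}.  Iterated over many
slices that mode amplifies FFT roundoff without bound, so the evanescent
kernel is restricted to the decaying eigenmode: M = e^{-kappa dz} P_d where
P_d projects onto the (1, -kappa) eigenvector.  This is exact for decaying
content, satisfies the semigroup property M(a)M(b) = M(a+b), and carries no
growing mode at all.  ``dz = 0`` is special-cased to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import fft as sfft

from .core import (
    ComplexField2D,
    FieldPair,
    OpticalGrid,
    PlaneWaveIllumination,
    RIVolume,
    incident_field_values,
    propagating_mask,
    transverse_frequency_grid,
)

@dataclass(frozen=True)
class PairPropagatorKernel:
    """2x2 per-frequency transfer matrix (A, B; C, D) for a step dz."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    dz: float


@lru_cache(maxsize=64)
def _pair_propagator_cached(grid: OpticalGrid, dz: float) -> PairPropagatorKernel:
    _, _, kz = transverse_frequency_grid(grid)
    shape = grid.shape_transverse
    if dz == 0.0:
        A = np.ones(shape, dtype=complex)
        B = np.zeros(shape, dtype=complex)
        C = np.zeros(shape, dtype=complex)
        D = np.ones(shape, dtype=complex)
    else:
        real = kz.imag == 0
        kzr = np.where(real, kz.real, 0.0)
        phi = kzr * dz
        A = np.cos(phi).astype(complex)
        # sin(x)/x -> dz at kz = 0 (grazing limit)
        B = np.where(kzr > 1e-12, np.sin(phi) / np.where(kzr > 0, kzr, 1.0), dz).astype(
            complex
        )
        C = (-kzr * np.sin(phi)).astype(complex)
        D = A.copy()
        # evanescent bins: decaying eigenmode only, M = e^{-kappa dz} * P_d
        kappa = np.where(~real, np.maximum(kz.imag, 1e-9), 1.0)
        decay = np.exp(-kappa * dz)
        A[~real] = (0.5 * decay)[~real]
        B[~real] = (-0.5 * decay / kappa)[~real]
        C[~real] = (-0.5 * decay * kappa)[~real]
        D[~real] = (0.5 * decay)[~real]
    for arr in (A, B, C, D):
        arr.setflags(write=False)
    return PairPropagatorKernel(A=A, B=B, C=C, D=D, dz=dz)


def make_pair_propagator(grid: OpticalGrid, dz: float) -> PairPropagatorKernel:
    """Exact homogeneous pair propagator exp(H0*dz) per FFT frequency."""
    if dz < 0:
        raise ValueError("dz must be >= 0")
    return _pair_propagator_cached(grid, float(dz))


def _apply_kernel(
    u: np.ndarray, du: np.ndarray, ker: PairPropagatorKernel, conjugate: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the kernel (or its adjoint) in the frequency domain to raw arrays."""
    uh = sfft.fft2(u)
    dh = sfft.fft2(du)
    if conjugate:
        # adjoint: M^H = [[conj A, conj C], [conj B, conj D]]
        uo = np.conj(ker.A) * uh + np.conj(ker.C) * dh
        do = np.conj(ker.B) * uh + np.conj(ker.D) * dh
    else:
        uo = ker.A * uh + ker.B * dh
        do = ker.C * uh + ker.D * dh
    return sfft.ifft2(uo), sfft.ifft2(do)


def propagate_pair(pair: FieldPair, dz: float) -> FieldPair:
    """Propagate a pair through a homogeneous slab of thickness dz."""
    grid = pair.grid
    ker = make_pair_propagator(grid, dz)
    u, du = _apply_kernel(pair.u.values, pair.dudz.values, ker)
    z = pair.z + dz
    return FieldPair(
        u=ComplexField2D(u, z=z, grid=grid),
        dudz=ComplexField2D(du, z=z, grid=grid),
    )


def scatter_update(
    pair: FieldPair, n_slice: np.ndarray, grid: OpticalGrid, dz: float
) -> FieldPair:
    """Apply one slice's scattering potential to the derivative component.

    u is unchanged; du/dz <- du/dz - k0^2 (n^2 - n0^2) u dz, pointwise in
    real space.
    """
    n_slice = np.asarray(n_slice, dtype=float)
    if n_slice.shape != grid.shape_transverse:
        raise ValueError("slice shape does not match grid")
    q = grid.k0**2 * (n_slice**2 - grid.n0**2)
    du = pair.dudz.values - q * pair.u.values * dz
    return FieldPair(
        u=pair.u,
        dudz=ComplexField2D(du, z=pair.z, grid=grid),
    )


def ssnp_propagate(
    volume: RIVolume,
    illum: PlaneWaveIllumination,
    return_states: bool = False,
):
    """Run the SSNP multislice model through ``volume``.

    Starting from the incident pair on the entrance plane, the homogeneous
    pair propagator (frequency domain) and the per-slice scattering update
    (real space) alternate in a symmetric arrangement: a half step dz/2 of
    diffraction, then scatter / full-step diffraction / ... / scatter, then
    a closing half step.  Each slice's update is thereby applied exactly at
    its center plane z = (k + 0.5) dz -- the same coordinates the scene
    builders and the direct Rytov inversion use -- and the total homogeneous
    path is exactly nz*dz.  Returns the pair at the measurement plane
    ``z = nz*dz``.

    With ``return_states=True``, additionally returns the list of
    slice-center ``u`` arrays needed by the adjoint gradient sweep.
    """
    grid = volume.grid
    ker_half = make_pair_propagator(grid, grid.dz / 2.0)
    ker_full = make_pair_propagator(grid, grid.dz)
    u = incident_field_values(illum, grid, 0.0)
    du = 1j * illum.kz * u
    k0sq = grid.k0**2
    n0sq = grid.n0**2
    dz = grid.dz
    states = [] if return_states else None
    u, du = _apply_kernel(u, du, ker_half)
    for k in range(grid.nz):
        if return_states:
            states.append(u)
        q = k0sq * (volume.n[:, :, k] ** 2 - n0sq)
        du = du - q * u * dz
        if k < grid.nz - 1:
            u, du = _apply_kernel(u, du, ker_full)
    u, du = _apply_kernel(u, du, ker_half)
    z = grid.exit_z
    pair = FieldPair(
        u=ComplexField2D(u, z=z, grid=grid),
        dudz=ComplexField2D(du, z=z, grid=grid),
    )
    if return_states:
        return pair, states
    return pair


def pair_to_forward_field(pair: FieldPair, grid: OpticalGrid | None = None) -> ComplexField2D:
    """Extract the forward-travelling field component of a pair.

    In the frequency domain ``u+ = (u_hat + du_hat/(i kz))/2`` on the
    propagating disk; evanescent frequencies are set to zero.
    """
    grid = grid or pair.grid
    _, _, kz = transverse_frequency_grid(grid)
    mask = propagating_mask(grid)
    uh = sfft.fft2(pair.u.values)
    dh = sfft.fft2(pair.dudz.values)
    out = np.zeros_like(uh)
    kzr = np.where(mask, kz.real, 1.0)
    out[mask] = 0.5 * (uh[mask] + dh[mask] / (1j * kzr[mask]))
    return ComplexField2D(sfft.ifft2(out), z=pair.z, grid=grid)


def field_to_pair(field: ComplexField2D, grid: OpticalGrid | None = None) -> FieldPair:
    """Pair up a purely forward-travelling field with its axial derivative.

    Holographic measurements are forward-travelling, so ``du_hat = i kz u_hat``
    per frequency (evanescent components zeroed).  This is how measured fields
    enter the SSNP data-fidelity residual.
    """
    grid = grid or field.grid
    _, _, kz = transverse_frequency_grid(grid)
    mask = propagating_mask(grid)
    uh = sfft.fft2(field.values)
    dh = np.where(mask, 1j * kz.real * uh, 0.0)
    return FieldPair(
        u=field,
        dudz=ComplexField2D(sfft.ifft2(dh), z=field.z, grid=grid),
    )


def _forward_projection_arrays(
    u: np.ndarray, du: np.ndarray, grid: OpticalGrid, adjoint: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Project a raw pair onto the forward-travelling band-limited subspace.

    Per propagating frequency the projection is T = v w with
    w = (1/2, 1/(2 i kz)) and v = (1, i kz)^T; evanescent bins map to zero.
    ``adjoint=True`` applies the conjugate transpose (needed by gradients).
    """
    _, _, kz = transverse_frequency_grid(grid)
    mask = propagating_mask(grid)
    kzr = np.where(mask, kz.real, 1.0)
    uh = sfft.fft2(u)
    dh = sfft.fft2(du)
    if adjoint:
        uo = 0.5 * uh - 0.5j * kzr * dh
        do = -1.0 / (2j * kzr) * uh + 0.5 * dh
    else:
        uplus = 0.5 * (uh + dh / (1j * kzr))
        uo = uplus
        do = 1j * kzr * uplus
    uo = np.where(mask, uo, 0.0)
    do = np.where(mask, do, 0.0)
    return sfft.ifft2(uo), sfft.ifft2(do)


def forward_project_pair(pair: FieldPair, grid: OpticalGrid | None = None) -> FieldPair:
    """Forward-travelling part of a pair, as a pair.

    Equivalent to ``field_to_pair(pair_to_forward_field(pair))``; this is the
    form of the SSNP prediction that a holographic measurement can be
    compared against.
    """
    grid = grid or pair.grid
    u, du = _forward_projection_arrays(pair.u.values, pair.dudz.values, grid)
    return FieldPair(
        u=ComplexField2D(u, z=pair.z, grid=grid),
        dudz=ComplexField2D(du, z=pair.z, grid=grid),
    )


__all__ = [
    "PairPropagatorKernel",
    "make_pair_propagator",
    "propagate_pair",
    "scatter_update",
    "ssnp_propagate",
    "pair_to_forward_field",
    "field_to_pair",
    "forward_project_pair",
]
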