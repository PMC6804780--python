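"""Direct tomographic inversion under the Rytov approximation.

This is the classical Wolf-transform reconstruction used as the initial
guess of the learning-tomography loop: per-angle complex-phase extraction
(with 2D least-squares phase unwrapping), mapping of each 2D spectrum onto
its Ewald-sphere cap in the object's 3D Fourier space, vote-averaged
accumulation, Hermitian symmetrization, and an inverse transform back to a
refractive-index volume.

Derivation sketch (Fourier diffraction theorem).  For an incident plane wave
k_i and a weak object with scattering potential f = k0^2 (n^2 - n0^2), the
first-order scattered field measured on the plane z = z_d satisfies

    f_hat(kperp - k_i_perp, kz - k_iz)
        = -2 i kz * Psi_hat(kperp - k_i_perp) * exp(-i (kz - k_iz) z_d)

where Psi_hat is the 2D transform of the Rytov complex phase
psi = ln(u_tot/u_inc) and kz = sqrt(k_med^2 - |kperp|^2) on the propagating
disk.  Limited angular coverage leaves a missing cone in f_hat, producing
the well-known axial elongation and RI underestimation that the iterative
loop subsequently corrects.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import fft as sfft

from .core import (
    ComplexField2D,
    MeasurementSet,
    OpticalGrid,
    RIVolume,
    incident_field_values,
    propagating_mask,
    transverse_frequency_grid,
)

_AMPLITUDE_FLOOR = 1e-12


def unwrap_phase_lsq(wrapped: np.ndarray) -> np.ndarray:
    """Transform-based least-squares 2D phase unwrapping.

    Solves the Poisson equation whose source is the divergence of the
    wrapped phase differences, with Neumann boundaries, via DCTs.  The
    result is deterministic and parameter-free; the additive constant is
    chosen so that the unwrapped phase agrees with the wrapped input in the
    circular mean.
    """
    w = np.asarray(wrapped, dtype=float)
    if w.ndim != 2:
        raise ValueError("expected a 2D phase map")

    def _wrap(a: np.ndarray) -> np.ndarray:
        return (a + np.pi) % (2.0 * np.pi) - np.pi

    dx = np.zeros_like(w)
    dy = np.zeros_like(w)
    dx[:-1, :] = _wrap(w[1:, :] - w[:-1, :])
    dy[:, :-1] = _wrap(w[:, 1:] - w[:, :-1])
    rho = np.zeros_like(w)
    rho[0, :] += dx[0, :]
    rho[1:, :] += dx[1:, :] - dx[:-1, :]
    rho[:, 0] += dy[:, 0]
    rho[:, 1:] += dy[:, 1:] - dy[:, :-1]

    nx, ny = w.shape
    rc = sfft.dctn(rho, type=2, norm="ortho")
    ix = np.arange(nx)[:, None]
    iy = np.arange(ny)[None, :]
    denom = (2.0 * np.cos(np.pi * ix / nx) - 2.0) + (2.0 * np.cos(np.pi * iy / ny) - 2.0)
    denom[0, 0] = 1.0
    phi = rc / denom
    phi[0, 0] = 0.0
    out = sfft.idctn(phi, type=2, norm="ortho")
    # fix the undetermined constant against the wrapped input
    delta = np.angle(np.exp(1j * (w - out)))
    return out + float(np.mean(delta))


def rytov_field(u_total: ComplexField2D, u_inc: ComplexField2D) -> ComplexField2D:
    """Complex Rytov phase psi = ln|u_tot/u_inc| + i unwrap(arg u_tot - arg u_inc)."""
    inc = u_inc.values
    tot = u_total.values
    if np.any(np.abs(inc) == 0):
        raise ValueError("incident field has zero-amplitude pixels")
    amp = np.abs(tot)
    if np.any(amp < _AMPLITUDE_FLOOR):
        warnings.warn(
            "zero-amplitude pixels in the total field; amplitude floored",
            RuntimeWarning,
        )
        amp = np.maximum(amp, _AMPLITUDE_FLOOR)
    log_amp = np.log(amp / np.abs(inc))
    dphi = np.angle(tot) - np.angle(inc)
    phase = unwrap_phase_lsq(np.angle(np.exp(1j * dphi)))
    return ComplexField2D(log_amp + 1j * phase, z=u_total.z, grid=u_total.grid)


def _continuous_ft2(values: np.ndarray, grid: OpticalGrid) -> np.ndarray:
    """Approximate the continuous 2D transform on the (unshifted) FFT grid.

    Accounts for the centered pixel coordinates x0 = (0.5 - n/2) dx.
    """
    kx, ky, _ = transverse_frequency_grid(grid)
    x0 = (0.5 - grid.nx / 2.0) * grid.dx
    y0 = (0.5 - grid.ny / 2.0) * grid.dx
    area = grid.dx * grid.dx if grid.ny > 1 else grid.dx
    return area * sfft.fft2(values) * np.exp(-1j * (kx * x0 + ky * y0))


def wolf_reconstruct(
    measurements: MeasurementSet, splat: str = "nearest"
) -> RIVolume:
    """Direct Rytov/Wolf-transform reconstruction of the RI volume.

    For each angle, the weighted 2D Rytov spectrum is placed on the Ewald
    cap shifted by the illumination wavevector in a 3D spectrum accumulator
    (nearest-voxel rounding, vote-count averaged); the symmetrized inverse
    transform yields the scattering potential f and n = sqrt(n0^2 + f/k0^2)
    floored at zero.
    """
    if splat not in ("nearest", "trilinear"):
        raise ValueError("splat must be 'nearest' or 'trilinear'")
    grid = measurements.grid
    nx, ny, nz = grid.shape_volume
    kxg, kyg, kzg = transverse_frequency_grid(grid)
    mask = propagating_mask(grid)
    kzr = kzg.real
    dkx = 2.0 * math.pi / (nx * grid.dx)
    dky = 2.0 * math.pi / (ny * grid.dx)
    dkz = 2.0 * math.pi / (nz * grid.dz)
    z_d = grid.exit_z - 0.5 * nz * grid.dz  # measurement plane from volume center

    acc = np.zeros((nx, ny, nz), dtype=complex)
    votes = np.zeros((nx, ny, nz))
    for il, fvals in zip(measurements.illuminations, measurements.fields):
        u_inc = incident_field_values(il, grid, grid.exit_z)
        psi = rytov_field(
            ComplexField2D(fvals, z=grid.exit_z, grid=grid),
            ComplexField2D(u_inc, z=grid.exit_z, grid=grid),
        )
        # spectrum of u_inc * psi, i.e. Psi shifted by the illumination
        psi_hat = _continuous_ft2(psi.values * u_inc / np.exp(1j * il.kz * grid.exit_z), grid)
        f_hat = -2j * kzr * psi_hat * np.exp(-1j * (kzr - il.kz) * z_d)
        Kx = kxg - il.kx
        Ky = kyg - il.ky
        Kz = kzr - il.kz
        sel = mask
        fx = Kx[sel] / dkx
        fy = Ky[sel] / dky if ny > 1 else np.zeros(int(sel.sum()))
        fz = Kz[sel] / dkz
        vals = f_hat[sel]
        if splat == "nearest":
            ix = np.rint(fx).astype(int)
            iy = np.rint(fy).astype(int)
            iz = np.rint(fz).astype(int)
            ok = (
                (np.abs(ix) <= nx // 2)
                & (np.abs(iy) <= ny // 2)
                & (np.abs(iz) <= nz // 2)
            )
            np.add.at(acc, (ix[ok] % nx, iy[ok] % ny, iz[ok] % nz), vals[ok])
            np.add.at(votes, (ix[ok] % nx, iy[ok] % ny, iz[ok] % nz), 1.0)
        else:  # trilinear
            bx = np.floor(fx).astype(int)
            by = np.floor(fy).astype(int)
            bz = np.floor(fz).astype(int)
            tx, ty, tz = fx - bx, fy - by, fz - bz
            for ox in (0, 1):
                for oy in (0, 1) if ny > 1 else (0,):
                    for oz in (0, 1):
                        wgt = (
                            (tx if ox else 1 - tx)
                            * ((ty if oy else 1 - ty) if ny > 1 else 1.0)
                            * (tz if oz else 1 - tz)
                        )
                        jx, jy, jz = bx + ox, by + oy, bz + oz
                        ok = (
                            (np.abs(jx) <= nx // 2)
                            & (np.abs(jy) <= ny // 2)
                            & (np.abs(jz) <= nz // 2)
                            & (wgt > 0)
                        )
                        np.add.at(
                            acc, (jx[ok] % nx, jy[ok] % ny, jz[ok] % nz), wgt[ok] * vals[ok]
                        )
                        np.add.at(votes, (jx[ok] % nx, jy[ok] % ny, jz[ok] % nz), wgt[ok])

    filled = votes > 0
    acc[filled] /= votes[filled]
    # Hermitian symmetry: f is real, so f_hat(-K) = conj(f_hat(K))
    rev = np.conj(acc[::-1, ::-1, ::-1])
    rev = np.roll(rev, (1, 1, 1), axis=(0, 1, 2))
    acc = 0.5 * (acc + rev)

    # inverse continuous transform onto centered voxel coordinates
    kx3 = (2.0 * math.pi * np.fft.fftfreq(nx, grid.dx))[:, None, None]
    ky3 = (2.0 * math.pi * np.fft.fftfreq(ny, grid.dx))[None, :, None]
    kz3 = (2.0 * math.pi * np.fft.fftfreq(nz, grid.dz))[None, None, :]
    x0 = (0.5 - nx / 2.0) * grid.dx
    y0 = (0.5 - ny / 2.0) * grid.dx
    z0c = (0.5 - nz / 2.0) * grid.dz
    phase = np.exp(1j * (kx3 * x0 + ky3 * y0 + kz3 * z0c))
    cell = (grid.dx if nx > 1 else 1.0) * (grid.dx if ny > 1 else 1.0) * grid.dz
    f = sfft.ifftn(acc * phase) / cell
    f_real = f.real
    n = np.sqrt(np.maximum(grid.n0**2 + f_real / grid.k0**2, 0.0))
    return RIVolume(n=n, grid=grid)


__all__ = ["unwrap_phase_lsq", "rytov_field", "wolf_reconstruct"]
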