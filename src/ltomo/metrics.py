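"""Quantitative evaluation of reconstructions.

Covers the relative squared-error metric on RI contrast, volume SSIM,
per-angle phase projection error, and the semisynthetic validation loop in
which a reconstruction is fed back through the coupled-dipole scattering
solver and its predicted phases are compared with the reference
measurements.  The semisynthetic loop is how reconstruction accuracy is
scored when no ground-truth RI exists.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import MeasurementSet, OpticalGrid, RIVolume, incident_field_values
from .rytov import unwrap_phase_lsq


def error_metric(x_recon: np.ndarray, x_true: np.ndarray) -> float:
    """Relative squared error ||x_recon - x_true||^2 / ||x_true||^2 on contrast."""
    x_recon = np.asarray(x_recon, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    if x_recon.shape != x_true.shape:
        raise ValueError("volumes must share a grid")
    denom = float(np.sum(x_true**2))
    if denom == 0.0:
        raise ValueError("ground-truth contrast is identically zero")
    return float(np.sum((x_recon - x_true) ** 2)) / denom


def quantize_ri(n_recon: np.ndarray, n0: float) -> np.ndarray:
    """Relative RI quantized to 1e-3 steps: round(n_recon/n0 * 1000)/1000."""
    n_recon = np.asarray(n_recon, dtype=float)
    if np.any(n_recon <= 0):
        raise ValueError("refractive index must be positive")
    return np.round(n_recon / n0 * 1000.0) / 1000.0


def dipole_spacing(wavelength: float, n0: float, dipoles_per_wavelength: int = 12) -> float:
    """Dipole lattice pitch lambda/(12 n0) in um."""
    if wavelength <= 0 or n0 <= 0:
        raise ValueError("wavelength and n0 must be positive")
    return wavelength / (dipoles_per_wavelength * n0)


def resample_to_dipoles(volume: RIVolume, spacing: float | None = None):
    """Interpolate an RI volume onto the dipole lattice and quantize.

    The lattice pitch defaults to lambda/(12 n0) -- twelve dipoles per
    medium wavelength.  Trilinear interpolation of n, then RI quantization
    to 1e-3 relative steps.
    """
    from .scatter import DipoleGrid  # local import to avoid a module cycle

    grid = volume.grid
    a = spacing if spacing is not None else dipole_spacing(grid.wavelength, grid.n0)
    # lattice spans the same physical box as the voxel grid
    px = max(int(round(grid.nx * grid.dx / a)), 1) if grid.nx > 1 else 1
    py = max(int(round(grid.ny * grid.dx / a)), 1) if grid.ny > 1 else 1
    pz = max(int(round(grid.nz * grid.dz / a)), 1)
    x0v = (0.5 - grid.nx / 2.0) * grid.dx
    y0v = (0.5 - grid.ny / 2.0) * grid.dx
    xs = ((np.arange(px) + 0.5) - px / 2.0) * a
    ys = ((np.arange(py) + 0.5) - py / 2.0) * a if py > 1 else np.array([0.0])
    # exact cubic pitch a, lattice centered in the axial box [0, nz*dz]
    zs = grid.nz * grid.dz / 2.0 + ((np.arange(pz) + 0.5) - pz / 2.0) * a
    ix = (xs - x0v) / grid.dx
    iy = (ys - y0v) / grid.dx if py > 1 else np.array([0.0])
    iz = zs / grid.dz - 0.5
    II, JJ, KK = np.meshgrid(ix, iy, iz, indexing="ij")
    n_interp = ndimage.map_coordinates(
        volume.n, [II, JJ, KK], order=1, mode="nearest"
    )
    m = quantize_ri(n_interp, grid.n0)
    origin = (float(xs[0]), float(ys[0]), float(zs[0]))
    return DipoleGrid(
        spacing=a,
        m=m,
        origin=origin,
        n0=grid.n0,
        wavelength=grid.wavelength,
    )


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phases to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


def phase_map(field_values: np.ndarray, illum, grid: OpticalGrid) -> np.ndarray:
    """Unwrapped phase delay of a measured field relative to its plane wave."""
    u_inc = incident_field_values(illum, grid, grid.exit_z)
    d = np.angle(field_values) - np.angle(u_inc)
    return unwrap_phase_lsq(wrap_phase(d))


def projection_error(
    phases_a: np.ndarray, phases_b: np.ndarray
) -> tuple[np.ndarray, float]:
    """Mean absolute phase discrepancy per angle (radians/pixel) and its mean.

    Differences are wrapped to (-pi, pi] before averaging so that isolated
    unwrapping failures cannot dominate the mean.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase stacks must share angles and grids")
    per_angle = np.array([np.mean(np.abs(wrap_phase(ai - bi))) for ai, bi in zip(a, b)])
    return per_angle, float(per_angle.mean())


def ssim_volume(a: np.ndarray, b: np.ndarray, sigma: float = 1.5) -> float:
    """Structural similarity between two volumes.

    Gaussian-weighted local statistics (sigma=1.5, 11-voxel support),
    dynamic range taken from the reference ``b``, averaged over the interior
    (a border of half the window is cropped).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    data_range = float(b.max() - b.min())
    if data_range == 0.0:
        raise ValueError("reference volume has zero dynamic range")
    truncate = 3.5
    radius = int(truncate * sigma + 0.5)

    def filt(x):
        return ndimage.gaussian_filter(x, sigma, truncate=truncate)

    ux = filt(a)
    uy = filt(b)
    uxx = filt(a * a)
    uyy = filt(b * b)
    uxy = filt(a * b)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    K1, K2 = 0.01, 0.03
    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    S = ((2 * ux * uy + C1) * (2 * vxy + C2)) / (
        (ux**2 + uy**2 + C1) * (vx + vy + C2)
    )
    sl = tuple(
        slice(radius, s - radius) if s > 2 * radius else slice(None) for s in S.shape
    )
    return float(S[sl].mean())


def semisynthetic_loop(
    recon_volume: RIVolume,
    measurements_reference: MeasurementSet,
    angle_subset=None,
    spacing: float | None = None,
    dda_rtol: float = 1e-6,
) -> dict:
    """Score a reconstruction against measurements via the dipole solver.

    The reconstruction is resampled onto the dipole lattice (quantized RI),
    the coupled-dipole solver predicts the exit field for each angle in the
    subset, and the predicted unwrapped phases are compared with the
    reference measurements' phases.  Returns per-angle projection errors and
    their mean (radians/pixel).
    """
    from .scatter import dda_solve  # local import to avoid a module cycle

    grid = measurements_reference.grid
    if recon_volume.grid != grid:
        raise ValueError("reconstruction is not on the measurement grid")
    idx = (
        list(range(len(measurements_reference)))
        if angle_subset is None
        else list(angle_subset)
    )
    dipoles = resample_to_dipoles(recon_volume, spacing=spacing)
    pred_phases = []
    ref_phases = []
    for l in idx:
        il = measurements_reference.illuminations[l]
        pred = dda_solve(dipoles, il, grid, rtol=dda_rtol)
        pred_phases.append(phase_map(pred.values, il, grid))
        ref_phases.append(phase_map(measurements_reference.fields[l], il, grid))
    per_angle, mean = projection_error(np.array(pred_phases), np.array(ref_phases))
    return {
        "angles": idx,
        "per_angle_rad_per_pixel": per_angle.tolist(),
        "mean_rad_per_pixel": mean,
    }


__all__ = [
    "error_metric",
    "quantize_ri",
    "dipole_spacing",
    "resample_to_dipoles",
    "wrap_phase",
    "phase_map",
    "projection_error",
    "ssim_volume",
    "semisynthetic_loop",
]
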