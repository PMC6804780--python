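"""Desk-scale reference studies used by the test suite and scripts.

Each study builds its scene from scratch, generates synthetic measurements
with a physically independent generator where feasible, runs the direct
Rytov inversion and the learning-tomography loop, and reports the headline
quantities.  Problem sizes, angle counts and iteration budgets are the
package's single-CPU defaults; docs/methods.md records them.
"""

from __future__ import annotations

import numpy as np

from .core import MeasurementSet, OpticalGrid, RIVolume
from .metrics import error_metric, semisynthetic_loop, ssim_volume
from .rytov import wolf_reconstruct
from .scatter import (
    angle_subsample,
    build_cell_phantom,
    cone_scheme,
    linear_scheme,
    make_measurements,
)
from .solver import ReconstructionConfig, fista_reconstruct


def three_cylinder_volume(grid: OpticalGrid, contrast: float = 0.05) -> RIVolume:
    """Three 6 um cylinders (9 um center-to-center) in a triangle.

    Two cylinders sit upstream and one downstream so oblique illuminations
    traverse multiple scatterers -- the regime where the fixed dz/cos(theta)
    path of the BPM accumulates error.
    """
    xs = grid.x_coords()[:, 0]
    zs = grid.z_slice_centers()
    zc = grid.nz * grid.dz / 2.0
    mask = np.zeros((grid.nx, grid.nz), dtype=bool)
    for ox, oz in [(-4.5, -4.5), (4.5, -4.5), (0.0, 4.5)]:
        mask |= (xs[:, None] - ox) ** 2 + (zs[None, :] - zc - oz) ** 2 <= 9.0
    return RIVolume.from_contrast(
        np.where(mask, contrast, 0.0)[:, None, :], grid
    )


def cylinder_study(
    seed: int = 0,
    nx: int = 256,
    nz: int = 128,
    n_angles: int = 51,
    gamma: float = 1e-4,
    tau: float = 0.04,
    iterations: int = 200,
    batch_size: int = 8,
) -> dict:
    """Multi-cylinder 2D benchmark: Rytov vs LT-BPM vs LT-SSNP.

    Measurements come from the coupled-dipole solver (independent of both
    reconstruction models); both learning loops share one (gamma, tau) pair
    on the BPM scale, with the C calibration applied for the SSNP.  Returns
    the relative reconstruction errors, the reconstructions, the scene and
    the measurements.
    """
    grid = OpticalGrid(
        nx=nx, ny=1, nz=nz, dx=0.15, dz=0.15, wavelength=0.6, n0=1.0
    )
    vol_true = three_cylinder_volume(grid)
    illums = linear_scheme(grid, n_angles, 45.0)
    ms = make_measurements(vol_true, illums, generator="dda", seed=seed)
    init = wolf_reconstruct(ms)
    x_true = vol_true.contrast
    out = {
        "grid": grid,
        "truth": vol_true,
        "measurements": ms,
        "rytov": init,
        "error_rytov": error_metric(init.contrast, x_true),
    }
    for model in ("bpm", "ssnp"):
        cfg = ReconstructionConfig(
            model=model, gamma=gamma, tau=tau, outer_iterations=iterations,
            batch_size=batch_size, rng_seed=seed, cost_every=0,
        )
        res = fista_reconstruct(ms, init, cfg)
        out[f"recon_{model}"] = res.volume
        out[f"error_{model}"] = error_metric(res.volume.contrast, x_true)
    return out


def angle_compression_study(
    seed: int = 0,
    n: int = 64,
    n_angles: int = 60,
    keep: int = 4,
    gamma: float = 5e-4,
    tau: float = 0.04,
    iterations: int = 80,
    batch_size: int = 8,
) -> dict:
    """Angular undersampling on a 3D cell phantom.

    Reconstructs with the full circular scan and with ``keep`` uniformly
    spaced azimuths, for both the direct Rytov inversion and the iterative
    multislice (SSNP) loop, then scores each compressed reconstruction
    against its own full-angle reference by volume SSIM.  Measurements are
    generated with the multislice model itself (a self-consistency setting;
    the comparison isolates robustness to missing angles, not forward-model
    mismatch).
    """
    grid = OpticalGrid(nx=n, ny=n, nz=n, dx=0.15, dz=0.15, wavelength=0.6, n0=1.0)
    vol_true = build_cell_phantom(grid, seed=seed)
    illums = cone_scheme(grid, n_angles, 35.0)
    ms = make_measurements(vol_true, illums, generator="ssnp", seed=seed)
    ms_few = angle_subsample(ms, keep)

    def _lt(m: MeasurementSet) -> RIVolume:
        cfg = ReconstructionConfig(
            model="ssnp", gamma=gamma, tau=tau, outer_iterations=iterations,
            batch_size=batch_size, rng_seed=seed, cost_every=0,
        )
        return fista_reconstruct(m, wolf_reconstruct(m), cfg).volume

    lt_full = _lt(ms)
    lt_few = _lt(ms_few)
    ry_full = wolf_reconstruct(ms)
    ry_few = wolf_reconstruct(ms_few)
    return {
        "grid": grid,
        "truth": vol_true,
        "ssim_lt": ssim_volume(lt_few.n, lt_full.n),
        "ssim_rytov": ssim_volume(ry_few.n, ry_full.n),
        "error_lt_full": error_metric(lt_full.contrast, vol_true.contrast),
        "error_lt_few": error_metric(lt_few.contrast, vol_true.contrast),
        "error_rytov_full": error_metric(ry_full.contrast, vol_true.contrast),
        "error_rytov_few": error_metric(ry_few.contrast, vol_true.contrast),
    }


def semisynthetic_study(study: dict, angle_subset=None) -> dict:
    """Score the cylinder-study reconstructions by the semisynthetic loop.

    Feeds the ground truth (closed-loop control) and both learning-loop
    reconstructions back through the coupled-dipole solver and compares the
    predicted phases with the reference measurements.
    """
    ms = study["measurements"]
    if angle_subset is None:
        L = len(ms)
        angle_subset = list(range(0, L, max(L // 7, 1)))
    out = {"angles": list(angle_subset)}
    for key, vol in (
        ("truth", study["truth"]),
        ("ssnp", study["recon_ssnp"]),
        ("bpm", study["recon_bpm"]),
    ):
        rep = semisynthetic_loop(vol, ms, angle_subset=angle_subset)
        out[f"projection_error_{key}"] = rep["mean_rad_per_pixel"]
    return out


__all__ = [
    "three_cylinder_volume",
    "cylinder_study",
    "angle_compression_study",
    "semisynthetic_study",
]
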