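"""Shared data model for optical diffraction tomography.

Grids, plane-wave illuminations, transverse fields, field/derivative pairs,
refractive-index volumes and measurement sets.  Every other module consumes
these types.

Conventions
-----------
* All lengths are in micrometres, all wavenumbers in rad/um.
* Transverse pixel centers sit at ``(i + 0.5 - n/2) * dx`` so the grid is
  centered on the optical axis.
* The axial coordinate starts at ``z = 0`` on the entrance plane; slice ``k``
  occupies ``[k*dz, (k+1)*dz]`` and the measurement (exit) plane is
  ``z = nz*dz``, i.e. the plane just past the last slice ``K = nz - 1``.
* FFT layout is unshifted (DC at index 0) everywhere; shifted views are
  presentation-only.
* Illumination angles are snapped to the nearest realizable FFT frequency so
  incident plane waves are periodic on the grid; the snapped ``kz`` is the one
  used in all downstream formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np


class NonPropagatingError(ValueError):
    """Raised when an illumination is evanescent (kx^2 + ky^2 >= k_med^2)."""


@dataclass(frozen=True)
class OpticalGrid:
    """Sampling geometry, wavelength and medium index.

    Parameters
    ----------
    nx, ny : int
        Transverse sample counts.  2D (cylinder) scenes use ``ny = 1``.
    nz : int
        Number of axial slices.
    dx : float
        Transverse pixel pitch in um (square pixels).
    dz : float
        Axial slice thickness in um.
    wavelength : float
        Vacuum wavelength in um.
    n0 : float
        Refractive index of the surrounding medium.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dz: float
    wavelength: float
    n0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.dx <= 0 or self.dz <= 0 or self.wavelength <= 0:
            raise ValueError("dx, dz and wavelength must be positive")
        if self.n0 < 1:
            raise ValueError("medium index n0 must be >= 1")

    @property
    def k0(self) -> float:
        """Free-space wavenumber 2*pi/lambda (rad/um)."""
        return 2.0 * math.pi / self.wavelength

    @property
    def k_med(self) -> float:
        """Wavenumber in the surrounding medium, k0*n0 (rad/um)."""
        return self.k0 * self.n0

    @property
    def shape_transverse(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def shape_volume(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def exit_z(self) -> float:
        """Axial position of the measurement plane (um)."""
        return self.nz * self.dz

    def x_coords(self) -> np.ndarray:
        """Pixel-center x coordinates, shape (nx, 1)."""
        return ((np.arange(self.nx) + 0.5 - self.nx / 2.0) * self.dx)[:, None]

    def y_coords(self) -> np.ndarray:
        """Pixel-center y coordinates, shape (1, ny)."""
        return ((np.arange(self.ny) + 0.5 - self.ny / 2.0) * self.dx)[None, :]

    def z_slice_centers(self) -> np.ndarray:
        """Axial slice-center coordinates, shape (nz,)."""
        return (np.arange(self.nz) + 0.5) * self.dz


@lru_cache(maxsize=32)
def _frequency_grid_cached(grid: OpticalGrid):
    kx = 2.0 * math.pi * np.fft.fftfreq(grid.nx, d=grid.dx)
    ky = 2.0 * math.pi * np.fft.fftfreq(grid.ny, d=grid.dx)
    kx2d = np.broadcast_to(kx[:, None], (grid.nx, grid.ny)).copy()
    ky2d = np.broadcast_to(ky[None, :], (grid.nx, grid.ny)).copy()
    arg = grid.k_med**2 - kx2d**2 - ky2d**2
    # principal branch: real on the propagating disk, +i*kappa outside
    kz2d = np.sqrt(arg.astype(complex))
    kx2d.setflags(write=False)
    ky2d.setflags(write=False)
    kz2d.setflags(write=False)
    return kx2d, ky2d, kz2d


def transverse_frequency_grid(grid: OpticalGrid):
    """Per-FFT-sample transverse wavenumbers and the axial wavenumber.

    Returns
    -------
    (kx, ky, kz) : ndarray, shape (nx, ny)
        ``kx``/``ky`` follow the unshifted FFT frequency convention scaled by
        ``2*pi/(n*dx)``.  ``kz = sqrt(k_med^2 - kx^2 - ky^2)`` on the principal
        branch: real on the propagating disk, purely imaginary with positive
        imaginary part outside it.
    """
    return _frequency_grid_cached(grid)


def propagating_mask(grid: OpticalGrid, margin: float = 0.0) -> np.ndarray:
    """Boolean mask of FFT samples inside the propagating disk (kz real > 0).

    ``margin`` excludes near-grazing frequencies with ``kz <= margin*k_med``;
    kernels carrying a 1/kz obliquity factor use a small margin to stay
    bounded (an implicit angular aperture of acos(margin)).
    """
    _, _, kz = transverse_frequency_grid(grid)
    return (kz.imag == 0) & (kz.real > margin * grid.k_med)


@dataclass(frozen=True)
class PlaneWaveIllumination:
    """A forward-travelling plane wave ``exp(i(kx x + ky y + kz z))``.

    ``kz = sqrt(k_med^2 - kx^2 - ky^2)`` is stored explicitly; ``k_med`` is
    kept so that the polar angle is recoverable.
    """

    kx: float
    ky: float
    kz: float
    k_med: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kx**2 + self.ky**2 >= self.k_med**2:
            raise NonPropagatingError(
                "non-propagating illumination: kx^2 + ky^2 >= k_med^2"
            )
        if self.kz <= 0:
            raise ValueError("kz must be positive (forward-travelling wave)")

    @classmethod
    def from_transverse(
        cls, grid: OpticalGrid, kx: float, ky: float, amplitude: float = 1.0
    ) -> "PlaneWaveIllumination":
        k_med = grid.k_med
        if kx**2 + ky**2 >= k_med**2:
            raise NonPropagatingError(
                "non-propagating illumination: kx^2 + ky^2 >= k_med^2"
            )
        kz = math.sqrt(k_med**2 - kx**2 - ky**2)
        return cls(kx=kx, ky=ky, kz=kz, k_med=k_med, amplitude=amplitude)

    @property
    def cos_theta(self) -> float:
        return self.kz / self.k_med

    @property
    def theta(self) -> float:
        """Polar angle in radians, cos(theta) = kz/k_med."""
        return math.acos(min(1.0, self.cos_theta))


def snap_illumination(
    grid: OpticalGrid, kx: float, ky: float, amplitude: float = 1.0
) -> PlaneWaveIllumination:
    """Snap a target transverse wavevector to the nearest FFT frequency.

    Snapped plane waves are exactly periodic on the grid, which prevents
    wrap-around artifacts in the multislice models.
    """
    dkx = 2.0 * math.pi / (grid.nx * grid.dx)
    dky = 2.0 * math.pi / (grid.ny * grid.dx)
    mx = round(kx / dkx) if grid.nx > 1 else 0
    my = round(ky / dky) if grid.ny > 1 else 0
    # if rounding lands on/outside the propagating disk, step back toward DC
    while (mx * dkx) ** 2 + (my * dky) ** 2 >= grid.k_med**2 and (mx or my):
        if abs(mx * dkx) >= abs(my * dky):
            mx -= int(np.sign(mx))
        else:
            my -= int(np.sign(my))
    return PlaneWaveIllumination.from_transverse(grid, mx * dkx, my * dky, amplitude)


@dataclass
class ComplexField2D:
    """Complex scalar field on one transverse plane."""

    values: np.ndarray
    z: float
    grid: OpticalGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.grid.shape_transverse:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid "
                f"{self.grid.shape_transverse}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


@dataclass
class FieldPair:
    """SSNP state v = (u, du/dz) on one transverse plane."""

    u: ComplexField2D
    dudz: ComplexField2D

    def __post_init__(self) -> None:
        if self.u.grid != self.dudz.grid:
            raise ValueError("u and du/dz must share a grid")
        if self.u.z != self.dudz.z:
            raise ValueError("u and du/dz must share an axial position")

    @property
    def grid(self) -> OpticalGrid:
        return self.u.grid

    @property
    def z(self) -> float:
        return self.u.z


@dataclass
class RIVolume:
    """Refractive-index map n(x, y, z) on a grid.

    The optimization variable of the learning-tomography loop is the contrast
    ``x = n - n0``.
    """

    n: np.ndarray
    grid: OpticalGrid

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != self.grid.shape_volume:
            raise ValueError(
                f"volume shape {self.n.shape} does not match grid "
                f"{self.grid.shape_volume}"
            )
        if not np.all(np.isfinite(self.n)):
            raise ValueError("volume contains non-finite values")

    @property
    def contrast(self) -> np.ndarray:
        """RI contrast x = n - n0."""
        return self.n - self.grid.n0

    @classmethod
    def from_contrast(cls, x: np.ndarray, grid: OpticalGrid) -> "RIVolume":
        return cls(n=np.asarray(x, dtype=float) + grid.n0, grid=grid)

    @classmethod
    def homogeneous(cls, grid: OpticalGrid) -> "RIVolume":
        return cls(n=np.full(grid.shape_volume, grid.n0), grid=grid)


@dataclass
class MeasurementSet:
    """Per-angle complex fields measured at the exit plane.

    ``fields[l]`` is the complex field for ``illuminations[l]`` recorded at
    the measurement plane past the last slice ``K = nz - 1``.
    """

    illuminations: list[PlaneWaveIllumination]
    fields: np.ndarray  # (L, nx, ny) complex
    grid: OpticalGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=complex)
        L = len(self.illuminations)
        if L < 1:
            raise ValueError("at least one measurement is required")
        if self.fields.shape != (L,) + self.grid.shape_transverse:
            raise ValueError(
                f"fields shape {self.fields.shape} does not match "
                f"(L={L},) + {self.grid.shape_transverse}"
            )
        keys = {(il.kx, il.ky) for il in self.illuminations}
        if len(keys) != L:
            raise ValueError("illuminations must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.illuminations)

    @property
    def k_index(self) -> int:
        """Index of the measurement slice (the last slice of the volume)."""
        return self.grid.nz - 1

    def subset(self, indices: Sequence[int]) -> "MeasurementSet":
        idx = list(indices)
        return MeasurementSet(
            illuminations=[self.illuminations[i] for i in idx],
            fields=self.fields[idx],
            grid=self.grid,
            meta=dict(self.meta),
        )


def incident_field_values(
    illum: PlaneWaveIllumination, grid: OpticalGrid, z: float
) -> np.ndarray:
    """Raw plane-wave samples exp(i(kx x + ky y + kz z)) at pixel centers."""
    x = grid.x_coords()
    y = grid.y_coords()
    phase = illum.kx * x + illum.ky * y + illum.kz * z
    return illum.amplitude * np.exp(1j * phase)


def incident_field(
    illum: PlaneWaveIllumination, grid: OpticalGrid, z: float
) -> ComplexField2D:
    """Incident plane-wave field on the plane at axial position ``z``."""
    return ComplexField2D(incident_field_values(illum, grid, z), z=z, grid=grid)


def incident_pair(
    illum: PlaneWaveIllumination, grid: OpticalGrid, z: float = 0.0
) -> FieldPair:
    """Incident plane-wave state (u, du/dz) with du/dz = i*kz*u."""
    u = incident_field(illum, grid, z)
    dudz = ComplexField2D(1j * illum.kz * u.values, z=z, grid=grid)
    return FieldPair(u=u, dudz=dudz)


__all__ = [
    "NonPropagatingError",
    "OpticalGrid",
    "PlaneWaveIllumination",
    "ComplexField2D",
    "FieldPair",
    "RIVolume",
    "MeasurementSet",
    "transverse_frequency_grid",
    "propagating_mask",
    "snap_illumination",
    "incident_field",
    "incident_field_values",
    "incident_pair",
]
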