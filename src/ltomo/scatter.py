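"""Ground-truth scenes and physically independent measurement generators.

Provides the analytic Mie partial-wave series for a single infinite
cylinder (the 2D oracle), a scalar coupled-dipole solver for arbitrary
volumes (multiple scattering from a lattice of mutually interacting
dipoles), parametric red-blood-cell and cell-phantom builders, the named
illumination schemes, and the measurement factory.

The entire reconstruction stack is scalar, so the coupled-dipole model is
scalar too: a vector solver would introduce polarization physics the
inversion never models.  In 3D the dipole polarizability follows the
Clausius-Mossotti relation; in 2D (infinite cylinders, field along the
invariant axis) there is no depolarization and the coupling reduces to the
collocation form of the Lippmann-Schwinger equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import fft as sfft
from scipy.sparse.linalg import LinearOperator, bicgstab
from scipy.special import h1vp, hankel1, jv, jvp
from scipy.spatial.transform import Rotation

from .core import (
    ComplexField2D,
    MeasurementSet,
    OpticalGrid,
    PlaneWaveIllumination,
    RIVolume,
    incident_field_values,
    snap_illumination,
)

_MAX_DIPOLES = 2_000_000


class ConvergenceError(RuntimeError):
    """Raised when an iterative scattering solve fails to converge."""


# ---------------------------------------------------------------------------
# Mie series for an infinite cylinder (2D scenes, ny = 1)
# ---------------------------------------------------------------------------


def mie_truncation_order(x_size: float) -> int:
    """Standard partial-wave truncation ceil(x + 4 x^(1/3) + 2)."""
    return int(math.ceil(x_size + 4.0 * x_size ** (1.0 / 3.0) + 2.0))


def mie_cylinder_coefficients(
    k_med: float, radius: float, m_rel: float, max_order: int | None = None
):
    """Scattering (a_m) and interior (c_m) coefficients, orders 0..M.

    Scalar wave with u and du/dr continuous across the cylinder boundary
    (the TM polarization of the electromagnetic problem).
    """
    x = k_med * radius
    x1 = m_rel * x
    M = max_order if max_order is not None else mie_truncation_order(x)
    orders = np.arange(M + 1)
    jx = jv(orders, x)
    jpx = jvp(orders, x)
    hx = hankel1(orders, x)
    hpx = h1vp(orders, x)
    j1 = jv(orders, x1)
    jp1 = jvp(orders, x1)
    num = m_rel * jp1 * jx - j1 * jpx
    den = m_rel * jp1 * hx - j1 * hpx
    a = -num / den
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(np.abs(j1) > 0, (jx + a * hx) / np.where(j1 != 0, j1, 1.0), 0.0)
    return a, c


def mie_cylinder_exit_field(
    diameter: float,
    n_cyl: float,
    illum: PlaneWaveIllumination,
    grid: OpticalGrid,
    exit_plane_z: float | None = None,
    center: tuple[float, float] | None = None,
) -> ComplexField2D:
    """Total field on the exit line for a single infinite cylinder.

    2D scene (``ny = 1``): the cylinder axis is y, the scene plane is (x, z)
    and the illumination travels in-plane with direction (kx, kz).  The
    series is the cylindrical-harmonic expansion with Bessel/Hankel radial
    functions, truncated at ceil(x + 4 x^(1/3) + 2); a residual scattering
    coefficient above 1e-10 at the truncation order raises.
    """
    if grid.ny != 1:
        raise ValueError("Mie cylinder scenes are 2D (ny must be 1)")
    radius = diameter / 2.0
    k = grid.k_med
    m_rel = n_cyl / grid.n0
    z_e = grid.exit_z if exit_plane_z is None else exit_plane_z
    xc, zc = center if center is not None else (0.0, grid.nz * grid.dz / 2.0)
    a, c = mie_cylinder_coefficients(k, radius, m_rel)
    M = len(a) - 1
    if abs(a[M]) > 1e-10:
        raise ConvergenceError(
            f"Mie series not converged at order {M}: |a_M| = {abs(a[M]):.2e}"
        )
    x = grid.x_coords()[:, 0]
    rx = x - xc
    rz = z_e - zc
    r = np.hypot(rx, rz)
    beta = np.arctan2(rz, rx)
    beta_i = math.atan2(illum.kz, illum.kx)
    # global phase of the incident wave at the cylinder center
    phase_c = np.exp(1j * (illum.kx * xc + illum.kz * zc))

    orders = np.arange(M + 1)[:, None]
    dbeta = (beta - beta_i)[None, :]
    cosm = np.cos(orders * dbeta)
    weight = np.where(orders == 0, 1.0, 2.0)
    i_pow = 1j**orders

    out = np.empty_like(r, dtype=complex)
    outside = r >= radius
    if np.any(outside):
        ro = r[outside]
        hr = hankel1(orders, k * ro)
        scat = np.sum(weight * i_pow * a[:, None] * hr * cosm[:, outside], axis=0)
        # incident part summed analytically (the Jacobi-Anger series would
        # need ~k*r terms at far observation points)
        inc = np.exp(1j * k * ro * np.cos(beta[outside] - beta_i))
        out[outside] = inc + scat
    if np.any(~outside):
        ri_ = r[~outside]
        jr1 = jv(orders, m_rel * k * ri_)
        tot = np.sum(weight * i_pow * c[:, None] * jr1 * cosm[:, ~outside], axis=0)
        out[~outside] = tot
    values = (illum.amplitude * phase_c * out)[:, None]
    return ComplexField2D(values, z=z_e, grid=grid)


# ---------------------------------------------------------------------------
# scalar coupled-dipole (DDA) solver
# ---------------------------------------------------------------------------


@dataclass
class DipoleGrid:
    """Regular cubic dipole lattice with per-site relative index m = n/n0.

    ``origin`` is the physical coordinate of lattice site (0, 0, 0); sites
    sit at origin + (i, j, k)*spacing.  2D scenes use a single y layer.
    """

    spacing: float
    m: np.ndarray
    origin: tuple[float, float, float]
    n0: float
    wavelength: float

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 3:
            raise ValueError("m must be a 3D lattice (use a singleton y axis in 2D)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def k_med(self) -> float:
        return 2.0 * math.pi * self.n0 / self.wavelength

    @property
    def is_2d(self) -> bool:
        return self.m.shape[1] == 1

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.m != 1.0))

    def polarizability(self) -> np.ndarray:
        """Per-site coupling beta such that p = beta * u_exciting.

        3D: Clausius-Mossotti, beta = (3 a^3 / 4 pi) (m^2-1)/(m^2+2), used
        with the propagator G = k^2 exp(ikR)/R.  2D: no depolarization for
        the field along the cylinder axis, beta = a^2 k^2 (m^2-1), used with
        G = (i/4) H0(kR).
        """
        a = self.spacing
        msq = self.m**2
        if self.is_2d:
            return a**2 * self.k_med**2 * (msq - 1.0)
        return (3.0 * a**3 / (4.0 * math.pi)) * (msq - 1.0) / (msq + 2.0)


def _crop_to_active(dipoles: DipoleGrid) -> DipoleGrid:
    """Restrict the lattice to the bounding box of sites with m != 1.

    Exact: the coupled system only involves sites with nonzero
    polarizability, and the radiated field is produced by those sites alone.
    """
    active = dipoles.m != 1.0
    if not active.any() or active.all():
        return dipoles
    idx = np.nonzero(active)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    m = dipoles.m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    a = dipoles.spacing
    origin = (
        dipoles.origin[0] + lo[0] * a,
        dipoles.origin[1] + lo[1] * a,
        dipoles.origin[2] + lo[2] * a,
    )
    return DipoleGrid(
        spacing=a, m=m, origin=origin, n0=dipoles.n0, wavelength=dipoles.wavelength
    )


def _greens_kernel(dipoles: DipoleGrid, shape_pad) -> np.ndarray:
    """Circulant Green's-function kernel over lattice offsets, self term 0."""
    a = dipoles.spacing
    k = dipoles.k_med
    px, py, pz = dipoles.m.shape
    Px, Py, Pz = shape_pad
    ox = np.minimum(np.arange(Px), Px - np.arange(Px))[:, None, None]
    oy = np.minimum(np.arange(Py), Py - np.arange(Py))[None, :, None]
    oz = np.minimum(np.arange(Pz), Pz - np.arange(Pz))[None, None, :]
    R = a * np.sqrt(ox**2 + oy**2 + oz**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if dipoles.is_2d:
            G = 0.25j * hankel1(0, k * np.where(R > 0, R, 1.0))
        else:
            G = k**2 * np.exp(1j * k * R) / np.where(R > 0, R, 1.0)
    G = np.where(R > 0, G, 0.0)
    # zero the wrap-around band that does not correspond to a true offset
    valid_x = (np.minimum(np.arange(Px), Px - np.arange(Px)) < px)[:, None, None]
    valid_y = (np.minimum(np.arange(Py), Py - np.arange(Py)) < py)[None, :, None]
    valid_z = (np.minimum(np.arange(Pz), Pz - np.arange(Pz)) < pz)[None, None, :]
    return np.where(valid_x & valid_y & valid_z, G, 0.0)


def dda_solve(
    dipoles: DipoleGrid,
    illum: PlaneWaveIllumination,
    grid: OpticalGrid,
    rtol: float = 1e-6,
    maxiter: int = 2000,
) -> ComplexField2D:
    """Solve the coupled-dipole system and return the exit-plane field.

    Solves (I - G beta) u = u_inc for the exciting field u on the lattice
    (FFT-accelerated lattice convolution, self term excluded, BiCGStab with
    relative tolerance ``rtol``), then radiates p = beta u to the
    measurement plane ``z = nz*dz`` of ``grid``.
    """
    dipoles = _crop_to_active(dipoles)
    if dipoles.m.size > _MAX_DIPOLES:
        raise ValueError(
            f"{dipoles.m.size} lattice sites exceeds the desk-scale cap {_MAX_DIPOLES}"
        )
    px, py, pz = dipoles.m.shape
    a = dipoles.spacing
    x0, y0, z0 = dipoles.origin
    beta = dipoles.polarizability()
    shape_pad = tuple(
        sfft.next_fast_len(2 * s - 1) if s > 1 else 1 for s in (px, py, pz)
    )
    Ghat = sfft.fftn(_greens_kernel(dipoles, shape_pad))

    def conv(v: np.ndarray) -> np.ndarray:
        buf = np.zeros(shape_pad, dtype=complex)
        buf[:px, :py, :pz] = v
        return sfft.ifftn(sfft.fftn(buf) * Ghat)[:px, :py, :pz]

    def matvec(flat: np.ndarray) -> np.ndarray:
        v = flat.reshape(px, py, pz)
        return (v - conv(beta * v)).ravel()

    xs = x0 + a * np.arange(px)
    ys = y0 + a * np.arange(py) if py > 1 else np.array([y0])
    zs = z0 + a * np.arange(pz)
    u_inc_lat = np.exp(
        1j
        * (
            illum.kx * xs[:, None, None]
            + illum.ky * ys[None, :, None]
            + illum.kz * zs[None, None, :]
        )
    ) * illum.amplitude

    if dipoles.n_active == 0:
        u = u_inc_lat
    else:
        op = LinearOperator(
            (dipoles.m.size, dipoles.m.size), matvec=matvec, dtype=complex
        )
        sol, info = bicgstab(
            op, u_inc_lat.ravel(), rtol=rtol, atol=0.0, maxiter=maxiter
        )
        if info != 0:
            res = np.linalg.norm(matvec(sol) - u_inc_lat.ravel()) / np.linalg.norm(
                u_inc_lat
            )
            raise ConvergenceError(
                f"coupled-dipole solve did not converge (info={info}, "
                f"relative residual {res:.2e})"
            )
        u = sol.reshape(px, py, pz)

    p = (beta * u).astype(complex)
    return _radiate_to_plane(dipoles, p, illum, grid)


def _radiate_to_plane(
    dipoles: DipoleGrid,
    p: np.ndarray,
    illum: PlaneWaveIllumination,
    grid: OpticalGrid,
    chunk: int = 4096,
) -> ComplexField2D:
    """Incident field plus the radiated field of all dipoles at the exit plane."""
    k = dipoles.k_med
    a = dipoles.spacing
    x0, y0, z0 = dipoles.origin
    px, py, pz = p.shape
    xs = x0 + a * np.arange(px)
    ys = y0 + a * np.arange(py) if py > 1 else np.array([y0])
    zs = z0 + a * np.arange(pz)
    XD, YD, ZD = np.meshgrid(xs, ys, zs, indexing="ij")
    active = p != 0.0
    pd = p[active]
    xd, yd, zd = XD[active], YD[active], ZD[active]

    xo = grid.x_coords()[:, 0]
    yo = grid.y_coords()[0, :]
    z_e = grid.exit_z
    XO, YO = np.meshgrid(xo, yo, indexing="ij")
    obs_x = XO.ravel()
    obs_y = YO.ravel()
    u_s = np.zeros(obs_x.size, dtype=complex)
    two_d = dipoles.is_2d
    for start in range(0, pd.size, chunk):
        sl = slice(start, start + chunk)
        dx_ = obs_x[:, None] - xd[None, sl]
        dz_ = z_e - zd[None, sl]
        if two_d:
            R = np.sqrt(dx_**2 + dz_**2)
            G = 0.25j * hankel1(0, k * R)
        else:
            dy_ = obs_y[:, None] - yd[None, sl]
            R = np.sqrt(dx_**2 + dy_**2 + dz_**2)
            G = k**2 * np.exp(1j * k * R) / R
        u_s += G @ pd[sl]
    u_inc = incident_field_values(illum, grid, z_e)
    values = u_inc + u_s.reshape(grid.nx, grid.ny)
    return ComplexField2D(values, z=z_e, grid=grid)


def greens_function(dipoles_or_k, r_obs, r_src, two_d: bool = False) -> complex:
    """Free-space scalar propagator between two points (for closed-form checks)."""
    k = dipoles_or_k.k_med if hasattr(dipoles_or_k, "k_med") else float(dipoles_or_k)
    R = float(np.linalg.norm(np.asarray(r_obs) - np.asarray(r_src)))
    if two_d:
        return complex(0.25j * hankel1(0, k * R))
    return complex(k**2 * np.exp(1j * k * R) / R)


# ---------------------------------------------------------------------------
# red blood cell shape (implicit quartic surface of revolution)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RBCShapeParams:
    """Biconcave-disc RBC shape.

    The surface is the zero set of the quartic
    ``rho^4 + 2 S rho^2 z^2 + z^4 + P rho^2 + Q z^2 + R = 0`` in cylinder
    coordinates.  The four coefficients (named S_q..R_q to avoid clashing
    with the cost-function symbols) are solved from four conditions: the rim
    radius d/2 at z=0, the dimple half-thickness b/2 on the axis, the point
    of maximum thickness h/2 at rho = c/2, and stationarity of the thickness
    there.

    Defaults are the standard human-RBC values d = 7.7 um, h/d = 0.3542,
    b/d = 0.1752, c/d = 0.6196.
    """

    d: float = 7.7
    h: float = 7.7 * 0.3542
    b: float = 7.7 * 0.1752
    c: float = 7.7 * 0.6196

    def __post_init__(self) -> None:
        if not (0 < self.b < self.h < self.d):
            raise ValueError("require 0 < b < h < d")
        if not (0 < self.c < self.d):
            raise ValueError("require 0 < c < d")

    @cached_property
    def quartic_coefficients(self) -> tuple[float, float, float, float]:
        """(S_q, P_q, Q_q, R_q), solved from the four surface constraints."""
        rd = self.d / 2.0
        zb = self.b / 2.0
        rc = self.c / 2.0
        zh = self.h / 2.0
        # linear system in (S, P, Q, R)
        A = np.array(
            [
                [0.0, rd**2, 0.0, 1.0],
                [0.0, 0.0, zb**2, 1.0],
                [2.0 * rc**2 * zh**2, rc**2, zh**2, 1.0],
                [4.0 * rc * zh**2, 2.0 * rc, 0.0, 0.0],  # dF/drho = 0 at (c/2, h/2)
            ]
        )
        rhs = np.array([-(rd**4), -(zb**4), -(rc**4 + zh**4), -4.0 * rc**3])
        try:
            S, P, Q, R = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError("non-physical RBC parameter combination") from exc
        return float(S), float(P), float(Q), float(R)

    def implicit(self, rho: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Quartic form F(rho, z); the interior is F <= 0."""
        S, P, Q, R = self.quartic_coefficients
        r2 = np.asarray(rho, dtype=float) ** 2
        z2 = np.asarray(z, dtype=float) ** 2
        return r2**2 + 2.0 * S * r2 * z2 + z2**2 + P * r2 + Q * z2 + R


def rbc_mask(
    params: RBCShapeParams,
    grid: OpticalGrid,
    center: tuple[float, float, float] | None = None,
    rotation: Rotation | None = None,
) -> np.ndarray:
    """Boolean volume of an (optionally rotated/translated) RBC.

    A voxel is inside iff the quartic form is <= 0 and |z| <= h/2 and
    rho <= d/2, evaluated in the cell's own frame.
    """
    if center is None:
        center = (0.0, 0.0, grid.nz * grid.dz / 2.0)
    X = np.broadcast_to(grid.x_coords()[:, :, None], grid.shape_volume)
    Y = np.broadcast_to(grid.y_coords()[:, :, None], grid.shape_volume)
    Z = np.broadcast_to(
        grid.z_slice_centers()[None, None, :], grid.shape_volume
    )
    pts = np.stack(
        [X.ravel() - center[0], Y.ravel() - center[1], Z.ravel() - center[2]], axis=1
    )
    if rotation is not None:
        pts = rotation.inv().apply(pts)
    rho = np.hypot(pts[:, 0], pts[:, 1])
    zz = pts[:, 2]
    inside = (
        (params.implicit(rho, zz) <= 0.0)
        & (np.abs(zz) <= params.h / 2.0)
        & (rho <= params.d / 2.0)
    )
    return inside.reshape(grid.shape_volume)


def build_rbc_cluster(
    grid: OpticalGrid,
    n_cells: int = 15,
    params: RBCShapeParams | None = None,
    ri: float = 1.05,
    placement_seed: int = 0,
    margin_fraction: float = 0.25,
    max_attempts_per_cell: int = 200,
) -> RIVolume:
    """Seeded cluster of identical, randomly rotated, non-overlapping RBCs."""
    params = params or RBCShapeParams()
    rng = np.random.default_rng(placement_seed)
    lx = grid.nx * grid.dx
    ly = grid.ny * grid.dx
    lz = grid.nz * grid.dz
    half = params.d / 2.0

    def _range(extent):
        r = extent / 2.0 - margin_fraction * extent - half
        return max(r, 0.0)

    rx_, ry_, rz_ = _range(lx), _range(ly), _range(lz)
    occupied = np.zeros(grid.shape_volume, dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_cells:
        if attempts >= max_attempts_per_cell * n_cells:
            raise RuntimeError(
                f"could only place {placed}/{n_cells} RBCs; use a larger grid"
            )
        attempts += 1
        cx = rng.uniform(-rx_, rx_) if rx_ > 0 else 0.0
        cy = rng.uniform(-ry_, ry_) if ry_ > 0 else 0.0
        cz = lz / 2.0 + (rng.uniform(-rz_, rz_) if rz_ > 0 else 0.0)
        rot = Rotation.random(rng=rng)
        mask = rbc_mask(params, grid, center=(cx, cy, cz), rotation=rot)
        if not mask.any():
            continue
        if (mask & occupied).any():
            continue
        occupied |= mask
        placed += 1
    n = np.where(occupied, ri * grid.n0, grid.n0)
    return RIVolume(n=n, grid=grid)


# ---------------------------------------------------------------------------
# cell phantom
# ---------------------------------------------------------------------------

PHANTOM_RI = {
    "cytoplasm": 1.0248,
    "nucleus": 1.0210,
    "nucleolus": 1.0413,
    "lipids": 1.0886,
}


def _ellipsoid(X, Y, Z, center, semi):
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def build_cell_phantom(
    grid: OpticalGrid, seed: int = 0, n_lipids: int = 5
) -> RIVolume:
    """Nested-ellipsoid cell phantom with four relative-RI compartments.

    Cytoplasm > nucleus > nucleolus as nested ellipsoids, plus seeded small
    lipid droplets in the cytoplasm; relative RI levels 1.0248 (cytoplasm),
    1.0210 (nucleus), 1.0413 (nucleolus) and 1.0886 (lipids) over the
    background n0.
    """
    rng = np.random.default_rng(seed)
    X = np.broadcast_to(grid.x_coords()[:, :, None], grid.shape_volume)
    Y = np.broadcast_to(grid.y_coords()[:, :, None], grid.shape_volume)
    Z = np.broadcast_to(grid.z_slice_centers()[None, None, :], grid.shape_volume)
    lx, ly, lz = grid.nx * grid.dx, grid.ny * grid.dx, grid.nz * grid.dz
    c0 = (0.0, 0.0, lz / 2.0)
    cyto_semi = (0.24 * lx, 0.22 * ly, 0.20 * lz)
    nuc_center = (0.06 * lx, -0.03 * ly, lz / 2.0 + 0.02 * lz)
    nuc_semi = (0.12 * lx, 0.11 * ly, 0.10 * lz)
    nucleo_center = (nuc_center[0] + 0.03 * lx, nuc_center[1], nuc_center[2])
    nucleo_semi = (0.04 * lx, 0.038 * ly, 0.035 * lz)

    cyto = _ellipsoid(X, Y, Z, c0, cyto_semi)
    nuc = _ellipsoid(X, Y, Z, nuc_center, nuc_semi) & cyto
    nucleo = _ellipsoid(X, Y, Z, nucleo_center, nucleo_semi) & nuc

    m = np.ones(grid.shape_volume)
    m[cyto] = PHANTOM_RI["cytoplasm"]
    m[nuc] = PHANTOM_RI["nucleus"]
    m[nucleo] = PHANTOM_RI["nucleolus"]

    r_lip = 0.035 * min(lx, ly, lz)
    placed = 0
    attempts = 0
    while placed < n_lipids and attempts < 100 * n_lipids:
        attempts += 1
        cx = rng.uniform(-0.2 * lx, 0.2 * lx)
        cy = rng.uniform(-0.18 * ly, 0.18 * ly)
        cz = rng.uniform(lz / 2 - 0.16 * lz, lz / 2 + 0.16 * lz)
        sph = _ellipsoid(X, Y, Z, (cx, cy, cz), (r_lip, r_lip, r_lip))
        if not sph.any():
            continue
        # lipids live in the cytoplasm, clear of the nucleus
        if not (sph & ~cyto).any() and not (sph & nuc).any():
            m[sph] = PHANTOM_RI["lipids"]
            placed += 1
    return RIVolume(n=m * grid.n0, grid=grid)


# ---------------------------------------------------------------------------
# illumination schemes and measurement factory
# ---------------------------------------------------------------------------


def linear_scheme(
    grid: OpticalGrid, count: int, half_angle_deg: float = 45.0
) -> list[PlaneWaveIllumination]:
    """Angles uniform in [-half_angle, +half_angle] in the (x, z) plane."""
    thetas = np.linspace(-half_angle_deg, half_angle_deg, count)
    return [
        snap_illumination(grid, grid.k_med * math.sin(math.radians(t)), 0.0)
        for t in thetas
    ]


def cone_scheme(
    grid: OpticalGrid, count: int, polar_deg: float
) -> list[PlaneWaveIllumination]:
    """Azimuths uniform on a circle at a fixed polar (incidence) angle."""
    kperp = grid.k_med * math.sin(math.radians(polar_deg))
    out = []
    for az in np.linspace(0.0, 2.0 * math.pi, count, endpoint=False):
        out.append(
            snap_illumination(grid, kperp * math.cos(az), kperp * math.sin(az))
        )
    return out


def illumination_scheme(
    name: str, grid: OpticalGrid, count: int | None = None
) -> list[PlaneWaveIllumination]:
    """Named angle sets, snapped to the FFT grid.

    * ``cylinders101`` -- 101 in-plane angles uniform in [-45 deg, 45 deg]
    * ``cone40_45deg`` -- 40 azimuths on a 45 deg cone
    * ``circle360_35deg`` -- 360 azimuths (1 deg steps) at 35 deg incidence

    ``count`` overrides the number of angles (for scaled-down scenes whose
    coarse frequency grids cannot hold the full set of distinct angles).
    """
    if name == "cylinders101":
        return linear_scheme(grid, count or 101, 45.0)
    if name == "cone40_45deg":
        return cone_scheme(grid, count or 40, 45.0)
    if name == "circle360_35deg":
        return cone_scheme(grid, count or 360, 35.0)
    raise ValueError(f"unknown illumination scheme {name!r}")


def make_measurements(
    volume: RIVolume,
    illuminations: list[PlaneWaveIllumination],
    generator: str = "dda",
    seed: int | None = None,
    scheme: str | None = None,
    dipole_spacing: float | None = None,
    mie_cylinder: dict | None = None,
    dda_rtol: float = 1e-6,
) -> MeasurementSet:
    """Generate exit-plane measurements for each illumination.

    ``generator`` is 'dda' (coupled dipoles; physically independent of the
    reconstruction models), 'mie' (single analytic cylinder; needs
    ``mie_cylinder={'diameter':..., 'n_cyl':..., 'center':...}``) or 'ssnp'
    (the reconstruction forward model itself -- self-consistency tests
    only, and labeled as such in the metadata).
    """
    grid = volume.grid
    fields = []
    if generator == "dda":
        from .metrics import resample_to_dipoles

        dipoles = resample_to_dipoles(volume, spacing=dipole_spacing)
        for il in illuminations:
            fields.append(dda_solve(dipoles, il, grid, rtol=dda_rtol).values)
    elif generator == "mie":
        if not mie_cylinder:
            raise ValueError("generator='mie' requires mie_cylinder parameters")
        for il in illuminations:
            fields.append(
                mie_cylinder_exit_field(
                    mie_cylinder["diameter"],
                    mie_cylinder["n_cyl"],
                    il,
                    grid,
                    center=mie_cylinder.get("center"),
                ).values
            )
    elif generator == "ssnp":
        from .ssnp import pair_to_forward_field, ssnp_propagate

        for il in illuminations:
            fields.append(pair_to_forward_field(ssnp_propagate(volume, il)).values)
    else:
        raise ValueError(f"unknown generator {generator!r}")
    meta = {
        "generator": generator,
        "seed": seed,
        "scheme": scheme,
        "note": "self-consistency generator" if generator == "ssnp" else "",
    }
    return MeasurementSet(
        illuminations=list(illuminations),
        fields=np.stack(fields),
        grid=grid,
        meta=meta,
    )


def angle_subsample(measurements: MeasurementSet, count: int) -> MeasurementSet:
    """Keep ``count`` maximally uniform angles (every floor(L/count)-th, from 0)."""
    L = len(measurements)
    if count > L:
        raise ValueError(f"cannot keep {count} of {L} angles")
    if count == L:
        return measurements
    stride = L // count
    return measurements.subset([i * stride for i in range(count)])


__all__ = [
    "ConvergenceError",
    "mie_truncation_order",
    "mie_cylinder_coefficients",
    "mie_cylinder_exit_field",
    "DipoleGrid",
    "dda_solve",
    "greens_function",
    "RBCShapeParams",
    "rbc_mask",
    "build_rbc_cluster",
    "PHANTOM_RI",
    "build_cell_phantom",
    "linear_scheme",
    "cone_scheme",
    "illumination_scheme",
    "make_measurements",
    "angle_subsample",
]
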