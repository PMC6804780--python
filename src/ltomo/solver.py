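"""Learning-tomography optimization.

Minimizes, over the RI contrast x = n - n0 restricted to x >= 0,

    (1/(2L)) sum_l || y_K^(l) - S_K^(l)(x) ||^2  +  tau * TV_iso(x)

where S is one of the multislice forward models (SSNP, BPM) or the linear
first-Born model, and y_K^(l) are the per-angle complex fields at the exit
plane.  For the SSNP the residual compares both components of the pair
(u, du/dz) -- the measured field is paired with its derivative via the
forward-travelling relation du_hat = i kz u_hat.  For BPM/Born the residual
is the plain field difference.

Optimization is FISTA with a fixed number of dual iterations for the
isotropic-TV proximal step, a non-negativity projection, and a stochastic
batch of angles per outer iteration.  Because the SSNP residual carries both
u and du/dz, its gradients are larger than the BPM's by roughly the
plane-wave ratio C = mean(1 + kz^2); the solver therefore uses gamma/C and
tau*C for the SSNP so that one (gamma, tau) pair, quoted on the BPM scale,
drives both models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import fft as sfft

from . import bpm as _bpm
from . import ssnp as _ssnp
from .core import (
    ComplexField2D,
    MeasurementSet,
    OpticalGrid,
    PlaneWaveIllumination,
    RIVolume,
    incident_field_values,
    transverse_frequency_grid,
)

Model = Literal["ssnp", "bpm", "born"]


class DivergenceError(RuntimeError):
    """Raised when the FISTA iteration diverges (cost > 10x initial)."""


@dataclass
class ReconstructionConfig:
    """Parameters of the learning-tomography loop.

    ``gamma`` and ``tau`` are quoted on the BPM scale; for ``model='ssnp'``
    the solver internally uses ``gamma/C`` and ``tau*C``.  ``C`` defaults to
    the calibration ratio computed from the measurement illuminations.
    """

    model: Model = "ssnp"
    gamma: float = 1e-3
    tau: float = 0.0
    C: float | None = None
    outer_iterations: int = 200
    tv_inner_iterations: int = 20
    batch_size: int = 8
    rng_seed: int = 0
    nonneg: bool = True
    cost_every: int = 1  # full-data cost trace cadence (0 disables)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.C is not None and self.C < 1:
            raise ValueError("C must be >= 1")
        if self.model not in ("ssnp", "bpm", "born"):
            raise ValueError(f"unknown model {self.model!r}")


def calibrate_C(
    illuminations: Iterable[PlaneWaveIllumination], grid: OpticalGrid | None = None
) -> float:
    """BPM<->SSNP parameter calibration ratio.

    For a plane wave ``u = exp(i(kx x + ky y + kz z))`` the pair residual
    energy ``||u||^2 + ||du/dz||^2 = ||u + du/dz||``-style ratio equals
    ``|1 + i kz|^2 = 1 + kz^2`` (kz in rad/um).  C is the mean of that over
    the illumination set, and rescales (gamma, tau) to (gamma/C, tau*C) for
    the SSNP.
    """
    vals = [1.0 + il.kz**2 for il in illuminations]
    if not vals:
        raise ValueError("at least one illumination is required")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# data term
# ---------------------------------------------------------------------------


def _measured_pairs(measurements: MeasurementSet) -> list[tuple[np.ndarray, np.ndarray]]:
    """Convert measured fields to (u, du/dz) arrays for the SSNP residual."""
    grid = measurements.grid
    out = []
    for f in measurements.fields:
        fld = ComplexField2D(f, z=grid.exit_z, grid=grid)
        pair = _ssnp.field_to_pair(fld, grid)
        out.append((pair.u.values, pair.dudz.values))
    return out


def _predict_field(volume: RIVolume, illum: PlaneWaveIllumination, model: Model):
    if model == "bpm":
        return _bpm.bpm_propagate(volume, illum).values
    if model == "born":
        return _bpm.first_born_predict(volume, illum).values
    raise ValueError(model)


def data_cost(
    volume: RIVolume,
    measurements: MeasurementSet,
    model: Model,
    angle_subset: Sequence[int] | None = None,
) -> float:
    """Data-fidelity term (1/(2L)) sum_l ||y - S(x)||^2 over the subset.

    For ``model='ssnp'`` the residual norm sums the squared moduli of both
    pair components; for bpm/born it is the field residual.
    """
    if measurements.grid != volume.grid:
        raise ValueError("volume and measurements are on different grids")
    idx = list(range(len(measurements))) if angle_subset is None else list(angle_subset)
    L = len(idx)
    total = 0.0
    if model == "ssnp":
        for l in idx:
            il = measurements.illuminations[l]
            pred = _ssnp.ssnp_propagate(volume, il)
            # the measurable part of the prediction: forward-travelling,
            # band-limited pair (backward/evanescent content has no
            # counterpart in a holographic measurement)
            pred = _ssnp.forward_project_pair(pred, volume.grid)
            meas = _ssnp.field_to_pair(
                ComplexField2D(
                    measurements.fields[l], z=volume.grid.exit_z, grid=volume.grid
                ),
                volume.grid,
            )
            total += float(
                np.sum(np.abs(pred.u.values - meas.u.values) ** 2)
                + np.sum(np.abs(pred.dudz.values - meas.dudz.values) ** 2)
            )
    else:
        for l in idx:
            il = measurements.illuminations[l]
            pred = _predict_field(volume, il, model)
            total += float(np.sum(np.abs(pred - measurements.fields[l]) ** 2))
    return total / (2.0 * L)


def _ssnp_gradient_one(
    volume: RIVolume,
    illum: PlaneWaveIllumination,
    y_field: np.ndarray,
) -> np.ndarray:
    """d/dx of (1/2)||pair residual||^2 for one angle, by adjoint sweep."""
    grid = volume.grid
    dz = grid.dz
    k0sq = grid.k0**2
    n0sq = grid.n0**2
    pair, states = _ssnp.ssnp_propagate(volume, illum, return_states=True)
    pred_u, pred_d = _ssnp._forward_projection_arrays(
        pair.u.values, pair.dudz.values, grid
    )
    meas = _ssnp.field_to_pair(
        ComplexField2D(y_field, z=grid.exit_z, grid=grid), grid
    )
    r_u = pred_u - meas.u.values
    r_d = pred_d - meas.dudz.values
    # chain the residual back through the forward projection
    s_u, s_d = _ssnp._forward_projection_arrays(r_u, r_d, grid, adjoint=True)
    ker_half = _ssnp.make_pair_propagator(grid, dz / 2.0)
    ker_full = _ssnp.make_pair_propagator(grid, dz)
    grad = np.zeros(grid.shape_volume)
    s_u, s_d = _ssnp._apply_kernel(s_u, s_d, ker_half, conjugate=True)
    for k in range(grid.nz - 1, -1, -1):
        if k < grid.nz - 1:
            s_u, s_d = _ssnp._apply_kernel(s_u, s_d, ker_full, conjugate=True)
        u_k = states[k]
        q_k = k0sq * (volume.n[:, :, k] ** 2 - n0sq)
        # scatter adjoint: du_out = du_in - q u dz
        grad_q = np.real(np.conj(s_d) * (-u_k)) * dz
        grad[:, :, k] = grad_q * (2.0 * k0sq * volume.n[:, :, k])  # dq/dx = 2 k0^2 n
        s_u = s_u - q_k * dz * s_d
    return grad


def _bpm_gradient_one(
    volume: RIVolume,
    illum: PlaneWaveIllumination,
    y_field: np.ndarray,
) -> np.ndarray:
    """d/dx of (1/2)||field residual||^2 for one BPM angle."""
    grid = volume.grid
    dz = grid.dz
    scale = grid.k0 * dz / illum.cos_theta
    exit_field, states = _bpm.bpm_propagate(volume, illum, return_states=True)
    s = exit_field.values - y_field
    ker_half_conj = np.conj(_bpm._diffraction_kernel(grid, dz / 2.0))
    ker_full_conj = np.conj(_bpm._diffraction_kernel(grid, dz))
    grad = np.zeros(grid.shape_volume)
    s = sfft.ifft2(ker_half_conj * sfft.fft2(s))
    for k in range(grid.nz - 1, -1, -1):
        if k < grid.nz - 1:
            s = sfft.ifft2(ker_full_conj * sfft.fft2(s))
        w_k = states[k]
        phase = np.exp(1j * scale * (volume.n[:, :, k] - grid.n0))
        u_out = w_k * phase
        grad[:, :, k] = scale * np.real(np.conj(s) * 1j * u_out)
        s = s * np.conj(phase)
    return grad


def _born_gradient_one(
    volume: RIVolume,
    illum: PlaneWaveIllumination,
    y_field: np.ndarray,
) -> np.ndarray:
    """d/dx of (1/2)||field residual||^2 for the linear Born model."""
    grid = volume.grid
    dz = grid.dz
    _, _, kz = transverse_frequency_grid(grid)
    mask, obliquity = _bpm._born_slice_kernels(grid)
    pred = _bpm.first_born_predict(volume, illum).values
    r_hat = sfft.fft2(pred - y_field)
    k0sq = grid.k0**2
    grad = np.zeros(grid.shape_volume)
    for k in range(grid.nz):
        d_k = np.exp(1j * np.where(mask, kz.real, 0.0) * (grid.nz - k - 0.5) * dz)
        a_k = sfft.ifft2(np.conj(d_k * obliquity) * r_hat) * dz
        u_inc_k = incident_field_values(illum, grid, (k + 0.5) * dz)
        grad_f = np.real(np.conj(a_k) * u_inc_k)
        grad[:, :, k] = grad_f * (2.0 * k0sq * volume.n[:, :, k])
    return grad


_GRAD_ONE = {
    "ssnp": _ssnp_gradient_one,
    "bpm": _bpm_gradient_one,
    "born": _born_gradient_one,
}


def data_gradient(
    volume: RIVolume,
    measurements: MeasurementSet,
    model: Model,
    angle_subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Gradient of the data term w.r.t. the contrast x, over a subset of angles.

    Implemented by reverse-sweeping the adjoint state through the slices;
    the chain rule through n^2 contributes the factor 2 n k0^2 dz per voxel
    for ssnp/born and the k0 dz / cos(theta) path for bpm.
    """
    idx = range(len(measurements)) if angle_subset is None else list(angle_subset)
    idx = list(idx)
    if not idx:
        raise ValueError("angle_subset must be non-empty")
    grad_one = _GRAD_ONE[model]
    grad = np.zeros(volume.grid.shape_volume)
    for l in idx:
        grad += grad_one(volume, measurements.illuminations[l], measurements.fields[l])
    return grad / len(idx)


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------


def _grad3(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward differences with Neumann boundary (last difference 0)."""
    gx = np.zeros_like(x)
    gy = np.zeros_like(x)
    gz = np.zeros_like(x)
    gx[:-1] = x[1:] - x[:-1]
    gy[:, :-1] = x[:, 1:] - x[:, :-1]
    gz[:, :, :-1] = x[:, :, 1:] - x[:, :, :-1]
    return gx, gy, gz


def _div3(px: np.ndarray, py: np.ndarray, pz: np.ndarray) -> np.ndarray:
    """Negative adjoint of _grad3."""
    d = np.zeros_like(px)
    d[0] = px[0]
    d[1:-1] = px[1:-1] - px[:-2]
    d[-1] = -px[-2] if px.shape[0] > 1 else 0.0
    d[:, 0] += py[:, 0]
    d[:, 1:-1] += py[:, 1:-1] - py[:, :-2]
    if py.shape[1] > 1:
        d[:, -1] += -py[:, -2]
    d[:, :, 0] += pz[:, :, 0]
    d[:, :, 1:-1] += pz[:, :, 1:-1] - pz[:, :, :-2]
    if pz.shape[2] > 1:
        d[:, :, -1] += -pz[:, :, -2]
    return d


def tv_value(x: np.ndarray) -> float:
    """Isotropic 3D total variation: sum of voxel gradient magnitudes."""
    gx, gy, gz = _grad3(np.asarray(x, dtype=float))
    return float(np.sum(np.sqrt(gx**2 + gy**2 + gz**2)))


def tv_prox(
    x: np.ndarray, weight: float, inner_iterations: int = 20
) -> np.ndarray:
    """Approximate proximal operator of ``weight * TV_iso``.

    Fast gradient projection on the dual problem (a fixed count of
    iterations); ``weight = 0`` returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if weight == 0.0 or inner_iterations <= 0:
        return x.copy()
    ndim_eff = sum(1 for s in x.shape if s > 1)
    lip = max(4.0 * ndim_eff, 4.0)
    px = np.zeros_like(x)
    py = np.zeros_like(x)
    pz = np.zeros_like(x)
    rx, ry, rz = px, py, pz
    t = 1.0
    for _ in range(inner_iterations):
        u = x - weight * _div3(rx, ry, rz)
        gx, gy, gz = _grad3(u)
        # the adjoint of _div3 is the negative forward difference
        qx = rx - gx / (lip * weight)
        qy = ry - gy / (lip * weight)
        qz = rz - gz / (lip * weight)
        norm = np.sqrt(qx**2 + qy**2 + qz**2)
        denom = np.maximum(norm, 1.0)
        nx_, ny_, nz_ = qx / denom, qy / denom, qz / denom
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        beta = (t - 1.0) / t_next
        rx = nx_ + beta * (nx_ - px)
        ry = ny_ + beta * (ny_ - py)
        rz = nz_ + beta * (nz_ - pz)
        px, py, pz = nx_, ny_, nz_
        t = t_next
    return x - weight * _div3(px, py, pz)


def project_nonneg(x: np.ndarray) -> np.ndarray:
    """Pointwise max(x, 0) on the contrast x = n - n0."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


# ---------------------------------------------------------------------------
# FISTA
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionResult:
    volume: RIVolume
    cost_trace: list[tuple[int, float]]  # (iteration, full-data cost)
    angle_history: list[list[int]]
    config: ReconstructionConfig
    C: float


def fista_reconstruct(
    measurements: MeasurementSet,
    init_volume: RIVolume | None = None,
    config: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    """Learning-tomography reconstruction by stochastic FISTA.

    Each outer iteration draws ``batch_size`` angles without replacement
    from the seeded generator, takes a gradient step of size gamma (gamma/C
    for ssnp), applies the TV prox with weight tau*gamma (tau*C*gamma for
    ssnp) for ``tv_inner_iterations`` dual iterations, then projects onto
    non-negativity.  Plain FISTA t-sequence, no restarts, fixed iteration
    count.
    """
    config = config or ReconstructionConfig()
    grid = measurements.grid
    if init_volume is None:
        init_volume = RIVolume.homogeneous(grid)
    if init_volume.grid != grid:
        raise ValueError("init volume is not on the measurement grid")
    L = len(measurements)
    batch = min(config.batch_size, L)
    C = config.C if config.C is not None else calibrate_C(measurements.illuminations)
    if config.model == "ssnp":
        gamma_eff = config.gamma / C
        tau_eff = config.tau * C
    else:
        gamma_eff = config.gamma
        tau_eff = config.tau
    rng = np.random.default_rng(config.rng_seed)

    x = init_volume.contrast.copy()
    if config.nonneg:
        x = project_nonneg(x)
    y = x.copy()
    t = 1.0
    trace: list[tuple[int, float]] = []
    history: list[list[int]] = []
    cost0 = None
    if config.cost_every:
        cost0 = data_cost(RIVolume.from_contrast(x, grid), measurements, config.model)
        trace.append((0, cost0))

    for it in range(1, config.outer_iterations + 1):
        subset = list(rng.choice(L, size=batch, replace=False)) if batch < L else list(range(L))
        history.append([int(s) for s in subset])
        vol_y = RIVolume.from_contrast(y, grid)
        g = data_gradient(vol_y, measurements, config.model, subset)
        z = y - gamma_eff * g
        if tau_eff > 0:
            z = tv_prox(z, tau_eff * gamma_eff, config.tv_inner_iterations)
        if config.nonneg:
            z = project_nonneg(z)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = z + ((t - 1.0) / t_next) * (z - x)
        x = z
        t = t_next
        if config.cost_every and (it % config.cost_every == 0 or it == config.outer_iterations):
            cost = data_cost(RIVolume.from_contrast(x, grid), measurements, config.model)
            trace.append((it, cost))
            if cost0 is not None and cost0 > 0 and cost > 10.0 * cost0:
                raise DivergenceError(
                    f"cost {cost:.3e} exceeded 10x initial {cost0:.3e} "
                    f"at iteration {it}; reduce gamma"
                )
    return ReconstructionResult(
        volume=RIVolume.from_contrast(x, grid),
        cost_trace=trace,
        angle_history=history,
        config=config,
        C=C,
    )


__all__ = [
    "Model",
    "ReconstructionConfig",
    "ReconstructionResult",
    "DivergenceError",
    "calibrate_C",
    "data_cost",
    "data_gradient",
    "tv_prox",
    "tv_value",
    "project_nonneg",
    "fista_reconstruct",
]
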