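# Methods

## Problem

Optical diffraction tomography (ODT) reconstructs the 3D refractive-index
(RI) map n(x, y, z) of a transparent sample from complex-field holograms
recorded at the exit plane under many plane-wave illumination angles.  The
optimization variable throughout is the RI contrast x = n − n0 over the
medium index n0, constrained to x ≥ 0.  The estimate minimizes

    (1/2L) Σ_l ‖ y_K^(l) − S_K^(l)(x) ‖²  +  τ · TV_iso(x),   x ≥ 0,

where y_K^(l) is the measured field for angle l at the exit plane (the
plane just past the last slice K = nz − 1), S is a multislice forward
model, and TV_iso is isotropic 3D total variation.  The loop is stochastic
FISTA: per outer iteration a batch of angles (default 8) is drawn without
replacement from a seeded generator, one gradient step of size γ is taken,
the TV proximal operator is applied with weight τ·γ (20 dual iterations by
default), and the iterate is projected onto x ≥ 0.  Plain FISTA t-sequence,
no restarts, fixed iteration count.

## Forward models

**SSNP (split-step non-paraxial).**  The Helmholtz equation is written as a
first-order system in the pair v = (u, ∂u/∂z).  The system matrix splits
exactly into a homogeneous part — diagonal per transverse FFT frequency,
with the 2×2 propagator [[cos kz·dz, sin(kz·dz)/kz], [−kz·sin kz·dz,
cos kz·dz]] — and a scattering part k0²(n² − n0²) that only increments the
derivative: du/dz ← du/dz − k0²(n² − n0²)·u·dz.  No approximation of the
index term is made; oblique and multiply-scattered components acquire their
phase through the exact homogeneous propagator rather than through a fixed
path length.

**BPM (beam propagation method).**  Alternates the non-paraxial
angular-spectrum kernel exp(i·kz·dz) applied to the total field with a thin
phase screen exp(i·k0·(n − n0)·dz/cosθ), where cosθ = kz/k_med is one scalar
per illumination, fixed through the volume.  That fixed oblique path is the
BPM's known deficiency for thick, multiply-scattering samples and is
deliberately retained.

**First Born ("linear tomography").**  Single scattering: each slice
contributes f·u_inc (f = k0²(n² − n0²)) propagated to the exit plane with
the homogeneous kernel and the i/(2kz) obliquity factor of the scalar
Green's function; exactly linear in f.

**Slice alignment.**  All three models use a symmetric split: a half-step
of diffraction at the entrance and exit and full steps between slices, so
every slice's modulation acts at its center plane z = (k + 0.5)·dz — the
same coordinates used by the scene builders, the dipole resampler and the
direct Rytov inversion.  The total homogeneous path is exactly nz·dz, so
free-space propagation of any plane wave is analytically exact (machine
precision), and the split error is smaller and angle-stable compared with
the one-sided ordering.

**Evanescent handling.**  The exact pair propagator analytically continues
to cosh/sinh on evanescent frequencies and therefore contains a growing
exponential e^{+κ·dz}.  Iterated over hundreds of slices that mode
amplifies FFT roundoff without bound (measured: O(100) errors on a
16-slice homogeneous run, overflow beyond ~100 slices), so the evanescent
kernel is restricted to its decaying eigenmode, M = e^{−κ·dz} P_d with P_d
the projector onto (1, −κ).  This is exact for decaying content, satisfies
the semigroup property, and carries no growing mode; dz = 0 is
special-cased to the identity.  Consequently the unit-determinant identity
of the kernel holds on the propagating disk only.

**Measurable part of the SSNP prediction.**  A holographic measurement
stores one forward-travelling, band-limited field per angle.  The SSNP exit
pair, however, carries backward-travelling and evanescent content that the
stored field cannot represent.  The data term therefore projects the
predicted pair onto the forward band-limited subspace before the residual;
the measured field is paired with its derivative via dû/dz = i·kz·û.  Both
components still enter the residual, the per-frequency energy ratio of the
pair residual to the field residual is exactly 1 + kz², and a measurement
generated by the model itself yields a numerically zero cost.

**Born aperture.**  The i/(2kz) obliquity diverges at grazing frequencies;
the Born kernels drop frequencies with kz ≤ 0.02·k_med (an implicit ~89°
angular aperture).  Scattered content there is negligible for the scenes
considered, and the gradient uses the identical kernels.

## Parameter calibration C

The SSNP residual holds u and du/dz, so for a plane wave its energy exceeds
the BPM's field residual by |1 + i·kz|² = 1 + kz² (kz in rad/µm).  C is the
mean of 1 + kz² over the illumination set; one (γ, τ) pair quoted on the
BPM scale drives both models as (γ/C, τ·C) for the SSNP.  The squared
magnitude reading of the ratio is adopted because it equals the stated
norm ratio for a plane wave; with it the shipped presets' C values follow
from their optics (101 angles ±45° at λ=0.6 µm in air → ≈90.4; a 40-angle
45° cone → ≈55.9; a 360-angle 35° scan at λ=0.532 µm in n0=1.338 → ≈168.5).

## Direct inversion (initial guess)

The Rytov complex phase ψ = ln|u/u_inc| + i·unwrap(Δφ) is extracted per
angle with transform-based (DCT/Poisson) least-squares unwrapping —
deterministic and parameter-free; the additive constant is fixed against
the wrapped input's circular mean.  Per the Fourier diffraction theorem the
weighted spectrum −2i·kz·Ψ̂, phase-referenced from the volume center to the
measurement plane, is placed on the Ewald cap shifted by the illumination
wavevector; votes are accumulated by nearest-voxel rounding (trilinear
splatting available) and averaged; Hermitian symmetry is enforced; the
inverse transform gives f and n = sqrt(n0² + f/k0²) floored at zero.  No
missing-cone correction is attempted here — filling that cone is the job of
the iterative loop.

## Synthetic scenes and independent generators

**Mie cylinder (2D oracle).**  Scalar partial-wave series for an infinite
cylinder (u and ∂u/∂r continuous at the boundary), truncated at
⌈x + 4x^{1/3} + 2⌉ with a convergence guard; the incident wave is summed
analytically so the series only carries the scattered part.  The optical
theorem (Σ w_m(|a_m|² + Re a_m) = 0 for lossless cylinders) holds to 1e−15.

**Scalar coupled dipoles (DDA).**  Arbitrary volumes are represented as a
cubic lattice of mutually interacting dipoles (default 12 per medium
wavelength).  The whole reconstruction stack is scalar, so the solver is
scalar by design — a vector solver would inject polarization physics the
inversion never models.  3D: Clausius–Mossotti polarizability with the
propagator k²e^{ikR}/R.  2D (fields along the cylinder axis, no
depolarization): collocation of the Lippmann–Schwinger equation with
(i/4)H0(kR).  The linear system is solved by BiCGStab (rtol 1e−6) with an
FFT-accelerated lattice convolution, self-term excluded; the solve is
restricted (exactly) to the bounding box of sites with m ≠ 1.  Radiation to
the exit plane is a direct chunked sum.  Cross-checks: single-dipole closed
form to 1e−10; weak cylinder vs Mie to <1%.

**Red blood cells.**  The biconcave surface is the zero set of
ρ⁴ + 2Sρ²z² + z⁴ + Pρ² + Qz² + R; the four coefficients are solved from
four linear conditions (rim radius d/2, dimple thickness b, maximum
thickness h at ρ = c/2, and stationarity there).  Defaults d = 7.7 µm,
h/d = 0.3542, b/d = 0.1752, c/d = 0.6196.  Clusters place seeded random
rigid transforms with voxel-exact overlap rejection.

**Cell phantom.**  Nested ellipsoids (cytoplasm ⊃ nucleus ⊃ nucleolus)
plus seeded lipid droplets, with exactly the relative-RI levels 1.0248,
1.0210, 1.0413 and 1.0886 over the background.

**Illumination schemes.**  Angles are snapped to the nearest FFT frequency
so incident waves are periodic on the grid (no wrap-around of the incident
field); the snapped kz feeds every downstream formula.  Named sets: 101
in-plane angles in ±45°, a 40-angle 45° cone, and a 360-angle 35° circle;
counts can be overridden for scaled-down grids whose coarse frequency
lattices cannot hold the full set of distinct angles.

## Evaluation

Error(x_recon, x_true) = ‖x_recon − x_true‖²/‖x_true‖² on contrast.
Volume SSIM uses a Gaussian window (σ = 1.5, 11-voxel support), dynamic
range from the reference, and interior averaging; it matches scikit-image
to 1e−6 and serves as the independent cross-check in the tests.  Projection
error is the mean absolute phase discrepancy (radians/pixel) per angle
between unwrapped phase maps, with differences wrapped to (−π, π] so
isolated unwrapping failures cannot dominate.  The semisynthetic loop
resamples a reconstruction onto the dipole lattice (pitch λ/(12·n0),
trilinear interpolation, RI quantized to round(n/n0·1000)/1000), re-runs
the coupled-dipole solver per angle, and scores the predicted phases
against the reference measurements — the accuracy proxy when no ground
truth exists.  A reconstruction equal to the exact ground truth of
DDA-generated measurements closes the loop at the solver tolerance.

## Study conditions (single CPU)

* **Multi-cylinder benchmark** — 2D scene, 256×128 voxels at 0.15 µm,
  three 6 µm cylinders of RI 1.05 in air, 9 µm center-to-center, arranged
  in a triangle so oblique beams traverse two scatterers in sequence; 51
  angles uniform in ±45° at λ = 0.6 µm; measurements from the coupled-dipole
  solver (independent of both reconstruction models).  Both loops use
  γ = 1e−4, τ = 0.04 (BPM scale; the SSNP applies γ/C and τ·C with
  C ≈ 90), batch 8, 200 iterations, Rytov init.  Typical outcome:
  Error ≈ 0.61 (Rytov) → 0.09 (LT-BPM) → 0.07 (LT-SSNP).
* **Angle compression** — 64³ phantom at 0.15 µm, 60-angle 35° circular
  scan, measurements generated with the SSNP model itself (a
  self-consistency setting that isolates robustness to missing angles from
  forward-model mismatch), subsampled to 4 uniform azimuths; SSNP loop with
  γ = 5e−4, τ = 0.04, batch 8, 80 iterations.  SSIM of the 4-angle vs the
  full-angle reconstruction ≈ 0.99 for the iterative loop vs ≈ 0.89 for the
  direct Rytov inversion.
* **Semisynthetic loop** — reuses the cylinder benchmark; seven evenly
  spaced angles are re-simulated with the coupled-dipole solver from the
  ground truth and from each reconstruction.

The step sizes, iteration counts and scene sizes above are this package's
desk-scale defaults, chosen once on these conditions; the shipped presets
carry the full-size parameters (grids up to 1024×256 and 512×512×180,
γ = 1e−3 … 0.25e−3, 200–400 iterations) for users with the cycles to run
them.

## What the synthetic data do and do not show

The generators emulate coherent, noise-free, aberration-free holographic
measurements of non-absorbing (real-RI) samples with perfectly known
illumination angles.  Passing tests therefore demonstrate the correctness
of the propagation physics, adjoints and inversion machinery, and the
relative merits of the forward models under multiple scattering — not
robustness to detector noise, phase-retrieval artifacts, miscalibrated
angles, or absorption, none of which are modeled.  The multislice models
are transversely periodic; scenes must be padded so scattered light does
not wrap (the fixture generators pad by ≥25% per side), and residual wrap
of slowly decaying 2D cylindrical waves sets the few-percent floor observed
when comparing periodic multislice fields against free-space Mie solutions.

## Numerical choices and degenerate inputs

* FFT layout unshifted everywhere; pixel centers at (i + 0.5 − n/2)·dx.
* kz on the principal square-root branch; the grazing bin (kz = 0) takes
  the series limit sin(kz·dz)/kz → dz.
* TV prox: fast dual projected gradient with momentum, Lipschitz constant
  4·(number of non-singleton axes); weight 0 returns the input; constant
  volumes are fixed points.
* Divergence guard: the loop aborts if the tracked cost exceeds 10× its
  initial value.
* Batch sampling is without replacement per iteration, reshuffled each
  iteration from a recorded seed; identical seeds give identical angle
  sequences and bitwise-identical volumes.
* The 2D mode is ny = 1 throughout; all operators reduce consistently
  (kz² = k_med² − kx²).

## Known limitations

Scalar fields only (no polarization, no absorption); transmission geometry
only; no reflection modeling; no GPU path; the first-Born model and the
Rytov initializer share the small-angle aperture cutoff; the coupled-dipole
solver is practical to ~2·10⁶ lattice sites on one CPU.
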