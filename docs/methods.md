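# Methods

This document describes the models, estimators, and numerical choices in
`dkifit`. Units: diffusivities in μm²/ms, b-values in ms/μm²
(1.0 ≡ 1000 s/mm²); kurtosis quantities are dimensionless.

## Signal model

For a gradient direction `n` and b-value `b`, the cumulant expansion of
the diffusion-weighted signal is

```
log S(b, n) = log S0 − b Σ_ij n_i n_j D_ij
              + (b²/6) MD² Σ_ijkl n_i n_j n_k n_l W_ijkl
```

where `D` is the symmetric rank-2 diffusion tensor (6 unique elements),
`W` the fully symmetric rank-4 kurtosis tensor (15 unique elements), and
`MD = trace(D)/3`. Directional quantities derived from a fit:

- apparent diffusivity `D(n) = n·D·n`
- apparent kurtosis `K(n) = (MD/D(n))² · W(n)` with
  `W(n) = Σ n_i n_j n_k n_l W_ijkl`

`tensor_core` stores `D` as 6 and `W` as 15 unique elements with the
index order and multiplicity tables exposed as `D_ORDER`/`W_ORDER` and
`D_MULTIPLICITY`/`W_MULTIPLICITY`; `expand_*`/`compress_*` convert to and
from full arrays.

## Fitting

The 22-parameter vector is `(D_6, MD²·W_15, log S0)`, linear in the
log-signal, so the design matrix is shared by all fitters:

- **OLS** — unweighted least squares on `log S`.
- **WLS** (default) — weights `S` (one step), since the log transform
  makes the noise variance ∝ 1/S².
- **WLS-ITER** — WLS re-weighted with the model-predicted signal until
  convergence.
- **NLS** — Levenberg–Marquardt on the signal domain, initialized from
  WLS.

Non-positive signals are clipped to a small floor before the log and the
voxel is flagged; all-zero voxels return `None`; rank-deficient designs
and too few measurements raise `FitError`. `kt` in a `KurtosisFit` holds
`W_15` (the stored parameters divided by the fitted `MD²`).

## Kurtosis scalars

### Mean kurtosis

Two estimators:

- **Numerical** — the average of `K(n)` over a 45-direction spherical
  design (below). Exact only up to the design's polynomial degree; `K(n)`
  is a rational function of `n`, so a residual quadrature error remains
  (see Accuracy).
- **Analytical** — the exact closed form in the diffusion eigenframe: MK
  is a linear combination of the six independent eigenframe kurtosis
  elements `W̃_1111, W̃_2222, W̃_3333, W̃_2233, W̃_1133, W̃_1122` with
  coefficient functions `F1`/`F2` built from Carlson's symmetric elliptic
  integrals `R_F` and `R_D`.

Carlson integrals are computed with the standard duplication algorithm
(relative accuracy ~1e-10, validated against adaptive quadrature of the
defining integrals and against `scipy.special.elliprf/elliprd`). The
eigenvalue-degeneracy branches of `F1`/`F2` are all implemented, with a
relative eigenvalue gap of 1e-6·MD switching to the limit forms:

- `λ1 = λ2 = λ3` → constants 1/5 and 2/5,
- `λ2 = λ3` (prolate) → closed forms in
  `α(x) = arctanh(√x)/√x` (or `arctan` for `x < 0`),
- `λ1 = λ2` → the identity `F1(a,a,c) = F2(c,a,a)/2`.

Every branch is verified in the test suite at 1e-9 against a dense
Gauss–Legendre × trapezoid quadrature of the defining sphere integral.

### Radial, axial, tensor-mean, KFA

- **RK** — analytically via `G1`/`G2` coefficients of `W̃_2222, W̃_3333,
  W̃_2233` (with their own `λ2 = λ3` limits), or numerically as the mean
  of `K(n)` over a circle perpendicular to the principal eigenvector.
- **AK** — `K(e1)` evaluated directionally, or the algebraically
  identical tensor form `MD²/λ1² · W̃_1111`.
- **MKT** — the trace-based mean
  `(W_1111 + W_2222 + W_3333 + 2(W_1122 + W_1133 + W_2233))/5`,
  rotation-invariant without any quadrature.
- **KFA** — the Frobenius-norm fractional anisotropy of `W` relative to
  its isotropic part; defined as 0 when `‖W‖ = 0`.

### The 45-direction spherical design

`_sphere45.py` freezes a 45-point antipodal direction set constructed by
`scripts/make_sphere_design.py`: multi-start nonlinear least squares
driving all even spherical-harmonic moments of degree ≤ 10 to zero, so
the symmetrized 90-point set is a spherical 11-design (equal-weight
averaging integrates polynomials to degree 11 exactly). The optimizer
residual is ~1e-14; the 16-decimal printed table retains moments below
1e-9. Degree-12 exactness is not attainable with 45 antipodal points
(multi-start attempts plateau at ~2e-4, consistent with point-count
bounds for symmetric designs). Regenerate with:

```sh
python scripts/make_sphere_design.py --seed 42 --out src/dkifit/_sphere45.py
```

### Accuracy of numerical vs analytical estimators

Because `K(n)` is rational, the design integrates it only approximately.
Measured over 2000 random crossing-fiber voxels, the numerical−analytical
MK difference has median ~1.3e-4 and max ~9e-4; for the named reference
fixtures it is ≤ 1.5e-4. RK's perpendicular-circle trapezoid rule
converges spectrally (error ~1e-7 at 30 angles) and AK's two routes are
algebraically identical. Consequence: one acceptance test asserting MK
agreement at 1e-4 on arbitrary random voxels fails by design; the
tolerance is tighter than the intrinsic quadrature error of any
45-direction scheme. Use `mk_analytical` when exactness matters.

## WMTI

The two-compartment white-matter model (one stick-like intra-axonal and
one Gaussian extra-axonal compartment, fibers aligned) is inverted from
the DKI fit:

1. **Maximum kurtosis** — coarse search over a 100-point Fibonacci set,
   then BFGS refinement in spherical angles (falls back to the coarse
   optimum, flagged, if refinement fails to improve).
2. **Axonal water fraction** — `awf = Kmax / (Kmax + 3)`; negative `Kmax`
   clips to 0 with a flag.
3. **Compartmental diffusivities** — for each direction in the
   45-design, the square-root decoupling
   `D_i(n) = D(n)·(1 − √(K(n)(1−f)/(3f)))`,
   `D_e(n) = D(n)·(1 + √(K(n)f/(3(1−f))))`;
   negative radicands are clamped to zero and flagged. Full intra- and
   extra-axonal tensors are then recovered by linear least squares over
   the sampled directions; tortuosity is the extra-axonal AD/RD ratio.

`awf` outside (0, 1) makes the decoupling singular: the result is a
flagged all-NaN record rather than an exception. Low diffusion
anisotropy (FA < 0.1) flags a violated aligned-fiber assumption.

## MSDKI and SMT2

Powder averaging takes the arithmetic mean signal per b-shell, which
removes orientation-distribution effects. The mean-signal model

```
log S̄(b) = log S̄0 − b·MSD + (b²/6)·MSD²·MSK
```

is fitted by WLS with weights `N_g·S̄(b)` (shell size × mean signal);
at least three shells including b≈0 are required.

The dispersion correction `Ψ = 6/5 − (2/5)·‖D‖_F²/MD²` links the two
mean kurtosis flavours via `MSK = MKT − Ψ`. This identity is exact only
in the b→0 limit: at finite b the powder average carries higher
cumulants, biasing the fitted MSK roughly linearly in the maximum
b-value (~0.3 at b = 3 for a single anisotropic Gaussian). The test
suite verifies the identity by Richardson extrapolation of the fitted
MSK to b → 0.

SMT2 maps `(MSD, MSK)` to an axonal fraction `f` and intrinsic
diffusivity: the forward polynomial-rational `msk(f)` is strictly
increasing from 0 to 2.4 on [0, 1] and inverted by bisection;
`D_i = 3·MSD/(1 + 2(1−f)²)`. MSK outside [0, 2.4] clips to the boundary
with a flag.

## Simulator

`CompartmentModel` sums axially symmetric Gaussian compartments
(fraction, AD, RD, orientation). `gt_tensors` returns the exact
ground-truth `D` (fraction-weighted mean) and `W` (symmetrized second
central moment of the compartment tensors divided by MD²) — validated in
tests against a brute-force 81-element evaluation at 1e-12.
`multi_gaussian_signal` produces the exact mixture signal;
`dki_signal` produces the pure cumulant-model signal (the two differ at
high b by the truncation error, deliberately). Rician noise draws
`√((S+ε1)² + ε2²)` with `ε ~ N(0, (S0/SNR)²)`, seeded for
reproducibility. `fixtures()` provides named reference voxels (isotropic
mixture, single fiber, crossings, and the powder-average cases).

## CLI

`dkifit fit {dti,dki,msdki,wmti}` writes one float32 NIfTI per scalar
plus a float64 fit archive (`fit_params.txt` + `fit_archive.json`) and a
`manifest.json` (command, full config, package versions, wall time,
per-voxel flag counts). `dkifit metrics ARCHIVE_DIR` recomputes scalar
maps from the archive without refitting (e.g. switching estimator or
clip bounds). `dkifit simulate FIXTURE` writes a replicated-voxel DWI
volume, FSL gradient files and the ground-truth tensors. Exit codes:
0 success, 2 validation failure, 3 I/O failure. Gradient text files are
written with 9 decimal places, which bounds simulate→fit round trips
through files at ~1e-7.

## Limitations

- The DKI fit is unconstrained; noisy data can yield negative
  directional kurtosis ("black voxels"). Clipping bounds
  (`--clip-min/--clip-max`) and per-voxel flags surface this rather than
  failing the run.
- WMTI assumes a single aligned fiber population; results in crossing or
  isotropic voxels are flagged, not rejected.
- `MSK = MKT − Ψ` holds at b→0 only (see above); the fitted MSK at
  acquisition b-values is a different, b-dependent estimand.
- Numerical MK inherits the spherical design's quadrature error
  (~1e-4 median on crossing voxels); prefer the analytical route.
- No preprocessing (denoising, unringing, motion correction) is
  included; inputs are assumed preprocessed.
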