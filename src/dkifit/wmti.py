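"""White Matter Tract Integrity (WMTI): a two-compartment readout of the
DKI fit for well-aligned-fiber voxels.

For a voxel made of a non-exchanging intra-axonal (stick-like) and
extra-axonal (hindered) Gaussian compartment, the directional kurtosis
carries the compartment heterogeneity.  The pipeline:

1. find the maximum directional kurtosis K_max (coarse sphere scan plus
   quasi-Newton refinement in spherical coordinates);
2. axonal water fraction  awf = K_max / (K_max + 3);
3. per direction n, decouple the compartment diffusivities

       D_i(n) = D(n) [1 - sqrt(K(n) (1-f) / (3 f))]
       D_e(n) = D(n) [1 + sqrt(K(n) f / (3 (1-f)))]

   (the extra-axonal diffusivity is taken as the larger branch);
4. fit a tensor to each compartment's directional samples by linear least
   squares and read scalar metrics: axonal diffusivity = trace(D_ia),
   hindered AD/RD = eigenvalues of D_ea, tortuosity = AD_ea / RD_ea.

The model assumes a single fiber orientation; on isotropic or crossing
voxels it still runs but the result is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .kurtosis_metrics import SPHERE45, dti_scalars
from .simulator import fibonacci_directions, sphere_vector
from .tensor_core import (D_MULTIPLICITY, D_ORDER, DiffusionTensor,
                          KurtosisFit, apparent_diffusivity,
                          apparent_kurtosis, expand_d)

__all__ = [
    "WMTIResult",
    "max_kurtosis",
    "awf_from_kmax",
    "compartmental_diffusivities",
    "fit_wmti",
    "DegenerateVoxelError",
]


class DegenerateVoxelError(ValueError):
    """Compartment decoupling is undefined (awf exactly 0 or 1)."""


@dataclass(frozen=True)
class WMTIResult:
    """Two-compartment parameters of one voxel.

    ``axonal_diffusivity`` is the trace (sum of eigenvalues) of the
    intra-axonal tensor; ``axonal_mean_diffusivity`` the trace/3 variant.
    """

    awf: float
    kmax: float
    kmax_direction: np.ndarray
    d_ia: np.ndarray               # 6 unique elements, um^2/ms
    d_ea: np.ndarray               # 6 unique elements, um^2/ms
    axonal_diffusivity: float
    hindered_ad: float
    hindered_rd: float
    tortuosity: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def axonal_mean_diffusivity(self) -> float:
        return self.axonal_diffusivity / 3.0


# ---------------------------------------------------------------------------
# Maximum kurtosis search
# ---------------------------------------------------------------------------

#: deterministic 100-direction coarse-scan set
_COARSE100 = fibonacci_directions(100)


def max_kurtosis(fit: KurtosisFit, n_coarse: int = 100):
    """Maximum directional kurtosis and its direction.

    Coarse scan over ``n_coarse`` quasi-uniform directions, then
    quasi-Newton (BFGS) refinement of K in spherical coordinates.
    Antipodal directions are identified; the returned vector has a
    non-negative z component (positive x, then y, breaking ties).
    Returns ``(kmax, direction, flags)``.
    """
    dirs = _COARSE100 if n_coarse == 100 else fibonacci_directions(n_coarse)
    k = apparent_kurtosis(fit, dirs)
    best = int(np.argmax(k))
    k0, n0 = float(k[best]), dirs[best]
    flags: list[str] = []

    theta0 = math.acos(min(1.0, max(-1.0, n0[2])))
    phi0 = math.atan2(n0[1], n0[0])

    def neg_k(x):
        return -apparent_kurtosis(fit, sphere_vector(x[0], x[1]))

    res = minimize(neg_k, np.array([theta0, phi0]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 200})
    k_ref = float(-res.fun)
    if not np.isfinite(k_ref) or k_ref < k0:
        flags.append("kmax refinement failed; coarse-scan value used")
        k_ref, n_ref = k0, n0
    else:
        n_ref = sphere_vector(res.x[0], res.x[1])
        if not res.success:
            flags.append("kmax refinement did not report convergence")
    # canonical antipodal representative
    for c in (2, 0, 1):
        if abs(n_ref[c]) > 1e-12:
            if n_ref[c] < 0:
                n_ref = -n_ref
            break
    return k_ref, n_ref, tuple(flags)


def awf_from_kmax(kmax: float):
    """Axonal water fraction awf = kmax / (kmax + 3), in [0, 1).

    Negative kmax is clipped to 0 and flagged.  Returns ``(awf, flags)``.
    """
    flags: tuple[str, ...] = ()
    if kmax < 0:
        flags = ("negative kmax clipped to 0",)
        kmax = 0.0
    return kmax / (kmax + 3.0), flags


# ---------------------------------------------------------------------------
# Compartment decoupling
# ---------------------------------------------------------------------------

def compartmental_diffusivities(fit: KurtosisFit, awf: float, n):
    """Directional intra/extra-axonal diffusivities ``(D_i(n), D_e(n))``.

    ``n`` may be one unit vector or an (M, 3) stack.  Negative radicands
    (possible for noisy negative K(n)) are clamped to zero and flagged;
    D_i is floored at 0.  Returns ``(d_i, d_e, flags)``.
    """
    if not 0.0 < awf < 1.0:
        raise DegenerateVoxelError(
            f"awf={awf} leaves no two-compartment decomposition")
    n = np.asarray(n, dtype=float)
    single = n.ndim == 1
    n2 = np.atleast_2d(n)
    dn = apparent_diffusivity(fit, n2)
    kn = apparent_kurtosis(fit, n2)
    flags: list[str] = []
    rad_i = kn * (1.0 - awf) / (3.0 * awf)
    rad_e = kn * awf / (3.0 * (1.0 - awf))
    if np.any(rad_i < 0):
        flags.append("negative radicand clamped (K(n) < 0)")
    d_i = np.maximum(dn * (1.0 - np.sqrt(np.maximum(rad_i, 0.0))), 0.0)
    d_e = dn * (1.0 + np.sqrt(np.maximum(rad_e, 0.0)))
    if single:
        return float(d_i[0]), float(d_e[0]), tuple(flags)
    return d_i, d_e, tuple(flags)


def _tensor_from_samples(directions: np.ndarray, values: np.ndarray):
    """Least-squares symmetric tensor from directional samples
    d(n) = n_i n_j T_ij."""
    A = np.stack([directions[:, i] * directions[:, j] for i, j in D_ORDER],
                 axis=1) * D_MULTIPLICITY
    sol, _, _, _ = np.linalg.lstsq(A, values, rcond=None)
    return sol


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def fit_wmti(fit: KurtosisFit,
             directions: np.ndarray | None = None) -> WMTIResult:
    """Run the full WMTI pipeline on one DKI fit.

    ``directions`` defaults to the 45-direction sphere design.  Isotropic
    or near-isotropic voxels (model assumptions violated) are flagged but
    a numeric result is still returned; voxels whose awf degenerates to
    0 or 1 yield a null (NaN) result with a flag.
    """
    dirs = SPHERE45 if directions is None else np.asarray(directions)
    kmax, kdir, flags = max_kurtosis(fit)
    awf, f2 = awf_from_kmax(kmax)
    flags = tuple(flags) + f2

    scalars_nan = dict(axonal_diffusivity=float("nan"),
                       hindered_ad=float("nan"), hindered_rd=float("nan"),
                       tortuosity=float("nan"))
    if not 0.0 < awf < 1.0:
        return WMTIResult(awf=awf, kmax=kmax, kmax_direction=kdir,
                          d_ia=np.full(6, np.nan), d_ea=np.full(6, np.nan),
                          flags=flags + ("degenerate awf; null result",),
                          **scalars_nan)

    if dti_scalars(fit.dt)["fa"] < 0.1:
        flags = flags + ("low diffusion anisotropy; "
                         "aligned-fiber assumption questionable",)

    d_i, d_e, f3 = compartmental_diffusivities(fit, awf, dirs)
    flags = flags + f3
    d_ia = _tensor_from_samples(dirs, d_i)
    d_ea = _tensor_from_samples(dirs, d_e)

    ea = DiffusionTensor.from_elements(d_ea)
    hindered_ad = float(ea.evals[0])
    hindered_rd = float((ea.evals[1] + ea.evals[2]) / 2.0)
    if hindered_rd > 0:
        tortuosity = hindered_ad / hindered_rd
    else:
        tortuosity = float("nan")
        flags = flags + ("non-positive hindered RD; tortuosity undefined",)
    if np.isfinite(tortuosity) and tortuosity < 1.0:
        flags = flags + ("tortuosity < 1; physically implausible voxel",)

    return WMTIResult(
        awf=awf, kmax=kmax, kmax_direction=kdir, d_ia=d_ia, d_ea=d_ea,
        axonal_diffusivity=float(np.trace(expand_d(d_ia))),
        hindered_ad=hindered_ad, hindered_rd=hindered_rd,
        tortuosity=tortuosity, flags=flags)
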