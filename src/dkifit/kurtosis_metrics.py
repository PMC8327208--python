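"""Rotationally invariant scalar metrics of the diffusion and kurtosis
tensors.

Mean kurtosis (MK) is the surface average of the directional kurtosis
K(n).  Two estimators are provided:

* numerical -- equal-weight average of K(n) over a fixed 45-direction
  sphere design (the symmetrized design integrates polynomials of degree
  up to 11 exactly; K(n) is rational in n, so the average is a high-order
  quadrature rather than an exact integral);
* analytical -- the exact closed form obtained by rotating W into the
  diffusion eigenframe and combining its six relevant elements with
  coefficient functions of the eigenvalues built from Carlson's symmetric
  elliptic integrals R_F and R_D, with dedicated branches for the
  eigenvalue-degeneracy singularities (prolate, oblate, isotropic).

Radial kurtosis (RK) is the average of K(n) over the unit circle
perpendicular to the principal eigenvector; axial kurtosis (AK) the value
along it.  MKT is the (rotation-invariant) trace-based mean of the
kurtosis tensor alone, and KFA its Frobenius-norm fractional anisotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._sphere45 import SPHERE45
from .tensor_core import (DiffusionTensor, KurtosisFit, MIN_DIFFUSIVITY,
                          apparent_kurtosis, expand_w)

__all__ = [
    "SphereDesign",
    "SPHERE45",
    "MK_DESIGN",
    "dti_scalars",
    "rotate_kurtosis_tensor",
    "mk_numerical",
    "mk_analytical",
    "mkt",
    "rk",
    "ak",
    "kfa",
    "carlson_rf",
    "carlson_rd",
    "perpendicular_circle",
]

#: relative eigenvalue-equality tolerance for the singular branches
EIG_DEGENERACY_RTOL = 1e-6


@dataclass(frozen=True)
class SphereDesign:
    """A fixed equal-weight quadrature direction set on the unit sphere."""

    directions: np.ndarray

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError(f"directions must be (N, 3); got {dirs.shape}")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("design directions must be unit vectors")
        object.__setattr__(self, "directions", dirs)

    @property
    def count(self) -> int:
        return len(self.directions)


#: the embedded 45-direction design used for MK quadrature
MK_DESIGN = SphereDesign(SPHERE45)


# ---------------------------------------------------------------------------
# Diffusion tensor scalars
# ---------------------------------------------------------------------------

def dti_scalars(dt: DiffusionTensor) -> dict[str, float]:
    """MD, RD, AD and FA from sorted eigenvalues.

    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||, which ranges over
    [0, 1]; an all-zero tensor returns FA = 0.
    """
    l1, l2, l3 = dt.evals
    md = (l1 + l2 + l3) / 3.0
    denom = l1 * l1 + l2 * l2 + l3 * l3
    if denom == 0:
        fa = 0.0
    else:
        fa = math.sqrt(1.5 * ((l1 - md) ** 2 + (l2 - md) ** 2
                              + (l3 - md) ** 2) / denom)
    return {"md": md, "rd": (l2 + l3) / 2.0, "ad": l1, "fa": fa}


# ---------------------------------------------------------------------------
# Carlson symmetric elliptic integrals (duplication algorithm)
# ---------------------------------------------------------------------------

def carlson_rf(x: float, y: float, z: float) -> float:
    """Carlson's R_F(x, y, z) by the duplication algorithm.

    Arguments must be non-negative with at most one zero; relative error
    is below 1e-10.
    """
    if min(x, y, z) < 0 or sorted((x, y, z))[1] == 0:
        raise ValueError("R_F requires non-negative args, at most one zero")
    x, y, z = float(x), float(y), float(z)
    while True:
        lam = math.sqrt(x * y) + math.sqrt(x * z) + math.sqrt(y * z)
        x, y, z = (x + lam) / 4, (y + lam) / 4, (z + lam) / 4
        mu = (x + y + z) / 3
        X, Y, Z = 1 - x / mu, 1 - y / mu, 1 - z / mu
        if max(abs(X), abs(Y), abs(Z)) < 1e-5:
            break
    e2 = X * Y - Z * Z
    e3 = X * Y * Z
    return (1 - e2 / 10 + e3 / 14 + e2 * e2 / 24
            - 3 * e2 * e3 / 44) / math.sqrt(mu)


def carlson_rd(x: float, y: float, z: float) -> float:
    """Carlson's R_D(x, y, z) by the duplication algorithm (z > 0)."""
    if min(x, y) < 0 or z <= 0 or x + y == 0:
        raise ValueError("R_D requires x, y >= 0 (not both zero) and z > 0")
    x, y, z = float(x), float(y), float(z)
    total = 0.0
    fac = 1.0
    while True:
        lam = math.sqrt(x * y) + math.sqrt(x * z) + math.sqrt(y * z)
        total += fac / (math.sqrt(z) * (z + lam))
        fac /= 4
        x, y, z = (x + lam) / 4, (y + lam) / 4, (z + lam) / 4
        mu = (x + y + 3 * z) / 5
        X, Y, Z = 1 - x / mu, 1 - y / mu, 1 - z / mu
        if max(abs(X), abs(Y), abs(Z)) < 1e-5:
            break
    ea = X * Y
    eb = Z * Z
    ec = ea - eb
    ed = ea - 6 * eb
    ee = ed + ec + ec
    return 3 * total + fac * (
        1 + ed * (-3 / 14 + 9 / 88 * ed - 4.5 / 26 * Z * ee)
        + Z * (ee / 6 + Z * (-9 / 22 * ec + 3 / 26 * Z * ea))
    ) / (mu * math.sqrt(mu))


# ---------------------------------------------------------------------------
# Kurtosis tensor rotation
# ---------------------------------------------------------------------------

def rotate_kurtosis_tensor(fit: KurtosisFit) -> np.ndarray:
    """W rotated into the diffusion eigenframe (full (3,3,3,3) array).

    In the returned frame axis 0 is e1, axis 1 is e2, axis 2 is e3.
    """
    R = fit.dt.evecs
    return np.einsum("ia,jb,kc,ld,ijkl->abcd", R, R, R, R, fit.kt_full)


# ---------------------------------------------------------------------------
# Mean kurtosis
# ---------------------------------------------------------------------------

def mk_numerical(fit: KurtosisFit, design: SphereDesign | None = None,
                 min_diffusivity: float = MIN_DIFFUSIVITY,
                 clip_range=None) -> float:
    """MK as the average directional kurtosis over the sphere design."""
    dirs = (MK_DESIGN if design is None else design).directions
    return float(np.mean(apparent_kurtosis(
        fit, dirs, min_diffusivity=min_diffusivity, clip_range=clip_range)))


def _alpha(x: float) -> float:
    """arctanh(sqrt(x))/sqrt(x) for x > 0, arctan form for x < 0."""
    if x > 0:
        s = math.sqrt(x)
        return math.atanh(s) / s
    s = math.sqrt(-x)
    return math.atan(s) / s


def _F1(l1, l2, l3, rtol=EIG_DEGENERACY_RTOL):
    """Coefficient of the rotated W_1111-type terms in the exact MK."""
    er = rtol * (l1 + l2 + l3) / 3.0
    if abs(l1 - l2) < er and abs(l2 - l3) < er:
        return 0.2
    if abs(l1 - l2) < er:
        return _F2(l3, l1, l2, rtol) / 2.0
    if abs(l1 - l3) < er:
        return _F2(l2, l1, l3, rtol) / 2.0
    rf_ = carlson_rf(l1 / l2, l1 / l3, 1.0)
    rd_ = carlson_rd(l1 / l2, l1 / l3, 1.0)
    return ((l1 + l2 + l3) ** 2 / (18 * (l1 - l2) * (l1 - l3))
            * (math.sqrt(l2 * l3) / l1 * rf_
               + (3 * l1 ** 2 - l1 * l2 - l1 * l3 - l2 * l3)
               / (3 * l1 * math.sqrt(l2 * l3)) * rd_
               - 1.0))


def _F2(l1, l2, l3, rtol=EIG_DEGENERACY_RTOL):
    """Coefficient of the rotated W_2233-type terms in the exact MK."""
    er = rtol * (l1 + l2 + l3) / 3.0
    if abs(l2 - l3) < er:
        if abs(l1 - l2) < er:
            return 0.4
        # prolate/oblate l2 == l3 branch
        lp = (l2 + l3) / 2.0
        a = _alpha(1.0 - l1 / lp)
        return (6 * (l1 + 2 * lp) ** 2 / (144 * lp ** 2 * (l1 - lp) ** 2)
                * (lp * (l1 + 2 * lp) + l1 * (l1 - 4 * lp) * a))
    rf_ = carlson_rf(l1 / l2, l1 / l3, 1.0)
    rd_ = carlson_rd(l1 / l2, l1 / l3, 1.0)
    return ((l1 + l2 + l3) ** 2 / (3 * (l2 - l3) ** 2)
            * ((l2 + l3) / math.sqrt(l2 * l3) * rf_
               + (2 * l1 - l2 - l3) / (3 * math.sqrt(l2 * l3)) * rd_
               - 2.0))


def mk_analytical(fit: KurtosisFit,
                  rtol: float = EIG_DEGENERACY_RTOL) -> float:
    """Exact surface average of the directional kurtosis.

    Requires finite, positive eigenvalues; returns NaN for invalid voxels.
    """
    l1, l2, l3 = fit.dt.evals
    if not np.all(np.isfinite(fit.dt.evals)) or min(l1, l2, l3) <= 0 \
            or not np.all(np.isfinite(fit.kt)):
        return float("nan")
    Wt = rotate_kurtosis_tensor(fit)
    return (_F1(l1, l2, l3, rtol) * Wt[0, 0, 0, 0]
            + _F1(l2, l1, l3, rtol) * Wt[1, 1, 1, 1]
            + _F1(l3, l2, l1, rtol) * Wt[2, 2, 2, 2]
            + _F2(l1, l2, l3, rtol) * Wt[1, 1, 2, 2]
            + _F2(l2, l1, l3, rtol) * Wt[0, 0, 2, 2]
            + _F2(l3, l2, l1, rtol) * Wt[0, 0, 1, 1])


# ---------------------------------------------------------------------------
# Mean kurtosis tensor and kurtosis fractional anisotropy
# ---------------------------------------------------------------------------

def mkt(fit: KurtosisFit) -> float:
    """Trace-based mean of W: (W1111 + W2222 + W3333 + 2 W1122 + 2 W1133
    + 2 W2233) / 5.  Rotation-invariant, independent of D."""
    w = fit.kt
    return float((w[0] + w[1] + w[2] + 2 * (w[9] + w[10] + w[11])) / 5.0)


#: fully symmetric rank-4 isotropic tensor I4_ijkl =
#: (d_ij d_kl + d_ik d_jl + d_il d_jk) / 3
_EYE4 = (np.einsum("ij,kl->ijkl", np.eye(3), np.eye(3))
         + np.einsum("ik,jl->ijkl", np.eye(3), np.eye(3))
         + np.einsum("il,jk->ijkl", np.eye(3), np.eye(3))) / 3.0


def kfa(fit: KurtosisFit) -> float:
    """Kurtosis fractional anisotropy ||W - MKT I4||_F / ||W||_F in [0, 1];
    zero by convention when W vanishes."""
    W = fit.kt_full
    norm = np.linalg.norm(W)
    if norm == 0:
        return 0.0
    return float(np.linalg.norm(W - mkt(fit) * _EYE4) / norm)


# ---------------------------------------------------------------------------
# Radial and axial kurtosis
# ---------------------------------------------------------------------------

def perpendicular_circle(e1: np.ndarray, n_angles: int = 30) -> np.ndarray:
    """Evenly spaced unit vectors perpendicular to e1.

    The in-plane basis is built deterministically by Gram-Schmidt against
    the coordinate axis least aligned with e1.
    """
    e1 = np.asarray(e1, dtype=float)
    axis = np.zeros(3)
    axis[np.argmin(np.abs(e1))] = 1.0
    u = axis - axis.dot(e1) * e1
    u /= np.linalg.norm(u)
    v = np.cross(e1, u)
    ang = np.arange(n_angles) * np.pi / n_angles  # antipodes identified
    return np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)


def _G1(l1, l2, l3, rtol=EIG_DEGENERACY_RTOL):
    if abs(l2 - l3) < rtol * (l1 + l2 + l3) / 3.0:
        return (l1 + 2 * l2) ** 2 / (24 * l2 ** 2)
    return ((l1 + l2 + l3) ** 2 / (18 * l2 * (l2 - l3) ** 2)
            * (2 * l2 + (l3 ** 2 - 3 * l2 * l3) / math.sqrt(l2 * l3)))


def _G2(l1, l2, l3, rtol=EIG_DEGENERACY_RTOL):
    if abs(l2 - l3) < rtol * (l1 + l2 + l3) / 3.0:
        return (l1 + 2 * l2) ** 2 / (12 * l2 ** 2)
    return ((l1 + l2 + l3) ** 2 / (3 * (l2 - l3) ** 2)
            * ((l2 + l3) / math.sqrt(l2 * l3) - 2.0))


def rk(fit: KurtosisFit, method: str = "analytical",
       n_perp: int = 30) -> float:
    """Radial kurtosis: mean K(n) over the circle perpendicular to e1.

    ``method='numerical'`` averages over ``n_perp`` evenly spaced
    perpendicular directions; ``'analytical'`` evaluates the closed form
    in the eigenframe (with the l2 == l3 singular branch).
    """
    if method == "numerical":
        if n_perp < 4:
            raise ValueError("numerical RK needs n_perp >= 4")
        circle = perpendicular_circle(fit.dt.evecs[:, 0], n_perp)
        return float(np.mean(apparent_kurtosis(fit, circle)))
    if method != "analytical":
        raise ValueError(f"unknown RK method {method!r}")
    l1, l2, l3 = fit.dt.evals
    if min(l2, l3) <= 0 or not np.all(np.isfinite(fit.kt)):
        return float("nan")
    Wt = rotate_kurtosis_tensor(fit)
    return (_G1(l1, l2, l3) * Wt[1, 1, 1, 1]
            + _G1(l1, l3, l2) * Wt[2, 2, 2, 2]
            + _G2(l1, l2, l3) * Wt[1, 1, 2, 2])


def ak(fit: KurtosisFit, method: str = "tensor") -> float:
    """Axial kurtosis K(e1).

    ``method='directional'`` contracts W with e1 directly;
    ``'tensor'`` uses MD^2 / lambda1^2 * rotated-W_1111.  The two are
    algebraically identical.
    """
    if method == "directional":
        return float(apparent_kurtosis(fit, fit.dt.evecs[:, 0]))
    if method != "tensor":
        raise ValueError(f"unknown AK method {method!r}")
    l1 = fit.dt.evals[0]
    Wt = rotate_kurtosis_tensor(fit)
    return float(fit.md ** 2 / l1 ** 2 * Wt[0, 0, 0, 0])
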