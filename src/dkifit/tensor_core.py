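"""DTI / DKI signal models: design matrices, least-squares fitting, and
directional diffusivity / kurtosis evaluation.

The DKI signal model expands the log signal in cumulants up to second
order in b:

    log S(n, b) / S0 = -b n_i n_j D_ij + (b^2 / 6) MD^2 n_i n_j n_k n_l W_ijkl

with D the rank-2 diffusion tensor (6 unique elements, um^2/ms) and W the
fully symmetric rank-4 kurtosis tensor (15 unique elements, dimensionless).
The linear solve is performed in the variables (D, MD^2 W); W is recovered
by dividing by the fitted MD^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionScheme

__all__ = [
    "DiffusionTensor",
    "KurtosisFit",
    "dti_design_matrix",
    "dki_design_matrix",
    "fit_dti",
    "fit_dki",
    "apparent_diffusivity",
    "apparent_kurtosis",
    "predict",
    "D_ORDER",
    "D_MULTIPLICITY",
    "W_ORDER",
    "W_MULTIPLICITY",
    "expand_d",
    "compress_d",
    "expand_w",
    "compress_w",
]

# ---------------------------------------------------------------------------
# Symmetric-tensor index bookkeeping (single source of truth, shared by the
# design matrix, tensor contractions and Frobenius norms).
# ---------------------------------------------------------------------------

#: unique-element order of the symmetric rank-2 tensor
D_ORDER = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))
#: number of index permutations mapping onto each unique element
D_MULTIPLICITY = np.array([1, 2, 2, 1, 2, 1], dtype=float)

#: unique-element order of the fully symmetric rank-4 tensor:
#: W1111, W2222, W3333, W1112, W1113, W1222, W2223, W1333, W2333,
#: W1122, W1133, W2233, W1123, W1223, W1233
W_ORDER = (
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2),
    (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
)
#: multinomial multiplicities 4!/prod(counts!)
W_MULTIPLICITY = np.array(
    [1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)

_W_LOOKUP = {}
for _pos, _idx in enumerate(W_ORDER):
    _W_LOOKUP[tuple(sorted(_idx))] = _pos


def expand_d(d6):
    """6 unique elements -> full symmetric 3x3 matrix."""
    d6 = np.asarray(d6, dtype=float)
    D = np.empty((3, 3))
    for v, (i, j) in zip(d6, D_ORDER):
        D[i, j] = D[j, i] = v
    return D


def compress_d(D):
    """Full symmetric 3x3 matrix -> 6 unique elements."""
    D = np.asarray(D, dtype=float)
    return np.array([D[i, j] for i, j in D_ORDER])


def expand_w(w15):
    """15 unique elements -> full symmetric (3,3,3,3) tensor."""
    w15 = np.asarray(w15, dtype=float)
    W = np.empty((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    W[i, j, k, l] = w15[_W_LOOKUP[tuple(sorted((i, j, k, l)))]]
    return W


def compress_w(W):
    """Full symmetric (3,3,3,3) tensor -> 15 unique elements."""
    W = np.asarray(W, dtype=float)
    return np.array([W[idx] for idx in W_ORDER])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric diffusion tensor with its eigen-decomposition.

    ``evals`` are sorted descending; ``evecs`` holds the matching unit
    eigenvectors as columns, flipped if necessary to form a right-handed
    frame.
    """

    elements: np.ndarray          # 6 unique values, um^2/ms
    evals: np.ndarray             # (3,) descending
    evecs: np.ndarray             # (3, 3), columns e1, e2, e3

    @classmethod
    def from_elements(cls, d6) -> "DiffusionTensor":
        D = expand_d(d6)
        evals, evecs = np.linalg.eigh(D)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
        if np.linalg.det(evecs) < 0:
            evecs = evecs.copy()
            evecs[:, 2] *= -1
        return cls(np.asarray(d6, dtype=float), evals, evecs)

    @property
    def matrix(self) -> np.ndarray:
        return expand_d(self.elements)

    @property
    def md(self) -> float:
        return float(np.mean(self.evals))


@dataclass(frozen=True)
class KurtosisFit:
    """Per-voxel DKI fit: diffusion tensor, kurtosis tensor, log S0."""

    dt: DiffusionTensor
    kt: np.ndarray                # 15 unique W elements, dimensionless
    log_s0: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def md(self) -> float:
        return self.dt.md

    @property
    def kt_full(self) -> np.ndarray:
        return expand_w(self.kt)

    @property
    def params(self) -> np.ndarray:
        """Packed linear parameter vector [D6, MD^2 * W15, log S0]."""
        return np.concatenate(
            [self.dt.elements, self.md ** 2 * self.kt, [self.log_s0]])


class FitError(RuntimeError):
    """Degenerate design or unusable voxel data."""


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def dti_design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(N, 7) rows: 6 monomials -b * mult * n_i n_j, then intercept 1."""
    b = scheme.bvals[:, None]
    n = scheme.bvecs
    cols = [n[:, i] * n[:, j] for i, j in D_ORDER]
    A = np.stack(cols, axis=1) * D_MULTIPLICITY
    return np.hstack([-b * A, np.ones((len(b), 1))])


def dki_design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(N, 22) rows for the log-domain DKI model.

    Columns: 6 diffusion monomials -b * mult * n_i n_j; 15 kurtosis
    monomials (b^2/6) * mult * n_i n_j n_k n_l (these columns multiply
    MD^2 * W, so the solve stays linear); intercept 1 for log S0.
    """
    b = scheme.bvals[:, None]
    n = scheme.bvecs
    d_cols = np.stack([n[:, i] * n[:, j] for i, j in D_ORDER],
                      axis=1) * D_MULTIPLICITY
    w_cols = np.stack(
        [n[:, i] * n[:, j] * n[:, k] * n[:, l] for i, j, k, l in W_ORDER],
        axis=1) * W_MULTIPLICITY
    return np.hstack([-b * d_cols, (b ** 2 / 6.0) * w_cols,
                      np.ones((len(b), 1))])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _prepare_signals(signals):
    """Clip non-positive values to a small positive floor before the log."""
    s = np.asarray(signals, dtype=float).ravel()
    flags = []
    if np.all(s <= 0):
        return None, ["all-zero voxel"]
    if np.any(s <= 0):
        floor = s[s > 0].min() * 1e-4
        s = np.where(s > 0, s, floor)
        flags.append("non-positive signals clipped")
    return s, flags


def _lls(X, y, weights=None):
    if weights is None:
        sol, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    else:
        sw = np.sqrt(weights)[:, None]
        sol, _, rank, _ = np.linalg.lstsq(X * sw, y * sw[:, 0], rcond=None)
    if rank < X.shape[1]:
        raise FitError(
            f"singular design matrix (rank {rank} < {X.shape[1]}): "
            "degenerate direction set")
    return sol


def _wls_solve(X, log_s, iterate_to_convergence=False, max_iter=20,
               tol=1e-6):
    """Two-step WLS: OLS pass, then reweighting with squared predictions.

    One reweighting pass by default; optionally iterated until the
    parameter vector changes by less than ``tol``.
    """
    p = _lls(X, log_s)
    for _ in range(max_iter if iterate_to_convergence else 1):
        w = np.exp(2.0 * (X @ p))
        p_new = _lls(X, log_s, weights=w)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return p


def _nls_solve(X, signals, p0):
    """Signal-domain least squares, parametrized by the linear coefficients."""

    def residuals(p):
        return np.exp(X @ p) - signals

    def jac(p):
        return np.exp(X @ p)[:, None] * X

    res = least_squares(residuals, p0, jac=jac, method="lm", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    return res.x


def _solve(X, signals, method):
    signals, flags = _prepare_signals(signals)
    if signals is None:
        return None, flags
    if len(signals) != X.shape[0]:
        raise FitError(
            f"{len(signals)} signals but {X.shape[0]} measurements in scheme")
    method = method.upper()
    log_s = np.log(signals)
    if method == "OLS":
        p = _lls(X, log_s)
    elif method == "WLS":
        p = _wls_solve(X, log_s)
    elif method == "WLS-ITER":
        p = _wls_solve(X, log_s, iterate_to_convergence=True)
    elif method == "NLS":
        p0 = _wls_solve(X, log_s)
        p = _nls_solve(X, signals, p0)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return p, flags


def fit_dti(signals, scheme: AcquisitionScheme, method: str = "WLS"):
    """Fit the DTI model; returns ``(DiffusionTensor, log_s0)``.

    ``None`` is returned in place of the tensor for an all-zero voxel.
    OLS/WLS minimize the log-domain residual; NLS refines in the signal
    domain starting from the WLS solution.
    """
    X = dti_design_matrix(scheme)
    if X.shape[0] < 7:
        raise FitError("DTI needs at least 7 measurements")
    p, flags = _solve(X, signals, method)
    if p is None:
        return None, float("nan")
    return DiffusionTensor.from_elements(p[:6]), float(p[6])


def fit_dki(signals, scheme: AcquisitionScheme,
            method: str = "WLS") -> KurtosisFit | None:
    """Fit the DKI model (22 parameters) to one voxel's signals.

    The linear solve is in (D, MD^2 W, log S0); the returned kurtosis
    tensor is the solved vector divided by the fitted MD^2.  Voxels whose
    fitted MD is non-positive are flagged and their W set to NaN.
    """
    X = dki_design_matrix(scheme)
    if X.shape[0] < 22:
        raise FitError("DKI needs at least 22 measurements")
    p, flags = _solve(X, signals, method)
    if p is None:
        return None
    dt = DiffusionTensor.from_elements(p[:6])
    md = dt.md
    if md <= 0:
        kt = np.full(15, np.nan)
        flags = list(flags) + ["non-positive mean diffusivity"]
    else:
        kt = p[6:21] / md ** 2
    if np.any(dt.evals < 0):
        flags = list(flags) + ["negative diffusion eigenvalue"]
    return KurtosisFit(dt=dt, kt=kt, log_s0=float(p[21]), flags=tuple(flags))


# ---------------------------------------------------------------------------
# Directional evaluation and prediction
# ---------------------------------------------------------------------------

#: floor (um^2/ms) guarding the D(n)^2 division in the kurtosis formula
MIN_DIFFUSIVITY = 1e-6


def apparent_diffusivity(fit, n):
    """Directional diffusivity D(n) = n_i n_j D_ij.

    ``fit`` may be a KurtosisFit or a DiffusionTensor; ``n`` one unit
    vector or an (M, 3) stack.
    """
    dt = fit.dt if isinstance(fit, KurtosisFit) else fit
    n = np.asarray(n, dtype=float)
    single = n.ndim == 1
    n = np.atleast_2d(n)
    out = np.einsum("pi,pj,ij->p", n, n, dt.matrix)
    return float(out[0]) if single else out


def apparent_kurtosis(fit: KurtosisFit, n, min_diffusivity: float =
                      MIN_DIFFUSIVITY, clip_range=None):
    """Directional kurtosis K(n) = MD^2 / D(n)^2 * n_i n_j n_k n_l W_ijkl.

    D(n) is floored at ``min_diffusivity`` in the denominator.  If
    ``clip_range`` is given, the result is clipped into [lo, hi].
    """
    n = np.asarray(n, dtype=float)
    single = n.ndim == 1
    n = np.atleast_2d(n)
    dn = np.maximum(apparent_diffusivity(fit, n), min_diffusivity)
    wn = np.einsum("pi,pj,pk,pl,ijkl->p", n, n, n, n, fit.kt_full)
    k = fit.md ** 2 / dn ** 2 * wn
    if clip_range is not None:
        k = np.clip(k, *clip_range)
    return float(k[0]) if single else k


def predict(fit: KurtosisFit, scheme: AcquisitionScheme) -> np.ndarray:
    """Forward-evaluate the fitted DKI model at the scheme's measurements."""
    X = dki_design_matrix(scheme)
    return np.exp(X @ fit.params)


def predict_dti(dt: DiffusionTensor, log_s0: float,
                scheme: AcquisitionScheme) -> np.ndarray:
    """Forward-evaluate a DTI model (Gaussian signal decay)."""
    X = dti_design_matrix(scheme)
    p = np.concatenate([dt.elements, [log_s0]])
    return np.exp(X @ p)
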