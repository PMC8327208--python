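"""Mean-signal DKI (MSDKI) and its two-compartment spherical-mean (SMT2)
conversion.

The powder average S-bar(b) -- the arithmetic mean of the signal over the
gradient directions of each shell -- depends only on b.  Its cumulant
expansion,

    log S-bar(b) = log S0 - b MSD + (b^2 / 6) MSD^2 MSK,

defines the mean signal diffusivity (MSD) and mean signal kurtosis (MSK),
fitted here by weighted least squares with per-shell weights
N_g * S-bar(b).

MSK relates to the kurtosis-tensor mean MKT through a dispersion
correction computed from the diffusion tensor alone:

    MSK = MKT - Psi,
    Psi = 6/5 - (2/5) (D11^2 + D22^2 + D33^2
                       + 2 D12^2 + 2 D13^2 + 2 D23^2) / MD^2.

Under the two-compartment stick model, MSK is a monotone rational
function of the axonal water fraction f alone:

    MSK(f) = (216 f - 504 f^2 + 504 f^3 - 180 f^4)
             / (135 - 360 f + 420 f^2 - 240 f^3 + 60 f^4),

inverted by bisection; the intrinsic diffusivity follows from
    MSD = D_I (1 + 2 (1-f)^2) / 3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionScheme
from .tensor_core import DiffusionTensor

__all__ = [
    "MSDKIResult",
    "powder_average",
    "fit_msdki",
    "psi",
    "msk_from_mkt",
    "smt2_forward",
    "smt2_from_msdki",
    "msdki_pipeline",
]


@dataclass(frozen=True)
class MSDKIResult:
    """Per-voxel mean-signal DKI parameters and SMT2 conversion."""

    msd: float                     # mean signal diffusivity, um^2/ms
    msk: float                     # mean signal kurtosis, dimensionless
    log_s0: float
    psi: float = float("nan")      # dispersion correction, when D available
    smt2_awf: float = float("nan")
    smt2_di: float = float("nan")
    flags: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Powder averaging and the mean-signal fit
# ---------------------------------------------------------------------------

def powder_average(signals, scheme: AcquisitionScheme):
    """Per-shell arithmetic signal means.

    Returns ``(b, s_mean, n_g)`` arrays ordered by b-value (b0 first when
    present).  Empty shells are excluded with a warning.
    """
    s = np.asarray(signals, dtype=float).ravel()
    if len(s) != scheme.n_measurements:
        raise ValueError(f"{len(s)} signals for {scheme.n_measurements} "
                         "measurements")
    b, means, ng = [], [], []
    for shell in scheme.shells:
        if shell.n_directions == 0:
            warnings.warn(f"empty shell at b={shell.b}; excluded")
            continue
        b.append(shell.b)
        means.append(float(np.mean(s[shell.indices])))
        ng.append(shell.n_directions)
    return np.array(b), np.array(means), np.array(ng)


def fit_msdki(shell_b, shell_means, shell_ng) -> MSDKIResult:
    """Weighted least squares of the mean-signal cumulant model.

    Regressors (1, -b, b^2/6) on log S-bar with weights N_g * S-bar(b);
    needs at least 3 shells including b0.  A non-positive fitted msd
    flags the voxel and leaves msk NaN.
    """
    b = np.asarray(shell_b, dtype=float)
    sbar = np.asarray(shell_means, dtype=float)
    ng = np.asarray(shell_ng, dtype=float)
    if len(b) < 3:
        raise ValueError("MSDKI needs at least 3 shells (including b=0)")
    if not np.any(b <= 0.05):
        raise ValueError("MSDKI needs a b=0 shell")
    if np.any(sbar <= 0):
        raise ValueError("non-positive shell means")
    X = np.stack([np.ones_like(b), -b, b ** 2 / 6.0], axis=1)
    sw = np.sqrt(ng * sbar)[:, None]
    beta, _, rank, _ = np.linalg.lstsq(X * sw, np.log(sbar) * sw[:, 0],
                                       rcond=None)
    if rank < 3:
        raise ValueError("degenerate shell structure for MSDKI")
    log_s0, msd = float(beta[0]), float(beta[1])
    if msd <= 0:
        return MSDKIResult(msd=msd, msk=float("nan"), log_s0=log_s0,
                           flags=("non-positive mean signal diffusivity",))
    # the quadratic regressor multiplies msd^2 * msk
    return MSDKIResult(msd=msd, msk=float(beta[2]) / msd ** 2,
                       log_s0=log_s0)


# ---------------------------------------------------------------------------
# Dispersion correction
# ---------------------------------------------------------------------------

def psi(dt: DiffusionTensor) -> float:
    """Dispersion correction Psi from the diffusion tensor.

    Psi = 6/5 - (2/5) * ||D||_F^2 / MD^2; rotation-invariant; NaN when
    MD = 0.
    """
    md = dt.md
    if md == 0 or not np.isfinite(md):
        return float("nan")
    frob2 = float(np.sum(dt.matrix ** 2))
    return 6.0 / 5.0 - (2.0 / 5.0) * frob2 / md ** 2


def msk_from_mkt(mkt_value: float, psi_value: float) -> float:
    """MSK = MKT - Psi."""
    return mkt_value - psi_value


# ---------------------------------------------------------------------------
# SMT2 conversion
# ---------------------------------------------------------------------------

def smt2_forward(awf: float) -> float:
    """MSK of the two-compartment stick model as a function of the axonal
    water fraction (monotone increasing on [0, 1]; range [0, 2.4])."""
    f = awf
    num = 216 * f - 504 * f ** 2 + 504 * f ** 3 - 180 * f ** 4
    den = 135 - 360 * f + 420 * f ** 2 - 240 * f ** 3 + 60 * f ** 4
    return num / den


#: MSK at awf = 1, the upper end of the invertible range
_MSK_MAX = smt2_forward(1.0)   # = 2.4


def smt2_from_msdki(msd: float, msk: float):
    """Invert the stick-model MSK relation; returns ``(awf, di, flags)``.

    Negative msk is clipped to 0 (flagged); msk above the awf=1 value 2.4
    maps to awf=1 (flagged).  di = 3 msd / (1 + 2 (1-awf)^2).  Non-finite
    inputs give NaN outputs.
    """
    if not (np.isfinite(msd) and np.isfinite(msk)) or msd <= 0:
        return float("nan"), float("nan"), ("invalid msd/msk input",)
    flags: tuple[str, ...] = ()
    if msk < 0:
        msk = 0.0
        flags = ("negative msk clipped to 0",)
    if msk >= _MSK_MAX:
        if msk > _MSK_MAX:
            flags = flags + ("msk above stick-model maximum; awf set to 1",)
        awf = 1.0
    elif msk == 0.0:
        awf = 0.0
    else:
        lo, hi = 0.0, 1.0
        for _ in range(60):   # bisection to ~1e-18 interval width
            mid = 0.5 * (lo + hi)
            if smt2_forward(mid) < msk:
                lo = mid
            else:
                hi = mid
        awf = 0.5 * (lo + hi)
    di = 3.0 * msd / (1.0 + 2.0 * (1.0 - awf) ** 2)
    return awf, di, flags


def msdki_pipeline(signals, scheme: AcquisitionScheme,
                   dt: DiffusionTensor | None = None) -> MSDKIResult:
    """Powder-average, fit, and convert one voxel's signals end to end."""
    b, sbar, ng = powder_average(signals, scheme)
    res = fit_msdki(b, sbar, ng)
    psi_value = psi(dt) if dt is not None else float("nan")
    awf, di, flags = smt2_from_msdki(res.msd, res.msk)
    return MSDKIResult(msd=res.msd, msk=res.msk, log_s0=res.log_s0,
                       psi=psi_value, smt2_awf=awf, smt2_di=di,
                       flags=res.flags + flags)
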