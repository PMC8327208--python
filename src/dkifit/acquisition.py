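"""Diffusion acquisition protocols: gradient tables, shells, image I/O.

Units convention
----------------
b-values are stored internally in ms/um^2 (1.0 == 1000 s/mm^2) and
diffusivities everywhere in the package are um^2/ms, so that typical white
matter values are of order one.  The FSL-dialect text files at the package
boundary are in s/mm^2 and are rescaled by 1/1000 on read (and back on
write).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionScheme",
    "Shell",
    "read_gradients",
    "write_gradients",
    "group_shells",
    "validate_for_dki",
    "ValidityReport",
    "load_dwi",
    "load_mask",
    "save_map",
]

#: default threshold (ms/um^2) below which a measurement counts as b=0;
#: 0.05 == 50 s/mm^2 so that near-zero b-values reported by some scanners
#: (b ~ 5 s/mm^2) are treated as b=0 volumes.
DEFAULT_B0_THRESHOLD = 0.05

#: default shell grouping tolerance (ms/um^2), accommodating scanner-reported
#: b-value jitter.
DEFAULT_SHELL_TOL = 0.05


class GradientFormatError(ValueError):
    """Malformed or inconsistent bval/bvec files."""


class GradientValidationError(ValueError):
    """Gradient table violates scheme invariants."""


@dataclass(frozen=True)
class Shell:
    """A group of measurements sharing a nominal b-value."""

    b: float                 # representative b-value, ms/um^2 (0.0 for b0)
    indices: np.ndarray      # measurement indices belonging to this shell

    @property
    def n_directions(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values and unit gradient directions of a dMRI protocol.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weightings in ms/um^2.
    bvecs : (N, 3) array
        Unit gradient directions; rows with b <= ``b0_threshold`` may be
        zero vectors.
    b0_threshold : float
        b-value (ms/um^2) below which a measurement counts as b=0.
    shell_tol : float
        b-value tolerance (ms/um^2) used to group measurements into shells.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD
    shell_tol: float = DEFAULT_SHELL_TOL

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientFormatError(
                f"bvecs must have shape (N, 3); got {bvecs.shape}")
        if bvecs.shape[0] != bvals.shape[0]:
            raise GradientFormatError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions")
        if np.any(bvals < 0):
            raise GradientValidationError("negative b-values")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > self.b0_threshold
        if np.any(np.abs(norms[dw] - 1.0) > 1e-4):
            bad = np.where(np.abs(norms - 1.0) > 1e-4)[0]
            raise GradientValidationError(
                f"non-unit gradient directions at diffusion-weighted "
                f"measurements {bad.tolist()}")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    # -- derived structure ------------------------------------------------
    @property
    def n_measurements(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def shells(self) -> list[Shell]:
        """Shell grouping at the scheme's default tolerance (b0 first)."""
        return group_shells(self, self.shell_tol)

    def unique_directions(self, tol: float = 1e-3) -> np.ndarray:
        """Distinct diffusion-weighted directions, antipodes identified."""
        dirs = self.bvecs[~self.b0_mask]
        kept: list[np.ndarray] = []
        for d in dirs:
            if not any(min(np.linalg.norm(d - k), np.linalg.norm(d + k)) < tol
                       for k in kept):
                kept.append(d)
        return np.array(kept).reshape(-1, 3)


def read_gradients(bval_path, bvec_path,
                   b0_threshold: float = DEFAULT_B0_THRESHOLD,
                   shell_tol: float = DEFAULT_SHELL_TOL) -> AcquisitionScheme:
    """Read an FSL-dialect bval/bvec pair.

    The bval file holds one whitespace-separated row of b-values in s/mm^2;
    the bvec file holds three rows (x, y, z) of the same length.  b-values
    are rescaled to ms/um^2 on read.
    """
    try:
        bvals = np.loadtxt(bval_path, dtype=float)
    except ValueError as exc:
        raise GradientFormatError(f"cannot parse {bval_path}: {exc}") from exc
    try:
        bvecs = np.loadtxt(bvec_path, dtype=float)
    except ValueError as exc:
        raise GradientFormatError(f"cannot parse {bvec_path}: {exc}") from exc
    bvals = np.atleast_1d(bvals)
    bvecs = np.atleast_2d(bvecs)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: rows are components
    if bvecs.shape[0] != bvals.shape[0]:
        raise GradientFormatError(
            f"bval file lists {bvals.shape[0]} measurements but bvec file "
            f"lists {bvecs.shape[0]}")
    return AcquisitionScheme(bvals / 1000.0, bvecs,
                             b0_threshold=b0_threshold, shell_tol=shell_tol)


def write_gradients(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write the scheme back to an FSL-dialect bval/bvec pair (s/mm^2)."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b * 1000.0:.6f}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in scheme.bvecs.T:
            fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")


def group_shells(scheme: AcquisitionScheme,
                 tol: float = DEFAULT_SHELL_TOL) -> list[Shell]:
    """Group measurements into b-value shells.

    Measurements with b <= ``scheme.b0_threshold`` form the b0 shell;
    remaining measurements whose b-values differ by <= ``tol`` share a
    shell.  The returned list is sorted by b-value (b0 shell first when
    present) and partitions the measurement index set.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    shells: list[Shell] = []
    b0_idx = np.where(scheme.b0_mask)[0]
    if len(b0_idx):
        shells.append(Shell(0.0, b0_idx))
    rest = np.where(~scheme.b0_mask)[0]
    # sort-and-sweep grouping: order-independent for fixed b multiset
    order = rest[np.argsort(scheme.bvals[rest], kind="stable")]
    current: list[int] = []
    b_ref = None
    for idx in order:
        b = scheme.bvals[idx]
        if b_ref is None or b - b_ref <= tol:
            current.append(idx)
            b_ref = b if b_ref is None else b_ref
        else:
            shells.append(Shell(float(np.mean(scheme.bvals[current])),
                                np.sort(np.array(current))))
            current, b_ref = [idx], b
    if current:
        shells.append(Shell(float(np.mean(scheme.bvals[current])),
                            np.sort(np.array(current))))
    return shells


@dataclass(frozen=True)
class ValidityReport:
    """Whether a scheme supports DTI / DKI fitting, with reasons."""

    dti_ok: bool
    dki_ok: bool
    n_nonzero_shells: int
    n_unique_directions: int
    messages: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_for_dki(scheme: AcquisitionScheme) -> ValidityReport:
    """Check the minimal protocol requirements of the two tensor models.

    DKI needs at least 15 distinct gradient directions for the kurtosis
    tensor and at least three b-value tiers, of which b=0 may be one --
    i.e. at least two distinct non-zero shells.  DTI needs 6 directions
    and a single non-zero shell.
    """
    shells = scheme.shells
    nonzero = [s for s in shells if s.b > scheme.b0_threshold]
    n_dirs = len(scheme.unique_directions())
    msgs = []
    dti_ok = len(nonzero) >= 1 and n_dirs >= 6
    dki_ok = len(nonzero) >= 2 and n_dirs >= 15
    if len(nonzero) < 2:
        msgs.append(
            "DKI requires at least three b-value tiers (b=0 plus two "
            f"non-zero shells); found {len(nonzero)} non-zero shell(s)")
    if n_dirs < 15:
        msgs.append(
            f"DKI requires at least 15 distinct gradient directions; "
            f"found {n_dirs}")
    if not dti_ok:
        msgs.append("scheme does not support DTI fitting")
    return ValidityReport(dti_ok=dti_ok, dki_ok=dki_ok,
                          n_nonzero_shells=len(nonzero),
                          n_unique_directions=n_dirs,
                          messages=tuple(msgs))


# -- NIfTI I/O ------------------------------------------------------------

def load_dwi(path):
    """Load a 4-D diffusion-weighted NIfTI volume.

    Returns ``(data, affine)``; the last axis of ``data`` indexes the
    measurements and must match the gradient table length.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    return data, img.affine


def load_mask(path, shape=None):
    """Load a 3-D boolean mask, optionally checking the spatial shape."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3-D, got shape {mask.shape}")
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match data {tuple(shape)}")
    return mask


def save_map(data, affine, path, dtype=np.float32):
    """Write a scalar map (or 4-D stack) as NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))
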