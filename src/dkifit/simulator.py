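"""Multi-compartment Gaussian voxel simulator.

Signals are sums of Gaussian diffusion compartments,

    S(n, b) / S0 = sum_m f_m exp(-b n_i n_j D^m_ij),

each compartment an axially symmetric tensor given by its axial/radial
diffusivity and principal-axis orientation.  The exact diffusion and
kurtosis tensors of the mixture are

    D_ij = sum_m f_m D^m_ij
    W_ijkl = (1/MD^2) [ sum_m f_m sym(D^m x D^m) - sym(D x D) ]_ijkl

where sym(A x B)_ijkl = A_ij B_kl + A_ik B_jl + A_il B_jk is the
symmetrized outer product -- W is the (scaled) covariance of the
compartment tensors and vanishes for a single compartment.

Pure-cumulant test signals are produced by plugging (D, W) into the DKI
log-signal expansion, so that fitting them recovers the tensors to
machine precision (the mixture signal itself carries cumulants beyond
second order in b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme
from .tensor_core import compress_d, compress_w, dki_design_matrix, expand_d, \
    expand_w

__all__ = [
    "Compartment",
    "CompartmentModel",
    "gt_tensors",
    "multi_gaussian_signal",
    "dki_signal",
    "add_rician_noise",
    "fixtures",
    "default_scheme",
    "fibonacci_directions",
    "sphere_vector",
]


def sphere_vector(theta: float, phi: float) -> np.ndarray:
    """Unit vector from polar angle theta and azimuth phi (radians)."""
    return np.array([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(theta)])


@dataclass(frozen=True)
class Compartment:
    """One axially symmetric Gaussian compartment.

    ``f`` is the water fraction, ``ad``/``rd`` the axial and radial
    diffusivities (um^2/ms), ``theta``/``phi`` the polar/azimuth angles
    (radians) of the principal axis.
    """

    f: float
    ad: float
    rd: float
    theta: float = 0.0
    phi: float = 0.0

    @property
    def axis(self) -> np.ndarray:
        return sphere_vector(self.theta, self.phi)

    @property
    def tensor(self) -> np.ndarray:
        v = self.axis
        return self.rd * np.eye(3) + (self.ad - self.rd) * np.outer(v, v)


@dataclass(frozen=True)
class CompartmentModel:
    """A simulated voxel: a list of Gaussian compartments."""

    compartments: tuple[Compartment, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.compartments)
        total = sum(c.f for c in comps)
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"fractions sum to {total}, expected 1")
        for c in comps:
            if not (c.ad >= c.rd >= 0):
                raise ValueError(
                    f"need ad >= rd >= 0, got ad={c.ad}, rd={c.rd}")
        object.__setattr__(self, "compartments", comps)

    def rotated(self, R: np.ndarray) -> "CompartmentModel":
        """The same mixture with every principal axis rotated by R."""
        comps = []
        for c in self.compartments:
            v = R @ c.axis
            theta = float(np.arccos(np.clip(v[2], -1, 1)))
            phi = float(np.arctan2(v[1], v[0]))
            comps.append(Compartment(c.f, c.ad, c.rd, theta, phi))
        return CompartmentModel(tuple(comps))


def gt_tensors(model: CompartmentModel):
    """Exact (D, W) of the mixture as (6,) and (15,) unique-element arrays.

    Raises if the mixture mean diffusivity is zero (W undefined).
    """
    tensors = [c.tensor for c in model.compartments]
    fracs = [c.f for c in model.compartments]
    D = sum(f * Dm for f, Dm in zip(fracs, tensors))
    md = np.trace(D) / 3.0
    if md == 0:
        raise ValueError("mean diffusivity is zero; W undefined")

    def sym_outer(A, B):
        return (np.einsum("ij,kl->ijkl", A, B)
                + np.einsum("ik,jl->ijkl", A, B)
                + np.einsum("il,jk->ijkl", A, B))

    W = sum(f * sym_outer(Dm, Dm) for f, Dm in zip(fracs, tensors))
    W = (W - sym_outer(D, D)) / md ** 2
    return compress_d(D), compress_w(W)


def multi_gaussian_signal(model: CompartmentModel,
                          scheme: AcquisitionScheme,
                          s0: float = 1.0) -> np.ndarray:
    """Exact mixture signal S(n, b) = s0 sum_m f_m exp(-b n D^m n)."""
    b = scheme.bvals
    n = scheme.bvecs
    out = np.zeros(len(b))
    for c in model.compartments:
        adc = np.einsum("pi,pj,ij->p", n, n, c.tensor)
        out += c.f * np.exp(-b * adc)
    return s0 * out


def dki_signal(d6, w15, scheme: AcquisitionScheme,
               s0: float = 1.0) -> np.ndarray:
    """Pure-cumulant signal from given (D, W): the DKI model evaluated
    forward, with no cumulants beyond second order in b."""
    md = np.trace(expand_d(d6)) / 3.0
    p = np.concatenate([np.asarray(d6, dtype=float),
                        md ** 2 * np.asarray(w15, dtype=float),
                        [np.log(s0)]])
    return np.exp(dki_design_matrix(scheme) @ p)


def add_rician_noise(signals, snr: float, s0: float = 1.0,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Corrupt signals with Rician noise of standard deviation s0/snr.

    S_noisy = sqrt((S + e1)^2 + e2^2) with e1, e2 ~ N(0, (s0/snr)^2).
    Deterministic for a fixed ``seed`` (or caller-provided ``rng``).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    signals = np.asarray(signals, dtype=float)
    sigma = s0 / snr
    e1 = rng.normal(0.0, sigma, signals.shape)
    e2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + e1) ** 2 + e2 ** 2)


# ---------------------------------------------------------------------------
# Reference acquisition and named fixtures
# ---------------------------------------------------------------------------

def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors from the golden-angle spiral
    (deterministic, seed-free)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.c_[r * np.cos(phi), r * np.sin(phi), z]


def default_scheme(n_directions: int = 33,
                   bvals=(1.0, 2.0, 3.0),
                   n_b0: int = 6) -> AcquisitionScheme:
    """Simulation protocol: n_directions per shell at b = 1, 2, 3 ms/um^2
    plus n_b0 b=0 volumes."""
    dirs = fibonacci_directions(n_directions)
    bv = [0.0] * n_b0
    vecs = [np.zeros(3)] * n_b0
    for b in bvals:
        bv.extend([b] * n_directions)
        vecs.extend(dirs)
    return AcquisitionScheme(np.array(bv), np.array(vecs))


def _aligned_pair(ad1, rd1, f1, ad2, rd2, theta=0.0, phi=0.0):
    return (Compartment(f1, ad1, rd1, theta, phi),
            Compartment(1 - f1, ad2, rd2, theta, phi))


def single_fiber(theta: float = 0.0, phi: float = 0.0) -> CompartmentModel:
    """Reference two-compartment aligned fiber: intra 0.99/0 (f=0.49),
    extra 2.26/0.87 (f=0.51)."""
    return CompartmentModel(_aligned_pair(0.99, 0.0, 0.49, 2.26, 0.87,
                                          theta, phi))


def crossing_fibers(theta1=np.radians(80), phi1=np.radians(10),
                    theta2=np.radians(20), phi2=np.radians(30),
                    ad_i=0.99, rd_i=0.0, ad_e=2.23, rd_e=0.87,
                    f_i=0.245, f_e=0.255) -> CompartmentModel:
    """Four-compartment crossing: two fibers, each split into an
    intra-like and extra-like component."""
    return CompartmentModel((
        Compartment(f_i, ad_i, rd_i, theta1, phi1),
        Compartment(f_e, ad_e, rd_e, theta1, phi1),
        Compartment(f_i, ad_i, rd_i, theta2, phi2),
        Compartment(f_e, ad_e, rd_e, theta2, phi2),
    ))


def fixtures() -> dict[str, CompartmentModel]:
    """Named simulation scenarios used across the test substrate.

    ``case1``..``case4`` are the four voxel toy-models (single tensor,
    healthy aligned pair, damaged-fiber variants, 60-degree crossing);
    the remaining entries are the scenarios used as reference values
    throughout the test suite.
    """
    half = np.radians(60.0)
    case2_comps = ((1.4, 0.1, 0.5), (2.0, 0.5, 0.5))
    case4 = tuple(
        Compartment(f / 2, ad, rd, theta, 0.0)
        for theta in (0.0, half)
        for ad, rd, f in case2_comps
    )
    return {
        "case1": CompartmentModel((Compartment(1.0, 1.7, 0.3),)),
        "case2": CompartmentModel(
            tuple(Compartment(f, ad, rd) for ad, rd, f in case2_comps)),
        # variant a: only f_intra and the extra-cellular RD change
        "case3a": CompartmentModel((Compartment(0.3, 1.4, 0.1),
                                        Compartment(0.7, 2.0, 0.7))),
        # variant b: intra AD lowered to 1.0 as well
        "case3b": CompartmentModel((Compartment(0.3, 1.0, 0.1),
                                           Compartment(0.7, 2.0, 0.7))),
        "case4": CompartmentModel(case4),
        "iso-mix": CompartmentModel(
            (Compartment(0.5, 0.99, 0.99), Compartment(0.5, 2.26, 2.26))),
        "single-fiber": single_fiber(),
        "crossing": crossing_fibers(),
        "crossing-90": crossing_fibers(theta1=np.radians(90),
                                              phi1=0.0),
        "two-crossing": CompartmentModel(
            (Compartment(0.5, 1.7, 0.3, 0.0, 0.0),
             Compartment(0.5, 1.7, 0.3, np.pi / 2, 0.0))),
    }
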