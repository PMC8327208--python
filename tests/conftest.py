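"""Shared test fixtures: the reference acquisition scheme, the named
voxel models, and helpers to build fits from exact ground-truth tensors."""

from __future__ import annotations

import numpy as np
import pytest

from dkifit.simulator import default_scheme, fixtures, gt_tensors
from dkifit.tensor_core import DiffusionTensor, KurtosisFit


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def models():
    return fixtures()


def gt_fit(model) -> KurtosisFit:
    """KurtosisFit holding a model's exact ground-truth tensors."""
    d6, w15 = gt_tensors(model)
    return KurtosisFit(dt=DiffusionTensor.from_elements(d6), kt=w15,
                       log_s0=0.0)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
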