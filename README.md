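# dkifit

Diffusion kurtosis imaging (DKI) model fitting, kurtosis scalar maps, and
two microstructural models derived from the kurtosis tensor, with a
multi-compartment Gaussian simulator for validation.

Diffusion MRI measures water displacement along sampled gradient
directions. The diffusion tensor (DTI) captures the Gaussian part of that
displacement distribution; DKI adds a fourth-order kurtosis tensor `W`
that quantifies the leading non-Gaussian correction, which in tissue
reports on cellular barriers and compartment heterogeneity. This package
implements:

- **Tensor fitting** — DTI (6 + 1 parameters) and DKI (21 + 1 parameters)
  by ordinary, weighted, iteratively reweighted, and non-linear least
  squares on the log-signal cumulant expansion.
- **Kurtosis scalars** — mean kurtosis (MK) by exact closed form (Carlson
  elliptic integrals, with all eigenvalue-degeneracy branches) and by
  spherical-design numerical averaging; radial (RK) and axial (AK)
  kurtosis, the kurtosis-tensor mean (MKT), and kurtosis fractional
  anisotropy (KFA), alongside the DTI scalars MD/RD/AD/FA.
- **WMTI** — the two-compartment white-matter model for aligned fibers:
  axonal water fraction from the maximum directional kurtosis, then
  intra- and extra-axonal diffusion tensors and tortuosity.
- **MSDKI / SMT2** — mean-signal DKI on powder-averaged shells (MSD,
  MSK), the dispersion correction Ψ linking MSK to MKT, and the
  spherical-mean two-compartment conversion to axonal fraction and
  intrinsic diffusivity.
- **Simulator** — sums of Gaussian compartments with exact ground-truth
  `D` and `W`, named reference fixtures, and seeded Rician noise.

Internally b-values are in ms/μm² (1.0 ≡ 1000 s/mm²); FSL-style
`bval`/`bvec` files in s/mm² are converted at the I/O boundary.

## Command-line use

Simulate a crossing-fiber voxel volume and fit DKI:

```console
$ dkifit simulate crossing --out-dir demo/sim --volume-shape 2,2,2
wrote simulated volume to demo/sim
$ dkifit fit dki --dwi demo/sim/dwi.nii.gz --bval demo/sim/dwi.bval \
    --bvec demo/sim/dwi.bvec --out-dir demo/maps
wrote 9 maps to demo/maps
```

`demo/maps/` then holds one float32 NIfTI per scalar (`md`, `rd`, `ad`,
`fa`, `mk`, `mkt`, `ak`, `rk`, `kfa`), a float64 fit archive
(`fit_params.txt` + `fit_archive.json`) and a `manifest.json` recording
the exact configuration, package versions and per-voxel flag counts.
Reading the maps back for this fixture gives

```
fa 0.4855
mk 1.5055
rk 1.914
ak 0.5665
kfa 0.5341
```

Other subcommands: `dkifit fit {dti,msdki,wmti} …` and
`dkifit metrics ARCHIVE_DIR` (recompute scalar maps from a saved fit
archive, e.g. with `--estimator numerical` or different clip bounds,
without refitting). Options can also come from a flat `key = value`
config file via `--config`; command-line flags override the file. Exit
codes: 0 success, 2 validation failure, 3 I/O failure.

## Library use

```python
import numpy as np
from dkifit import (default_scheme, fixtures, gt_tensors, dki_signal,
                    fit_dki, mk_analytical, rk, ak, fit_wmti)

scheme = default_scheme()                  # 3 shells x 33 dirs + 6 b0
model = fixtures()["single-fiber"]  # two aligned compartments
signal = dki_signal(*gt_tensors(model), scheme, s0=100.0)

fit = fit_dki(signal, scheme, method="WLS")
print(mk_analytical(fit), rk(fit), ak(fit))   # 1.4801 2.8824 0.4508

wmti = fit_wmti(fit)
print(wmti.awf, wmti.tortuosity)              # 0.49 2.5977
```

## Testing

```sh
python -m pytest -q tests/
```

The suite covers index bookkeeping, fitting, every closed-form scalar
against independent quadrature and library oracles, the microstructural
models, the simulator against a brute-force covariance oracle, and the
CLI end to end. `scripts/acceptance.py --seed N --out out.json` writes
the headline reference values as JSON. One acceptance test
(`test_mk_numerical_vs_analytical_100_random_voxels`) fails by design:
it asserts a 1e-4 agreement between the numerical and analytical MK
estimators that a 45-direction spherical design cannot deliver for
arbitrary voxels; see `docs/methods.md` for the analysis.

## Documentation

`docs/methods.md` describes the signal model, all estimators, the
45-direction spherical design and its provenance
(`scripts/make_sphere_design.py`), numerical edge-case handling, and
known limitations.
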