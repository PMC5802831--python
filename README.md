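# rdcorr

Model-free 6D relaxation–diffusion correlation NMR in Python.

A heterogeneous voxel is described by a joint distribution
P(R1, R2, Diso, DΔ, θ, φ) over longitudinal/transverse relaxation rates
and axisymmetric diffusion tensors (isotropic diffusivity, normalized
anisotropy, symmetry-axis orientation). `rdcorr` implements the complete
computational chain around that picture:

- **`rdcorr.tensor_math`** — axisymmetric tensor algebra: size/shape/
  orientation parameterization, matrix reconstruction, the closed-form
  generalized scalar product `b:D`, and the shape conversions
  (cone angle ζ ↔ bΔ, DΔ ↔ D∥/D⊥).
- **`rdcorr.acquisition`** — pseudo-random 6D acquisition design
  (τR, τe, b, bΔ, Θ, Φ): uniform draws in the transformed coordinates, the
  low-b anisotropy funnel `bΔ ← bΔ·(b − b_min)/b`, and the 30/15/10/5 %
  biases towards the linear / spherical / planar encoding lines and a
  fixed stability point; plus rectangular-grid schemes and CSV I/O.
- **`rdcorr.forward_model`** — the relaxation–diffusion kernel
  `[1 − exp(−τR·R1)]·exp(−τe·R2)·exp(−b:D)`, vectorized kernel matrices,
  multi-component signal synthesis, and additive Gaussian noise (σ = S0/SNR).
- **`rdcorr.phantom`** — the synthetic three-compartment voxel
  (aligned liquid crystal with D∥/D⊥ = 100, plus slow intracellular and
  fast extracellular isotropic yeast water).
- **`rdcorr.inversion`** — model-free Monte-Carlo NNLS inversion: random
  candidate components in the analysis range box, proliferation and
  mutation rounds with a provably non-increasing residual, bootstrap
  resampling of acquisition points, robust residual-noise estimation.
  The only constraints are non-negativity and the range box.
- **`rdcorr.analysis`** — 2D/1D projections of the pooled solution cloud
  (contour levels linearly spaced from 7.5 % to 90 % of the maximum),
  orientation distribution functions on a geodesic spherical mesh for
  components with D∥/D⊥ above threshold, and per-bootstrap sub-volume
  statistics (Pvol, E[X]).
- **`rdcorr.cli`** — orchestration: deterministic seeding of every stage,
  recovery experiments against ground truth, and (n_points, SNR) sweeps.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, an end-to-end check of the
analytic identities, scheme composition, and phantom parameter recovery
(1500 points, SNR 120, 100 bootstrap replicates, plus a sampling/SNR
trend sweep); it takes several minutes on one CPU.

## Command line

```sh
rdcorr generate-scheme --n 1500 --seed 1 --out scheme.csv
rdcorr simulate --phantom yeast-lc --scheme scheme.csv --snr 120 --seed 2 --out data.csv
rdcorr invert --data data.csv --scheme scheme.csv --n-boot 100 --seed 3 --out ensemble.json
rdcorr analyze --ensemble ensemble.json --odf --out report/
rdcorr recover --n-points 1500 --snr 120 --n-boot 100 --seed 4 --out run/
rdcorr sweep --n-points 500,1500,5000 --snr 120 --n-boot 25 --out sweep.json
```

Ensembles serialize to JSON by default, or to HDF5 when the output path
ends in `.h5`.

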