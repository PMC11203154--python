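# spikelft

Lattice-action analysis of binary spike rasters.

A spike raster is treated as an N × T binary *kernel* (neurons × clock-time
bins).  From it the package builds the "hypermatrix" of observables — the
N × N space-correlation matrix, the T × T time-correlation (joint-spike)
matrix, first-order averages and their quantile spectra — and places them
inside a lattice-action statistical model: a potential matrix A couples
neurons within a time bin, a causal kinetic matrix B couples time bins
within a neuron, and an input kernel I drives individual cells.  Gibbs
weights `exp(-lam * action)` define the statistical theory.

Included machinery:

- **kernelspace** — binary/spin kernel types (`sigma = 2*phi - 1` duality),
  index maps, first-order observables, quantile (order-statistics) spectra.
- **observables** — correlation/overlap matrices with free-field and
  connected variants, lagged autocorrelation profiles, ergodicity and
  stationarity diagnostics, Wasserstein distances between mean spectra.
- **action** — action evaluation in both representations (with the exact
  binary↔spin parameter transform), Lagrangian potential/kinetic split,
  pulse (momentum) kernel, exact-enumeration and Metropolis/thermodynamic-
  integration partition functions, Gibbs averages, the Gibbs variational
  bound, input partition function, ground-state search.
- **inference** — grand covariance over the mixed space-time index and
  closed-form inverse-Ising reconstruction: Callen (free-field), naive
  mean-field, TAP, independent-pair, Sessak–Monasson, plus the
  non-relativistic reduction to equal-time/equal-neuron covariance blocks.
- **renormalize** — bin (any-spike) renormalization, Kadanoff decimation,
  planar electrode lattices (including the standard 10×10-minus-corners,
  96-channel array), effective-coupling bookkeeping with exact
  coarse-partition perturbations on small systems.
- **ensembles** — trial ensembles, integer time-shift alignment by
  overlap-norm maximization (exhaustive or coordinate-ascent), ensemble
  hypermatrices with covariance corrections.
- **scaling_pca** — coupling ensembles with prescribed connectivity scaling,
  variance-scaling exponent fits, and the PCA-as-lattice-action map.
- **synthetic** — seeded generators: Bernoulli-with-refractory rasters,
  Gibbs-sampled rasters (global and causal-chain), columnar lattices,
  jittered trial ensembles.
- **io / cli** — delimited-text raster format with metadata headers,
  hypermatrix bundle directories with checksums, and the `spikelft` CLI.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(scaling-exponent recovery, coarse-graining reduction factor, electrode-mask
channel count, spin-moduli identity, and the property suites).

## CLI examples

```bash
# simulate a raster with a 5-bin refractory period
spikelft simulate refractory --neurons 50 --bins 2000 --rate 0.05 \
    --refractory 5 --seed 1 --out raster.csv

# compute and bundle its hypermatrix
spikelft hypermatrix --raster raster.csv --out bundle/

# coarse-grain 1 ms -> 10 ms
spikelft renorm --raster raster.csv --bin-time 10 --out coarse.csv

# sample a Gibbs model and reconstruct couplings
spikelft sample --params params/ --n 1000 --seed 2 --out samples/
spikelft infer --method sm --trials samples/ --out solution/

# coupling-scaling analysis
spikelft scaling --sizes 40,80,160,320 --alpha 0.5 --reps 50 --seed 7
```

Raster files are plain delimited text (rows = neurons, columns = bins,
cells 0/1) with `#`-prefixed headers:

```
# tau_ms=1.0
# t0_bin=0
# labels=n0,n1,n2
1,0,1,0
0,1,0,0
1,1,0,1
```

## Conventions

- Indices are 0-based internally; time bins are half-open `[t, t + tau)`.
- The kinetic matrix is causal: `B[a, b]` may be nonzero only for `b < a`
  (each bin couples only to strictly earlier bins).
- The space matrix Phi (N × N) is the *neuron-pair* correlation matrix and
  Pi (T × T) the *time* (joint-spike) matrix.
- Coupling inverters return the symmetric interaction matrix J of
  `P(s) ∝ exp(sum_{l<l'} J s s' + sum_l lam*h s)`; the relation to action
  parameters F is `J = -lam (F + F^T)`.
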