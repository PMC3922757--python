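# hocca — higher-order canonical correlation analysis

`hocca` finds coupled sparse representations of two jointly observed
data sets.  Classical CCA extracts feature pairs whose outputs are
maximally *linearly* correlated across the sets; ICA extracts sparse,
independent features within one set but knows nothing about the other.
Neither alone explains data such as natural image patches recorded
under two illuminants, where corresponding content is linked both by
linear correlation and by shared energy (variance) fluctuations, and
where efficient (sparse) coding matters within each condition.

HOCCA unifies the two: for whitened sets `x` and `y` it fits
orthonormal feature matrices `W_x`, `W_y` (columns paired one-to-one)
together with a correlation coefficient `ρ_i` and a shape parameter
`ν_i` per pair, by maximum likelihood under a coupled-sources model

    x = W_x s_x,  y = W_y s_y,
    (s_i^x, s_i^y) = σ_i · (z_1, z_2),   corr(z_1, z_2) = ρ_i,
    σ_i² ~ InvGamma(ν_i/2, (ν_i−2)/2),

so each coupled pair is a unit-variance bivariate Student-t:
`log p(s_i) = G(s_i' Λ(ρ_i) s_i; ν_i, ρ_i)` with
`G(u) = −(ν+2)/2 · log(1 + u/(ν−2)) + const`.  Small `ν` (near 2)
means sparse coordinates coupled through their variances; as `ν → ∞`
the model becomes Gaussian and the maximizing features provably reduce
to classical CCA.  The mutual information of a pair decomposes as
`I = c(ν) − ½ log₂(1 − ρ²)` with a closed-form non-Gaussian part
`c(ν)`.

The package is aimed at researchers in natural-scene statistics,
computational neuroscience and multi-view learning who need coupled
component analyses that are sensitive to higher-order dependencies.

It ships with:

- `HOCCA`, a scikit-learn-style estimator (plus functional interfaces),
- baselines: SVD-based CCA, orthonormal FastICA, whitening with greedy
  mutual-information matching,
- metrics: Amari index, Hoyer sparsity, Miller-Madow histogram MI,
  parametric bivariate-t MI, multi-information reduction,
- a synthetic benchmark generator and HOCCA-vs-CCA validation protocol,
- an adaptation pipeline: paired-patch extraction, PCA whitening with
  R²-based dimension choice, cross-condition prediction, Fano-factor
  noise model with noise-distortion curves, and rotated chromatic
  stimuli — exercised on synthetic paired pseudo-images,
- a CLI (`hocca fit | fit-cca | fit-ica | match | metrics | benchmark`).

See `docs/methods.md` for the model, estimation and evaluation details.

## Worked example

Generate data from a known coupled basis and recover it:

```python
import numpy as np
from hocca import (HOCCA, CoupledBasis, SourcePairParams, amari_index,
                   fit_cca, generate_coupled_data, mi_parametric,
                   sparsity_index)

rng = np.random.default_rng(0)
A_x, _ = np.linalg.qr(rng.standard_normal((8, 8)))
A_y, _ = np.linalg.qr(rng.standard_normal((8, 8)))
pairs = [SourcePairParams(rho=r, nu=n) for r, n in
         [(0.85, 2.4), (0.7, 3.0), (0.55, 2.6), (0.4, 3.5),
          (0.3, 2.8), (0.25, 4.0), (0.2, 3.2), (0.15, 2.5)]]
truth = CoupledBasis(W_x=A_x, W_y=A_y, pairs=pairs)
data = generate_coupled_data(truth, T=20_000, seed=1)

model = HOCCA(random_state=0).fit(data.x, data.y)
print("per-pair correlation rho:", np.round(model.rhos_, 3))
print("per-pair shape nu:       ", np.round(model.nus_, 2))
print("per-pair MI (bits):      ",
      np.round([mi_parametric(p) for p in model.pairs_], 3))

cca = fit_cca(data)
print("Amari index  HOCCA: %.4f   CCA: %.4f" % (
    amari_index(model.components_x_.T @ A_x),
    amari_index(cca.W_x.T @ A_x)))
Sx, _ = model.transform(data.x, data.y)
print("mean coordinate sparsity: %.3f (Gaussian reference 0.202)"
      % np.mean([sparsity_index(Sx[:, j]) for j in range(8)]))
```

Output:

```
per-pair correlation rho: [0.852 0.702 0.543 0.402 0.306 0.147 0.202 0.238]
per-pair shape nu:        [2.41 3.03 2.59 3.51 2.82 2.5  3.19 3.99]
per-pair MI (bits):       [1.022 0.549 0.33  0.174 0.139 0.099 0.085 0.079]
Amari index  HOCCA: 0.0044   CCA: 0.0523
mean coordinate sparsity: 0.400 (Gaussian reference 0.202)
```

The fitted `ρ_i` and `ν_i` track the generating values (pairs are
sorted by decreasing parametric MI, so the weakest couplings appear
last and in estimation-noise order), HOCCA's feature-recovery error
(Amari index of estimated-unmixing × true-mixing; 0 is perfect) is an
order of magnitude below CCA's, and the recovered coordinates are about
twice as sparse as Gaussian.

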