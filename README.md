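# lesionmap

Regression modelling of binary brain-lesion masks, with a calibrated
simulator for method validation.

Studies of white matter hyperintensities (WMHs) and similar lesions work
with one binary 3D mask per subject (1 = lesion at voxel `s`, 0 = not),
aligned to a common template, plus subject covariates such as age or blood
pressure. The standard analysis fits, at every voxel independently, a
binary-response GLM

    Y_i(s) ~ Bernoulli(p_i(s)),      Phi^{-1}(p_i(s)) = x_i' beta(s),

with probit link `Phi^{-1}`. Two well-known problems arise at the low
incidences typical of lesion data: maximum likelihood (ML) estimates are
badly biased at finite N, and under *data separation* (a covariate
combination perfectly predicting the outcome) they are infinite, silently
wrecking Wald inference. This package implements and compares three
estimators, plus the machinery needed to validate them on realistic
synthetic masks:

* **Voxel-wise probit ML** via Fisher scoring, with an exact
  linear-programming separation test so infinite estimates are reported as
  infinite, never as huge finite numbers.
* **Voxel-wise mean bias reduction (MeanBR)**: solves the adjusted score
  equations `U(beta) + A(beta) = 0` with `A = -F b` (`F` expected
  information, `b` the first-order bias of the MLE), which for the probit
  link reduces to `U*_t = sum_i [(y_i - mu_i) d_i / v_i - h_i eta_i / 2] x_it`.
  Estimates are finite even under complete separation and carry
  asymptotically smaller bias than ML.
* **Bayesian spatial probit GLMM (BSGLMM)**: `eta_i(s) = x_i'(alpha + beta(s))`
  with spatially varying coefficients under a multivariate pairwise-difference
  (intrinsic MCAR) prior over the 6-adjacency graph of active voxels and a
  Wishart hyperprior on the between-term precision; fitted by Gibbs sampling
  with Albert–Chib truncated-normal augmentation.

The simulator generates binary masks that actually *follow* a chosen probit
model voxel-wise while still looking like lesion data: it thresholds
`Phi(x_m' beta(s) + G_m(s)) > 0.5`, where `G_m` is a per-subject zero-mean
Gaussian random field with squared-exponential covariance
`C(h) = sigma^2 exp(-h^2 / 2 ell^2)`. With `sigma^2 = 1` the marginal law at
every voxel is exactly `Bernoulli(Phi(x'beta))`, so fitted estimates can be
scored against known truth; the correlation length `ell` is tuned so that
total lesion volume, 6-connected lesion count and average lesion size match
a reference cohort across age-decile bins. Evaluation utilities compute
Monte-Carlo bias, MSE, probability of underestimation (PU), truth
correlation, Dice overlap of top-|z| voxel sets, and null false-positive
tables.

## Worked example

```python
import numpy as np
from lesionmap import (ReferenceSpec, make_reference_maps, SimulationConfig,
                       GRFSpec, build_design, simulate_masks,
                       build_response_matrix, fit_voxelwise)

spec = ReferenceSpec()                      # 24 x 24 x 18 synthetic cohort
coeffs = make_reference_maps(spec)          # intercept + age truth maps
config = SimulationConfig(n_subjects=500, age_range=spec.age_range,
                          age_center=spec.age_center,
                          grf=GRFSpec(shape=spec.grid_shape, scale=1.5),
                          base_seed=7)
design = build_design(config)
masks = simulate_masks(coeffs, design, config)      # 500 binary volumes
resp = build_response_matrix(masks)
fits = fit_voxelwise(resp, design, method="meanbr")
print(resp.n_active, fits.n_separated_voxels)
rho = np.corrcoef(fits.estimates[0], coeffs.maps[0][tuple(resp.voxel_index.T)])[0, 1]
print(round(rho, 3))
```

prints

```
2891 0
0.939
```

i.e. 2,891 of the 10,368 grid voxels saw at least one lesion across the 500
subjects, no voxel needed a separation flag under mean-BR, and the fitted
intercept map correlates 0.94 with the generating truth on those voxels.
The same `resp`/`design` pair feeds `SpatialProbitGibbs` for the Bayesian
fit, and `lesionmap simulate/tune/fit/evaluate` expose the pipeline on the
command line for NIfTI mask directories and covariate CSVs.

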