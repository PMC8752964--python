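# Methods

This note records the models, numerical choices, and the design decisions
that were genuinely open, along with what the synthetic studies do and do
not demonstrate.

## Models

**Voxel-wise probit GLM.** At each active voxel `s` the responses are
`Y_i(s) ~ Bernoulli(Phi(x_i' beta(s)))`, fitted independently across voxels.
Maximum likelihood uses Fisher scoring with the expected information
`F = X' W X`, `W = diag(phi(eta)^2 / [Phi(eta) Phi(-eta)])`. Score residuals
and weights are evaluated through the tail-stable ratios
`a = phi/Phi(eta)`, `b = phi/Phi(-eta)` (`w = a b`, `(y-mu) d/v = y a - (1-y) b`)
computed via `log_ndtr`, which keeps the iteration well-behaved out to
`|eta| ~ 35`; the naive `d^2 / mu(1-mu)` form underflows around `|eta| ~ 10`
and silently stalls separated fits.

**Mean bias reduction.** The mean-BR estimator solves the adjusted score
equations `U(beta) + A(beta) = 0`, `A = -F(beta) b(beta)` with `b` the
first-order (Cox–Snell) bias of the MLE. For a binary GLM this adjustment
has the closed per-observation form `(1/2) h_i d'_i / d_i` added to the
working residual, where `h_i` are the hat values of the weighted least
squares at the current iterate; for the probit link `d'/d = -eta`, giving

    U*_t = sum_i [ (y_i - mu_i) d_i / v_i - h_i eta_i / 2 ] x_it .

This closed form was verified (to machine precision, and again in the frozen
test oracle) against the generic moment-based adjustment
`A_t = tr[F^{-1}(P_t + Q_t)]/2` with exact Bernoulli moments, and the
generic route against the Jeffreys-penalised logistic mode, the classical
anchor for this family of adjustments. Quasi-Fisher steps are capped at 2
per component per iteration; convergence is `max |U*| < 1e-8` within 100
iterations. Standard errors for both ML and mean-BR come from the inverse
*expected* information at the solution, so the two z-score families are
directly comparable.

**Separation.** A coefficient's MLE is infinite iff a direction of
recession `b` exists with `s_i x_i' b >= 0` for all observations
(`s_i = 2y_i - 1`) and `b_j != 0`. This is decided exactly by linear
programming (two LPs per coefficient over the cone intersected with the unit
box). The LP is run for any ML column that diverges (`|beta|_inf > 50`,
essentially beyond representable probit incidences), fails to converge, or
converges with `max |eta| > 5.5` — the latter catches quasi-separated
columns whose score underflows the tolerance at merely-large estimates.
Flagged coefficients are reported as signed infinities with infinite SE and
NaN z, never as large finite values.

**Bayesian spatial GLMM.** `eta_i(s) = x_i'(alpha + beta(s))` with flat
prior on `alpha`, intrinsic multivariate pairwise-difference (MCAR) prior on
the voxel fields (`beta(s_j) | rest ~ MVN(mean of face neighbours, Sigma/N_j)`),
and `Sigma^{-1} ~ Wishart(nu, I_P)`, `nu = 0` by default (improper; the
conditional is proper when `M - G > P - 1`, with `G` the number of graph
components). Gibbs sampling uses Albert–Chib truncated-normal augmentation;
all full conditionals are conjugate:

* latent `w_i(s) ~ N(eta, 1)` truncated by the response sign, drawn by
  inverse CDF through a compiled kernel (Acklam's inverse-normal
  approximation, relative error < 1.2e-9 — far below chain Monte-Carlo
  resolution);
* `beta(s_j)`: precision `N_j Sigma^{-1} + X'X`, updated in two
  coordinate-parity colours (no two face neighbours share a colour), which
  vectorises the single-site sweep without changing the stationary law;
* `alpha`: Gaussian with precision `M X'X`;
* `Sigma^{-1}`: Wishart with df `nu + (M - G)` — the rank of the
  pairwise-difference precision, i.e. the exponent carried by the intrinsic
  prior density — and scale `(I_P + sum_pairs dd')^{-1}` over
  neighbouring-coefficient differences `d`.

Because the intrinsic prior is invariant to per-term constant shifts of
`beta` (absorbed by `alpha`), the chain recenters after every sweep:
the active-voxel mean of each `beta` term is moved into `alpha`. This is a
deterministic reparameterisation along the flat direction and leaves the
posterior invariant while pinning the identifiable total effect
`alpha + beta(s)`, which is what all posterior summaries (mean, sd,
`z* = mean/sd`) report. Isolated active voxels get a zero-mean `N(0, Sigma)`
prior (the MCAR conditional is undefined at `N_j = 0`). Exactness anchors:
on one voxel the total effect has a flat prior, and the chain reproduces the
quadrature posterior of intercept-only probit; on two voxels with fixed
`Sigma` it reproduces 2D grid-integration moments.

## Simulator

Masks are `I{Phi(x_m' beta(s) + G_m(s)) > 0.5}` with `G_m` a zero-mean GRF
with squared-exponential covariance, simulated per subject. With unit
variance and the 0.5 threshold, `P(lesion) = Phi(x'beta)` exactly at every
voxel, so the generated data follow the fitted probit model marginally —
the property that makes truth-referenced bias/MSE/PU meaningful. Any other
variance/threshold pairing breaks this identity and triggers a warning.
The design is drawn once per study (ages uniform on the reference range,
centered by the *reference* offset so coefficient maps keep their meaning)
and held fixed across replicates; a flag allows redrawing.

**GRF backends.** The squared-exponential kernel factorises over axes, so
the grid covariance is a Kronecker product of three small 1D matrices; the
sampler contracts their symmetric square roots (eigendecompositions with
clipping of numerically negative eigenvalues, which for these severely
ill-conditioned 1D SE matrices is the robust factorisation) against white
noise. This is exact at every grid size and two orders of magnitude cheaper
than FFT circulant embedding at the grid sizes used here. A dense-Cholesky
backend (jitter `1e-10`) serves as the independent small-grid reference;
both backends are tested against the analytic covariance. Distances are in
voxel units, so `ell = 1.5` means 1.5 voxel edges. Fields are generated
over the full bounding box and masked only at thresholding, avoiding edge
artefacts. Per-subject noise uses counter-based Philox streams keyed by
`(seed, subject index)`, so a subject's field is invariant to batch size and
subject count; the simulator consumes single-precision noise (the threshold
comparison is insensitive to float32 granularity at Monte-Carlo resolution).

**Tuning.** The correlation length is chosen on a grid by matching medians
of total lesion volume, 6-connected lesion count and average lesion size
across ten age-decile bins between reference and simulated data. The
discrepancy score is the mean over bins and summaries of
`|med_sim - med_ref| / (|med_ref| + 1e-6)`; curves per scale are emitted so
the choice can also be made visually. The grid search is run conditionally
on the noise: every candidate scale reuses the same white-noise seed, so
only smoothness varies. Age bins are `[q_k, q_{k+1})` with the last bin
closed; zero-lesion subjects enter volume/count medians as zeros but are
excluded from average-size medians (the ratio is undefined). Automated
continuous optimisation of the scale is out of scope.

## Synthetic reference

Real coefficient maps come from a large reference cohort; the stand-in is
a pair of ellipsoidal "periventricular" cores with a linearly decaying
probit intercept spanning incidence ~0.4 at the core to below 0.005 at the
periphery (at mean age), a non-negative age-effect map peaked at the cores
(default 0.02 per year at peak, Gaussian decay in ellipsoidal distance),
an optional smooth seeded perturbation so the maps are not symmetric, and
an analysis mask at implied max-age incidence above 0.002. The default
24 x 24 x 18 grid yields ~3,000 active voxels so hundred-replicate studies
run in minutes. The geometry is deliberately cartoonish: it reproduces the
incidence *range*, spatial smoothness and age gradient of cohort-derived
maps, not their anatomy. Passing tests therefore demonstrate estimator
properties (bias orderings, calibration, separation handling) under a
correctly specified marginal model with realistic incidence structure —
not clinical realism, left–right symmetry, or registration/segmentation
effects, which are all out of scope.

## Desk-scale study sizes

The test suite runs reduced but statistically decisive versions of the
replicate studies: bias ordering at R = 200 replicates of N* = 250
subjects; the BSGLMM-vs-MeanBR MSE comparison on a 16-replicate subset with
shortened chains (the MSE margin in the rarest-incidence bin is several
fold, so 16 replicates decide it); false-positive control at N* = 600 with
a 2,000-iteration chain; PU at R = 120, N* = 600 with a 3.5-point
Monte-Carlo allowance. The acceptance script runs the full stated setups
(N* = 1000; R = 200; 6000-iteration chains). Chain defaults (6000/1000/5)
are desk-scale; production inference should scale these up by an order of
magnitude.

## Known limitations

* The simulator's noise is spatially *dependent* across voxels within a
  subject while all three fitted models assume conditional independence;
  marginal (per-voxel) inference is exactly calibrated by construction, but
  pooled quantities are not — e.g. the BSGLMM fixed effect `alpha` has an
  overconfident posterior under null simulations (observed ~3.7 posterior
  sds from zero at N = 500, stable in chain length). Voxel-level null z*
  maps remain conservative.
* Mean-BR's residual bias is below the Monte-Carlo noise floor at desk
  scale, so rate-of-decay checks are run on the ML bias (clearly O(1/N));
  mean-BR is verified to dominate ML at every sample size instead.
* Logit/cloglog links, robust variances, GPU execution, registration and
  segmentation are out of scope; the affine is carried through I/O but all
  statistics are computed in voxel index space.
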