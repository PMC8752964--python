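"""Bayesian spatial probit GLMM with MCAR spatially varying coefficients.

Model, per subject i and active voxel s:

    Y_i(s) ~ Bernoulli(Phi(eta_i(s))),   eta_i(s) = x_i' (alpha + beta(s)),

with flat prior on the fixed effects ``alpha``, a multivariate pairwise-
difference (intrinsic MCAR) prior coupling each voxel's P-vector ``beta(s)``
to its face-adjacent neighbours,

    beta(s_j) | beta(-s_j), Sigma  ~  MVN( mean of neighbours, Sigma / N(s_j) ),

and ``Sigma^{-1} ~ Wishart(nu, I_P)``.  Inference is by Gibbs sampling with
Albert-Chib truncated-normal data augmentation: latent ``w_i(s) ~ N(eta_i(s), 1)``
truncated to (0, inf) when y = 1 and to (-inf, 0] otherwise, which makes every
full conditional conjugate:

* ``beta(s_j)`` is multivariate normal with precision ``N(s_j) Sigma^{-1} + X'X``;
  voxels are swept in two face-adjacency colours (even/odd coordinate parity),
  so each colour's updates are mutually independent and can be vectorised
  without changing the stationary distribution;
* ``alpha`` is multivariate normal under the flat prior;
* ``Sigma^{-1}`` is Wishart with degrees of freedom ``nu + (M - G)`` (G = number
  of connected components of the active-voxel graph, i.e. the rank of the
  pairwise-difference precision) and scale ``(I_P + sum of outer products of
  neighbouring-coefficient differences)^{-1}``.

The joint MCAR prior is improper along per-term constant shifts of ``beta``
(compensated by ``alpha``); after each sweep the active-voxel mean of ``beta``
is moved into ``alpha`` (hierarchical recentering), a deterministic
reparameterisation that leaves the posterior invariant and pins the
identifiable total effect ``alpha + beta(s)``.  Posterior summaries (mean, sd
and z* = mean/sd) are reported for the total effect per term per voxel.

Isolated active voxels (no face neighbours) have an undefined MCAR
conditional; they receive a zero-mean normal prior with the current Sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.special import ndtr, ndtri
from scipy.stats import wishart
from sklearn.base import BaseEstimator

from ._latent import latent_update
from .glm import DesignMatrix
from .volume_io import ResponseMatrix, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "build_neighbours",
    "Adjacency",
    "PosteriorSummaryMaps",
    "SpatialProbitGibbs",
    "gibbs_fit",
    "posterior_z",
]


@dataclass
class Adjacency:
    """Symmetric 6-adjacency over the active voxel set."""

    matrix: sparse.csr_matrix  # (M, M) 0/1, symmetric, zero diagonal
    n_neighbours: np.ndarray  # (M,)
    colours: np.ndarray  # (M,) in {0, 1}: coordinate-parity two-colouring
    n_components: int

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pairs(self) -> int:
        return int(self.matrix.nnz // 2)


def build_neighbours(voxel_index: np.ndarray, grid: VoxelGrid | tuple) -> Adjacency:
    """Face (6-)adjacency restricted to the active voxel set.

    ``voxel_index`` is (M, 3) integer voxel coordinates.  Isolated voxels
    (zero neighbours) are allowed.
    """
    idx = np.asarray(voxel_index, dtype=np.intp)
    if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] == 0:
        raise ValueError("voxel_index must be a non-empty (M, 3) array")
    shape = grid.shape if isinstance(grid, VoxelGrid) else tuple(grid)
    m = idx.shape[0]
    flat = np.ravel_multi_index(tuple(idx.T), shape)
    lookup = {f: r for r, f in enumerate(flat)}
    rows, cols = [], []
    for axis in range(3):
        for step in (-1, 1):
            nb = idx.copy()
            nb[:, axis] += step
            ok = (nb[:, axis] >= 0) & (nb[:, axis] < shape[axis])
            nb_flat = np.ravel_multi_index(tuple(nb[ok].T), shape)
            src = np.nonzero(ok)[0]
            for r, f in zip(src, nb_flat):
                tgt = lookup.get(f)
                if tgt is not None:
                    rows.append(r)
                    cols.append(tgt)
    mat = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, m)
    )
    counts = np.asarray(mat.sum(axis=1)).ravel().astype(np.intp)
    n_comp, _ = connected_components(mat, directed=False)
    colours = (idx.sum(axis=1) % 2).astype(np.int8)
    return Adjacency(matrix=mat, n_neighbours=counts, colours=colours, n_components=n_comp)


@dataclass
class PosteriorSummaryMaps:
    """Posterior summaries of the total effect ``alpha + beta(s)`` per term."""

    grid: VoxelGrid
    voxel_index: np.ndarray
    term_names: tuple[str, ...]
    post_mean: np.ndarray  # (P, M)
    post_sd: np.ndarray  # (P, M)
    z_scores: np.ndarray  # (P, M)
    alpha_mean: np.ndarray  # (P,)
    alpha_sd: np.ndarray
    sigma_mean: np.ndarray  # (P, P)
    n_kept: int
    ess_alpha: np.ndarray = field(default=None)  # type: ignore[assignment]
    alpha_draws: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    probe_draws: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def to_volume(self, statistic: str, term: int | str, fill=np.nan) -> np.ndarray:
        if isinstance(term, str):
            term = self.term_names.index(term)
        arr = {"mean": self.post_mean, "sd": self.post_sd, "z": self.z_scores}[statistic]
        vol = np.full(self.grid.shape, fill, dtype=float)
        vol[tuple(self.voxel_index.T)] = arr[term]
        return vol


def _trunc_normal(eta, y_pos: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of N(eta, 1) truncated to (0, inf) where ``y_pos``
    else (-inf, 0]; tail-stable via the reflection identity."""
    tiny = np.finfo(eta.dtype).tiny
    # y = 0: w = eta + ndtri(u * Phi(-eta)); y = 1: w = eta - ndtri(u * Phi(eta)) reflected
    p = np.where(y_pos, ndtr(eta), ndtr(-eta))
    q = ndtri(np.clip(u * p, tiny, None).astype(np.float64))
    return np.where(y_pos, eta - q, eta + q)


class SpatialProbitGibbs(BaseEstimator):
    """Gibbs sampler for the Bayesian spatial probit GLMM.

    Parameters
    ----------
    n_iter, burn_in, thin : int
        Chain length, warm-up discarded, and post-burn-in thinning stride.
        The desk default (6000/1000/5) is far below the chain lengths used
        for production inference; scale up for final maps.
    nu : float
        Wishart prior degrees of freedom for ``Sigma^{-1}`` (0 = improper
        reference choice; the data/graph must then make the conditional
        proper, which requires ``M - G > P - 1``).
    fix_sigma : ndarray or None
        If given, ``Sigma`` is held fixed at this P x P matrix and the
        Wishart step is skipped (used for validation).
    recenter : bool
        Move the mean of ``beta`` into ``alpha`` each sweep (identifiability).
    seed : int
        Chain seed; the whole trajectory is reproducible.
    latent_dtype : {"float64", "float32"}
        Precision of the (N x M) latent-augmentation arrays.  Single
        precision roughly halves the cost of large chains; all P x P algebra
        and the posterior accumulators stay in double precision.
    probe_voxels : sequence of int or None
        Active-set row indices whose thinned total-effect draws are stored.

    Attributes (after ``fit``)
    ----------
    summary_ : PosteriorSummaryMaps
    alpha_, sigma_ : posterior means of the fixed effects and Sigma.
    """

    def __init__(
        self,
        n_iter: int = 6000,
        burn_in: int = 1000,
        thin: int = 5,
        nu: float = 0.0,
        fix_sigma=None,
        recenter: bool = True,
        seed: int = 0,
        latent_dtype: str = "float64",
        probe_voxels=None,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.nu = nu
        self.fix_sigma = fix_sigma
        self.recenter = recenter
        self.seed = seed
        self.latent_dtype = latent_dtype
        self.probe_voxels = probe_voxels

    def fit(self, X, Y, coords=None, adjacency: Adjacency | None = None, grid=None):
        """Run the chain.

        ``X`` is (N, P) (or a DesignMatrix), ``Y`` (N, M) binary (or a
        ResponseMatrix, which also supplies coords and grid); otherwise pass
        ``coords`` (M, 3) voxel coordinates (with ``grid``) or a prebuilt
        ``adjacency``.
        """
        term_names = None
        if isinstance(X, DesignMatrix):
            term_names = X.column_names
            X = X.values
        if isinstance(Y, ResponseMatrix):
            coords = Y.voxel_index
            grid = Y.grid
            Y = Y.values.T
        X = np.ascontiguousarray(X, dtype=float)
        Y = np.ascontiguousarray(Y)
        if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
            raise ValueError("X must be (N, P) and Y (N, M) with matching N")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        n, p = X.shape
        m = Y.shape[1]
        if term_names is None:
            term_names = tuple(f"term{t}" for t in range(p))
        if adjacency is None:
            if coords is None:
                raise ValueError("need coords, adjacency, or a ResponseMatrix")
            if grid is None:
                grid = VoxelGrid(shape=tuple(np.asarray(coords).max(axis=0) + 1))
            adjacency = build_neighbours(coords, grid)
        if adjacency.n_voxels != m:
            raise ValueError("adjacency size does not match the number of voxels")
        if coords is None:
            raise ValueError("voxel coords are required to build summary maps")
        coords = np.asarray(coords, dtype=np.intp)
        if grid is None:
            grid = VoxelGrid(shape=tuple(coords.max(axis=0) + 1))

        dtype = np.dtype(self.latent_dtype)
        rng = np.random.Generator(np.random.Philox(key=int(self.seed)))
        ypos = Y.astype(bool)
        Xd = X.astype(dtype)
        G = X.T @ X  # (P, P), shared by every voxel's conditional
        A = adjacency.matrix
        nbr = adjacency.n_neighbours
        iso = nbr == 0
        if iso.any():
            logger.info("%d isolated active voxels get a N(0, Sigma) prior", int(iso.sum()))
        # prior precision multiplier: N(s_j), but 1 for isolated voxels (zero-mean prior)
        prior_mult = np.where(iso, 1, nbr).astype(float)
        colour_groups = [np.nonzero(adjacency.colours == c)[0] for c in (0, 1)]
        colour_mats = [A[g].tocsr() for g in colour_groups]
        count_groups = []  # per colour: list of (Q multiplier, rows within group, rows in full set)
        for g in colour_groups:
            by_cnt = []
            for cnt in np.unique(prior_mult[g]):
                local = np.nonzero(prior_mult[g] == cnt)[0]
                by_cnt.append((float(cnt), local, g[local]))
            count_groups.append(by_cnt)
        e_rows, e_cols = A.nonzero()
        upper = e_rows < e_cols
        e_rows, e_cols = e_rows[upper], e_cols[upper]

        wish_df = self.nu + (m - adjacency.n_components)
        if self.fix_sigma is None and wish_df <= p - 1:
            raise ValueError(
                f"Wishart conditional improper: nu + (M - G) = {wish_df} <= P - 1; "
                "increase nu or supply fix_sigma"
            )

        alpha = np.zeros(p)
        beta = np.zeros((m, p))
        sigma = np.eye(p) if self.fix_sigma is None else np.asarray(self.fix_sigma, float)
        sigma_inv = np.linalg.inv(sigma)

        keep = max(0, (self.n_iter - self.burn_in + self.thin - 1) // self.thin)
        sum_tot = np.zeros((m, p))
        sum_tot2 = np.zeros((m, p))
        sum_sigma = np.zeros((p, p))
        alpha_draws = np.empty((keep, p))
        probe = None
        if self.probe_voxels is not None:
            probe_idx = np.asarray(self.probe_voxels, dtype=np.intp)
            probe = np.empty((keep, len(probe_idx), p))
        kept = 0

        eta = np.empty((n, m), dtype=dtype)
        w = np.empty((n, m), dtype=dtype)
        sgn = np.where(ypos, 1.0, -1.0).astype(dtype)
        u_dtype = np.float32 if dtype == np.float32 else np.float64
        for it in range(self.n_iter):
            # --- latent truncated normals (compiled inverse-CDF kernel) ---
            np.matmul(Xd, (alpha[None, :] + beta).T.astype(dtype), out=eta)
            u = rng.random(size=(n, m), dtype=u_dtype)
            latent_update(eta, sgn, u, w)

            # --- beta: two-colour sweep of conjugate MVN updates ---
            xtw = (Xd.T @ w).astype(float)  # (P, M): X' w_j per voxel
            rhs_like = xtw.T - (G @ alpha)[None, :]  # (M, P)
            for A_c, group, by_cnt in zip(colour_mats, colour_groups, count_groups):
                nb_sum = A_c @ beta  # (g, P); neighbours are all other colour
                prior_rhs = nb_sum @ sigma_inv.T  # Sigma^{-1} sum_nbr beta
                rhs = prior_rhs + rhs_like[group]
                for cnt, local, sel in by_cnt:  # distinct precisions by neighbour count
                    Q = cnt * sigma_inv + G
                    L = np.linalg.cholesky(Q)
                    mean = np.linalg.solve(Q, rhs[local].T)  # (P, g)
                    noise = np.linalg.solve(L.T, rng.standard_normal((p, sel.size)))
                    beta[sel] = (mean + noise).T

            # --- alpha: flat prior, conjugate MVN ---
            resid = xtw.sum(axis=1) - G @ beta.sum(axis=0)
            Qa = m * G
            La = np.linalg.cholesky(Qa)
            alpha = np.linalg.solve(Qa, resid) + np.linalg.solve(
                La.T, rng.standard_normal(p)
            )

            # --- recentering (identifiability) ---
            if self.recenter:
                shift = beta.mean(axis=0)
                beta -= shift[None, :]
                alpha += shift

            # --- Sigma^{-1}: Wishart driven by neighbour differences ---
            if self.fix_sigma is None:
                diff = beta[e_rows] - beta[e_cols]
                scale = np.eye(p) + diff.T @ diff
                for attempt in range(3):
                    try:
                        sigma_inv = wishart.rvs(
                            df=wish_df, scale=np.linalg.inv(scale), random_state=rng
                        )
                        sigma_inv = np.atleast_2d(sigma_inv)
                        sigma = np.linalg.inv(sigma_inv)
                        break
                    except np.linalg.LinAlgError:  # pragma: no cover - jittered retry
                        logger.warning("non-PD Wishart scale; jittering (attempt %d)", attempt)
                        scale += 1e-8 * np.eye(p)
                else:  # pragma: no cover
                    raise np.linalg.LinAlgError("Sigma update failed after jittered retries")

            if np.abs(beta).max() > 1e6:  # pragma: no cover - divergence guard
                raise FloatingPointError(
                    f"beta diverged at iteration {it} (max |beta| > 1e6)"
                )

            # --- accumulate ---
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                total = alpha[None, :] + beta
                sum_tot += total
                sum_tot2 += total**2
                sum_sigma += sigma
                alpha_draws[kept] = alpha
                if probe is not None:
                    probe[kept] = total[probe_idx]
                kept += 1

        post_mean = (sum_tot / kept).T  # (P, M)
        var = sum_tot2.T / kept - post_mean**2
        post_sd = np.sqrt(np.clip(var, 0.0, None) * kept / max(kept - 1, 1))
        zero_sd = post_sd <= 0
        if zero_sd.any():
            logger.warning("%d voxel-terms have zero posterior sd", int(zero_sd.sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(zero_sd, np.nan, post_mean / post_sd)

        ess = _ess(alpha_draws)
        self.summary_ = PosteriorSummaryMaps(
            grid=grid,
            voxel_index=coords if coords is not None else np.empty((m, 3), dtype=np.intp),
            term_names=tuple(term_names),
            post_mean=post_mean,
            post_sd=post_sd,
            z_scores=z,
            alpha_mean=alpha_draws.mean(axis=0),
            alpha_sd=alpha_draws.std(axis=0, ddof=1),
            sigma_mean=sum_sigma / kept,
            n_kept=kept,
            ess_alpha=ess,
            alpha_draws=alpha_draws,
            probe_draws=probe,
        )
        self.alpha_ = self.summary_.alpha_mean
        self.sigma_ = self.summary_.sigma_mean
        self.coef_ = post_mean
        self.n_features_in_ = p
        return self


def _ess(draws: np.ndarray) -> np.ndarray:
    """Initial-positive-sequence effective sample size per column."""
    n, p = draws.shape
    out = np.empty(p)
    for j in range(p):
        x = draws[:, j] - draws[:, j].mean()
        var = x @ x / n
        if var == 0:
            out[j] = n
            continue
        rho_sum = 0.0
        for lag in range(1, n):
            rho = (x[:-lag] @ x[lag:]) / (n * var)
            if rho <= 0.0:
                break
            rho_sum += rho
        out[j] = n / (1.0 + 2.0 * rho_sum)
    return out


def gibbs_fit(
    responses: ResponseMatrix,
    X: DesignMatrix,
    n_iter: int = 6000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
    **kwargs,
) -> PosteriorSummaryMaps:
    """Thin wrapper over :class:`SpatialProbitGibbs` for a response matrix."""
    est = SpatialProbitGibbs(
        n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed, **kwargs
    )
    est.fit(X, responses)
    return est.summary_


def posterior_z(summaries: PosteriorSummaryMaps) -> np.ndarray:
    """Standardised posterior effects (mean / sd) per term per voxel."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(summaries.post_sd > 0, summaries.post_mean / summaries.post_sd, np.nan)
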