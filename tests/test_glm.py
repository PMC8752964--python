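"""Voxel-wise probit fitting: ML, mean bias reduction, separation handling."""

import json
from pathlib import Path

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr, ndtri

from lesionmap import (
    DesignMatrix,
    VoxelwiseProbitRegression,
    detect_separation,
    fit_meanbr_probit,
    fit_ml_probit,
)

DATA = Path(__file__).parent / "data"


def _random_fixture(rng, n=200, beta=(-0.5, 0.8)):
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = (rng.random(n) < ndtr(X @ np.asarray(beta))).astype(float)
    return y, X


class TestML:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0.05, 0.95)
            y = (rng.random(100) < p).astype(float)
            if y.std() == 0:
                continue
            fit = fit_ml_probit(y, np.ones((100, 1)))
            assert fit.estimates[0] == pytest.approx(ndtri(y.mean()), abs=1e-8)
            assert fit.converged

    def test_loglik_matches_derivative_free_optimum(self):
        """20-observation fixture: IRLS optimum ties a Nelder-Mead search."""
        rng = np.random.default_rng(3)
        y, X = _random_fixture(rng, n=20)
        fit = fit_ml_probit(y, X)

        def negll(b):
            eta = X @ b
            return -np.sum(np.where(y > 0.5, log_ndtr(eta), log_ndtr(-eta)))

        res = minimize(negll, np.zeros(2), method="Nelder-Mead",
                       options=dict(xatol=1e-9, fatol=1e-12, maxiter=10_000))
        assert fit.log_lik == pytest.approx(-res.fun, abs=1e-6)

    def test_matches_statsmodels_probit(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        y, X = _random_fixture(rng, n=500)
        fit = fit_ml_probit(y, X)
        ref = sm.Probit(y, X).fit(disp=0)
        assert np.allclose(fit.estimates, ref.params, atol=1e-7)

    def test_perfect_separation_flagged_nonfinite(self):
        rng = np.random.default_rng(1)
        x2 = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x2])
        y = (x2 > 0.0).astype(float)
        fit = fit_ml_probit(y, X)
        assert fit.separated.any()
        assert not np.isfinite(fit.estimates[fit.separated]).any()

    def test_constant_response_columns_fit_and_flagged(self):
        for y, sign in ((np.zeros(25), -1), (np.ones(25), 1)):
            fit = fit_ml_probit(y, np.ones((25, 1)))
            assert fit.separated[0]
            assert fit.estimates[0] == sign * np.inf


class TestMeanBR:
    def test_finite_under_perfect_separation(self):
        rng = np.random.default_rng(1)
        x2 = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x2])
        fit = fit_meanbr_probit((x2 > 0.0).astype(float), X)
        assert np.isfinite(fit.estimates).all()
        assert np.isfinite(fit.std_errors).all()
        assert fit.converged

    def test_balanced_intercept_is_zero_by_symmetry(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        fit = fit_meanbr_probit(y, np.ones((20, 1)))
        assert fit.estimates[0] == pytest.approx(0.0, abs=1e-10)

    def test_frozen_reference_oracle(self):
        """Estimates match the independently derived adjusted-score solutions
        (generic moment-based adjustment, frozen once) to 1e-4."""
        records = json.loads((DATA / "meanbr_oracle.json").read_text())
        assert len(records) == 20
        for rec in records:
            fit = fit_meanbr_probit(np.array(rec["y"]), np.array(rec["X"]))
            assert np.abs(fit.estimates - np.array(rec["estimates"])).max() < 1e-4

    def test_agrees_with_ml_at_high_incidence_large_n(self):
        """The adjustment is O(1/N): both estimators coincide for large N."""
        rng = np.random.default_rng(5)
        y, X = _random_fixture(rng, n=20_000, beta=(0.1, 0.4))
        ml = fit_ml_probit(y, X)
        br = fit_meanbr_probit(y, X)
        assert np.abs(ml.estimates - br.estimates).max() < 1e-3

    def test_shrinkage_on_low_incidence_fixtures(self):
        """Mean |estimate| shrinks towards zero relative to ML."""
        rng = np.random.default_rng(9)
        ml_tot, br_tot, n_used = 0.0, 0.0, 0
        for _ in range(40):
            X = np.column_stack([np.ones(120), rng.normal(size=120)])
            y = (rng.random(120) < ndtr(X @ np.array([-2.0, 0.3]))).astype(float)
            if y.sum() == 0:
                continue
            ml = fit_ml_probit(y, X)
            if ml.separated.any():
                continue
            br = fit_meanbr_probit(y, X)
            ml_tot += np.abs(ml.estimates).mean()
            br_tot += np.abs(br.estimates).mean()
            n_used += 1
        assert n_used > 10
        assert br_tot <= ml_tot


class TestSeparationLP:
    def test_constant_responses(self):
        X = np.ones((10, 1))
        assert detect_separation(np.zeros(10), X)[0]
        assert detect_separation(np.ones(10), X)[0]

    def test_interleaved_not_separated(self):
        x2 = np.sort(np.random.default_rng(2).normal(size=20))
        X = np.column_stack([np.ones(20), x2])
        y = np.tile([0.0, 1.0], 10)
        assert not detect_separation(y, X).any()

    def test_lp_matches_brute_force_direction_search(self):
        """Exhaustive scan over direction angles reproduces the LP verdict."""
        rng = np.random.default_rng(12)
        angles = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        grid_dirs = np.column_stack([np.cos(angles), np.sin(angles)])
        n_sep = 0
        for _ in range(60):
            X = np.column_stack([np.ones(12), rng.normal(size=12)])
            y = (rng.random(12) < 0.3).astype(float)
            s = 2 * y - 1
            # a non-empty feasible cone either has interior (grid directions
            # hit it) or is a boundary ray orthogonal to some observation
            boundary = np.concatenate([
                np.column_stack([-X[:, 1], X[:, 0]]),
                np.column_stack([X[:, 1], -X[:, 0]]),
            ])
            boundary /= np.linalg.norm(boundary, axis=1, keepdims=True)
            dirs = np.vstack([grid_dirs, boundary])
            proj = (s[:, None] * X) @ dirs.T  # (n, ndirs)
            feasible = (proj >= -1e-9).all(axis=0) & (proj.max(axis=0) > 1e-6)
            brute_any = bool(feasible.any())
            lp_any = bool(detect_separation(y, X).any())
            assert lp_any == brute_any
            n_sep += lp_any
        assert 0 < n_sep < 60  # the fixture family exercises both verdicts


class TestVoxelwise:
    def test_matches_single_voxel_calls(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        Y = (rng.random((80, 2)) < 0.3).astype(float)
        est = VoxelwiseProbitRegression(method="meanbr").fit(X, Y)
        for j in range(2):
            single = fit_meanbr_probit(Y[:, j], X)
            assert np.allclose(est.coef_[:, j], single.estimates, atol=1e-12)
            assert np.allclose(est.se_[:, j], single.std_errors, atol=1e-12)

    def test_thread_count_does_not_change_results(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        Y = (rng.random((100, 700)) < rng.uniform(0.01, 0.5, 700)).astype(float)
        for method in ("ml", "meanbr"):
            a = VoxelwiseProbitRegression(method=method, threads=1).fit(X, Y)
            b = VoxelwiseProbitRegression(method=method, threads=8).fit(X, Y)
            assert np.array_equal(a.coef_, b.coef_, equal_nan=True)
            assert np.array_equal(a.separated_, b.separated_)

    def test_sklearn_params_roundtrip(self):
        est = VoxelwiseProbitRegression(method="ml", tol=1e-6)
        assert est.get_params()["tol"] == 1e-6
        est.set_params(method="meanbr")
        assert est.method == "meanbr"
        with pytest.raises(ValueError):
            VoxelwiseProbitRegression(method="logit").fit(
                np.ones((4, 1)), np.zeros((4, 1))
            )

    def test_z_equals_estimate_over_se(self):
        rng = np.random.default_rng(10)
        X = np.column_stack([np.ones(150), rng.normal(size=150)])
        Y = (rng.random((150, 30)) < 0.4).astype(float)
        est = VoxelwiseProbitRegression(method="meanbr").fit(X, Y)
        ok = np.isfinite(est.se_) & (est.se_ > 0)
        assert np.allclose(est.z_[ok], (est.coef_ / est.se_)[ok])


def test_design_matrix_contract():
    with pytest.raises(ValueError, match="intercept"):
        DesignMatrix(values=np.random.default_rng(0).normal(size=(10, 2)),
                     column_names=("a", "b"))
    with pytest.raises(ValueError, match="rank"):
        x = np.ones((10, 2))
        DesignMatrix(values=x, column_names=("intercept", "dup"))
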