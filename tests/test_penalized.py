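"""From-scratch penalized least-squares solvers: thresholding operators,
path coordinate descent, closed-form identities and the TLP DC iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinpen import penalized as pen
from kinpen.penalized import PenaltySpec


def _instance(rng, n=30, p=6, snr=2.0):
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[: p // 2] = rng.uniform(0.5, snr, size=p // 2) * rng.choice(
        (-1, 1), size=p // 2
    )
    y = X @ beta + rng.standard_normal(n)
    return X, y


def _std(X):
    s = np.sqrt((X**2).mean(axis=0))
    return X / s, s


class TestThresholds:
    @pytest.mark.parametrize(
        "z, t, out", [(0.5, 1, 0.0), (3, 1, 2.0), (-3, 1, -2.0), (2, 0, 2.0)]
    )
    def test_soft_threshold(self, z, t, out):
        assert pen.soft_threshold(z, t) == out

    @pytest.mark.parametrize(
        "z, expected",
        [
            (1.5, 0.5),              # soft region |z| <= 2*lam
            (5.0, 5.0),              # beyond a*lam: untouched
            (3.0, 4.4 / 1.7),        # interpolating region
            (-3.0, -4.4 / 1.7),
        ],
    )
    def test_scad_threshold_regimes(self, z, expected):
        assert pen.scad_threshold(z, 1.0, 3.7) == pytest.approx(expected)

    def test_scad_invalid_shape_raises(self):
        with pytest.raises(ValueError):
            pen.scad_threshold(1.0, 1.0, a=2.0)

    def test_scad_matches_fine_grid_minimizer(self):
        # 1e-6-resolution minimization of the univariate SCAD objective
        lam, a = 1.0, 3.7

        def scad_pen(b):
            ab = np.abs(b)
            quad = (
                2 * a * lam * ab - b**2 - lam**2
            ) / (2 * (a - 1))
            return np.where(
                ab <= lam,
                lam * ab,
                np.where(ab <= a * lam, quad, lam**2 * (a + 1) / 2),
            )

        for z in np.arange(-6.0, 6.01, 0.25):
            coarse = np.arange(-7.0, 7.0, 1e-4)
            f = 0.5 * (z - coarse) ** 2 + scad_pen(coarse)
            b0 = coarse[np.argmin(f)]
            fine = np.arange(b0 - 2e-4, b0 + 2e-4, 1e-6)
            f = 0.5 * (z - fine) ** 2 + scad_pen(fine)
            b_star = fine[np.argmin(f)]
            assert pen.scad_threshold(z, lam, a) == pytest.approx(
                b_star, abs=5e-6
            )


class TestOls:
    def test_identity_design(self):
        res = pen.fit_ols(np.eye(3), np.array([1.0, 2.0, 3.0]))
        assert np.allclose(res.coef, [1, 2, 3])
        assert not res.rank_deficient

    def test_duplicated_column_minimum_norm_splits_weight(self):
        x = np.array([[1.0], [2.0]])
        X = np.hstack([x, x, x])  # p > n, rank 1
        y = np.array([3.0, 6.0])
        res = pen.fit_ols(X, y)
        assert res.rank_deficient
        assert np.allclose(res.coef, [1.0, 1.0, 1.0])

    def test_matches_normal_equations(self, rng):
        X, y = _instance(rng, n=20, p=5)
        res = pen.fit_ols(X, y)
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(res.coef, ref, atol=1e-10)


class TestLambdaMax:
    def test_single_predictor_kkt_anchor(self, rng):
        x = rng.standard_normal(50)
        x /= np.sqrt((x**2).mean())
        y = rng.standard_normal(50)
        lm = pen.lambda_max(x[:, None], y, np.array([True]), alpha=1.0)
        assert lm == pytest.approx(abs(x @ y) / 50)

    def test_orthogonal_response_gives_zero(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 1.0])
        assert pen.lambda_max(X, y, np.array([True])) == pytest.approx(0.0)

    def test_fit_just_above_anchor_is_all_zero(self, rng):
        X, y = _instance(rng)
        mask = np.ones(X.shape[1], bool)
        lm = pen.lambda_max(X, y, mask)
        res = pen.fit_path(X, y, PenaltySpec("lasso"), np.array([1.01 * lm]), mask)[0]
        assert res.n_nonzero == 0

    def test_unpenalized_columns_fitted_first(self, rng):
        X, y = _instance(rng, p=4)
        mask = np.array([False, True, True, True])
        lm = pen.lambda_max(X, y, mask)
        res = pen.fit_path(X, y, PenaltySpec("lasso"), np.array([1.01 * lm]), mask)[0]
        assert res.n_nonzero == 0
        assert res.coef[0] != 0.0  # the free column absorbs what it can

    def test_ridge_alpha_zero_rejected(self, rng):
        X, y = _instance(rng)
        with pytest.raises(ValueError):
            pen.lambda_max(X, y, alpha=0.0)


class TestPaths:
    def test_zero_penalty_limit_matches_ols(self, rng):
        X, y = _instance(rng, n=40, p=6)
        for fam in ("lasso", "ridge", "enet", "scad"):
            res = pen.fit_path(X, y, PenaltySpec(fam), np.array([0.0]))[0]
            assert np.allclose(res.coef, pen.fit_ols(X, y).coef, atol=1e-7), fam

    def test_enet_alpha_one_is_lasso(self, rng):
        X, y = _instance(rng)
        mask = np.ones(X.shape[1], bool)
        grid = pen.default_lambda_grid(pen.lambda_max(X, y, mask), 20)
        lasso = pen.fit_path(X, y, PenaltySpec("lasso"), grid, mask)
        enet = pen.fit_path(X, y, PenaltySpec("enet", alpha=1.0), grid, mask)
        for a, b in zip(lasso, enet):
            assert np.allclose(a.coef, b.coef, atol=1e-8)

    def test_enet_alpha_zero_is_ridge_closed_form(self, rng):
        X, y = _instance(rng)
        n, p = X.shape
        mask = np.ones(p, bool)
        lam = 0.37
        res = pen.fit_path(X, y, PenaltySpec("enet", alpha=0.0),
                           np.array([lam]), mask)[0]
        Xs, s = _std(X)
        ref = np.linalg.solve(Xs.T @ Xs / n + 2 * lam * np.eye(p), Xs.T @ y / n)
        assert np.allclose(res.coef * s, ref, atol=1e-8)

    def test_ridge_cd_and_closed_path_agree(self, rng):
        X, y = _instance(rng, n=25, p=8)
        mask = np.array([False] * 2 + [True] * 6)
        grid = np.array([1.0, 0.3, 0.05])
        cd = pen.fit_path(X, y, PenaltySpec("ridge"), grid, mask, tol=1e-10)
        closed = pen.ridge_path_closed(X, y, grid, mask)
        for a, b in zip(cd, closed):
            assert np.allclose(a.coef, b.coef, atol=1e-7)

    def test_lasso_kkt_conditions_along_path(self, rng):
        X, y = _instance(rng, n=40, p=10)
        n, p = X.shape
        mask = np.ones(p, bool)
        grid = pen.default_lambda_grid(pen.lambda_max(X, y, mask), 30)
        Xs, s = _std(X)
        for res in pen.fit_path(X, y, PenaltySpec("lasso"), grid, mask):
            b = res.coef * s
            g = -Xs.T @ (y - Xs @ b) / n
            lam = res.spec.lam
            zero = np.abs(b) <= 1e-12
            assert np.all(np.abs(g[zero]) <= lam + 1e-6)
            active = ~zero
            assert np.all(
                np.abs(g[active] + lam * np.sign(b[active])) <= 1e-6
            )

    def test_l1_norm_monotone_in_lambda(self, rng):
        X, y = _instance(rng, n=50, p=12)
        mask = np.ones(12, bool)
        grid = pen.default_lambda_grid(pen.lambda_max(X, y, mask), 40)
        fits = pen.fit_path(X, y, PenaltySpec("lasso"), grid, mask)
        norms = [np.abs(r.coef).sum() for r in fits]
        assert all(a <= b + 1e-10 for a, b in zip(norms, norms[1:]))

    def test_lasso_beats_random_perturbations(self, rng):
        X, y = _instance(rng, n=30, p=5)
        n, p = X.shape
        mask = np.ones(p, bool)
        lam = 0.5 * pen.lambda_max(X, y, mask)
        res = pen.fit_path(X, y, PenaltySpec("lasso"), np.array([lam]), mask)[0]
        Xs, s = _std(X)
        b = res.coef * s

        def obj(bb):
            r = y - Xs @ bb
            return 0.5 * r @ r / n + lam * np.abs(bb).sum()

        f0 = obj(b)
        perturbed = b[None, :] + 0.05 * rng.standard_normal((10_000, p))
        worst = min(obj(bb) for bb in perturbed)
        assert f0 <= worst + 1e-12

    def test_sparse_families_return_exact_zeros(self, rng):
        X, y = _instance(rng, n=40, p=10)
        mask = np.ones(10, bool)
        lm = pen.lambda_max(X, y, mask)
        for fam in ("lasso", "scad"):
            res = pen.fit_path(X, y, PenaltySpec(fam), np.array([0.5 * lm]), mask)[0]
            assert np.any(res.coef[mask] == 0.0), fam
        ridge = pen.ridge_path_closed(X, y, np.array([0.5 * lm]), mask)[0]
        assert np.all(ridge.coef[mask] != 0.0)

    def test_ascending_grid_rejected(self, rng):
        X, y = _instance(rng)
        with pytest.raises(ValueError, match="descending"):
            pen.fit_path(X, y, PenaltySpec("lasso"), np.array([0.1, 0.2]))


class TestTlp:
    def test_zero_lambda_is_ols(self, rng):
        X, y = _instance(rng, n=30, p=5)
        res = pen.fit_tlp(X, y, 0.0, 0.5)
        assert np.allclose(res.coef, pen.fit_ols(X, y).coef, atol=1e-8)

    def test_huge_tau_fixed_point_is_weighted_lasso(self, rng):
        X, y = _instance(rng, n=40, p=8)
        mask = np.ones(8, bool)
        lam, tau = 0.05, 1e7
        res = pen.fit_tlp(X, y, lam, tau, mask)
        ref = pen.fit_path(
            X, y, PenaltySpec("lasso"), np.array([lam / tau]), mask
        )[0]
        assert np.allclose(res.coef, ref.coef, atol=1e-7)

    def test_small_tau_single_predictor_two_candidate_oracle(self, rng):
        # tau -> 0: penalty approaches lam * #nonzero; the solution is 0 or
        # the OLS coefficient, whichever has the lower objective
        for inst in range(10):
            r = np.random.default_rng(300 + inst)
            x = r.standard_normal(25)
            y = 0.4 * x + r.standard_normal(25)
            X = x[:, None]
            lam, tau = float(r.uniform(0.01, 0.4)), 1e-4
            res = pen.fit_tlp(X, y, lam, tau, np.array([True]))
            n = 25
            Xs, s = _std(X)
            b_ols = float((Xs[:, 0] @ y) / (Xs[:, 0] @ Xs[:, 0]))

            def obj(b):
                resid = y - Xs[:, 0] * b
                return 0.5 * resid @ resid / n + lam * float(
                    min(abs(b) / tau, 1.0)
                )

            best = min((obj(0.0), 0.0), (obj(b_ols), b_ols))[1]
            assert res.coef[0] * s[0] == pytest.approx(best, abs=1e-3)

    def test_dc_objective_monotone_nonincreasing(self, rng):
        X, y = _instance(rng, n=40, p=10)
        res = pen.fit_tlp(X, y, 0.08, 0.2, np.ones(10, bool))
        diffs = np.diff(res.dc_objectives)
        assert np.all(diffs <= 1e-9)

    def test_invalid_tau_rejected(self, rng):
        X, y = _instance(rng)
        with pytest.raises(ValueError):
            pen.fit_tlp(X, y, 0.1, 0.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    z=st.floats(-50, 50, allow_nan=False),
    t=st.floats(0, 20, allow_nan=False),
)
def test_soft_threshold_properties(z, t):
    out = pen.soft_threshold(z, t)
    assert abs(out) <= abs(z) + 1e-12
    assert out * z >= 0  # never flips sign
    if out != 0:
        assert abs(out) == pytest.approx(abs(z) - t)
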