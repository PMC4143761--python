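"""IBS relatedness, missingness QC, variance components and whitening."""

import numpy as np
import pytest
from scipy import stats

from kinpen import kinship as kin
from kinpen import simulate as sim
from kinpen.simulate import GenotypeMatrix, KinshipMatrix


def _gm(dosages, prefix="S"):
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix.from_dosages(
        d,
        [f"{prefix}{i}" for i in range(d.shape[0])],
        [f"v{j}" for j in range(d.shape[1])],
    )


class TestIbs:
    def test_entry_formula(self):
        K = kin.ibs_matrix(_gm([[0, 1], [0, 1]])).values
        assert K[0, 1] == 1.0          # identical rows
        K = kin.ibs_matrix(_gm([[0, 0], [2, 2]])).values
        assert K[0, 1] == 0.0          # opposite homozygotes share nothing
        K = kin.ibs_matrix(_gm([[0, 1], [2, 1]])).values
        assert K[0, 1] == 0.5          # ((2-2)/2 + (2-0)/2)/2
        assert np.allclose(np.diag(K), 1.0)

    def test_missing_entries_use_joint_observations(self):
        G = _gm([[0, np.nan, 1], [0, 2, np.nan], [2, 2, 1]])
        K = kin.ibs_matrix(G).values
        assert K[0, 1] == 1.0  # only variant 0 jointly observed
        assert K[0, 2] == 0.5  # variants 0 and 2: (0 + 1)/2

    def test_invariant_to_variant_and_sample_order(self, rng):
        d = rng.integers(0, 3, size=(8, 30)).astype(float)
        G = _gm(d)
        K = kin.ibs_matrix(G).values
        perm_v = rng.permutation(30)
        K2 = kin.ibs_matrix(_gm(d[:, perm_v])).values
        assert np.allclose(K, K2)
        perm_s = rng.permutation(8)
        K3 = kin.ibs_matrix(_gm(d[perm_s])).values
        assert np.allclose(K3, K[np.ix_(perm_s, perm_s)])

    def test_disjoint_observation_pair_fails_with_names(self):
        G = _gm([[0, np.nan], [np.nan, 1]])
        with pytest.raises(ValueError, match="S0.*S1"):
            kin.ibs_matrix(G)


class TestMissingnessQc:
    def test_complete_data_unchanged(self):
        G = _gm(np.zeros((3, 10)) + [0, 1] * 5)
        out = kin.exclude_high_missingness(G, 0.10)
        assert out.sample_ids == G.sample_ids

    def test_sample_over_threshold_removed(self):
        d = np.tile([0.0, 1.0], (4, 5))
        d[2, :3] = np.nan  # 30% missing
        out = kin.exclude_high_missingness(_gm(d), 0.10)
        assert out.sample_ids == ["S0", "S1", "S3"]

    def test_threshold_one_keeps_everyone(self):
        d = np.tile([0.0, 1.0], (4, 5))
        d[2, :9] = np.nan
        out = kin.exclude_high_missingness(_gm(d), 1.0)
        assert out.n_samples == 4

    def test_all_removed_raises(self):
        d = np.full((2, 4), np.nan)
        d[:, 0] = 1.0
        with pytest.raises(ValueError):
            kin.exclude_high_missingness(_gm(d), 0.10)


def _family_kinship(n_families=12, size=(8, 14), seed=0) -> KinshipMatrix:
    peds = sim.simulate_pedigrees(n_families, size, 3, seed=seed)
    return sim.expected_relationship(peds)


def _draw(K: KinshipMatrix, sg2, sr2, seed, mean=0.0):
    rng = np.random.default_rng(seed)
    n = K.n_samples
    L = np.linalg.cholesky(
        sg2 * K.values + sr2 * np.eye(n) + 1e-10 * np.eye(n)
    )
    return mean + L @ rng.standard_normal(n)


class TestVarianceComponents:
    def test_optimum_beats_fine_delta_grid(self, rng):
        # brute-force 1-D oracle over the variance ratio
        K = _family_kinship(4, (8, 12), seed=1)
        n = K.n_samples
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        from kinpen.kinship import _profiled_loglik

        lam, U = np.linalg.eigh(K.values)
        lam = np.clip(lam, 0, None)
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        for inst in range(10):
            Y = _draw(K, 1.5, 1.0, seed=100 + inst)
            for method in ("ML", "REML"):
                vc = kin.fit_variance_components(Y, X, K, method)
                grid = np.logspace(-5, 5, 1000)
                lls = [
                    _profiled_loglik(
                        d, lam, U.T @ Y, U.T @ X, logdet_xx, method == "REML"
                    )[0]
                    for d in grid
                ]
                assert vc.loglik >= max(lls) - 1e-4

    def test_ml_likelihood_matches_direct_density(self):
        # independent check of the profiled formula against the full
        # multivariate-normal density at the fitted parameters
        K = _family_kinship(3, (6, 10), seed=2)
        n = K.n_samples
        X = np.ones((n, 1))
        Y = _draw(K, 2.0, 1.0, seed=3, mean=5.0)
        vc = kin.fit_variance_components(Y, X, K, "ML")
        Sigma = vc.sigma()
        Si = np.linalg.inv(Sigma)
        b = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ Y)
        ll = stats.multivariate_normal(
            mean=(X @ b).ravel(), cov=Sigma, allow_singular=True
        ).logpdf(Y)
        assert np.isclose(vc.loglik, ll, atol=1e-6)

    def test_null_data_gives_low_heritability(self):
        K = _family_kinship(10, (10, 16), seed=4)
        n = K.n_samples
        X = np.ones((n, 1))
        h2 = []
        for rep in range(30):
            Y = np.random.default_rng(500 + rep).standard_normal(n)
            vc = kin.fit_variance_components(Y, X, K, "REML")
            h2.append(vc.heritability)
        assert np.median(h2) < 0.1

    def test_identity_kinship_flat_profile_warns(self):
        n = 60
        K = KinshipMatrix(np.eye(n), [f"S{i}" for i in range(n)])
        Y = np.random.default_rng(0).standard_normal(n)
        with pytest.warns(RuntimeWarning, match="flat"):
            vc = kin.fit_variance_components(Y, np.ones((n, 1)), K, "REML")
        assert vc.sigma_g2 == 0.0
        assert vc.sigma_r2 > 0.0

    def test_input_validation(self):
        K = _family_kinship(2, (5, 8), seed=5)
        n = K.n_samples
        X = np.ones((n, 1))
        with pytest.raises(ValueError, match="finite"):
            kin.fit_variance_components(
                np.full(n, np.nan), X, K, "REML"
            )
        bad = KinshipMatrix(
            K.values - 0.5 * np.eye(n), K.sample_ids
        )
        with pytest.raises(ValueError, match="PSD"):
            kin.fit_variance_components(np.ones(n) + np.arange(n), X, bad)


class TestInverseSqrt:
    def test_identity_and_diagonal(self):
        assert np.allclose(kin.inverse_sqrt(np.eye(3)), np.eye(3))
        W = kin.inverse_sqrt(np.diag([4.0, 9.0]))
        assert np.allclose(W, np.diag([0.5, 1.0 / 3.0]))

    def test_algebraic_identity_random_spd(self, rng):
        A = rng.standard_normal((5, 5))
        M = A @ A.T + 5 * np.eye(5)
        W = kin.inverse_sqrt(M)
        assert np.allclose(W, W.T)
        assert np.allclose(W @ W @ M, np.eye(5), atol=1e-8)

    def test_singular_matrix_reports_eigenvalue(self):
        M = np.diag([1.0, 0.0])
        with pytest.raises(ValueError, match="eigenvalue"):
            kin.inverse_sqrt(M)


def _vc_from_truth(K: KinshipMatrix, sg2, sr2) -> kin.VarianceComponents:
    lam, U = np.linalg.eigh(K.values)
    return kin.VarianceComponents(
        sg2, sr2, 0.0, "fixed", K, np.clip(lam, 0, None), U
    )


class TestWhitening:
    def test_identity_kinship_unit_scale_is_noop(self):
        n = 5
        K = KinshipMatrix(np.eye(n), [f"S{i}" for i in range(n)])
        vc = _vc_from_truth(K, 0.4, 0.6)
        Y = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), Y**2])
        wh = kin.whiten(Y, X, vc)
        assert np.allclose(wh.Y_star, Y)
        assert np.allclose(wh.X_star, X)

    def test_identity_kinship_scales_by_total_sd(self):
        n = 4
        K = KinshipMatrix(np.eye(n), [f"S{i}" for i in range(n)])
        vc = _vc_from_truth(K, 3.0, 1.0)
        Y = np.ones(n)
        wh = kin.whiten(Y, np.ones((n, 1)), vc)
        assert np.allclose(wh.Y_star, 0.5)

    def test_gls_identity_on_whitened_data(self, rng):
        # OLS on (Y*, X*) must equal (X' Sigma^-1 X)^-1 X' Sigma^-1 Y
        K = _family_kinship(3, (5, 9), seed=6)
        n = K.n_samples
        vc = _vc_from_truth(K, 1.3, 0.7)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        Y = rng.standard_normal(n)
        wh = kin.whiten(Y, X, vc)
        b_white, *_ = np.linalg.lstsq(wh.X_star, wh.Y_star, rcond=None)
        Si = np.linalg.inv(vc.sigma())
        b_gls = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ Y)
        assert np.allclose(b_white, b_gls, atol=1e-8)

    def test_whitening_decorrelates_family_draws(self):
        # Y ~ N(0, Sigma): whitened draws should look iid unit-normal
        peds = sim.simulate_pedigrees(5, (10, 10), 3, seed=7)
        K = sim.expected_relationship(peds)
        n = K.n_samples
        vc = _vc_from_truth(K, 2.0, 1.0)
        draws = np.stack(
            [
                kin.whiten(
                    _draw(K, 2.0, 1.0, seed=900 + r), np.ones((n, 1)), vc
                ).Y_star
                for r in range(200)
            ]
        )
        emp = np.cov(draws, rowvar=False)
        se = 1.0 / np.sqrt(draws.shape[0])
        assert abs(np.diag(emp).mean() - 1.0) < 3 * se
        off = emp[~np.eye(n, dtype=bool)]
        assert np.abs(off).mean() < 3 * se
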