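"""Relatedness estimation and linear-mixed-model whitening.

Family (or cryptic population) structure induces correlated errors in the
trait model Y = X beta + eps, eps ~ N(0, Sigma). Following the EMMAX-style
variance-component approach, Sigma is modelled as

    Sigma = sigma_g^2 * K + sigma_r^2 * I,

with K an identity-by-state (IBS) similarity matrix estimated from
genome-wide genotypes. The two variance components are fitted by ML or REML
after a single eigendecomposition of K, profiling fixed effects and total
scale out of the likelihood and optimizing the 1-D ratio
delta = sigma_r^2 / sigma_g^2. Samples are then decorrelated ("whitened") by
premultiplying both Y and X by the symmetric inverse square root
Sigma^(-1/2), after which ordinary least squares on (Y*, X*) reproduces the
generalized-least-squares estimator and the residual variance is ~1 when
Sigma is correctly specified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .simulate import GenotypeMatrix, KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "WhitenedData",
    "ibs_matrix",
    "exclude_high_missingness",
    "fit_variance_components",
    "inverse_sqrt",
    "whiten",
]


# ---------------------------------------------------------------------------
# IBS relatedness
# ---------------------------------------------------------------------------

def ibs_matrix(G: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state similarity: entry (i, j) is the average over
    variants non-missing in both samples of (2 - |g_i - g_j|) / 2.

    Dosages must be hard calls in {0, 1, 2, missing}. The pairwise sums of
    |g_i - g_j| are assembled from dosage-indicator matrix products so
    missing entries drop out of both the numerator and the per-pair count.
    """
    D = G.dosages
    obs = ~np.isnan(D)
    ind = [((D == k) & obs).astype(float) for k in (0.0, 1.0, 2.0)]
    counts = obs.astype(float) @ obs.T.astype(float)
    if np.any(counts == 0):
        i, j = np.argwhere(counts == 0)[0]
        raise ValueError(
            "samples "
            f"{G.sample_ids[i]!r} and {G.sample_ids[j]!r} share no jointly "
            "observed variants"
        )
    absdiff = np.zeros_like(counts)
    for k in range(3):
        for l in range(3):
            if k != l:
                absdiff += abs(k - l) * (ind[k] @ ind[l].T)
    vals = 1.0 - absdiff / (2.0 * counts)
    vals = 0.5 * (vals + vals.T)  # exact symmetry despite float summation order
    return KinshipMatrix(vals, list(G.sample_ids))


def exclude_high_missingness(
    G: GenotypeMatrix, max_missing_fraction: float = 0.10
) -> GenotypeMatrix:
    """Drop samples whose fraction of missing genotypes exceeds the
    threshold (order of the remaining samples preserved; MAF and CV/RV
    class flags are recomputed on the retained samples)."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    if G.n_variants == 0:
        return G
    frac = np.isnan(G.dosages).mean(axis=1)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValueError("missingness filter removed every sample")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "excluded %d/%d samples with missing fraction > %.2f",
            n_dropped, G.n_samples, max_missing_fraction,
        )
    ids = [s for s, k in zip(G.sample_ids, keep) if k]
    return GenotypeMatrix.from_dosages(G.dosages[keep], ids, G.variant_ids)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Fitted (sigma_g^2, sigma_r^2) of Sigma = sigma_g^2 K + sigma_r^2 I,
    with the maximized (restricted) log-likelihood and the eigendecomposition
    of K cached for cheap whitening."""

    sigma_g2: float
    sigma_r2: float
    loglik: float
    method: str
    kinship: KinshipMatrix
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_r2
        return self.sigma_g2 / tot if tot > 0 else 0.0

    def sigma(self) -> np.ndarray:
        n = self.kinship.n_samples
        return self.sigma_g2 * self.kinship.values + self.sigma_r2 * np.eye(n)


def _profiled_loglik(
    delta: float,
    lam: np.ndarray,
    Yt: np.ndarray,
    Xt: np.ndarray,
    logdet_xx: float,
    reml: bool,
) -> tuple[float, float]:
    """Log-likelihood of Sigma = s2 * (K + delta I) at the profiled optimum
    over fixed effects and s2; returns (loglik, s2_hat = sigma_g^2)."""
    n, q = Xt.shape
    w = lam + delta
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    b = np.linalg.solve(A, Xw.T @ Yt)
    r = Yt - Xt @ b
    S = float(np.sum(r * r / w))
    logdet_w = float(np.sum(np.log(w)))
    if reml:
        df = n - q
        s2 = S / df
        sign, logdet_a = np.linalg.slogdet(A)
        ll = -0.5 * (
            df * np.log(2 * np.pi * s2) + df + logdet_w + logdet_a - logdet_xx
        )
    else:
        s2 = S / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + n + logdet_w)
    return ll, s2


def _iid_loglik(
    Y: np.ndarray, X: np.ndarray, reml: bool
) -> tuple[float, float]:
    """(loglik, sigma_r^2) of the boundary model sigma_g^2 = 0."""
    n, q = X.shape
    b, *_ = np.linalg.lstsq(X, Y, rcond=None)
    r = Y - X @ b
    S = float(r @ r)
    if reml:
        # same normalisation as _profiled_loglik (includes +1/2 log|X'X|),
        # where the log|X'X| terms cancel for Sigma proportional to I
        df = n - q
        s2 = S / df
        ll = -0.5 * (df * np.log(2 * np.pi * s2) + df)
    else:
        s2 = S / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + n)
    return ll, s2


def fit_variance_components(
    Y: np.ndarray,
    X_cov: np.ndarray,
    K: KinshipMatrix,
    method: str = "REML",
    n_grid: int = 80,
) -> VarianceComponents:
    """Fit (sigma_g^2, sigma_r^2) by maximizing the (restricted) likelihood
    of Y ~ N(X_cov b, sigma_g^2 K + sigma_r^2 I).

    K is eigendecomposed once; the ratio delta = sigma_r^2 / sigma_g^2 is
    optimized on a log grid refined by bounded scalar minimization, and the
    sigma_g^2 = 0 boundary (iid errors) is checked explicitly. A flat delta
    profile (likelihood range < 1e-6 across the grid, e.g. K = I where the
    split is unidentifiable) returns sigma_g^2 = 0 with a warning — the
    whitening transform is invariant to the split in that case.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    X_cov = np.atleast_2d(np.asarray(X_cov, dtype=float))
    if X_cov.shape[0] != Y.size:
        raise ValueError("X_cov rows must match phenotype length")
    if not np.all(np.isfinite(Y)):
        raise ValueError("phenotype contains non-finite values")
    n, q = X_cov.shape
    if n < q + 2:
        raise ValueError(f"need at least {q + 2} samples to fit {q} fixed effects")
    if K.n_samples != n:
        raise ValueError("kinship size does not match phenotype length")
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    reml = method == "REML"

    lam, U = np.linalg.eigh(K.values)
    tol = 1e-8 * max(lam[-1], 1.0)
    if lam[0] < -tol:
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {lam[0]:.3e})")
    lam = np.clip(lam, 0.0, None)
    Yt = U.T @ Y
    Xt = U.T @ X_cov
    _, logdet_xx = np.linalg.slogdet(X_cov.T @ X_cov)

    grid = np.logspace(-5, 5, n_grid)
    lls = np.array(
        [_profiled_loglik(d, lam, Yt, Xt, logdet_xx, reml)[0] for d in grid]
    )
    ll_iid, s2_iid = _iid_loglik(Y, X_cov, reml)

    if lls.max() - lls.min() < 1e-6:
        warnings.warn(
            "delta profile is flat (kinship ~ identity); returning sigma_g2 = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return VarianceComponents(0.0, s2_iid, ll_iid, method, K, lam, U)

    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_profiled_loglik(
            float(np.exp(t)), lam, Yt, Xt, logdet_xx, reml
        )[0],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    ll, s2 = _profiled_loglik(delta, lam, Yt, Xt, logdet_xx, reml)
    if ll < lls[i]:
        delta, ll = grid[i], lls[i]
        _, s2 = _profiled_loglik(delta, lam, Yt, Xt, logdet_xx, reml)

    if ll_iid >= ll:
        return VarianceComponents(0.0, s2_iid, ll_iid, method, K, lam, U)
    return VarianceComponents(s2, delta * s2, ll, method, K, lam, U)


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

@dataclass
class WhitenedData:
    """Phenotype and design after premultiplication by Sigma^(-1/2); the
    intercept column of X is transformed like any other column."""

    Y_star: np.ndarray
    X_star: np.ndarray
    sigma_inv_sqrt: np.ndarray


def inverse_sqrt(Sigma: np.ndarray, tol_factor: float = 1e-8) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition; fails loudly on
    eigenvalues at or below tol_factor * max eigenvalue rather than silently
    repairing a near-singular covariance."""
    Sigma = np.asarray(Sigma, dtype=float)
    if not np.allclose(Sigma, Sigma.T, atol=1e-8):
        raise ValueError("Sigma must be symmetric")
    w, U = np.linalg.eigh(Sigma)
    tol = tol_factor * max(w[-1], 0.0)
    if w[0] <= tol:
        raise ValueError(
            f"Sigma has eigenvalue {w[0]:.3e} <= tolerance {tol:.3e}; "
            "cannot form Sigma^(-1/2)"
        )
    return (U / np.sqrt(w)) @ U.T


def whiten(Y: np.ndarray, X: np.ndarray, vc: VarianceComponents) -> WhitenedData:
    """Y* = Sigma^(-1/2) Y, X* = Sigma^(-1/2) X with
    Sigma = sigma_g^2 K + sigma_r^2 I, using the cached eigendecomposition
    of K (Sigma shares K's eigenvectors)."""
    Y = np.asarray(Y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = vc.kinship.n_samples
    if Y.size != n or X.shape[0] != n:
        raise ValueError("Y/X dimensions do not match the fitted kinship")
    w = vc.sigma_g2 * vc.eigenvalues + vc.sigma_r2
    tol = 1e-8 * max(w[-1], 0.0)
    if w.min() <= tol:
        raise ValueError(
            f"Sigma has eigenvalue {w.min():.3e} <= tolerance {tol:.3e}; "
            "cannot form Sigma^(-1/2)"
        )
    U = vc.eigenvectors
    W = (U / np.sqrt(w)) @ U.T
    return WhitenedData(W @ Y, W @ X, W)
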