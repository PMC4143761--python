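"""Penalized least squares on whitened data: OLS, ridge, LASSO, elastic
net, SCAD, and the truncated L1 penalty (TLP).

All solvers minimize

    f(beta) = (1/2n) ||Y* - X* beta||^2 + lambda * P(beta_penalized)

with the penalty applied to internally standardized coefficients (each
column of X* is scaled to unit root mean square; coefficients are reported
back on the original scale). Covariates and the transformed intercept
column are unpenalized by default. Penalty families:

* ridge          P = sum b^2                     (proportional shrinkage)
* lasso          P = sum |b|                     (selection)
* elastic net    P = (1-alpha) sum b^2 + alpha sum |b|
* SCAD           nonconvex; derivative lam*sign(b)[ I(|b|<=lam)
                 + (a*lam-|b|)_+ / ((a-1)lam) * I(|b|>lam) ], a = 3.7
* TLP            P = sum min(|b|/tau, 1): no further penalty beyond the
                 threshold tau; solved by difference-of-convex iteration
                 (each step a weighted lasso).

Convex families and SCAD are solved by cyclic coordinate descent with warm
starts down a descending lambda grid; the SCAD coordinate update is the
exact univariate SCAD minimizer (three-regime closed form), not a local
linear approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._cd import cd_sweeps

logger = logging.getLogger(__name__)

FAMILIES = ("ols", "ridge", "lasso", "enet", "scad", "tlp")

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 10_000


@dataclass
class PenaltySpec:
    """Penalty family with its parameters.

    alpha is meaningful only for the elastic net, ``a`` only for SCAD and
    ``tau`` only for TLP; lambda = 0 reduces every family to OLS.
    """

    family: str
    lam: float = 0.0
    alpha: float = 0.5
    a: float = 3.7
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.family == "enet" and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("elastic-net alpha must be in [0, 1]")
        if self.family == "scad" and self.a <= 2.0:
            raise ValueError("SCAD shape parameter a must be > 2")
        if self.family == "tlp" and self.tau <= 0.0:
            raise ValueError("TLP threshold tau must be > 0")


@dataclass
class FitResult:
    """Coefficients (original scale, one per design column) plus the
    convergence record of the solver that produced them."""

    coef: np.ndarray
    penalized_mask: np.ndarray
    spec: PenaltySpec
    n_iter: int = 0
    max_delta: float = 0.0
    converged: bool = True
    rank_deficient: bool = False
    dc_objectives: list = field(default_factory=list)

    @property
    def n_nonzero(self) -> int:
        """Number of penalized coefficients with |b| above 1e-8."""
        return int(np.sum(np.abs(self.coef[self.penalized_mask]) > 1e-8))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef


# ---------------------------------------------------------------------------
# scalar thresholding operators
# ---------------------------------------------------------------------------

def soft_threshold(z: float, t: float) -> float:
    """sign(z) * max(|z| - t, 0)."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def scad_threshold(z: float, lam: float, a: float = 3.7) -> float:
    """Exact minimizer of 0.5*(z - b)^2 + SCAD(b; lam, a).

    Three regimes: soft-thresholding for |z| <= 2*lam; the interpolating
    solution ((a-1)z - sign(z)*a*lam)/(a-2) for 2*lam < |z| <= a*lam; and
    the identity (no shrinkage) for |z| > a*lam.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if a <= 2.0:
        raise ValueError("SCAD shape parameter a must be > 2")
    az = abs(z)
    if az <= 2.0 * lam:
        return soft_threshold(z, lam)
    if az <= a * lam:
        return float(((a - 1.0) * z - np.sign(z) * a * lam) / (a - 2.0))
    return float(z)


# ---------------------------------------------------------------------------
# design standardization
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale columns to unit root mean square (no centering: after
    whitening there is no constant intercept column, so mean-centering
    would not be a valid reparameterisation). Returns (X_scaled F-ordered,
    scales, active-mask v with 0 marking empty columns)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    s = np.sqrt(np.einsum("ij,ij->j", X, X) / n)
    v = (s > 0).astype(float)
    s_safe = np.where(s > 0, s, 1.0)
    return np.asfortranarray(X / s_safe), s_safe, v


def _resolve_mask(p: int, penalized_mask: np.ndarray | None) -> np.ndarray:
    if penalized_mask is None:
        return np.ones(p, dtype=bool)
    mask = np.asarray(penalized_mask, dtype=bool)
    if mask.shape != (p,):
        raise ValueError("penalized_mask length does not match design columns")
    return mask


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def fit_ols(Xs: np.ndarray, Ys: np.ndarray) -> FitResult:
    """Least squares; on rank-deficient or p > n designs returns the
    minimum-norm solution (SVD) and flags the deficiency."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Ys = np.asarray(Ys, dtype=float).ravel()
    coef, _, rank, _ = np.linalg.lstsq(Xs, Ys, rcond=None)
    return FitResult(
        coef=coef,
        penalized_mask=np.zeros(Xs.shape[1], dtype=bool),
        spec=PenaltySpec("ols"),
        converged=True,
        rank_deficient=rank < Xs.shape[1],
    )


# ---------------------------------------------------------------------------
# path anchor
# ---------------------------------------------------------------------------

def lambda_max(
    Xs: np.ndarray,
    Ys: np.ndarray,
    penalized_mask: np.ndarray | None = None,
    alpha: float = 1.0,
) -> float:
    """Smallest lambda at which all penalized coefficients are zero.

    With unpenalized columns fitted by least squares and r the resulting
    residual, the KKT condition for the all-zero penalized solution is
    |x_j' r| / n <= lambda * alpha on standardized columns, so
    lambda_max = max_j |x_j' r| / (n * alpha). alpha = 0 (pure ridge) has
    no finite anchor and raises.
    """
    if alpha <= 0.0:
        raise ValueError("lambda_max undefined for alpha = 0 (ridge grid is fixed)")
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Ys = np.asarray(Ys, dtype=float).ravel()
    n, p = Xs.shape
    mask = _resolve_mask(p, penalized_mask)
    if mask.all():
        r = Ys
    else:
        Xu = Xs[:, ~mask]
        b, *_ = np.linalg.lstsq(Xu, Ys, rcond=None)
        r = Ys - Xu @ b
    if not mask.any():
        return 0.0
    Xstd, _, v = _standardize(Xs[:, mask])
    grads = np.abs(Xstd.T @ r) / n * v
    return float(grads.max() / alpha) if grads.size else 0.0


def default_lambda_grid(
    lam_max: float, n_lambda: int = 100, min_ratio: float = 1e-3
) -> np.ndarray:
    """Descending log-spaced grid from lam_max to min_ratio * lam_max."""
    if lam_max <= 0:
        return np.array([0.0])
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n_lambda)


# ---------------------------------------------------------------------------
# coordinate-descent paths (ridge / lasso / enet / scad)
# ---------------------------------------------------------------------------

def _penalty_arrays(
    spec: PenaltySpec, lam: float, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = mask.size
    lam1 = np.zeros(p)
    lam2 = np.zeros(p)
    scad_lam = np.zeros(p)
    if spec.family in ("ols",) or lam == 0.0:
        pass
    elif spec.family == "lasso":
        lam1[mask] = lam
    elif spec.family == "ridge":
        lam2[mask] = 2.0 * lam
    elif spec.family == "enet":
        lam1[mask] = lam * spec.alpha
        lam2[mask] = 2.0 * lam * (1.0 - spec.alpha)
    elif spec.family == "scad":
        scad_lam[mask] = lam
    else:
        raise ValueError(f"family {spec.family!r} has no coordinate path")
    return lam1, lam2, scad_lam


def fit_path(
    Xs: np.ndarray,
    Ys: np.ndarray,
    spec: PenaltySpec,
    lam_grid: np.ndarray,
    penalized_mask: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> list[FitResult]:
    """Warm-started coordinate descent down a strictly descending lambda
    grid. Non-convergence at max_iter flags the result rather than raising.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("empty lambda grid")
    if lam_grid.size > 1 and not np.all(np.diff(lam_grid) < 0):
        raise ValueError("lambda grid must be strictly descending")
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Ys = np.asarray(Ys, dtype=float).ravel()
    n, p = Xs.shape
    mask = _resolve_mask(p, penalized_mask)

    Xstd, scales, v = _standardize(Xs)
    beta = np.zeros(p)
    r = Ys.copy()
    results: list[FitResult] = []
    for lam in lam_grid:
        lam1, lam2, scad_lam = _penalty_arrays(spec, float(lam), mask)
        n_it, max_d, conv = cd_sweeps(
            Xstd, beta, r, v, lam1, lam2, scad_lam, spec.a, tol, max_iter
        )
        if not conv:
            logger.warning(
                "%s path did not converge at lambda=%.4g (max delta %.2e)",
                spec.family, lam, max_d,
            )
        results.append(
            FitResult(
                coef=beta / scales,
                penalized_mask=mask.copy(),
                spec=PenaltySpec(
                    spec.family, float(lam), spec.alpha, spec.a, spec.tau
                ),
                n_iter=n_it,
                max_delta=max_d,
                converged=conv,
            )
        )
    return results


def ridge_path_closed(
    Xs: np.ndarray,
    Ys: np.ndarray,
    lam_grid: np.ndarray,
    penalized_mask: np.ndarray | None = None,
) -> list[FitResult]:
    """Exact ridge solutions for a whole lambda grid from one
    eigendecomposition.

    The ridge objective is strictly convex, so instead of iterating
    coordinates the unpenalized columns are profiled out with a QR
    projector and the penalized block is diagonalized once; every lambda
    then costs only a diagonal rescaling. Identical (to numerical
    tolerance) to ``fit_path`` with the ridge family, at a fraction of the
    cost for long grids on wide panels.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Ys = np.asarray(Ys, dtype=float).ravel()
    n, p = Xs.shape
    mask = _resolve_mask(p, penalized_mask)
    Xstd, scales, v = _standardize(Xs)
    act = v > 0
    pen_cols = np.flatnonzero(mask & act)
    unp_cols = np.flatnonzero(~mask & act)

    P = np.ascontiguousarray(Xstd[:, pen_cols])
    if unp_cols.size:
        Q, R = np.linalg.qr(Xstd[:, unp_cols])
        My = Ys - Q @ (Q.T @ Ys)
        MP = P - Q @ (Q.T @ P)
    else:
        My, MP = Ys, P
    A = MP.T @ MP / n
    c = MP.T @ My / n
    w, V = np.linalg.eigh(A)
    Vc = V.T @ c

    results = []
    for lam in lam_grid:
        beta = np.zeros(p)
        if pen_cols.size:
            b = V @ (Vc / (w + 2.0 * lam))
            beta[pen_cols] = b
        if unp_cols.size:
            rhs = Q.T @ (Ys - P @ beta[pen_cols]) if pen_cols.size else Q.T @ Ys
            beta[unp_cols] = np.linalg.solve(R, rhs)
        results.append(
            FitResult(
                coef=beta / scales,
                penalized_mask=mask.copy(),
                spec=PenaltySpec("ridge", float(lam)),
                converged=True,
            )
        )
    return results


# ---------------------------------------------------------------------------
# TLP by difference-of-convex iteration
# ---------------------------------------------------------------------------

def _tlp_objective(
    Xstd: np.ndarray, Ys: np.ndarray, beta: np.ndarray,
    mask: np.ndarray, lam: float, tau: float,
) -> float:
    r = Ys - Xstd @ beta
    pen = np.sum(np.minimum(np.abs(beta[mask]) / tau, 1.0))
    return float(0.5 * np.dot(r, r) / Ys.size + lam * pen)


def fit_tlp(
    Xs: np.ndarray,
    Ys: np.ndarray,
    lam: float,
    tau: float,
    penalized_mask: np.ndarray | None = None,
    init: FitResult | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    max_dc_iter: int = 50,
) -> FitResult:
    """Truncated-L1 fit by difference-of-convex (DC) iteration.

    At step m the concave part of min(|b|/tau, 1) is linearized at the
    current iterate, leaving a weighted lasso with per-coordinate L1 weight
    (lam/tau) * I(|b_k^(m)| <= tau). Iteration stops when the objective
    decrease falls below tolerance and the sub/super-threshold active set
    stabilizes; the objective sequence is recorded and is non-increasing by
    the majorize-minimize construction.

    DC iteration only finds a local solution, so two starts are tried — the
    all-zero vector and either ``init`` or the (minimum-norm) least-squares
    solution — and the lower-objective fixed point is returned. At small
    tau this reproduces the exact best-subset-style choice between the null
    and unpenalized solutions on simple instances.
    """
    if tau <= 0:
        raise ValueError("TLP threshold tau must be > 0")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Ys = np.asarray(Ys, dtype=float).ravel()
    n, p = Xs.shape
    mask = _resolve_mask(p, penalized_mask)
    spec = PenaltySpec("tlp", lam, tau=tau)

    if lam == 0.0:
        res = fit_ols(Xs, Ys)
        res.spec = spec
        res.penalized_mask = mask
        return res

    Xstd, scales, v = _standardize(Xs)
    lam2 = np.zeros(p)
    scad_lam = np.zeros(p)

    def dc_run(beta0: np.ndarray):
        beta = beta0.copy()
        r = Ys - Xstd @ beta
        objs = [_tlp_objective(Xstd, Ys, beta, mask, lam, tau)]
        iters = 0
        max_d = 0.0
        conv = True
        for _ in range(max_dc_iter):
            low = (np.abs(beta) <= tau) & mask
            lam1 = np.where(low, lam / tau, 0.0)
            n_it, max_d, ok = cd_sweeps(
                Xstd, beta, r, v, lam1, lam2, scad_lam, 3.7, tol, max_iter
            )
            iters += n_it
            conv = conv and ok
            obj = _tlp_objective(Xstd, Ys, beta, mask, lam, tau)
            # MM guarantee up to round-off
            assert obj <= objs[-1] + 1e-9 * (1.0 + abs(objs[-1])), (
                "TLP objective increased across a DC step"
            )
            objs.append(obj)
            new_low = (np.abs(beta) <= tau) & mask
            if np.array_equal(new_low, low) and objs[-2] - obj < 1e-9 * (
                1 + abs(obj)
            ):
                break
        else:
            conv = False
        return beta, objs, iters, max_d, conv

    if init is not None:
        warm = init.coef * scales
    else:
        warm, *_ = np.linalg.lstsq(Xstd, Ys, rcond=None)
    runs = [dc_run(np.zeros(p)), dc_run(warm)]
    beta, objs, iters, max_d, conv = min(runs, key=lambda r: r[1][-1])
    return FitResult(
        coef=beta / scales,
        penalized_mask=mask,
        spec=spec,
        n_iter=sum(r[2] for r in runs),
        max_delta=max_d,
        converged=conv,
        dc_objectives=objs,
    )
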