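"""Numba inner kernel for cyclic coordinate descent.

Operates on a design whose columns have been scaled to unit root mean
square (``v_j = x_j'x_j / n = 1``; zero-variance columns carry ``v_j = 0``
and are skipped). The objective is

    (1/2n) ||y - X beta||^2  +  sum_j penalty_j(beta_j)

with per-coordinate penalties expressed through three arrays:

* ``lam1[j]`` — L1 weight (soft-threshold amount),
* ``lam2[j]`` — quadratic shrink added to the unit curvature,
* ``scad_lam[j]`` — if > 0, the coordinate uses the exact univariate SCAD
  minimizer with shape ``scad_a`` instead of the L1/L2 rule.

Unpenalized coordinates simply have all three weights at zero. The residual
vector is maintained in place. Sweeps alternate the usual way: a full pass
over all coordinates, then repeated passes over the active set (nonzero or
unpenalized coordinates) until it stabilizes, then a full pass again;
convergence is declared when a *full* pass moves no coordinate by more
than ``tol``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def scad_univariate(z: float, lam: float, a: float) -> float:
    """Global minimizer of 0.5*(z - b)^2 + SCAD(b; lam, a) for unit
    curvature: soft-thresholding up to 2*lam, linear interpolation up to
    a*lam, identity (no further shrinkage) beyond a*lam."""
    az = abs(z)
    if az <= 2.0 * lam:
        return soft(z, lam)
    if az <= a * lam:
        sign = 1.0 if z > 0 else -1.0
        return ((a - 1.0) * z - sign * a * lam) / (a - 2.0)
    return z


@njit(cache=True, inline="always")
def _update(
    X: np.ndarray,
    beta: np.ndarray,
    r: np.ndarray,
    lam1: np.ndarray,
    lam2: np.ndarray,
    scad_lam: np.ndarray,
    scad_a: float,
    j: int,
    n: int,
) -> float:
    bj = beta[j]
    z = 0.0
    for i in range(n):
        z += X[i, j] * r[i]
    z = z / n + bj  # v_j = 1 for active columns
    if scad_lam[j] > 0.0:
        bnew = scad_univariate(z, scad_lam[j], scad_a)
    else:
        bnew = soft(z, lam1[j]) / (1.0 + lam2[j])
    d = bnew - bj
    if d != 0.0:
        beta[j] = bnew
        for i in range(n):
            r[i] -= X[i, j] * d
    return abs(d)


@njit(cache=True)
def cd_sweeps(
    X: np.ndarray,
    beta: np.ndarray,
    r: np.ndarray,
    v: np.ndarray,
    lam1: np.ndarray,
    lam2: np.ndarray,
    scad_lam: np.ndarray,
    scad_a: float,
    tol: float,
    max_iter: int,
) -> tuple[int, float, bool]:
    """Active-set cyclic coordinate descent. X is (n, p) Fortran-ordered;
    r = y - X @ beta on entry and is kept consistent in place. Returns
    (sweeps used, last max coordinate change, converged)."""
    n, p = X.shape
    it = 0
    max_d = 0.0
    active = np.empty(p, np.int64)
    while it < max_iter:
        # full pass
        it += 1
        max_d = 0.0
        for j in range(p):
            if v[j] == 0.0:
                continue
            d = _update(X, beta, r, lam1, lam2, scad_lam, scad_a, j, n)
            if d > max_d:
                max_d = d
        if max_d < tol:
            return it, max_d, True
        # collect the active set: unpenalized or currently nonzero
        na = 0
        for j in range(p):
            if v[j] == 0.0:
                continue
            if beta[j] != 0.0 or (
                lam1[j] == 0.0 and scad_lam[j] == 0.0
            ):
                active[na] = j
                na += 1
        # iterate on the active set until it stops moving
        while it < max_iter:
            it += 1
            max_d = 0.0
            for k in range(na):
                j = active[k]
                d = _update(X, beta, r, lam1, lam2, scad_lam, scad_a, j, n)
                if d > max_d:
                    max_d = d
            if max_d < tol:
                break
    return it, max_d, it < max_iter
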