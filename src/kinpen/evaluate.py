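"""Repeated train/tune/test evaluation of the penalized predictors.

The study design: samples are randomly partitioned into equal training,
tuning and testing thirds; every penalty family is fitted on the training
set along its hyperparameter grid; the hyperparameters minimizing
prediction error on the tuning set are selected (ties prefer the stronger
penalty); and the *training* coefficients at the selected hyperparameters
are applied unchanged to the testing set. The whole procedure is repeated
over many random splits, and methods/scenarios are compared by the median
test predictive mean squared error (PMSE).

Scenarios follow a CV/RV panel grid: models using only the top-k common
variants, only the top-k rare variants, and the fixed top-k of one class
plus the top 1/10/100/... of the complementary class, where the combined
column reports, per replicate, the smallest test PMSE over the added
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import penalized
from .penalized import FitResult, PenaltySpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# splits and the error metric
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """One random partition into disjoint train/tune/test sample sets."""

    replicate: int
    seed: int
    train: np.ndarray  # integer row indices
    tune: np.ndarray
    test: np.ndarray


def split_three_way(
    sample_ids: list[str] | int, seed: int, replicate: int = 0
) -> SplitPlan:
    """Uniformly random partition into near-equal thirds; the remainder
    (n mod 3) is assigned one extra sample to train, then tune."""
    n = sample_ids if isinstance(sample_ids, int) else len(sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for a three-way split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, 3)
    n_train = base + (1 if rem >= 1 else 0)
    n_tune = base + (1 if rem >= 2 else 0)
    return SplitPlan(
        replicate=replicate,
        seed=seed,
        train=np.sort(perm[:n_train]),
        tune=np.sort(perm[n_train : n_train + n_tune]),
        test=np.sort(perm[n_train + n_tune :]),
    )


def pmse(Yhat: np.ndarray, Y: np.ndarray) -> float:
    """Predictive mean squared error sum((Yhat - Y)^2) / n."""
    Yhat = np.asarray(Yhat, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    if Yhat.size != Y.size:
        raise ValueError("prediction and observation lengths differ")
    if Y.size == 0:
        raise ValueError("empty vectors")
    d = Yhat - Y
    return float(d @ d / Y.size)


# ---------------------------------------------------------------------------
# hyperparameter grids
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    """Hyperparameter grid configuration for the tuning search.

    The study design fixes the elastic-net mix at alpha = 0.5 and SCAD
    at a = 3.7 and tunes only lambda (plus tau for TLP, on a deliberately
    coarse grid since each (lambda, tau) pair costs a full DC solve).
    """

    n_lambda: int = 100
    lambda_min_ratio: float | None = None  # auto: 0.01 if p > n else 1e-3
    alpha: float = 0.5
    scad_a: float = 3.7
    ridge_n_lambda: int = 50
    ridge_log_span: tuple[float, float] = (1.0, -4.0)
    tlp_n_lambda: int = 8
    tlp_lambda_min_ratio: float = 1e-2
    tlp_taus: tuple[float, ...] = (0.01, 0.1, 0.5)
    tol: float = 1e-5  # path tolerance; the solver default (1e-7) is stricter

    def min_ratio(self, n: int, p: int) -> float:
        """Path floor as a fraction of lambda_max; on p > n designs the
        small-lambda tail interpolates the data and is skipped (the usual
        glmnet-style convention)."""
        if self.lambda_min_ratio is not None:
            return self.lambda_min_ratio
        return 1e-2 if p >= n else 1e-3


def _fit_candidates(
    family: str,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    mask: np.ndarray,
    cfg: GridConfig,
) -> list[FitResult]:
    """Fit the training-set model sequence for one family, ordered from the
    strongest penalty to the weakest (so tuning ties resolve to sparser
    models)."""
    n, p = X_tr.shape
    ratio = cfg.min_ratio(n, int(mask.sum()))
    if family == "ols":
        return [penalized.fit_ols(X_tr, y_tr)]
    if family == "tlp":
        anchor = penalized.lambda_max(X_tr, y_tr, mask, alpha=1.0)
        fits: list[FitResult] = []
        for tau in cfg.tlp_taus:
            if anchor <= 0:
                lam_grid = np.array([0.0])
            else:
                lam_grid = tau * anchor * np.logspace(
                    0.0, np.log10(cfg.tlp_lambda_min_ratio), cfg.tlp_n_lambda
                )
            init = None
            for lam in lam_grid:
                res = penalized.fit_tlp(
                    X_tr, y_tr, float(lam), tau, penalized_mask=mask,
                    init=init, tol=cfg.tol,
                )
                init = res
                fits.append(res)
        return fits
    if family == "ridge":
        anchor = penalized.lambda_max(X_tr, y_tr, mask, alpha=1.0)
        anchor = anchor if anchor > 0 else 1.0
        lo, hi = cfg.ridge_log_span
        grid = anchor * np.logspace(lo, hi, cfg.ridge_n_lambda)
        return penalized.ridge_path_closed(X_tr, y_tr, grid, penalized_mask=mask)
    if family == "lasso":
        anchor = penalized.lambda_max(X_tr, y_tr, mask, alpha=1.0)
        grid = penalized.default_lambda_grid(anchor, cfg.n_lambda, ratio)
        spec = PenaltySpec("lasso")
    elif family == "enet":
        alpha = cfg.alpha
        anchor = penalized.lambda_max(
            X_tr, y_tr, mask, alpha=max(alpha, 1e-3)
        )
        grid = penalized.default_lambda_grid(anchor, cfg.n_lambda, ratio)
        spec = PenaltySpec("enet", alpha=alpha)
    elif family == "scad":
        anchor = penalized.lambda_max(X_tr, y_tr, mask, alpha=1.0)
        grid = penalized.default_lambda_grid(anchor, cfg.n_lambda, ratio)
        spec = PenaltySpec("scad", a=cfg.scad_a)
    else:
        raise ValueError(f"unknown method {family!r}")
    return penalized.fit_path(
        X_tr, y_tr, spec, grid, penalized_mask=mask, tol=cfg.tol
    )


def tune_and_test(
    X: np.ndarray,
    Y: np.ndarray,
    plan: SplitPlan,
    family: str,
    penalized_mask: np.ndarray,
    cfg: GridConfig | None = None,
) -> dict:
    """Fit one family's model sequence on the training rows, select the
    hyperparameters minimizing tuning-set PMSE (strict improvement, so ties
    keep the stronger penalty), and apply the training coefficients to the
    testing rows. No refit on train+tune is performed."""
    cfg = cfg or GridConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    X_tr, y_tr = X[plan.train], Y[plan.train]
    n_empty = int(np.sum(X_tr[:, penalized_mask].std(axis=0) == 0.0))
    if n_empty:
        logger.debug(
            "%d zero-variance panel columns in the training split "
            "(coefficients pinned to zero)", n_empty,
        )
    fits = _fit_candidates(family, X_tr, y_tr, penalized_mask, cfg)

    X_tu, y_tu = X[plan.tune], Y[plan.tune]
    best: FitResult | None = None
    best_pmse = np.inf
    for res in fits:
        err = pmse(res.predict(X_tu), y_tu)
        if err < best_pmse:
            best, best_pmse = res, err
    assert best is not None
    test_pmse = pmse(best.predict(X[plan.test]), Y[plan.test])
    return {
        "method": family,
        "lam": best.spec.lam,
        "alpha": best.spec.alpha if family == "enet" else np.nan,
        "tau": best.spec.tau if family == "tlp" else np.nan,
        "tune_pmse": best_pmse,
        "test_pmse": test_pmse,
        "n_nonzero": best.n_nonzero,
        "converged": best.converged,
    }


# ---------------------------------------------------------------------------
# the scenario study
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """One panel composition: the top n_cv common and top n_rv rare
    variants (not both zero)."""

    n_cv: int
    n_rv: int

    def __post_init__(self) -> None:
        if self.n_cv == 0 and self.n_rv == 0:
            raise ValueError("scenario needs at least one variant class")

    @property
    def key(self) -> tuple[int, int]:
        return (self.n_cv, self.n_rv)


@dataclass
class StudyData:
    """Whitened inputs shared by every scenario: decorrelated phenotype,
    decorrelated covariate design (intercept included), and the decorrelated
    dosage columns of all screened panel variants in screen-rank order."""

    Y_star: np.ndarray
    C_star: np.ndarray
    G_star: np.ndarray
    variant_ids: list[str]
    cv_order: list[str]
    rv_order: list[str]
    sample_ids: list[str]
    _col: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self._col:
            self._col = {v: j for j, v in enumerate(self.variant_ids)}

    def design(self, n_cv: int, n_rv: int) -> tuple[np.ndarray, np.ndarray]:
        """(X, penalized_mask) for the top-n_cv + top-n_rv panel; covariate
        columns come first and are unpenalized."""
        if n_cv > len(self.cv_order):
            raise ValueError(f"requested {n_cv} CVs, only {len(self.cv_order)}")
        if n_rv > len(self.rv_order):
            raise ValueError(f"requested {n_rv} RVs, only {len(self.rv_order)}")
        cols = [self._col[v] for v in self.cv_order[:n_cv]]
        cols += [self._col[v] for v in self.rv_order[:n_rv]]
        X = np.hstack([self.C_star, self.G_star[:, cols]])
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[self.C_star.shape[1] :] = True
        return X, mask


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed derived from the master seed by a
    counter through numpy's SeedSequence (kept below 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ScenarioResultTable:
    """Long-format records of every (replicate, scenario, method) cell plus
    the study's median pivot built from them."""

    long: pd.DataFrame
    base_sizes: tuple[int, ...]
    added_sizes: tuple[int, ...]
    methods: tuple[str, ...]

    def scenario_labels(self) -> list[str]:
        labels = []
        for b in self.base_sizes:
            labels += [f"CV only (top {b})", f"RV only (top {b})"]
            if self.added_sizes:
                labels += [f"CV={b},RV>0", f"RV={b},CV>0"]
        return labels

    def aggregated(self) -> pd.DataFrame:
        """Per-replicate scenario columns: single cells for the pure-class
        panels; the minimum test PMSE over the added complementary counts
        for the combined columns."""
        lng = self.long
        out = []
        for (rep, method), sub in lng.groupby(["replicate", "method"]):
            cell = {
                (r.n_cv, r.n_rv): r.test_pmse for r in sub.itertuples()
            }
            for b in self.base_sizes:
                rows = {
                    f"CV only (top {b})": [cell.get((b, 0), np.nan)],
                    f"RV only (top {b})": [cell.get((0, b), np.nan)],
                }
                if self.added_sizes:
                    rows[f"CV={b},RV>0"] = [
                        cell.get((b, a), np.nan) for a in self.added_sizes
                    ]
                    rows[f"RV={b},CV>0"] = [
                        cell.get((a, b), np.nan) for a in self.added_sizes
                    ]
                for label, vals in rows.items():
                    vals = [v for v in vals if np.isfinite(v)]
                    out.append(
                        {
                            "replicate": rep,
                            "method": method,
                            "scenario": label,
                            "test_pmse": min(vals) if vals else np.nan,
                        }
                    )
        return pd.DataFrame(out)

    def median_pivot(self) -> pd.DataFrame:
        """Methods x scenarios table of median test PMSE across replicates
        (the shape of the study's summary table)."""
        agg = self.aggregated()
        pivot = agg.pivot_table(
            index="method", columns="scenario", values="test_pmse",
            aggfunc="median",
        )
        order = [c for c in self.scenario_labels() if c in pivot.columns]
        methods = [m for m in self.methods if m in pivot.index]
        return pivot.loc[methods, order]


def build_study_data(
    G,
    pheno: pd.DataFrame,
    n_cv_panel: int,
    n_rv_panel: int,
    kinship_matrix=None,
    vc_method: str = "REML",
    max_missing_fraction: float = 0.10,
    screen_on_decorrelated: bool = False,
):
    """Assemble the whitened study inputs from raw genotypes and the
    phenotype/covariate table.

    Order of operations mirrors the study design: sample QC by missingness,
    IBS kinship (unless a matrix is supplied), variance-component fit with
    intercept + the four covariates as fixed effects, Kruskal-Wallis
    screening on the raw trait (optionally on the decorrelated trait), and
    a single whitening of phenotype, covariates and all screened panel
    columns estimated once on the full sample.

    Returns (StudyData, dict of intermediates: genotypes after QC, kinship,
    variance components, screening result, panel).
    """
    from . import kinship as kin
    from . import screen as scr
    from .simulate import COVARIATE_COLUMNS

    G = kin.exclude_high_missingness(G, max_missing_fraction)
    pheno = (
        pheno.set_index("sample_id").loc[G.sample_ids].reset_index()
    )
    Y = pheno["sbp"].to_numpy(dtype=float)
    C = np.column_stack(
        [np.ones(G.n_samples)]
        + [pheno[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    )
    K = kinship_matrix
    if K is None:
        K = kin.ibs_matrix(G)
    else:
        K = K.reorder(G.sample_ids)
    vc = kin.fit_variance_components(Y, C, K, method=vc_method)

    if screen_on_decorrelated:
        wh0 = kin.whiten(Y, C, vc)
        y_screen = wh0.Y_star
    else:
        y_screen = Y
    screening = scr.screen_variants(G, y_screen)
    panel = scr.build_panel(screening, n_cv_panel, n_rv_panel)

    panel_ids = panel.cv_ids + panel.rv_ids
    col_of = {v: j for j, v in enumerate(G.variant_ids)}
    D = G.imputed()[:, [col_of[v] for v in panel_ids]]
    wh = kin.whiten(Y, np.hstack([C, D]), vc)
    q = C.shape[1]
    data = StudyData(
        Y_star=wh.Y_star,
        C_star=wh.X_star[:, :q],
        G_star=wh.X_star[:, q:],
        variant_ids=panel_ids,
        cv_order=panel.cv_ids,
        rv_order=panel.rv_ids,
        sample_ids=list(G.sample_ids),
    )
    extras = {
        "genotypes": G,
        "kinship": K,
        "variance_components": vc,
        "screening": screening,
        "panel": panel,
    }
    return data, extras


def run_scenarios(
    data: StudyData,
    methods: tuple[str, ...] = ("ols", "scad", "lasso", "enet", "ridge", "tlp"),
    base_sizes: tuple[int, ...] = (10, 100, 1000),
    added_sizes: tuple[int, ...] = (1, 10, 100, 1000),
    n_replicates: int = 100,
    seed: int = 0,
    cfg: GridConfig | None = None,
) -> ScenarioResultTable:
    """Run the full scenario study: for every replicate split, scenario cell
    and method, one tune-and-test record. A failed cell is recorded with its
    reason and the run continues (ill-conditioned OLS cells must not abort
    the study). Deterministic for a fixed master seed."""
    cfg = cfg or GridConfig()
    cells: list[tuple[int, int]] = []
    for b in base_sizes:
        for cell in [(b, 0), (0, b)]:
            if cell not in cells:
                cells.append(cell)
        for a in added_sizes:
            for cell in [(b, a), (a, b)]:
                if cell not in cells:
                    cells.append(cell)
    need_cv = max(c[0] for c in cells)
    need_rv = max(c[1] for c in cells)
    if need_cv > len(data.cv_order) or need_rv > len(data.rv_order):
        raise ValueError(
            f"scenario grid needs top {need_cv} CVs / {need_rv} RVs; panel has "
            f"{len(data.cv_order)} / {len(data.rv_order)}"
        )

    records = []
    for rep in range(n_replicates):
        plan = split_three_way(
            data.sample_ids, replicate_seed(seed, rep), replicate=rep
        )
        for n_cv, n_rv in cells:
            X, mask = data.design(n_cv, n_rv)
            for method in methods:
                base = {"replicate": rep, "n_cv": n_cv, "n_rv": n_rv}
                try:
                    rec = tune_and_test(X, data.Y_star, plan, method, mask, cfg)
                    records.append({**base, **rec, "error": ""})
                except Exception as exc:  # noqa: BLE001 - study must continue
                    logger.warning(
                        "cell (CV=%d, RV=%d, %s, rep %d) failed: %s",
                        n_cv, n_rv, method, rep, exc,
                    )
                    records.append(
                        {
                            **base,
                            "method": method,
                            "lam": np.nan,
                            "alpha": np.nan,
                            "tau": np.nan,
                            "tune_pmse": np.nan,
                            "test_pmse": np.nan,
                            "n_nonzero": -1,
                            "converged": False,
                            "error": str(exc),
                        }
                    )
    return ScenarioResultTable(
        long=pd.DataFrame.from_records(records),
        base_sizes=tuple(base_sizes),
        added_sizes=tuple(added_sizes),
        methods=tuple(methods),
    )
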