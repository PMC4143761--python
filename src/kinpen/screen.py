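"""Marginal variant screening by the Kruskal-Wallis rank test.

Variants are ranked by the marginal association between their minor-allele
count (treated as a grouping factor with up to three levels) and the
quantitative trait, separately within the common-variant (MAF >= 5%) and
rare-variant (MAF < 5%) classes. The top-k lists per class form the SNP
panels fed to the penalized regressions. Screening is a ranking device, not
inference, so no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)


def minor_allele_frequency(column: np.ndarray) -> float:
    """Folded minor-allele frequency of a 0/1/2 dosage vector, ignoring
    missing entries: min(p, 1 - p) with p = (sum of dosages) / (2 n_obs)."""
    col = np.asarray(column, dtype=float).ravel()
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("cannot compute MAF of an all-missing column")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def kruskal_wallis(
    column: np.ndarray, Y: np.ndarray
) -> tuple[float, int, float]:
    """Kruskal-Wallis H of the trait grouped by dosage level.

    Mid-ranks with the standard tie correction; df = (number of dosage
    groups) - 1; p from the chi-square approximation. A trait that is
    constant across all observations yields H = 0 by convention (the tie
    correction degenerates). Samples with a missing dosage are dropped.

    Raises if fewer than two dosage groups are present (monomorphic column;
    callers exclude such variants before screening).
    """
    col = np.asarray(column, dtype=float).ravel()
    y = np.asarray(Y, dtype=float).ravel()
    if col.size != y.size:
        raise ValueError("dosage and phenotype lengths differ")
    keep = ~np.isnan(col)
    col, y = col[keep], y[keep]
    levels = np.unique(col)
    if levels.size < 2:
        raise ValueError("monomorphic dosage column: need >= 2 groups")
    ranks = stats.rankdata(y)
    n = y.size
    h = 0.0
    for lev in levels:
        grp = ranks[col == lev]
        h += grp.sum() ** 2 / grp.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction on the trait ranks
    _, t = np.unique(y, return_counts=True)
    denom = 1.0 - np.sum(t**3 - t) / (n**3 - n)
    if denom <= 0.0:
        return 0.0, int(levels.size - 1), 1.0
    h /= denom
    df = int(levels.size - 1)
    return float(h), df, float(stats.chi2.sf(h, df))


@dataclass
class ScreeningResult:
    """Per-variant screening records with within-class ranks.

    ``table`` columns: variant, maf, vclass ('CV'/'RV'), H, df, p, rank.
    Ranks run 1..k within each class, ordered by ascending p with ties
    broken by descending H then ascending variant id (deterministic across
    platforms).
    """

    table: pd.DataFrame
    n_monomorphic: int = 0
    provenance: dict = field(default_factory=dict)

    def top(self, vclass: str, k: int) -> list[str]:
        sub = self.table[self.table["vclass"] == vclass]
        if k > len(sub):
            raise ValueError(
                f"requested top {k} {vclass}s but only {len(sub)} available"
            )
        sub = sub.sort_values("rank").head(k)
        return sub["variant"].tolist()


@dataclass
class SnpPanel:
    """Ordered CV and RV id lists selected by the screen (disjoint)."""

    cv_ids: list[str]
    rv_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.cv_ids) & set(self.rv_ids):
            raise ValueError("CV and RV panel lists overlap")


def screen_variants(G: GenotypeMatrix, Y: np.ndarray) -> ScreeningResult:
    """Kruskal-Wallis screen of every polymorphic variant against the trait.

    Monomorphic columns (and columns reduced to a single dosage group by
    missingness) are excluded and counted. When a column has no missing
    entries the trait ranks and tie correction are shared across variants,
    so the screen reduces to per-variant group sums of precomputed ranks.
    """
    y = np.asarray(Y, dtype=float).ravel()
    if y.size != G.n_samples:
        raise ValueError("phenotype length does not match genotype samples")

    ranks_full = stats.rankdata(y)
    n_full = y.size
    _, t = np.unique(y, return_counts=True)
    denom_full = 1.0 - np.sum(t**3 - t) / (n_full**3 - n_full) if n_full > 1 else 0.0

    records = []
    n_mono = 0
    for j in range(G.n_variants):
        col = G.dosages[:, j]
        missing = np.isnan(col)
        if not missing.any():
            levels = np.unique(col)
            if levels.size < 2:
                n_mono += 1
                continue
            h = 0.0
            for lev in levels:
                grp = ranks_full[col == lev]
                h += grp.sum() ** 2 / grp.size
            h = 12.0 / (n_full * (n_full + 1)) * h - 3.0 * (n_full + 1)
            if denom_full <= 0.0:
                h, p = 0.0, 1.0
            else:
                h /= denom_full
                p = float(stats.chi2.sf(h, levels.size - 1))
            df = int(levels.size - 1)
        else:
            obs = col[~missing]
            if np.unique(obs).size < 2:
                n_mono += 1
                continue
            h, df, p = kruskal_wallis(col, y)
        records.append(
            {
                "variant": G.variant_ids[j],
                "maf": float(G.maf[j]),
                "vclass": "CV" if G.is_common[j] else "RV",
                "H": float(h),
                "df": df,
                "p": p,
            }
        )
    if not records:
        raise ValueError("no polymorphic variants to screen")
    if n_mono:
        logger.info("screening excluded %d monomorphic variants", n_mono)

    table = pd.DataFrame.from_records(records)
    table["_negH"] = -table["H"]
    table = table.sort_values(["p", "_negH", "variant"]).drop(columns="_negH")
    table["rank"] = table.groupby("vclass").cumcount() + 1
    table = table.reset_index(drop=True)
    return ScreeningResult(table=table, n_monomorphic=n_mono)


def build_panel(res: ScreeningResult, n_cv: int, n_rv: int) -> SnpPanel:
    """Top ``n_cv`` common and ``n_rv`` rare variants by within-class rank."""
    return SnpPanel(
        cv_ids=res.top("CV", n_cv) if n_cv else [],
        rv_ids=res.top("RV", n_rv) if n_rv else [],
        provenance=dict(res.provenance),
    )
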