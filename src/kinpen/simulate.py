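"""Synthetic family study generator.

Emulates the structure of a sequencing-based family study of systolic blood
pressure (SBP): a modest number of extended pedigrees, genotypes at a mix of
common variants (CV, minor allele frequency >= 5%) and rare variants
(RV, 0 < MAF < 5%), four covariates (age, gender, smoking status,
antihypertensive-medication use), and a quantitative trait driven by a sparse
set of causal variants plus a polygenic component whose covariance follows the
pedigree relationship matrix:

    Y = X beta + g + e,   g ~ N(0, sigma_g^2 * K),   e ~ N(0, sigma_r^2 * I).

Genotypes are produced by gene dropping: founders draw two alleles at the
variant's population MAF and non-founders inherit one randomly chosen allele
from each parent, so family linkage disequilibrium and relatedness arise
mechanistically rather than by fiat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAF_THRESHOLD = 0.05  # CV/RV boundary on the folded minor-allele frequency


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Member:
    """One pedigree member. Founders (including married-in spouses) have no
    parent references; sex is 1 = male, 2 = female (PED convention)."""

    id: str
    family_id: str
    father: str | None
    mother: str | None
    generation: int
    sex: int

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Family:
    id: str
    members: list[Member]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PedigreeSet:
    families: list[Family]

    @property
    def members(self) -> list[Member]:
        return [m for fam in self.families for m in fam.members]

    @property
    def sample_ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def n_samples(self) -> int:
        return sum(len(f) for f in self.families)

    def validate(self) -> None:
        for fam in self.families:
            ids = {m.id for m in fam.members}
            for m in fam.members:
                for p in (m.father, m.mother):
                    if p is not None and p not in ids:
                        raise ValueError(
                            f"member {m.id}: parent {p} not in family {fam.id}"
                        )
        # acyclicity is checked by the topological sort in expected_relationship


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage table.

    ``dosages`` is float with NaN for missing calls; observed entries are
    0/1/2 counts of the minor allele. ``maf`` is the folded frequency
    computed from non-missing entries, and the CV/RV class flag follows the
    5% cut. Monomorphic columns (realized MAF 0) are kept but flagged so QC
    and screening can exclude them explicitly.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    maf: np.ndarray
    is_common: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_monomorphic(self) -> np.ndarray:
        return self.maf <= 0.0

    @property
    def is_rare(self) -> np.ndarray:
        return (~self.is_common) & (~self.is_monomorphic)

    @classmethod
    def from_dosages(
        cls,
        dosages: np.ndarray,
        sample_ids: list[str],
        variant_ids: list[str],
    ) -> "GenotypeMatrix":
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosage table must be 2-D (samples x variants)")
        if dosages.shape != (len(sample_ids), len(variant_ids)):
            raise ValueError("dosage shape does not match id lists")
        ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage entry at sample {sample_ids[bad[0]]}, variant "
                f"{variant_ids[bad[1]]} is not in {{0, 1, 2, missing}}"
            )
        maf = folded_frequencies(dosages)
        return cls(
            dosages=dosages,
            sample_ids=list(sample_ids),
            variant_ids=list(variant_ids),
            maf=maf,
            is_common=maf >= MAF_THRESHOLD,
        )

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.nan_to_num(col_mean)  # all-missing column -> 0
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d


def folded_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Per-column folded allele frequency min(p, 1-p) from 0/1/2 dosages,
    ignoring missing entries. Columns with no observations get NaN."""
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing column
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


@dataclass
class CausalSpec:
    """Generating model for the quantitative trait.

    Effect sizes are in trait units (mmHg for an SBP-like trait) per minor
    allele; covariate effects follow the column order of the covariate table
    (age, gender, smoking, medication).
    """

    causal_idx: np.ndarray
    effect_sizes: np.ndarray
    covariate_effects: np.ndarray
    intercept: float
    sigma_g2: float
    sigma_r2: float

    def __post_init__(self) -> None:
        self.causal_idx = np.asarray(self.causal_idx, dtype=int)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        if self.causal_idx.shape != self.effect_sizes.shape:
            raise ValueError("causal_idx and effect_sizes must align")
        if self.sigma_g2 < 0:
            raise ValueError("polygenic variance sigma_g2 must be >= 0")
        if self.sigma_r2 <= 0:
            raise ValueError("residual variance sigma_r2 must be > 0")


COVARIATE_COLUMNS = ("age", "gender", "smoking", "medication")


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigrees(
    n_families: int,
    size_range: tuple[int, int],
    n_generations: int = 3,
    seed: int = 0,
) -> PedigreeSet:
    """Grow ``n_families`` pedigrees member by member until each reaches a
    target size drawn uniformly from ``size_range``.

    Each family starts from one founder couple; children are added to a
    randomly chosen couple in a non-terminal generation, and a child may
    acquire a married-in (founder) spouse, opening a new reproducing couple
    in the next generation. Growth stops exactly at the target size, so all
    family sizes land inside the configured range.
    """
    lo, hi = size_range
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if lo > hi or lo < 1:
        raise ValueError(f"invalid size_range {size_range}")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if n_generations >= 2 and hi < 2:
        raise ValueError(
            f"size_range {size_range} cannot hold a founder couple over "
            f"{n_generations} generations"
        )
    rng = np.random.default_rng(seed)
    families: list[Family] = []
    for fi in range(n_families):
        fam_id = f"F{fi + 1:03d}"
        target = int(rng.integers(lo, hi + 1))
        members: list[Member] = []
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fam_id}_{counter:03d}"

        if n_generations == 1:
            # founders only: no couples can reproduce
            for _ in range(target):
                members.append(
                    Member(new_id(), fam_id, None, None, 0, int(rng.integers(1, 3)))
                )
            families.append(Family(fam_id, members))
            continue

        if target < 2:
            raise ValueError(
                f"family target size {target} cannot hold a founder couple"
            )
        father = Member(new_id(), fam_id, None, None, 0, 1)
        mother = Member(new_id(), fam_id, None, None, 0, 2)
        members += [father, mother]
        couples: list[tuple[Member, Member]] = [(father, mother)]

        while len(members) < target:
            open_couples = [
                c for c in couples if c[0].generation < n_generations - 1
            ]
            ci = int(rng.integers(len(open_couples)))
            cf, cm = open_couples[ci]
            sex = int(rng.integers(1, 3))
            child = Member(new_id(), fam_id, cf.id, cm.id, cf.generation + 1, sex)
            members.append(child)
            can_marry = (
                child.generation < n_generations - 1
                and len(members) < target
                and rng.random() < 0.6
            )
            if can_marry:
                spouse_sex = 2 if sex == 1 else 1
                spouse = Member(
                    new_id(), fam_id, None, None, child.generation, spouse_sex
                )
                members.append(spouse)
                couple = (child, spouse) if sex == 1 else (spouse, child)
                couples.append(couple)
        families.append(Family(fam_id, members))

    peds = PedigreeSet(families)
    peds.validate()
    return peds


# ---------------------------------------------------------------------------
# genotype simulation (gene dropping)
# ---------------------------------------------------------------------------

def simulate_genotypes(
    peds: PedigreeSet,
    n_cv: int,
    n_rv: int,
    cv_maf_range: tuple[float, float] = (0.05, 0.5),
    rv_maf_range: tuple[float, float] = (0.005, 0.05),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Gene-drop ``n_cv`` common and ``n_rv`` rare variants through the
    pedigrees.

    Population MAFs are drawn uniformly from the per-class range; founders
    receive two independent Bernoulli(MAF) alleles and non-founders inherit
    one uniformly chosen allele from each parent, so Mendelian consistency
    holds by construction. Dosage columns are re-oriented afterwards so the
    stored count is of the *realized* minor allele, and the stored MAF/class
    flags reflect the realized (not population) frequencies. ``missing_rate``
    masks entries at random to emulate missing calls.
    """
    if peds.n_samples == 0:
        raise ValueError("empty pedigree set")
    if not (0.05 <= cv_maf_range[0] <= cv_maf_range[1] <= 0.5):
        raise ValueError("cv_maf_range must lie within [0.05, 0.5]")
    if not (0.0 < rv_maf_range[0] <= rv_maf_range[1] <= 0.05):
        raise ValueError("rv_maf_range must lie within (0, 0.05]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    pop_maf = np.concatenate([
        rng.uniform(cv_maf_range[0], cv_maf_range[1], size=n_cv),
        rng.uniform(rv_maf_range[0], rv_maf_range[1], size=n_rv),
    ])
    variant_ids = [f"cv{j + 1:05d}" for j in range(n_cv)] + [
        f"rv{j + 1:05d}" for j in range(n_rv)
    ]
    n_var = n_cv + n_rv
    members = peds.members
    dosage = np.zeros((len(members), n_var), dtype=float)

    alleles: dict[str, np.ndarray] = {}
    for row, m in enumerate(members):
        if m.is_founder:
            a = (rng.random((n_var, 2)) < pop_maf[:, None]).astype(np.int8)
        else:
            pa = alleles[m.father]
            ma = alleles[m.mother]
            pick_f = rng.integers(0, 2, size=n_var)
            pick_m = rng.integers(0, 2, size=n_var)
            a = np.stack(
                [pa[np.arange(n_var), pick_f], ma[np.arange(n_var), pick_m]],
                axis=1,
            )
        alleles[m.id] = a
        dosage[row] = a.sum(axis=1)

    # fold columns where the simulated allele ended up being the major one
    if n_var:
        flip = dosage.mean(axis=0) / 2.0 > 0.5
        dosage[:, flip] = 2.0 - dosage[:, flip]

    if missing_rate > 0 and n_var:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan

    return GenotypeMatrix.from_dosages(dosage, peds.sample_ids, variant_ids)


# ---------------------------------------------------------------------------
# pedigree-expected relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Symmetric n x n relatedness matrix with its sample ids.

    Holds either a pedigree-expected relationship (2x the kinship
    coefficient; diagonal 1 for non-inbred members) or an identity-by-state
    estimate from genotypes (entries in [0, 1]).
    """

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def reorder(self, sample_ids: list[str]) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in kinship matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in sample_ids])
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(sample_ids))


def _topological_order(fam: Family) -> list[Member]:
    """Members ordered parents-before-children; raises on cyclic parentage."""
    by_id = {m.id: m for m in fam.members}
    state: dict[str, int] = {}
    order: list[Member] = []

    def visit(mid: str) -> None:
        st = state.get(mid, 0)
        if st == 1:
            raise ValueError(f"cyclic parentage involving {mid} in {fam.id}")
        if st == 2:
            return
        state[mid] = 1
        m = by_id[mid]
        for p in (m.father, m.mother):
            if p is not None:
                visit(p)
        state[mid] = 2
        order.append(m)

    for m in fam.members:
        visit(m.id)
    return order


def expected_relationship(peds: PedigreeSet) -> KinshipMatrix:
    """Pedigree-expected relationship matrix (2x kinship coefficient),
    computed per family by the standard recursion and assembled block
    diagonally (members of different families are unrelated)."""
    peds.validate()
    ids = peds.sample_ids
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    R = np.zeros((n, n))
    for fam in peds.families:
        order = _topological_order(fam)
        k = len(order)
        phi = np.zeros((k, k))
        local = {m.id: i for i, m in enumerate(order)}
        for i, m in enumerate(order):
            if m.is_founder:
                phi[i, i] = 0.5
                # unrelated to everyone placed before (marry-ins are founders)
            else:
                fi, mi = local[m.father], local[m.mother]
                phi[i, i] = 0.5 * (1.0 + phi[fi, mi])
                for j in range(i):
                    phi[i, j] = phi[j, i] = 0.5 * (phi[fi, j] + phi[mi, j])
        gidx = np.array([pos[m.id] for m in order])
        R[np.ix_(gidx, gidx)] = 2.0 * phi
    return KinshipMatrix(R, ids)


# ---------------------------------------------------------------------------
# covariates and phenotype
# ---------------------------------------------------------------------------

def simulate_covariates(
    sample_ids: list[str],
    seed: int = 0,
    age_range: tuple[float, float] = (20.0, 80.0),
    smoking_rate: float = 0.25,
    medication_rate: float = 0.30,
) -> pd.DataFrame:
    """Age uniform over ``age_range``; gender Bernoulli(0.5); smoking and
    antihypertensive-medication flags Bernoulli at the given rates."""
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": rng.uniform(*age_range, size=n).round(1),
            "gender": rng.integers(0, 2, size=n),
            "smoking": (rng.random(n) < smoking_rate).astype(int),
            "medication": (rng.random(n) < medication_rate).astype(int),
        }
    )


def default_causal_spec(
    G: GenotypeMatrix,
    seed: int = 0,
    n_causal_cv: int = 8,
    n_causal_rv: int = 15,
    cv_effect_range: tuple[float, float] = (1.0, 2.5),
    rv_effect_range: tuple[float, float] = (3.0, 8.0),
    intercept: float = 120.0,
    covariate_effects: tuple[float, float, float, float] = (0.4, 4.0, 3.0, -4.0),
    sigma_g2: float = 40.0,
    sigma_r2: float = 60.0,
) -> CausalSpec:
    """Sparse causal architecture on an SBP-like scale (mmHg).

    A handful of common variants carry modest per-allele effects and a
    larger handful of rare variants carry larger per-allele effects (rare
    alleles must act more strongly to contribute comparable trait variance);
    signs are random. Covariate effects are (age, gender, smoking,
    medication) in mmHg.
    """
    rng = np.random.default_rng(seed)
    cv_pool = np.flatnonzero(G.is_common)
    rv_pool = np.flatnonzero(G.is_rare)
    if len(cv_pool) < n_causal_cv or len(rv_pool) < n_causal_rv:
        raise ValueError("not enough polymorphic variants for the causal spec")
    cv_idx = rng.choice(cv_pool, size=n_causal_cv, replace=False)
    rv_idx = rng.choice(rv_pool, size=n_causal_rv, replace=False)
    cv_eff = rng.uniform(*cv_effect_range, size=n_causal_cv)
    rv_eff = rng.uniform(*rv_effect_range, size=n_causal_rv)
    signs = rng.choice((-1.0, 1.0), size=n_causal_cv + n_causal_rv)
    return CausalSpec(
        causal_idx=np.concatenate([cv_idx, rv_idx]),
        effect_sizes=np.concatenate([cv_eff, rv_eff]) * signs,
        covariate_effects=np.array(covariate_effects),
        intercept=intercept,
        sigma_g2=sigma_g2,
        sigma_r2=sigma_r2,
    )


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Factor L with L L' = M for a PSD matrix; falls back to an
    eigendecomposition square root when Cholesky fails on a semidefinite M."""
    try:
        return np.linalg.cholesky(M + 1e-10 * np.eye(M.shape[0]))
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(M)
        w = np.clip(w, 0.0, None)
        return U * np.sqrt(w)


def simulate_phenotype(
    G: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: CausalSpec,
    relationship: KinshipMatrix,
    seed: int = 0,
) -> np.ndarray:
    """Draw the trait from Y = b0 + C gamma + G_causal beta + g + e with
    g ~ N(0, sigma_g2 * relationship) and e ~ N(0, sigma_r2 * I).

    Missing dosages at causal variants are mean-imputed before computing the
    fixed genetic contribution.
    """
    n = G.n_samples
    if len(covariates) != n or relationship.n_samples != n:
        raise ValueError("covariates/relationship do not match genotype samples")
    if np.any(spec.causal_idx >= G.n_variants) or np.any(spec.causal_idx < 0):
        raise ValueError("causal variant index out of range")

    rng = np.random.default_rng(seed)
    C = covariates.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    y = np.full(n, spec.intercept, dtype=float) + C @ spec.covariate_effects
    if spec.causal_idx.size:
        D = G.imputed()[:, spec.causal_idx]
        y += D @ spec.effect_sizes
    if spec.sigma_g2 > 0:
        L = _psd_factor(relationship.values)
        y += np.sqrt(spec.sigma_g2) * (L @ rng.standard_normal(n))
    y += np.sqrt(spec.sigma_r2) * rng.standard_normal(n)
    return y
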