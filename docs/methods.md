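# Methods

This note documents the models, algorithms, numerical conventions and
design choices behind `kinpen`, and what the synthetic-data generator does
and does not emulate.

## Trait model and decorrelation

The observed trait (an SBP-like quantitative phenotype, mmHg) is modelled
as

    Y = Xβ + ε,   ε ~ N(0, Σ),   Σ = σg²·K + σr²·I,

where `X` contains an intercept, four covariates (age in years, gender,
smoking status, antihypertensive-medication use, the latter included as a
covariate rather than an exclusion criterion so medicated individuals stay
in the sample), and minor-allele dosage columns; `K` is a relatedness
matrix. Two choices of `K` are supported:

* **IBS similarity** (`kinship.ibs_matrix`): entry (i, j) is the average
  over jointly observed variants of `(2 − |gᵢ − gⱼ|)/2`. Entries lie in
  [0, 1] with diagonal 1. Note that IBS has a nonzero baseline between
  unrelated individuals (allele sharing by state), so the fitted `σg²` on
  the IBS scale is not comparable to a generating variance defined on the
  pedigree-relationship scale; the whitening transform is invariant to this
  affine ambiguity up to its absorption into the component split.
* **Pedigree-expected relationship** (`simulate.expected_relationship`):
  2× the kinship coefficient from the standard recursion, block-diagonal
  across families. This is the generating covariance of the simulator and
  the ground truth for variance-component recovery tests.

**Variance components.** `fit_variance_components` maximizes the ML or
REML likelihood of `Y ~ N(X_cov b, σg²K + σr²I)` with the intercept and all
four covariates as fixed effects (the default; whether a published analysis
would include them is generally ambiguous, so the design matrix is an
argument). `K` is eigendecomposed once; writing `Σ = σg²(K + δI)` with
`δ = σr²/σg²`, the fixed effects and overall scale are profiled out, leaving
a 1-D problem in `δ` solved on a log-spaced grid (80 points over
[1e−5, 1e5]) refined by bounded scalar minimization; the `σg² = 0` boundary
(iid errors) is evaluated explicitly and wins ties. REML is the default
(ML by flag). When the `δ` profile is flat — `K = I` makes the split
unidentifiable — the fit warns and returns `σg² = 0`; the whitening
transform is invariant to the split in that case. `K` must be PSD within
tolerance (−1e−8 × largest eigenvalue); anything worse is an error, not a
silent repair.

**Whitening.** `Σ^(-1/2)` is the *symmetric* inverse square root via
eigendecomposition (not a Cholesky factor), so the transform is symmetric
and uniquely defined. Eigenvalues at or below 1e−8 × max eigenvalue raise
an error naming the offending eigenvalue. The intercept column is
transformed like any other column; after whitening there is no constant
column in the design. On correctly specified data the whitened residual
variance is ≈ 1, and OLS on `(Y*, X*)` equals the closed-form GLS
estimator — both properties are asserted by tests.

## Screening

`screen.kruskal_wallis` computes the Kruskal–Wallis H of the trait grouped
by dosage level (up to three groups), on mid-ranks with the standard tie
correction, `df = groups − 1`, p-values from the chi-square approximation.
A trait constant across observations yields `H = 0` by convention.
Monomorphic columns (including columns reduced to one dosage group by
missingness) are excluded and counted. Screening is performed on the raw
(pre-whitening) phenotype of the full sample by default — matching the
study design this package reimplements, where screening precedes the
train/tune/test split; `build_study_data(screen_on_decorrelated=True)`
gives the alternative. Within each MAF class (CV ≥ 5% > RV > 0) variants
are ranked by ascending p, ties broken by descending H then ascending
variant id, so orderings are deterministic across platforms. No
multiple-testing correction is applied: screening is ranking, not
inference.

## Penalized estimators

All families minimize `½‖Y* − X*β‖²/n + λP(β)` with the penalty applied to
internally standardized coefficients. Standardization scales each column
by its root mean square *without centering*: mean-centering is only a valid
reparameterisation in the presence of a constant column, which whitening
removes. Coefficients are reported on the original scale. The intercept
and covariate columns are unpenalized by default (a mask argument allows
penalizing everything).

Penalties and coordinate updates (unit-curvature `z` = partial-residual
correlation):

| family | penalty | update |
|---|---|---|
| ridge | `Σβ²` | `z/(1 + 2λ)` |
| lasso | `Σ|β|` | `S(z, λ)` |
| elastic net | `(1−α)Σβ² + αΣ|β|` | `S(z, λα)/(1 + 2λ(1−α))` |
| SCAD | nonconvex, `a = 3.7` | exact 3-regime univariate minimizer |
| TLP | `Σ min(|β|/τ, 1)` | DC iteration over weighted lassos |

The elastic-net penalty is implemented exactly in the form above — the
quadratic term carries no ½ factor, unlike the common software convention —
which rescales the λ axis but not the geometry of the solution path; λ is
tuned, so this is a pure labelling choice. `enet(α=1) ≡ lasso` and
`enet(α=0) ≡ ridge` hold exactly, and every family at `λ = 0` reduces to
OLS (minimum-norm via SVD on rank-deficient designs, flagged).

SCAD uses the exact closed-form univariate minimizer (soft-thresholding for
`|z| ≤ 2λ`; `((a−1)z − sign(z)aλ)/(a−2)` for `2λ < |z| ≤ aλ`; identity
beyond `aλ`) rather than a local linear approximation, which keeps the
per-coordinate step a genuine argmin and simplifies convergence checking.

TLP is solved by difference-of-convex iteration: linearizing the concave
part at the current iterate leaves a weighted lasso with per-coordinate L1
weight `(λ/τ)·1{|βₖ| ≤ τ}`; the objective is non-increasing across DC steps
by the majorize–minimize construction (asserted at run time). Because DC
finds only a local solution, each fit tries two starts — all-zero and a
least-squares (or caller-supplied warm) start — and returns the
lower-objective fixed point; at small τ this reproduces the exact choice
between the null and unpenalized solutions on simple instances.

**Paths and convergence.** Coordinate descent is cyclic with warm starts
down a descending λ grid anchored at `λ_max` (the smallest λ whose all-zero
penalized solution satisfies the KKT conditions after fitting the
unpenalized columns: `max |x̃ⱼ'r|/(nα)`). Sweeps alternate a full pass with
repeated active-set passes (nonzero or unpenalized coordinates), the usual
glmnet-style structure; convergence requires a full pass whose largest
coordinate change is below tolerance. The solver default tolerance is 1e−7
with a 10,000-sweep cap; the tuning search (`GridConfig`) uses a 1e−5 path
tolerance, which changes scenario-study medians by < 1e−3 while cutting
runtime several-fold. Default path: 100 λ values from `λ_max` down to
0.001·`λ_max` (0.01·`λ_max` when the panel is wider than the training set,
where the small-λ tail merely interpolates the data). Ridge has no finite
`λ_max`; its grid spans `[10, 1e−4]`·(lasso anchor) over 50 points, and
ridge paths in the tuning search are solved exactly — unpenalized columns
projected out by QR, the penalized block eigendecomposed once, every λ a
diagonal rescale — which is identical to the coordinate-descent solution
(tested) at a fraction of the cost. TLP uses a deliberately coarse grid
(default 3 τ values × 8 λ values per τ) because each pair costs a full DC
solve; as in the original study design, TLP results on coarse grids likely
understate the method.

## Study design

`split_three_way` partitions samples uniformly at random into near-equal
thirds (remainder to train, then tune; n = 759 gives 253/253/253). For each
replicate, family and scenario: the model sequence is fitted on the
training third; the hyperparameters minimizing tuning-third PMSE are
selected (ties prefer the stronger penalty — parsimony); and the *training*
coefficients are applied unchanged to the testing third (no refit on
train+tune). Scenario cells combine the top-`n_cv` CVs and top-`n_rv` RVs
from the screen; the combined columns `CV=k,RV>0` report, per replicate,
the minimum test PMSE over the added RV counts (and symmetrically for
`RV=k,CV>0`). Medians across replicates form the methods × scenarios pivot.
Whitening and screening are estimated once on the full sample, matching the
single decorrelation of the reimplemented design (per-replicate screening
on the training third is available via the `screen_on_decorrelated` /
re-screening options); panels are fixed across replicates. Failed cells are
recorded with their reason and never abort a run — unregularized OLS on
p ≫ n panels is expected to behave badly, and that is part of the result.
Replicate seeds derive from the master seed by a counter through numpy's
`SeedSequence`, so studies are bit-reproducible for a fixed master seed.

## Synthetic data: what it emulates, what it does not

The generator mirrors the structure of a 20-pedigree family sequencing
study: families of 21–76 members grown over (default) three generations
from a founder couple, with married-in founders opening new reproducing
couples; genotypes gene-dropped variant by variant (founders draw two
Bernoulli(MAF) alleles, children inherit one uniformly chosen allele per
parent), so Mendelian consistency and family-driven linkage disequilibrium
arise mechanistically. Dosage columns are re-oriented to the realized minor
allele, and class flags (CV/RV at 5%) follow realized, not population,
frequencies; monomorphic columns are kept but flagged and excluded from
screening, mirroring real-data QC. Covariates are simulated as age ~
U(20, 80), gender ~ Bernoulli(0.5), smoking/medication ~ Bernoulli(0.25/0.30)
— none of these distributions is pinned down by the emulated study, so they
are configuration. The default causal architecture (8 causal CVs with
±1–2.5 mmHg per-allele effects, 15 causal RVs with ±3–8 mmHg, intercept
120, covariate effects 0.4/4/3/−4 mmHg, `σg² = 40`, `σr² = 60`) encodes the
standard expectation that rare alleles must act more strongly to contribute
comparable trait variance; effect-size distributions for SBP are not
inference from any dataset.

Not emulated: population-level LD beyond family co-inheritance,
ascertainment (e.g. disease enrichment), genotyping error or
imputation-quality structure, and pharmacological response heterogeneity
(medication is a fixed covariate both in generation and analysis). Passing
tests therefore certify the pipeline's statistical machinery under its own
assumptions, not performance on real sequencing data.

Missing dosages are mean-imputed per variant before IBS computation and
regression (the QC threshold — exclude samples missing > 10% of genotypes —
runs first); imputation here is plumbing, not a method under study.

## Scale of the shipped studies

The default `RunConfig` mirrors the emulated study's shape (20 pedigrees of
21–76, top-1000 panels per class, 12 scenario columns, 100 replicates). The
shipped acceptance checks run scaled versions chosen to keep a complete
desk run in minutes: 1200 CV + 1200 RV simulated variants, 20 replicate
splits for the qualitative-direction checks (10 in the acceptance script),
base panels {10, 100} with added counts {1, 10, 100} plus the wide
{1000}-panel cells, variance-component recovery at n ≈ 600 over 30–50
replicates. Taking the per-replicate minimum over a subset of added-RV
counts is conservative for the "adding RVs helps" direction.

## Known limitations

* Single random effect; no Balding–Nichols or centered-GRM kinship
  variants, no sparse-matrix scale (the eigendecomposition is dense n × n).
* Gaussian loss only; no logistic/survival analogues, no group or fused
  penalties.
* IBS requires hard-call dosages {0, 1, 2, missing}.
* The nonconvex fits (SCAD, TLP) certify stationarity/descent, not global
  optimality; tests verify them against univariate oracles and
  perturbation checks on small instances.
* VCF support is biallelic-SNP-only; multi-allelic records are skipped
  with a logged count.
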