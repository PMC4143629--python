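# Methods

## Model and likelihood

The package models quantitative trait values over a pedigree sample as
multivariate Gaussian. For a single trait on `n` individuals the mean is
`ν = Aβ` and the covariance is a nonnegative combination of structured
kernels,

    Σ = σa²·(2Φ) + σd²·Δ7 + σh²·H + σe²·I,

with `Φ` the kinship matrix, `Δ7` the condensed identity (both-pairs-IBD)
matrix, `H` the household indicator and `I` the identity. The additive
kernel is stored as `2Φ`, whose diagonal is 1 for non-inbred individuals,
so the scalar coefficients read directly as trait-variance shares and
`h² = σa²/(σa² + σe²)`. The loglikelihood is

    L = −½ ln det Σ − ½ (y − ν)ᵀ Σ⁻¹ (y − ν)

with no `2π` constant; every internal comparison uses the same
convention.

With `T` traits the stacked vector is **trait-major** (all individuals
for trait 1, then trait 2, …) and each component becomes `Γ_c ⊗ K_c`.
`Γ_c` is either an unstructured `T×T` PSD matrix (default for `T > 1`) or
a scalar times a fixed trait-structure matrix; the all-ones structure
`1·1ᵀ` expresses person-level effects constant across visits (the
random-intercept and permanent-environment models). The Kronecker order
(traits outer, individuals inner) is fixed and asserted in tests because
it is a classic silent bug. Missing trait entries are removed by row
deletion of `(y, A, Σ)`, which equals marginalizing the unobserved
entries of a Gaussian; a `(T, n)` boolean mask records the layout.

Unrelated individuals are singleton families contributing `½·I` blocks to
`Φ`, so one code path serves random samples, pedigrees, or mixtures.

## Relationship matrices

Kinship uses the standard recursion over a topological ordering (parents
before children): founders are mutually unrelated with `φ_ii = ½`;
`φ_ii = ½(1 + φ_fm)`; `φ_ij = ½(φ_fj + φ_mj)` for `j` processed earlier.
Dense `O(n²)` computation; the intended scale is a few thousand
individuals. `Δ7` uses the non-inbred closed form
`Δ7_ij = φ_ac φ_bd + φ_ad φ_bc` from the parental kinships, zero when
either member of the pair is a founder, diagonal fixed at 1. If an inbred
individual is detected (parents with `φ > 0`) the same formula is applied
after a warning — exact condensed identity coefficients for inbred
pedigrees are out of scope. Half-known parentage is rejected rather than
patched with dummy founders, because silent dummy creation changes `Φ`.
Both recursions are validated against a gene-dropping Monte-Carlo oracle
(IBD-label frequencies over 10⁵ drops).

## Null fit

`fit_null_ml` maximizes `L` by Fisher scoring on the variance parameters.
`Σ` is linear in every variance parameter (scalars and the entries of
unstructured `Γ_c` alike), so the score and expected information have
closed forms. β is profiled out by GLS at the current `Σ` each iteration.
Numerical choices:

- starting values: OLS β; OLS residual variance split evenly among
  components;
- step-halving until the loglikelihood is non-decreasing; convergence at
  relative change `< 1e−8` (default), `max_iter = 200`;
- scalars projected to `≥ 0` (the environment scalar to a small positive
  floor, `1e−10` of the trait variance, so `Σ` stays invertible);
  unstructured `Γ_c` eigenvalue-clipped;
- an active-set reduction: a parameter pinned at its bound whose score
  points outward is dropped from the scoring system for that iteration.
  Without this, the projected joint step can stall on the boundary and
  leave the free parameters at a non-optimum (caught against a
  Nelder-Mead oracle);
- boundary estimates are legal and flagged; rank-deficient covariate
  designs raise with a collinearity diagnostic.

ML (not REML) is used throughout, which gives the familiar small-sample
downward bias in variance ratios; the recovery tests bound the bias
rather than pretend it is absent.

## Score test and scan

With the null fit in hand, `P = Σ̂⁻¹ − Σ̂⁻¹A(AᵀΣ̂⁻¹A)⁻¹AᵀΣ̂⁻¹` and `Py`
are cached. A SNP with dosage vector `g` enters as `G = I_T ⊗ g`
(per-trait effects, df = T) or `1_T ⊗ g` (shared effect, df = 1),
restricted to observed entries, and

    U = GᵀPy,  V = GᵀPG,  S = UᵀV⁻¹U ~ χ²_df.

Holding the variance parameters at their null estimates is the classic
efficient-score construction; in Gaussian models the expected information
between mean and covariance parameters is block diagonal, so no nuisance
correction is needed. `V⁻¹U` is reported as a one-step effect estimate.
Missing dosages are mean-imputed per SNP (count reported); monomorphic or
covariate-collinear SNPs are skipped with a reason code, never aborting a
scan. For unrelated samples with an intercept-only mean the statistic
reduces exactly to `n·r²`, which is asserted numerically.

The scan processes SNPs with matrix-matrix products on the per-trait
blocks of `P`. Internally SNPs are always grouped into fixed 64-wide
zero-padded chunks, so the BLAS calls see identical shapes whatever
`batch_size` the caller requests — results are bit-identical across batch
sizes. The top `k` SNPs by score p-value (default 50, ties broken by
(p, chrom, bp)) are refit by full ML with the SNP in the mean,
warm-started at the null optimum so the LRT statistic is nonnegative.
QQ data uses expected quantiles `−log10((i − ½)/m)`; the conventional
genome-wide line `5×10⁻⁸` is written into the plot metadata.

## Longitudinal adjustment and residual methods

A trait observed at `T` visits with visit-level covariates is adjusted by
a pedigree random-intercept LMM: stacking visits, the intercepts
contribute `σg²·(1·1ᵀ ⊗ 2Φ)` and the errors `σe²·I`, fitted by the same
ML engine. The per-person intercept prediction is the conditional mean
(BLUP), `μ̂_i = μ̂ + σ̂g²·(2Φ)_i,obs Σ̂⁻¹(y − Aβ̂)`. Two adjusted traits
follow:

- method 1 (decorrelated): `r_{i,t} = y_{i,t} − (μ̂_i + x_{i,t}ᵀβ̂)`; the
  polygenic effect is removed, and downstream scans drop the genetic
  components (treating residuals as independent, which ignores any
  remaining correlation between the longitudinal traits);
- method 2 (correlated): `r_{i,t} = y_{i,t} − (μ̂ + x_{i,t}ᵀβ̂)`; the
  polygenic effects remain and the scan keeps the genetic components.

`R²` is reported as `1 − SSE/SST` with fitted values from the fixed
effects plus predicted intercepts. Variable visit counts are plain row
deletion.

A structural property worth stating: when the adjustment model matches
the trait's true covariance, the method-1 residuals have covariance
`σ̂e⁴·Σ̂⁻¹` — *negatively* correlated within person and across relatives,
because the ML intercept variance aggressively absorbs person-level
covariance (it overshoots under misspecification too; verified against
an independent optimizer). An independence-model scan of such residuals
is therefore calibrated-to-conservative in this simulation framework.
Reports of method-1 type-I inflation on real consortium data plausibly
reflect generative structure (serial correlation, non-normality,
time-varying genetic effects) richer than anything this model class
produces; the size study below states exactly what it does and does not
reproduce.

## Simulator and the size/power study

Gene dropping assigns each founder haplotype a unique label (and the
effect allele with probability MAF), then transmits one of each parent's
two labels per meiosis, independently per replicate. Dosage moments
(founder mean `2·maf`, sib covariance `2φ·2pq`) and IBD frequencies are
checked against theory; the same machinery is the Monte-Carlo oracle for
`Φ` and `Δ7`.

Traits follow `y_{i,t} = x_{i,t}ᵀβ + Σ_s g_{i,s}γ_s + a_i + d_i + h_i +
c_i + e_{i,t}` with `a ~ N(0, 2σa²Φ)`, `d ~ N(0, σd²Δ7)`, household
`h ~ N(0, σh²H)`, permanent environment `c ~ N(0, σc²I)` (all
person-level, shared across visits) and visit noise `e ~ N(0, σe²I)`.
Optionally a variant's effect acts partly on the within-person age trend
(`γ_age` per allele per year of age deviation), emulating longitudinal
variant effects. Covariates are Age (first visit `N(45, 12²)` years,
visits 2 years apart) and Sex. Defaults: ten replicate three-generation
16-person families (a founder couple, three married children, sibships
3/3/2), three visits, seed mandatory; one RNG stream per replicate
derived from `(seed, replicate)`.

The canonical study conditions (`size_study_config`,
`power_study_config`): σa² = 2, σd² = 1.5, σe² = 1, 200 replicates. The
dominance variance is deliberately not representable by the additive-only
adjustment LMM, mirroring the gap between a real trait's familial
covariance and the simple model used to adjust it. The size study uses
four null variants (MAF 0.05–0.4; rarer variants are mostly monomorphic
at n = 160). The power study plants level effects of 0.15 and age-trend
effects of 0.12 per allele at two common variants. Per replicate the full
pipeline runs: simulate → LMM adjust → residuals → null fit → score test.
Method-2 scans keep additive (and dominance, when present) components
with the person-level `1·1ᵀ` trait structure plus a permanent-environment
component so the retained longitudinal covariance is modeled; method-1
scans use the independence model, as its description implies.

What passing these tests shows: the whole chain is internally consistent,
calibrated under its own null, and reproduces the qualitative power
ordering for longitudinally acting effects. What it does not show:
behavior under generative processes outside this model class (LD between
markers, non-Gaussian traits, ascertainment), and — per the structural
note above — the method-1 size inflation reported in real family-study
analyses is not reproduced by an exactly-specified-BLUP simulation.

## Degenerate inputs and edge cases

Non-PD covariance proposals raise with the offending parameters;
all-missing or monomorphic SNPs are skipped with reasons; QC removing
every SNP is a hard error; empty pedigree/genotype/phenotype
intersections are hard errors; cycles and half-specified parents are
rejected at parse time with the individual named. Positions are 1-based
(PLINK/VCF convention); the effect allele is A1 in .bim, ALT in VCF.
Call-rate QC is SNP-first, then individuals on the surviving SNPs, both
at 0.98 by default.

## Problem sizes

Dense linear algebra throughout; fits materialize `m × m` matrices for
`m` observed entries (≤ a few thousand), and the default study scale is
10 × 16 individuals × 3 visits with 200 replicates. These sizes were
chosen so every statistical check runs comfortably on a laptop-class
machine; all of them scale up by configuration, not code changes.

## Known limitations

ML (not REML) variance components; exact condensed identity coefficients
for inbred pedigrees are not computed (warned, approximated); no sparse
or low-rank covariance machinery for biobank-scale samples; no
rare-variant set tests or GxE; multi-allelic VCF records are skipped;
population-structure PCs are accepted as covariates but not computed.
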