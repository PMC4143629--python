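"""Simulation of pedigrees, genotypes and longitudinal traits.

The generator inverts the model the association machinery assumes:
genotypes arise by gene dropping (founder alleles i.i.d. Bernoulli(MAF)
per haplotype, independent Mendelian transmissions down the pedigree) and
traits follow

    y_{i,t} = x_{i,t}ᵀ β + Σ_s g_{i,s} γ_s + a_i + d_i + h_i + c_i + e_{i,t},

with a ~ N(0, 2σa²Φ), d ~ N(0, σd²Δ7), optional household h ~ N(0, σh²H)
and permanent-environment c ~ N(0, σc²I) terms, and visit noise
e ~ N(0, σe²I); all person-level values are shared across visits, so
longitudinal visits are equicorrelated within person beyond the
covariates.  Gene dropping doubles as the Monte-Carlo oracle for the
kinship and Δ7 recursions (IBD-sharing frequencies).

The size/power study mirrors a residual-adjustment association design:
per replicate, simulate genotypes and a trait, adjust the trait for
covariates by the random-intercept LMM, then scan the candidate variants
with the score (and optionally LRT) test using either decorrelated
(method 1, environment-only scan) or correlated residuals (method 2,
additive + environment scan), and report the rejection fraction at the
stated α per variant.  Variants simulated with zero effect yield empirical
type I error; the rest yield power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pedscore._errors import ConfigurationError, NumericalError
from pedscore.adjust import fit_adjustment_lmm, residuals
from pedscore.genio import GenotypeSource, PhenotypeTable
from pedscore.pedstruct import (
    Individual,
    Pedigree,
    delta7_matrix,
    household_matrix,
    kinship_matrix,
)
from pedscore.vcfit import Component, StackedData, VarComponentSpec, fit_null_ml
from pedscore.assoc import score_test_snp, lrt_snp

__all__ = [
    "SimConfig",
    "three_generation_pedigree",
    "random_pedigree",
    "replicate_pedigrees",
    "gene_drop",
    "gene_drop_alleles",
    "simulate_covariates",
    "simulate_traits",
    "size_power_study",
    "size_study_config",
    "power_study_config",
]


def three_generation_pedigree(family_id: str = "fam1",
                              sibship_sizes=(3, 3, 2)) -> Pedigree:
    """One founder couple, one married child per sibship, fixed sibships.

    The default (3, 3, 2) yields 16 individuals: 2 grandparents, 3 adult
    children each married to an unrelated spouse, and 8 grandchildren.
    """
    recs = []
    fam = str(family_id)
    recs.append((fam, f"{fam}_gf", "", "", "male", fam))
    recs.append((fam, f"{fam}_gm", "", "", "female", fam))
    for c, size in enumerate(sibship_sizes, start=1):
        child = f"{fam}_c{c}"
        spouse = f"{fam}_s{c}"
        sex = "male" if c % 2 else "female"
        recs.append((fam, child, f"{fam}_gf", f"{fam}_gm", sex, f"{fam}h{c}"))
        recs.append((fam, spouse, "", "",
                     "female" if sex == "male" else "male", f"{fam}h{c}"))
        fa, mo = (child, spouse) if sex == "male" else (spouse, child)
        for k in range(1, size + 1):
            recs.append((fam, f"{fam}_c{c}k{k}", fa, mo,
                         "male" if k % 2 else "female", f"{fam}h{c}"))
    return Pedigree.from_records(recs)


def random_pedigree(rng: np.random.Generator, family_id: str = "fam1",
                    max_sibship: int = 4) -> Pedigree:
    """Random 3-generation pedigree (for property tests and oracles)."""
    n_children = int(rng.integers(2, 5))
    sibs = tuple(int(rng.integers(1, max_sibship + 1)) for _ in range(n_children))
    return three_generation_pedigree(family_id, sibs)


def replicate_pedigrees(n_pedigrees: int, sibship_sizes=(3, 3, 2)) -> Pedigree:
    """n independent copies of the template family, one Pedigree object."""
    inds: list[Individual] = []
    for k in range(1, n_pedigrees + 1):
        inds.extend(three_generation_pedigree(f"fam{k}", sibship_sizes).individuals)
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# gene dropping

def _drop_alleles(ped: Pedigree, rng: np.random.Generator, size: int) -> np.ndarray:
    """Founder-allele labels propagated down the pedigree.

    Returns (n, 2, size) integer labels; each founder haplotype gets a
    unique label, transmissions are independent fair coin flips per
    meiosis and per replicate.
    """
    n = ped.n
    parents = ped.parent_indices()
    labels = np.zeros((n, 2, size), dtype=np.int64)
    next_label = 0
    for i in ped.order:
        f, m = parents[i]
        if f < 0:
            labels[i, 0] = next_label
            labels[i, 1] = next_label + 1
            next_label += 2
        else:
            pick_f = rng.integers(0, 2, size=size)
            pick_m = rng.integers(0, 2, size=size)
            labels[i, 0] = labels[f, pick_f, np.arange(size)]
            labels[i, 1] = labels[m, pick_m, np.arange(size)]
    return labels


def gene_drop_alleles(ped: Pedigree, rng: np.random.Generator,
                      size: int = 1) -> np.ndarray:
    """IBD labels (n, 2, size) for use as a Monte-Carlo kinship/Δ7 oracle."""
    return _drop_alleles(ped, rng, size)


def gene_drop(ped: Pedigree, maf: float, rng: np.random.Generator,
              size: int = 1) -> np.ndarray:
    """Gene-drop dosages at an autosomal biallelic locus.

    Founder haplotypes carry the effect allele i.i.d. with probability
    ``maf``; Mendelian transmission uses an independent pick per meiosis.
    Returns an integer dosage array of shape (n,) for size=1, else (n, size).
    """
    if not 0.0 <= maf <= 0.5:
        raise ConfigurationError("minor allele frequency must lie in [0, 0.5]")
    labels = _drop_alleles(ped, rng, size)
    n_founder_alleles = 2 * len(ped.founders)
    # founder haplotypes are labeled 0..2F-1 in topological founder order
    carrier = (rng.random(size=(n_founder_alleles, size)) < maf).astype(np.int64)
    d = carrier[labels[:, 0], np.arange(size)] + carrier[labels[:, 1], np.arange(size)]
    return d[:, 0] if size == 1 else d


# ---------------------------------------------------------------------------
# trait simulation

@dataclass
class SimConfig:
    """Study conditions for trait simulation and the size/power design.

    Defaults: 10 replicate three-generation families of 16 individuals,
    three visits per person, additive heritability σa²/(σa²+σe²) = 0.5 on
    the residual scale, six candidate variants spanning rare to common
    MAFs, 200 replicates.  A seed is mandatory.
    """

    seed: int
    n_pedigrees: int = 10
    sibship_sizes: tuple = (3, 3, 2)
    n_visits: int = 3
    mafs: tuple = (0.005, 0.01, 0.05, 0.1, 0.2, 0.4)
    snp_effects: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    # per-variant effect on the within-person age trend (units of trait per
    # allele per year); longitudinal traits often express variant effects
    # partly through age, which a person-level intercept cannot absorb
    snp_age_effects: tuple | None = None
    beta_age: float = 0.1
    beta_sex: float = -2.0
    mu: float = 50.0
    sigma_a2: float = 1.0
    sigma_d2: float = 0.0
    sigma_h2: float = 0.0
    # permanent-environment variance: person-level, non-genetic, shared
    # across visits; makes trait repeatability exceed heritability as in
    # real longitudinal traits
    sigma_c2: float = 0.0
    sigma_e2: float = 1.0
    n_replicates: int = 200
    alpha: float = 0.05

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory for reproducibility")
        if len(self.snp_effects) != len(self.mafs):
            raise ConfigurationError("snp_effects must match mafs in length")
        if self.snp_age_effects is None:
            self.snp_age_effects = tuple(0.0 for _ in self.mafs)
        if len(self.snp_age_effects) != len(self.mafs):
            raise ConfigurationError("snp_age_effects must match mafs in length")
        for m in self.mafs:
            if not 0.0 < m <= 0.5:
                raise ConfigurationError("MAFs must lie in (0, 0.5]")
        if min(self.sigma_a2, self.sigma_d2, self.sigma_h2, self.sigma_c2,
               self.sigma_e2) < 0:
            raise ConfigurationError("variance components must be nonnegative")

    def rng_for(self, replicate: int) -> np.random.Generator:
        # one independent, reproducible stream per replicate
        return np.random.default_rng([self.seed, replicate])

    def pedigree(self) -> Pedigree:
        return replicate_pedigrees(self.n_pedigrees, self.sibship_sizes)


def simulate_covariates(ped: Pedigree, n_visits: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Per-(person, visit) Age and per-person Sex.

    Age at first visit ~ N(45, 12²) years, subsequent visits 2 years
    apart; Sex is 0/1 taken from the pedigree record (unknowns randomized).
    """
    rows = []
    age0 = rng.normal(45.0, 12.0, size=ped.n)
    for i, ind in enumerate(ped.individuals):
        sex = {"male": 0.0, "female": 1.0}.get(ind.sex, float(rng.integers(0, 2)))
        for t in range(1, n_visits + 1):
            rows.append((ind.person, t, age0[i] + 2.0 * (t - 1), sex))
    return pd.DataFrame(rows, columns=["person", "visit", "Age", "Sex"])


def simulate_traits(ped: Pedigree, cfg: SimConfig, causal=None,
                    rng: np.random.Generator | None = None,
                    trait: str = "Y") -> PhenotypeTable:
    """Simulate a longitudinal trait over the pedigree.

    ``causal`` is an optional (dosages, effects) or (dosages, effects,
    age_effects) tuple: dosages (n, s), per-variant level effects (s,) and
    optional per-variant effects on the within-person age trend (trait per
    allele per year of age deviation from the person's mean visit age).
    The implied covariance must be PSD, which holds whenever the variance
    components are nonnegative.
    """
    rng = cfg.rng_for(0) if rng is None else rng
    n, T = ped.n, cfg.n_visits
    cov = simulate_covariates(ped, T, rng)

    mean = np.zeros((n, T))
    mean += cfg.mu
    age = cov.pivot(index="person", columns="visit", values="Age") \
             .loc[[i.person for i in ped.individuals]].to_numpy()
    sex = cov.pivot(index="person", columns="visit", values="Sex") \
             .loc[[i.person for i in ped.individuals]].to_numpy()
    mean += cfg.beta_age * age + cfg.beta_sex * sex
    if causal is not None:
        dos, eff, *rest = causal
        dos = np.atleast_2d(np.asarray(dos, dtype=float))
        if dos.shape[0] != n:
            dos = dos.T
        mean += (dos @ np.asarray(eff, dtype=float))[:, None]
        if rest and np.any(np.asarray(rest[0]) != 0):
            age_dev = age - age.mean(axis=1, keepdims=True)
            mean += (dos @ np.asarray(rest[0], dtype=float))[:, None] * age_dev

    a = np.zeros(n)
    if cfg.sigma_a2 > 0:
        K = 2.0 * kinship_matrix(ped).values
        La = np.linalg.cholesky(K + 1e-12 * np.eye(n))
        a = np.sqrt(cfg.sigma_a2) * (La @ rng.standard_normal(n))
    d = np.zeros(n)
    if cfg.sigma_d2 > 0:
        D7 = delta7_matrix(ped).values
        w, V = np.linalg.eigh(D7)
        Ld = V * np.sqrt(np.maximum(w, 0.0))
        d = np.sqrt(cfg.sigma_d2) * (Ld @ rng.standard_normal(n))
    h = np.zeros(n)
    if cfg.sigma_h2 > 0:
        # one shared environmental deviate per household, constant over visits
        labels = [ind.household for ind in ped.individuals]
        if any(l is None for l in labels):
            raise ConfigurationError(
                "household variance requested but pedigree lacks household labels")
        uniq = list(dict.fromkeys(labels))
        per_house = np.sqrt(cfg.sigma_h2) * rng.standard_normal(len(uniq))
        hpos = {lab: k for k, lab in enumerate(uniq)}
        h = per_house[[hpos[l] for l in labels]]
    c = np.zeros(n)
    if cfg.sigma_c2 > 0:
        c = np.sqrt(cfg.sigma_c2) * rng.standard_normal(n)
    e = np.sqrt(cfg.sigma_e2) * rng.standard_normal((n, T))

    Y = mean + (a + d + h + c)[:, None] + e
    tab = cov.copy()
    person_pos = {ind.person: i for i, ind in enumerate(ped.individuals)}
    tab[trait] = [Y[person_pos[p], int(t) - 1] for p, t in zip(tab["person"], tab["visit"])]
    return PhenotypeTable(tab)


# ---------------------------------------------------------------------------
# size / power study

def size_study_config(seed: int, n_replicates: int = 200) -> SimConfig:
    """Canonical type-I-error study conditions.

    Traits carry additive (σa² = 2), dominance (σd² = 1.5) and visit-level
    environmental (σe² = 1) variance; the candidate variants have no
    effect.  The dominance variance is deliberately not representable by
    the random-intercept adjustment model, mirroring the gap between a
    real trait's familial covariance and the simple LMM used to adjust it.
    Rare MAFs are dropped here because they are frequently monomorphic in
    160 individuals and contribute mostly missing tests.
    """
    return SimConfig(seed=seed, n_replicates=n_replicates,
                     sigma_a2=2.0, sigma_d2=1.5, sigma_e2=1.0,
                     mafs=(0.05, 0.1, 0.2, 0.4),
                     snp_effects=(0.0, 0.0, 0.0, 0.0))


def power_study_config(seed: int, n_replicates: int = 200) -> SimConfig:
    """Canonical power study conditions: two common causal variants.

    Each causal variant shifts the trait level by 0.15 per allele and the
    within-person age trend by 0.12 per allele per year — longitudinal
    variant effects expressed partly through age, as is typical in
    blood-pressure genetics.  Variance components as in the size study.
    """
    return SimConfig(seed=seed, n_replicates=n_replicates,
                     sigma_a2=2.0, sigma_d2=1.5, sigma_e2=1.0,
                     mafs=(0.2, 0.4),
                     snp_effects=(0.15, 0.15),
                     snp_age_effects=(0.12, 0.12))

def _scan_variants(dosages: np.ndarray, resid_values: np.ndarray,
                   genetic_kernels: dict, tests):
    """Fit the post-adjustment null and test each candidate variant.

    ``resid_values`` is persons × visits.  Method 1 (empty
    ``genetic_kernels``) scans the decorrelated residuals with an
    independence model, ignoring the correlation between the longitudinal
    traits.  Method 2 keeps the genetic components (person-level
    compound-symmetric trait structure 1·1ᵀ) and additionally models the
    non-genetic person-level correlation between visits with a
    permanent-environment component, so the retained longitudinal
    covariance is represented.
    """
    n, T = resid_values.shape
    data = StackedData.from_traits(resid_values)
    comps = [Component(label, K, trait_structure=np.ones((T, T)))
             for label, K in genetic_kernels.items()]
    if genetic_kernels and T > 1:
        comps.append(Component("permanent_env", np.eye(n),
                               trait_structure=np.ones((T, T))))
    comps.append(Component("environment", np.eye(n)))
    spec = VarComponentSpec(comps, n_traits=T)
    fit = fit_null_ml(spec, data)
    out = {}
    for s in range(dosages.shape[1]):
        res = score_test_snp(dosages[:, s], fit)
        out[("score", s)] = res.pvalue
        if "lrt" in tests:
            _, p_lrt, ok = lrt_snp(dosages[:, s], fit)
            out[("lrt", s)] = p_lrt if ok else np.nan
    return out


def size_power_study(cfg: SimConfig, methods=("method1", "method2"),
                     tests=("score",), alpha: float | None = None,
                     progress=None) -> pd.DataFrame:
    """Empirical power / type-I error per variant, method and test.

    Runs the full adjust → scan pipeline per replicate.  Returns a tidy
    StudyTable with columns snp_id, maf, effect, truth, method, test,
    rejection_rate, n_replicates, n_valid.  Variants with zero simulated
    effect report empirical size; the rest report power.
    """
    alpha = cfg.alpha if alpha is None else alpha
    if cfg.n_replicates < 100:
        import warnings
        warnings.warn("fewer than 100 replicates gives unstable power estimates",
                      stacklevel=2)
    ped = cfg.pedigree()
    phi = kinship_matrix(ped)
    K = 2.0 * phi.values
    # method-2 scans keep every covariance component the traits carry
    kernels = {"additive": K}
    if cfg.sigma_d2 > 0:
        kernels["dominance"] = delta7_matrix(ped).values
    if cfg.sigma_h2 > 0:
        kernels["household"] = household_matrix(ped).values
    effects = np.asarray(cfg.snp_effects, dtype=float)
    age_effects = np.asarray(cfg.snp_age_effects, dtype=float)

    counts = {}
    valid = {}
    for rep in range(cfg.n_replicates):
        rng = cfg.rng_for(rep)
        dosages = np.column_stack([
            gene_drop(ped, maf, rng) for maf in cfg.mafs]).astype(float)
        ph = simulate_traits(ped, cfg, causal=(dosages, effects, age_effects),
                             rng=rng)
        fit = fit_adjustment_lmm(ph, "Y", ["Age", "Sex"], phi)
        pos = {p: i for i, p in enumerate(ped.ids)}
        for method in methods:
            rt = residuals(fit, ph, method)
            idx = [pos[p] for p in rt.persons]
            sub_kernels = ({} if method == "method1" else
                           {lab: Km[np.ix_(idx, idx)]
                            for lab, Km in kernels.items()})
            try:
                pvals = _scan_variants(dosages[idx], rt.values, sub_kernels,
                                       tests=tests)
            except NumericalError:
                continue
            for (test, s), p in pvals.items():
                key = (method, test, s)
                counts.setdefault(key, 0)
                valid.setdefault(key, 0)
                if not np.isnan(p):
                    valid[key] += 1
                    if p < alpha:
                        counts[key] += 1
        if progress is not None:
            progress(rep)

    rows = []
    for (method, test, s), nrej in sorted(counts.items()):
        nv = valid[(method, test, s)]
        causal = effects[s] != 0 or age_effects[s] != 0
        rows.append({
            "snp_id": f"v{s + 1}", "maf": cfg.mafs[s], "effect": effects[s],
            "age_effect": age_effects[s],
            "truth": "causal" if causal else "null",
            "method": method, "test": test,
            "rejection_rate": (nrej / nv) if nv else np.nan,
            "n_replicates": cfg.n_replicates, "n_valid": nv, "alpha": alpha,
        })
    return pd.DataFrame(rows)
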