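"""Covariate adjustment of longitudinal traits via a pedigree random-intercept LMM.

A trait measured at several visits (e.g. blood pressure with Age, BPMed,
Smoke, Sex recorded per visit) is modeled as

    y_{i,t} = μ_i + x_{i,t}ᵀ β + ε_{i,t},

where the individual random intercepts μ_i are jointly normal with
cov(μ_i, μ_j) = 2 φ_ij σ_g² (the polygenic component) and the errors are
independent N(0, σ_e²).  Stacking visits, this is a variance-component
model with genetic kernel σ_g² (1_T 1_Tᵀ ⊗ 2Φ) and environmental kernel
σ_e² I, fitted by maximum likelihood through the same engine as the
association null model.

Two kinds of adjusted traits are produced for downstream QTL scanning:

* method 1 (decorrelated): r_{i,t} = y_{i,t} − (μ̂_i + x_{i,t}ᵀβ̂), where
  μ̂_i is the predicted random intercept (the conditional-mean / BLUP
  predictor).  These residuals can be scanned without genetic variance
  components, but ignoring the residual familial correlation inflates
  type I error when polygenic variance is substantial.
* method 2 (correlated): r_{i,t} = y_{i,t} − (μ̂ + x_{i,t}ᵀβ̂) with the
  grand intercept only; the polygenic signal is retained and the scan must
  keep the genetic components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pedscore._errors import ConfigurationError, DataError
from pedscore.genio import PhenotypeTable
from pedscore.pedstruct import RelationshipMatrix
from pedscore.vcfit import Component, NullFit, StackedData, VarComponentSpec, fit_null_ml

__all__ = ["AdjustmentFit", "ResidualTraits", "fit_adjustment_lmm", "residuals",
           "design_columns"]


def design_columns(ph: pd.DataFrame, covariates) -> np.ndarray:
    """Covariate design from named columns; "A:B" denotes the product A×B."""
    cols = []
    for name in covariates:
        if ":" in name:
            a, b = name.split(":", 1)
            for c in (a, b):
                if c not in ph.columns:
                    raise ConfigurationError(f"covariate column {c!r} not found")
            cols.append(ph[a].to_numpy(float) * ph[b].to_numpy(float))
        else:
            if name not in ph.columns:
                raise ConfigurationError(f"covariate column {name!r} not found")
            cols.append(ph[name].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(ph), 0))


@dataclass
class AdjustmentFit:
    """ML fit of the random-intercept LMM for one trait."""

    trait: str
    covariates: list
    beta_hat: pd.Series          # grand intercept 'mu' + one entry per covariate
    sigma_g2: float
    sigma_e2: float
    mu_i: pd.Series              # predicted intercepts μ̂_i = μ̂ + û_i per person
    loglik: float
    r2: float                    # 1 − SSE/SST with fixed effects + predicted intercepts
    persons: list
    visits: list
    null_fit: NullFit

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return 0.0 if tot == 0 else self.sigma_g2 / tot


@dataclass
class ResidualTraits:
    """Adjusted trait values, individuals × visits (NaN = unobserved visit)."""

    values: np.ndarray
    persons: list
    visits: list
    method: str  # {method1_decorrelated, method2_correlated}

    def to_phenotype_table(self, trait: str = "resid") -> PhenotypeTable:
        rows = []
        for i, p in enumerate(self.persons):
            for t, v in enumerate(self.visits):
                if not np.isnan(self.values[i, t]):
                    rows.append((p, v, self.values[i, t]))
        return PhenotypeTable(pd.DataFrame(rows, columns=["person", "visit", trait]))


def _layout(ph: PhenotypeTable, trait: str, covariates, phi: RelationshipMatrix):
    if trait not in ph.table.columns:
        raise ConfigurationError(f"trait column {trait!r} not found in phenotype table")
    tab = ph.table
    persons = [p for p in phi.ids if p in set(tab["person"])]
    if not persons:
        raise DataError("no phenotyped individuals found in the kinship matrix")
    pos = {p: i for i, p in enumerate(persons)}
    visits = sorted(tab["visit"].unique())
    vpos = {v: t for t, v in enumerate(visits)}
    n, T = len(persons), len(visits)

    Y = np.full((n, T), np.nan)
    Xcells = np.full((n, T, max(len(covariates), 0)), np.nan)
    X = design_columns(tab, covariates)
    for r, row in enumerate(tab.itertuples(index=False)):
        p, v = row.person, row.visit
        if p not in pos:
            continue
        yv = getattr(row, trait)
        Y[pos[p], vpos[v]] = yv
        if len(covariates):
            Xcells[pos[p], vpos[v]] = X[r]
    return persons, visits, Y, Xcells


def fit_adjustment_lmm(ph: PhenotypeTable, trait: str, covariates,
                       phi: RelationshipMatrix) -> AdjustmentFit:
    """Fit the random-intercept LMM for ``trait`` over ``covariates``.

    ``phi`` is the kinship matrix over (at least) the phenotyped
    individuals; persons missing from it are dropped.  Returns estimated
    fixed effects, variance components σ̂_g², σ̂_e², per-person predicted
    intercepts and the underlying variance-component fit.
    """
    covariates = list(covariates)
    persons, visits, Y, Xc = _layout(ph, trait, covariates, phi)
    n, T = Y.shape
    keep = np.where(~np.isnan(Y).all(axis=1))[0]
    persons = [persons[i] for i in keep]
    Y, Xc = Y[keep], Xc[keep]
    n = len(persons)

    pphi = {p: i for i, p in enumerate(phi.ids)}
    sub = phi.subset([pphi[p] for p in persons])
    K = 2.0 * sub.values

    mask = ~np.isnan(Y.T)  # (T, n), visit-major stacking
    y = Y.T[mask]
    # shared coefficients across visits: [1, x_{i,t}]
    rows = []
    for t in range(T):
        for i in range(n):
            if mask[t, i]:
                rows.append(np.concatenate([[1.0], Xc[i, t]]))
    A = np.asarray(rows)
    if np.isnan(A).any():
        raise DataError("covariate values missing at an observed trait visit")
    data = StackedData(y, A, mask, n, T)
    spec = VarComponentSpec([
        Component("additive", K, trait_structure=np.ones((T, T))),
        Component("environment", np.eye(n)),
    ], n_traits=T)
    fit = fit_null_ml(spec, data)
    sigma_g2 = float(fit.component("additive"))
    sigma_e2 = float(fit.component("environment"))

    # predicted intercepts: μ̂_i = μ̂ + σ̂g² Σ_t (2Φ)[i, obs_t] · (Py)_t
    mu_hat = float(fit.beta_hat[0])
    offsets = np.concatenate([[0], np.cumsum(mask.sum(axis=1))])
    u = np.zeros(n)
    for t in range(T):
        idx = np.where(mask[t])[0]
        u += K[:, idx] @ fit.Py[offsets[t]:offsets[t + 1]]
    u *= sigma_g2
    mu_i = mu_hat + u

    # R² with fitted mean + predicted intercepts
    fitted = np.full_like(Y, np.nan)
    beta_cov = fit.beta_hat[1:]
    for t in range(T):
        for i in range(n):
            if mask[t, i]:
                fitted[i, t] = mu_i[i] + (Xc[i, t] @ beta_cov if len(covariates) else 0.0)
    obs = ~np.isnan(Y)
    sse = float(np.nansum((Y - fitted) ** 2))
    sst = float(np.nansum((Y - np.nanmean(Y)) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan

    names = ["mu"] + covariates
    return AdjustmentFit(
        trait=trait, covariates=covariates,
        beta_hat=pd.Series(fit.beta_hat, index=names),
        sigma_g2=sigma_g2, sigma_e2=sigma_e2,
        mu_i=pd.Series(mu_i, index=persons),
        loglik=fit.loglik, r2=r2, persons=persons, visits=visits,
        null_fit=fit)


def residuals(fit: AdjustmentFit, ph: PhenotypeTable, method: str) -> ResidualTraits:
    """Adjusted traits by residual method.

    method1 subtracts the predicted individual intercept μ̂_i (decorrelated
    residuals); method2 subtracts only the grand intercept μ̂ (correlated
    residuals, polygenic effects retained).  The two differ by μ̂_i − μ̂ at
    every visit of person i.
    """
    if method not in ("method1", "method2"):
        raise ConfigurationError("method must be 'method1' or 'method2'")
    tab = ph.table
    pos = {p: i for i, p in enumerate(fit.persons)}
    vpos = {v: t for t, v in enumerate(fit.visits)}
    n, T = len(fit.persons), len(fit.visits)
    out = np.full((n, T), np.nan)
    X = design_columns(tab, fit.covariates)
    beta_cov = fit.beta_hat.to_numpy()[1:]
    mu_hat = float(fit.beta_hat.iloc[0])
    yvals = tab[fit.trait].to_numpy(float)
    for r, row in enumerate(tab.itertuples(index=False)):
        p, v = row.person, row.visit
        if p not in pos or np.isnan(yvals[r]):
            continue
        xb = X[r] @ beta_cov if len(fit.covariates) else 0.0
        center = fit.mu_i[p] if method == "method1" else mu_hat
        out[pos[p], vpos[v]] = yvals[r] - (center + xb)
    tag = "method1_decorrelated" if method == "method1" else "method2_correlated"
    return ResidualTraits(out, fit.persons, fit.visits, tag)
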