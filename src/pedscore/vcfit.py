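"""Multivariate Gaussian variance-component likelihood and null-model ML fit.

The trait vector y over a pedigree sample is modeled as multivariate normal
with mean ν = Aβ and covariance

    Σ = σa² · (2Φ) + σd² · Δ7 + σh² · H + σe² · I,

where 2Φ is the additive (kinship) kernel, Δ7 the dominance kernel, H the
household indicator and I individual environment/measurement error.  With T
traits the covariance of the trait-major stacked vector (all individuals for
trait 1, then trait 2, ...) is augmented by Kronecker products,

    Σ = Σ_c  Γ_c ⊗ K_c,

with Γ_c either an unstructured T×T PSD trait covariance or σ²_c times a
fixed trait structure matrix (identity by default; the longitudinal
random-intercept model uses the all-ones matrix).  The loglikelihood is

    L = −1/2 ln det Σ − 1/2 (y−ν)ᵀ Σ⁻¹ (y−ν)

with no additive constant.  Missing trait entries are handled by row
deletion, which for a Gaussian equals marginalizing the unobserved entries.

The null model is fitted by maximum likelihood (not REML) with Fisher
scoring on the variance parameters (Σ is linear in all of them, so expected
information is available in closed form), profiling β by GLS at each
iteration, with step-halving and projection onto the PSD cone.  All linear
algebra is dense; the intended scale is up to a few thousand observed
entries per fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh

from pedscore._errors import ConfigurationError, NumericalError
from pedscore.pedstruct import (
    Pedigree,
    delta7_matrix,
    household_matrix,
    kinship_matrix,
)

__all__ = [
    "Component",
    "VarComponentSpec",
    "StackedData",
    "NullFit",
    "loglikelihood",
    "fit_null_ml",
    "heritability",
    "heritability_from_variances",
    "build_projection",
    "spec_from_pedigree",
]


@dataclass
class Component:
    """One variance component: a kernel over individuals plus its trait law.

    ``kernel`` is n×n (additive kernel = 2Φ so its diagonal is 1 for
    non-inbred individuals and scalar coefficients read as trait-variance
    shares).  ``trait_structure`` fixes the T×T matrix multiplying a scalar
    parameter; ``unstructured=True`` instead estimates a full PSD Γ.
    """

    label: str
    kernel: np.ndarray
    trait_structure: np.ndarray | None = None
    unstructured: bool = False

    def n_params(self, T: int) -> int:
        return T * (T + 1) // 2 if self.unstructured else 1


@dataclass
class VarComponentSpec:
    components: list[Component]
    n_traits: int = 1

    def __post_init__(self):
        labels = [c.label for c in self.components]
        if "environment" not in labels:
            raise ConfigurationError(
                "an environment component is required so that Σ can be nonsingular")
        n = self.components[0].kernel.shape[0]
        for c in self.components:
            if c.kernel.shape != (n, n):
                raise ConfigurationError("all kernels must share one individual ordering")

    @property
    def n_individuals(self) -> int:
        return self.components[0].kernel.shape[0]


def spec_from_pedigree(ped: Pedigree, components=("additive", "environment"),
                       n_traits: int = 1, unstructured: bool | None = None) -> VarComponentSpec:
    """Build a VarComponentSpec from a pedigree and component labels.

    additive → 2Φ, dominance → Δ7, household → H, environment → I.
    ``unstructured`` defaults to True when n_traits > 1.
    """
    if unstructured is None:
        unstructured = n_traits > 1
    comps = []
    for label in components:
        if label == "additive":
            K = 2.0 * kinship_matrix(ped).values
        elif label == "dominance":
            K = delta7_matrix(ped).values
        elif label == "household":
            K = household_matrix(ped).values
        elif label == "environment":
            K = np.eye(ped.n)
        else:
            raise ConfigurationError(f"unknown component label {label!r}")
        comps.append(Component(label, K, unstructured=unstructured and n_traits > 1))
    return VarComponentSpec(comps, n_traits)


@dataclass
class StackedData:
    """Observed entries of the trait-major stacked trait vector.

    ``mask`` is (T, n) boolean; ``y`` and the rows of ``A`` correspond to
    the True entries of ``mask`` raveled trait-major (trait index outer,
    individual index inner), i.e. entry (t, i) sits before (t, i+1) and
    before (t+1, j).
    """

    y: np.ndarray
    A: np.ndarray
    mask: np.ndarray
    n: int
    T: int

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        m = int(self.mask.sum())
        if self.y.shape != (m,) or self.A.shape[0] != m:
            raise ConfigurationError("y/A rows must match the observed-entry mask")

    @classmethod
    def from_traits(cls, Y: np.ndarray, X: np.ndarray | None = None,
                    per_trait_coef: bool = True) -> "StackedData":
        """Stack an n×T trait matrix (NaN = missing) over covariates X (n×q).

        X should not contain an intercept column; one is prepended.  With
        ``per_trait_coef`` each trait gets its own coefficient vector
        (A = I_T ⊗ [1 X]); otherwise coefficients are shared across traits.
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, T = Y.shape
        Xfull = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
        mask = ~np.isnan(Y.T)  # (T, n)
        y = Y.T[mask]
        if per_trait_coef:
            A = np.kron(np.eye(T), Xfull)
        else:
            A = np.tile(Xfull, (T, 1))
        A = A[mask.ravel()]
        return cls(y, A, mask, n, T)


def _derivative_matrices(spec: VarComponentSpec, mask: np.ndarray):
    """Per-parameter derivative matrices D_k restricted to observed entries.

    Σ(θ) = Σ_k θ_k D_k — the model is linear in every variance parameter,
    whether scalar or an element of an unstructured Γ.
    Returns (list of D_k, list of (component index, param slice)).
    """
    T = spec.n_traits
    obs = mask.ravel()
    mats, slices = [], []
    pos = 0
    for ci, comp in enumerate(spec.components):
        if comp.unstructured:
            for t in range(T):
                for u in range(t + 1):
                    B = np.zeros((T, T))
                    B[t, u] = B[u, t] = 1.0
                    D = np.kron(B, comp.kernel)
                    mats.append(D[np.ix_(obs, obs)])
            k = T * (T + 1) // 2
        else:
            B = comp.trait_structure if comp.trait_structure is not None else np.eye(T)
            D = np.kron(np.asarray(B, dtype=float), comp.kernel)
            mats.append(D[np.ix_(obs, obs)])
            k = 1
        slices.append((ci, slice(pos, pos + k)))
        pos += k
    return mats, slices


def _theta_to_gammas(spec: VarComponentSpec, theta: np.ndarray, slices):
    """Unpack the flat parameter vector into per-component Γ / scalars."""
    T = spec.n_traits
    out = []
    for ci, sl in slices:
        comp = spec.components[ci]
        if comp.unstructured:
            G = np.zeros((T, T))
            vals = theta[sl]
            k = 0
            for t in range(T):
                for u in range(t + 1):
                    G[t, u] = G[u, t] = vals[k]
                    k += 1
            out.append(G)
        else:
            out.append(float(theta[sl][0]))
    return out


def _gammas_to_theta(spec: VarComponentSpec, gammas, slices) -> np.ndarray:
    T = spec.n_traits
    npar = sum(c.n_params(T) for c in spec.components)
    theta = np.zeros(npar)
    for (ci, sl), g in zip(slices, gammas):
        comp = spec.components[ci]
        if comp.unstructured:
            G = np.asarray(g, dtype=float)
            vals = []
            for t in range(T):
                for u in range(t + 1):
                    vals.append(G[t, u])
            theta[sl] = vals
        else:
            theta[sl] = float(g)
    return theta


def _build_sigma(theta: np.ndarray, mats) -> np.ndarray:
    S = np.zeros_like(mats[0])
    for t, D in zip(theta, mats):
        if t != 0.0:
            S += t * D
    return S


def _chol(S: np.ndarray, params=None):
    try:
        return cho_factor(S, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("covariance matrix is not positive definite",
                             detail=params) from exc


def loglikelihood(spec: VarComponentSpec, params, data: StackedData) -> float:
    """Evaluate L = −½ ln det Σ − ½ (y−Aβ)ᵀΣ⁻¹(y−Aβ).

    ``params`` is (β, gammas) where gammas is a list matching
    ``spec.components``: a scalar for scalar components, a T×T matrix for
    unstructured ones.  No 2π constant is included.
    """
    beta, gammas = params
    mats, slices = _derivative_matrices(spec, data.mask)
    theta = _gammas_to_theta(spec, gammas, slices)
    S = _build_sigma(theta, mats)
    c = _chol(S, params=gammas)
    r = data.y - data.A @ np.asarray(beta, dtype=float)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    quad = float(r @ cho_solve(c, r, check_finite=False))
    return -0.5 * logdet - 0.5 * quad


@dataclass
class NullFit:
    """Null-model ML fit plus the precomputed pieces per-SNP testing needs."""

    beta_hat: np.ndarray
    varcomp_hat: list  # per component: scalar or T×T Γ̂
    loglik: float
    P: np.ndarray              # Σ̂⁻¹ − Σ̂⁻¹A(AᵀΣ̂⁻¹A)⁻¹AᵀΣ̂⁻¹ over observed entries
    Py: np.ndarray
    AtSiA: np.ndarray
    beta_se: np.ndarray
    varcomp_se: np.ndarray     # flat, one per variance parameter
    n_iter: int
    converged: bool
    trace: list = field(default_factory=list)   # loglik per iteration
    boundary: list = field(default_factory=list)  # labels of components at 0
    spec: VarComponentSpec | None = None
    data: StackedData | None = None
    sigma: np.ndarray | None = None

    def component(self, label: str):
        for comp, g in zip(self.spec.components, self.varcomp_hat):
            if comp.label == label:
                return g
        raise ConfigurationError(f"no component labeled {label!r} in fit")

    def report(self) -> dict:
        out = {
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "beta": self.beta_hat.tolist(),
            "beta_se": self.beta_se.tolist(),
            "varcomp_se": self.varcomp_se.tolist(),
            "boundary": self.boundary,
            "trace": [float(v) for v in self.trace],
            "varcomp": {},
        }
        for comp, g in zip(self.spec.components, self.varcomp_hat):
            out["varcomp"][comp.label] = (np.asarray(g).tolist()
                                          if comp.unstructured else float(g))
        return out


def _project_theta(spec, theta, slices, floor):
    """Project variance parameters onto the PSD cone.

    Scalars are clipped at 0 (environment at a small positive floor so Σ
    stays invertible); unstructured Γ blocks are eigenvalue-clipped.
    """
    T = spec.n_traits
    theta = theta.copy()
    for ci, sl in slices:
        comp = spec.components[ci]
        lo = floor if comp.label == "environment" else 0.0
        if comp.unstructured:
            G = _theta_to_gammas(spec, theta, [(ci, sl)])[0]
            w, V = eigh(G)
            w = np.maximum(w, max(lo, 1e-10 * max(w.max(), floor)))
            G = (V * w) @ V.T
            theta[sl] = _gammas_to_theta(spec, [G], [(ci, sl)])[sl]
        else:
            theta[sl] = max(float(theta[sl][0]), lo)
    return theta


def _gls_beta(A, y, chol_fac):
    SiA = cho_solve(chol_fac, A, check_finite=False)
    AtSiA = A.T @ SiA
    # detect collinear columns before solving
    diag = np.sqrt(np.maximum(np.diag(AtSiA), 1e-300))
    corr = AtSiA / np.outer(diag, diag)
    if np.linalg.matrix_rank(corr, tol=1e-10) < A.shape[1]:
        w = np.linalg.eigvalsh(corr)
        raise NumericalError(
            "covariate design is rank deficient (collinear columns)",
            detail={"min_eig": float(w[0])})
    beta = np.linalg.solve(AtSiA, SiA.T @ y)
    return beta, AtSiA, SiA


def fit_null_ml(spec: VarComponentSpec, data: StackedData, tol: float = 1e-8,
                max_iter: int = 200, verbose: bool = False,
                init_varcomp=None) -> NullFit:
    """Maximize the loglikelihood over (β, variance parameters).

    Fisher scoring on the variance parameters with step-halving; β is
    profiled out by GLS at the current Σ.  Starting values: β from OLS and
    the OLS residual variance split evenly among components (or
    ``init_varcomp``, a per-component list used to warm-start alternative
    fits from the null optimum).  Convergence when the relative loglik
    change drops below ``tol``.  Boundary estimates (a component at 0) are
    allowed and flagged.
    """
    y, A = data.y, data.A
    m = y.shape[0]
    mats, slices = _derivative_matrices(spec, data.mask)
    npar = len(mats)
    T = spec.n_traits

    # warn when the additive kernel is indistinguishable from I (unrelateds)
    for comp in spec.components:
        if comp.label == "additive":
            K = comp.kernel
            if np.allclose(K - np.diag(np.diag(K)), 0.0, atol=1e-12):
                warnings.warn(
                    "additive kernel is (block-)diagonal with no relatedness; "
                    "additive and environmental variances are not separately "
                    "identifiable", stacklevel=2)

    beta0, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid0 = y - A @ beta0
    s2 = float(resid0 @ resid0) / m
    floor = 1e-10 * max(s2, 1e-12)
    ncomp = len(spec.components)
    if init_varcomp is None:
        init = []
        for comp in spec.components:
            if comp.unstructured:
                init.append((s2 / ncomp) * np.eye(T))
            else:
                init.append(s2 / ncomp)
    else:
        init = init_varcomp
    theta = _project_theta(spec, _gammas_to_theta(spec, init, slices), slices, floor)

    def eval_at(theta):
        S = _build_sigma(theta, mats)
        c = _chol(S, params=_theta_to_gammas(spec, theta, slices))
        beta, AtSiA, SiA = _gls_beta(A, y, c)
        r = y - A @ beta
        Sir = cho_solve(c, r, check_finite=False)
        L = -float(np.sum(np.log(np.diag(c[0])))) - 0.5 * float(r @ Sir)
        return S, c, beta, AtSiA, SiA, r, Sir, L

    # lower bound per parameter: scalar components are nonnegative
    # (environment floored above 0); unstructured Γ entries are kept PSD by
    # projection only and carry no box bound here
    lower = np.full(npar, -np.inf)
    for ci, sl in slices:
        comp = spec.components[ci]
        if not comp.unstructured:
            lower[sl] = floor if comp.label == "environment" else 0.0

    S, c, beta, AtSiA, SiA, r, Sir, L = eval_at(theta)
    trace = [L]
    converged = False
    it = 0
    info = np.eye(npar)
    for it in range(1, max_iter + 1):
        # score and expected information for the variance parameters
        Q = [cho_solve(c, D, check_finite=False) for D in mats]  # Σ⁻¹ D_k
        score = np.array([
            0.5 * (float(Sir @ (D @ Sir)) - float(np.trace(Qk)))
            for D, Qk in zip(mats, Q)
        ])
        info = np.empty((npar, npar))
        for k in range(npar):
            for l in range(k + 1):
                v = 0.5 * float(np.sum(Q[k] * Q[l].T))
                info[k, l] = info[l, k] = v
        # active-set reduction: a parameter pinned at its bound with a
        # negative score stays fixed, so the Fisher step for the free
        # parameters is not dragged along the constraint
        bound_eps = np.where(np.isfinite(lower),
                             lower + 1e-12 * (1.0 + np.abs(np.where(
                                 np.isfinite(lower), lower, 0.0))), -np.inf)
        free = ~((theta <= bound_eps) & (score < 0.0))
        if not free.any():
            converged = True
            break
        delta = np.zeros(npar)
        sub_info = info[np.ix_(free, free)]
        try:
            delta[free] = np.linalg.solve(
                sub_info + 1e-12 * np.eye(int(free.sum())) * np.trace(sub_info),
                score[free])
        except np.linalg.LinAlgError:
            delta[free] = score[free] / max(np.trace(sub_info) / free.sum(), 1e-12)

        step = 1.0
        accepted = False
        for _ in range(60):
            cand = _project_theta(spec, theta + step * delta, slices, floor)
            try:
                out = eval_at(cand)
            except NumericalError:
                step *= 0.5
                continue
            if out[-1] >= L - 1e-12:
                theta = cand
                S, c, beta, AtSiA, SiA, r, Sir, Lnew = out
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no ascent direction improves: at a (boundary) optimum
            break
        trace.append(Lnew)
        if verbose:
            print(f"iter {it}: loglik {Lnew:.10f}")
        if abs(Lnew - L) < tol * (1.0 + abs(L)):
            L = Lnew
            converged = True
            break
        L = Lnew

    if not converged:
        raise NumericalError(
            f"null-model fit did not converge in {max_iter} iterations",
            detail={"trace": trace})

    gammas = _theta_to_gammas(spec, theta, slices)
    boundary = []
    for comp, g in zip(spec.components, gammas):
        val = np.min(np.linalg.eigvalsh(g)) if comp.unstructured else g
        if val <= max(floor, 1e-8 * s2):
            boundary.append(comp.label)

    # standard errors from expected information at the optimum
    beta_cov = np.linalg.inv(AtSiA)
    try:
        vc_cov = np.linalg.inv(info)
        vc_se = np.sqrt(np.maximum(np.diag(vc_cov), 0.0))
    except np.linalg.LinAlgError:
        vc_se = np.full(npar, np.nan)

    P, Py, _ = build_projection(S, A, y, chol_fac=c)
    return NullFit(
        beta_hat=beta, varcomp_hat=gammas, loglik=L, P=P, Py=Py, AtSiA=AtSiA,
        beta_se=np.sqrt(np.maximum(np.diag(beta_cov), 0.0)), varcomp_se=vc_se,
        n_iter=it, converged=converged, trace=trace, boundary=boundary,
        spec=spec, data=data, sigma=S)


def build_projection(sigma: np.ndarray, A: np.ndarray, y: np.ndarray,
                     chol_fac=None):
    """Materialize P = Σ⁻¹ − Σ⁻¹A(AᵀΣ⁻¹A)⁻¹AᵀΣ⁻¹ together with P·y.

    P annihilates the covariate design (PA = 0) and P·y equals
    Σ⁻¹(y − Aβ̂) at the GLS β̂.
    """
    c = chol_fac if chol_fac is not None else _chol(sigma)
    Si = cho_solve(c, np.eye(sigma.shape[0]), check_finite=False)
    _, AtSiA, SiA = _gls_beta(A, y, c)
    P = Si - SiA @ np.linalg.solve(AtSiA, SiA.T)
    P = 0.5 * (P + P.T)
    return P, P @ y, AtSiA


def heritability(fit: NullFit) -> np.ndarray:
    """Narrow-sense heritability per trait, h² = σ̂g² / (σ̂g² + σ̂e²).

    Requires additive and environment components.  With unstructured trait
    covariances the ratio is taken on the per-trait diagonals.  The additive
    kernel is 2Φ (unit diagonal for non-inbred pedigrees), so scalar
    coefficients are directly trait-variance shares.
    """
    ga = fit.component("additive")
    ge = fit.component("environment")
    T = fit.spec.n_traits
    ga = np.diag(ga) if np.ndim(ga) == 2 else np.full(T, float(ga))
    ge = np.diag(ge) if np.ndim(ge) == 2 else np.full(T, float(ge))
    tot = ga + ge
    out = np.where(tot > 0, ga / np.where(tot > 0, tot, 1.0), 0.0)
    return out


def heritability_from_variances(sigma_g2: float, sigma_e2: float) -> float:
    """h² = σg² / (σg² + σe²) from reported variance components."""
    tot = sigma_g2 + sigma_e2
    return 0.0 if tot == 0 else sigma_g2 / tot
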