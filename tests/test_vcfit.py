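"""Variance-component likelihood, null-model ML fit, and projection."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pedscore._errors import ConfigurationError, NumericalError
from pedscore.pedstruct import Pedigree
from pedscore.simkit import SimConfig, replicate_pedigrees, simulate_traits
from pedscore.vcfit import (
    Component,
    StackedData,
    VarComponentSpec,
    build_projection,
    fit_null_ml,
    heritability,
    heritability_from_variances,
    loglikelihood,
    spec_from_pedigree,
)


def env_spec(n, T=1, unstructured=False):
    return VarComponentSpec(
        [Component("environment", np.eye(n), unstructured=unstructured)],
        n_traits=T)


def two_family_pedigree() -> Pedigree:
    """8 individuals in two families (one trio + one five-person family)."""
    return Pedigree.from_records([
        ("f1", "a", "", "", "male"), ("f1", "b", "", "", "female"),
        ("f1", "c", "a", "b", "male"),
        ("f2", "d", "", "", "male"), ("f2", "e", "", "", "female"),
        ("f2", "g", "d", "e", "female"), ("f2", "h", "d", "e", "male"),
        ("f2", "i", "", "", "female"),
    ])


def dense_loglik(y, A, beta, Sigma):
    r = y - A @ beta
    sign, logdet = np.linalg.slogdet(Sigma)
    assert sign > 0
    return -0.5 * logdet - 0.5 * r @ np.linalg.inv(Sigma) @ r


class TestLoglikelihood:
    def test_zero_residual_identity_sigma(self):
        n = 5
        data = StackedData(np.zeros(n), np.ones((n, 1)), np.ones((1, n), bool), n, 1)
        L = loglikelihood(env_spec(n), (np.zeros(1), [1.0]), data)
        assert L == 0.0

    def test_single_observation_closed_form(self):
        data = StackedData(np.array([1.0]), np.ones((1, 1)), np.ones((1, 1), bool), 1, 1)
        L = loglikelihood(env_spec(1), (np.zeros(1), [1.0]), data)
        assert L == pytest.approx(-0.5)

    def test_matches_dense_brute_force_on_pedigree(self, rng):
        """Structured evaluation equals explicit inverse + logdet."""
        ped = two_family_pedigree()
        spec = spec_from_pedigree(ped, ("additive", "dominance", "environment"))
        n = ped.n
        y = rng.standard_normal(n)
        A = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = rng.standard_normal(2)
        sa, sd, se = 0.7, 0.3, 1.2
        data = StackedData(y, A, np.ones((1, n), bool), n, 1)
        L = loglikelihood(spec, (beta, [sa, sd, se]), data)
        Sigma = (sa * spec.components[0].kernel + sd * spec.components[1].kernel
                 + se * np.eye(n))
        assert L == pytest.approx(dense_loglik(y, A, beta, Sigma), abs=1e-8)

    def test_kronecker_multitrait_matches_dense(self, rng):
        """Γ ⊗ K structured loglik equals the fully dense evaluation, T=2."""
        ped = two_family_pedigree()
        n, T = ped.n, 2
        spec = spec_from_pedigree(ped, ("additive", "environment"),
                                  n_traits=T, unstructured=True)
        Ga = np.array([[0.8, 0.2], [0.2, 0.5]])
        Ge = np.array([[1.0, -0.1], [-0.1, 0.9]])
        y = rng.standard_normal(n * T)
        A = np.kron(np.eye(T), np.ones((n, 1)))
        beta = rng.standard_normal(T)
        data = StackedData(y, A, np.ones((T, n), bool), n, T)
        L = loglikelihood(spec, (beta, [Ga, Ge]), data)
        Sigma = (np.kron(Ga, spec.components[0].kernel)
                 + np.kron(Ge, np.eye(n)))
        assert L == pytest.approx(dense_loglik(y, A, beta, Sigma), abs=1e-8)

    def test_missing_entries_equal_gaussian_marginal(self, rng):
        """Row deletion equals marginalizing the unobserved entries."""
        ped = two_family_pedigree()
        n, T = ped.n, 2
        spec = spec_from_pedigree(ped, ("additive", "environment"),
                                  n_traits=T, unstructured=True)
        Ga = np.array([[0.8, 0.2], [0.2, 0.5]])
        Ge = np.eye(2)
        mask = np.ones((T, n), bool)
        mask[0, 2] = mask[1, 5] = mask[1, 6] = False
        obs = mask.ravel()
        yfull = rng.standard_normal(n * T)
        Afull = np.kron(np.eye(T), np.ones((n, 1)))
        beta = rng.standard_normal(T)
        data = StackedData(yfull[obs], Afull[obs], mask, n, T)
        L = loglikelihood(spec, (beta, [Ga, Ge]), data)
        Sigma = (np.kron(Ga, spec.components[0].kernel) + np.kron(Ge, np.eye(n)))
        Lmarg = dense_loglik(yfull[obs], Afull[obs], beta,
                             Sigma[np.ix_(obs, obs)])
        assert L == pytest.approx(Lmarg, abs=1e-8)

    def test_non_pd_sigma_raises(self):
        n = 3
        data = StackedData(np.zeros(n), np.ones((n, 1)), np.ones((1, n), bool), n, 1)
        with pytest.raises(NumericalError):
            loglikelihood(env_spec(n), (np.zeros(1), [-1.0]), data)

    def test_environment_component_required(self):
        with pytest.raises(ConfigurationError, match="environment"):
            VarComponentSpec([Component("additive", np.eye(3))], 1)


class TestFitNullML:
    def test_unrelated_closed_form(self, rng):
        """Environment-only intercept model: β̂ = mean, σ̂e² = MSD (ML, /n)."""
        y = rng.standard_normal(40) * 2.0 + 5.0
        data = StackedData(y, np.ones((40, 1)), np.ones((1, 40), bool), 40, 1)
        fit = fit_null_ml(env_spec(40), data)
        assert fit.beta_hat[0] == pytest.approx(y.mean(), abs=1e-8)
        assert fit.varcomp_hat[0] == pytest.approx(((y - y.mean()) ** 2).mean(),
                                                   rel=1e-6)

    def test_unrelated_additive_kernel_warns(self, rng):
        """All-singleton samples leave σa² and σe² unidentifiable: warn."""
        y = rng.standard_normal(20)
        data = StackedData(y, np.ones((20, 1)), np.ones((1, 20), bool), 20, 1)
        spec = VarComponentSpec([
            Component("additive", np.eye(20)),
            Component("environment", np.eye(20))], 1)
        with pytest.warns(UserWarning, match="identifiable"):
            fit_null_ml(spec, data)

    def test_matches_independent_optimizer(self, rng):
        """Fisher scoring optimum equals a derivative-free optimizer's."""
        ped = replicate_pedigrees(3)
        cfg = SimConfig(seed=77, n_pedigrees=3, n_visits=1,
                        sigma_a2=1.0, sigma_e2=1.0)
        ph = simulate_traits(ped, cfg, rng=rng)
        Y = ph.wide("Y").loc[ped.ids].to_numpy()
        data = StackedData.from_traits(Y)
        spec = spec_from_pedigree(ped, ("additive", "environment"))
        fit = fit_null_ml(spec, data)

        def negloglik(logvars):
            va, ve = np.exp(logvars)
            beta = np.zeros(1)
            # profile beta by GLS for a fair comparison
            S = va * spec.components[0].kernel + ve * np.eye(ped.n)
            Si = np.linalg.inv(S)
            A = data.A
            b = np.linalg.solve(A.T @ Si @ A, A.T @ Si @ data.y)
            return -loglikelihood(spec, (b, [va, ve]), data)

        res = minimize(negloglik, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 4000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_loglik_trace_monotone(self, rng):
        ped = replicate_pedigrees(2)
        cfg = SimConfig(seed=5, n_pedigrees=2, n_visits=2, sigma_a2=1.5, sigma_e2=1.0)
        ph = simulate_traits(ped, cfg, rng=rng)
        Y = ph.wide("Y").loc[ped.ids].to_numpy()
        spec = spec_from_pedigree(ped, ("additive", "environment"), n_traits=2)
        fit = fit_null_ml(spec, StackedData.from_traits(Y))
        assert np.all(np.diff(fit.trace) >= -1e-10)

    def test_scalar_and_unstructured_agree_for_single_trait(self, rng):
        ped = replicate_pedigrees(2)
        cfg = SimConfig(seed=6, n_pedigrees=2, n_visits=1, sigma_a2=1.0, sigma_e2=1.0)
        ph = simulate_traits(ped, cfg, rng=rng)
        Y = ph.wide("Y").loc[ped.ids].to_numpy()
        data = StackedData.from_traits(Y)
        f_scalar = fit_null_ml(
            spec_from_pedigree(ped, ("additive", "environment"), 1, False), data)
        f_unstr = fit_null_ml(
            spec_from_pedigree(ped, ("additive", "environment"), 1, True), data)
        # force unstructured flag even at T=1
        spec_u = spec_from_pedigree(ped, ("additive", "environment"), 1)
        for c in spec_u.components:
            c.unstructured = True
        f_forced = fit_null_ml(spec_u, data)
        assert f_scalar.loglik == pytest.approx(f_unstr.loglik, abs=1e-8)
        assert f_forced.loglik == pytest.approx(f_scalar.loglik, abs=1e-8)
        assert float(np.ravel(f_forced.varcomp_hat[0])[0]) == pytest.approx(
            f_scalar.varcomp_hat[0], abs=1e-6)

    def test_mean_gradient_zero_at_optimum(self, rng):
        ped = replicate_pedigrees(2)
        cfg = SimConfig(seed=8, n_pedigrees=2, n_visits=1, sigma_a2=1.0, sigma_e2=1.0)
        ph = simulate_traits(ped, cfg, rng=rng)
        Y = ph.wide("Y").loc[ped.ids].to_numpy()
        X = ph.wide("Age").loc[ped.ids].to_numpy()  # one visit -> one column
        data = StackedData.from_traits(Y, X)
        spec = spec_from_pedigree(ped, ("additive", "environment"))
        fit = fit_null_ml(spec, data)
        # gradient of L wrt beta: Aᵀ Σ⁻¹ (y − Aβ) = Aᵀ (Py) at the optimum
        grad = data.A.T @ fit.Py
        assert np.max(np.abs(grad)) < 1e-6


class TestHeritability:
    def test_reported_variance_component_arithmetic(self):
        # printed LMM components for diastolic blood pressure and the null
        # trait: 49.848/(49.848+40.395) and 53.373/(53.373+31.615)
        assert round(heritability_from_variances(49.848, 40.395), 2) == 0.55
        assert round(heritability_from_variances(53.373, 31.615), 2) == 0.63

    def test_zero_genetic_variance(self):
        assert heritability_from_variances(0.0, 3.0) == 0.0

    def test_fit_accessor_requires_components(self, rng):
        y = rng.standard_normal(30)
        data = StackedData(y, np.ones((30, 1)), np.ones((1, 30), bool), 30, 1)
        fit = fit_null_ml(env_spec(30), data)
        with pytest.raises(ConfigurationError):
            heritability(fit)


class TestBuildProjection:
    def test_intercept_identity_gives_centering_matrix(self, rng):
        n = 12
        y = rng.standard_normal(n)
        A = np.ones((n, 1))
        P, Py, _ = build_projection(np.eye(n), A, y)
        C = np.eye(n) - np.ones((n, n)) / n
        assert np.allclose(P, C, atol=1e-10)
        assert np.allclose(Py, y - y.mean(), atol=1e-10)

    def test_annihilates_design_and_matches_dense_formula(self, rng):
        n = 15
        S = rng.standard_normal((n, n))
        S = S @ S.T + n * np.eye(n)
        A = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        P, Py, AtSiA = build_projection(S, A, y)
        assert np.max(np.abs(P @ A)) < 1e-8 * np.linalg.norm(P)
        Si = np.linalg.inv(S)
        Pdense = Si - Si @ A @ np.linalg.inv(A.T @ Si @ A) @ A.T @ Si
        assert np.allclose(P, Pdense, atol=1e-8)
        # Py equals Σ⁻¹(y − Aβ̂) at the GLS optimum
        beta = np.linalg.solve(A.T @ Si @ A, A.T @ Si @ y)
        assert np.allclose(Py, Si @ (y - A @ beta), atol=1e-8)
        eig = np.linalg.eigvalsh(P)
        assert eig.min() > -1e-10

    def test_collinear_design_rejected(self, rng):
        n = 10
        x = rng.standard_normal(n)
        A = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(NumericalError, match="rank deficient"):
            build_projection(np.eye(n), A, rng.standard_normal(n))
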