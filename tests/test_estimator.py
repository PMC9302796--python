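"""GMM machinery: extended scores, QIF objectives, fitting and CV."""

import numpy as np
import pytest

from qifmrr import (
    Cohort,
    MarginalVarianceSpec,
    SimulationScenario,
    ThetaParams,
    ar1_basis,
    exchangeable_basis,
    extended_score,
    fit,
    fit_structure,
    generate_cohort,
    mean_model_jacobian,
    mean_response,
    qif_objective,
    ridge_objective,
    select_lambda_cv,
    state_residuals,
    subject_score,
)
from qifmrr.model import StateResidualModel

from conftest import THETA_TRUE


def brute_force_components(cohort, theta, basis, Z, mode="paper"):
    """Explicit-loop extended score, g_n and C_n (the independent oracle)."""
    h = mean_response(Z, cohort.states, cohort.actions, theta)
    J = mean_model_jacobian(Z, cohort.states, cohort.actions, theta, mode)
    g_list = []
    for i in range(cohort.n):
        r = cohort.responses[i] - h[i]
        g_list.append(np.concatenate([J[i] @ M @ r for M in basis.matrices]))
    G = np.array(g_list)
    g_n = G.mean(axis=0)
    C_n = sum(np.outer(g, g) for g in g_list) / cohort.n**2
    return G, g_n, C_n


class TestSubjectScore:
    def test_vanishes_at_perfect_fit(self, small_generated, theta_true):
        c = small_generated.cohort
        Z = small_generated.true_residuals
        Y = mean_response(Z, c.states, c.actions, theta_true)
        g = subject_score((c.states[0], c.actions[0], Y[0], Z[0]), theta_true,
                          ar1_basis(c.K))
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_identity_block_matches_loop(self, random_cohort_factory, theta_true):
        c = random_cohort_factory(n=4, K=3)
        Z = np.zeros((4, 3))
        basis = ar1_basis(3)
        g = subject_score((c.states[1], c.actions[1], c.responses[1], Z[1]),
                          theta_true, basis)
        h = mean_response(Z, c.states, c.actions, theta_true)
        J = mean_model_jacobian(Z, c.states, c.actions, theta_true)[1]
        block0 = np.zeros(5)
        for v in range(5):
            for k in range(3):
                block0[v] += J[v, k] * (c.responses[1, k] - h[1, k])
        assert np.allclose(g[:5], block0, atol=1e-10)

    def test_variance_scaling(self, random_cohort_factory, theta_true):
        c = random_cohort_factory(n=3, K=4)
        traj = (c.states[0], c.actions[0], c.responses[0], np.zeros(4))
        basis = ar1_basis(4)
        g1 = subject_score(traj, theta_true, basis,
                           MarginalVarianceSpec("known_sigma2", 1.0))
        g4 = subject_score(traj, theta_true, basis,
                           MarginalVarianceSpec("known_sigma2", 4.0))
        assert np.allclose(g4, g1 / 4.0)


class TestExtendedScore:
    def test_duplicated_subjects(self, random_cohort_factory, theta_true):
        c1 = random_cohort_factory(n=4, K=3)
        dup = Cohort([1, 2], states=np.tile(c1.states[0], (2, 1)),
                     actions=np.tile(c1.actions[0], (2, 1)),
                     responses=np.tile(c1.responses[0], (2, 1)))
        comp = extended_score(dup, theta_true, ar1_basis(3), Z=np.zeros((2, 3)))
        assert np.allclose(comp.g_n, comp.g_i[0])
        assert np.allclose(comp.C_n, np.outer(comp.g_i[0], comp.g_i[0]) / 2)

    def test_matches_brute_force(self, random_cohort_factory, theta_true):
        for mode in ("paper", "analytic"):
            for basis_fn, K in ((ar1_basis, 4), (exchangeable_basis, 3)):
                c = random_cohort_factory(n=6, K=K)
                Z = state_residuals(c).Z
                basis = basis_fn(K)
                comp = extended_score(c, theta_true, basis, Z=Z,
                                      psi1_derivative_mode=mode)
                G, g_n, C_n = brute_force_components(c, theta_true, basis, Z, mode)
                assert np.allclose(comp.g_i, G, atol=1e-8)
                assert np.allclose(comp.g_n, g_n, atol=1e-8)
                assert np.allclose(comp.C_n, C_n, atol=1e-8)

    def test_weight_matrix_is_psd(self, random_cohort_factory, theta_true):
        c = random_cohort_factory(n=6, K=4)
        comp = extended_score(c, theta_true, ar1_basis(4))
        assert np.allclose(comp.C_n, comp.C_n.T)
        assert np.linalg.eigvalsh(comp.C_n).min() >= -1e-10

    def test_score_unbiased_under_generative_model(self):
        scen = SimulationScenario(n=5000, rho=0.5, seed=99)
        gen = generate_cohort(scen)
        comp = extended_score(gen.cohort, scen.theta_true, ar1_basis(scen.K),
                              Z=gen.true_residuals)
        se = comp.g_i.std(axis=0, ddof=1) / np.sqrt(scen.n)
        assert np.all(np.abs(comp.g_n) < 4 * se)


class TestObjectives:
    def test_zero_at_perfect_fit(self, small_generated, theta_true):
        c = small_generated.cohort
        Z = small_generated.true_residuals
        Y = mean_response(Z, c.states, c.actions, theta_true)
        perfect = Cohort(c.subject_ids, c.states, c.actions, Y)
        assert qif_objective(theta_true, perfect, ar1_basis(c.K), Z=Z) == pytest.approx(0.0)

    def test_invariant_to_uniform_variance_scaling(self, small_generated, theta_true):
        c = small_generated.cohort
        basis = ar1_basis(c.K)
        base = qif_objective(theta_true, c, basis)
        for scale in (0.1, 64.0):
            scaled = qif_objective(theta_true, c, basis,
                                   MarginalVarianceSpec("known_sigma2", scale))
            assert scaled == pytest.approx(base, rel=1e-8)

    def test_matches_dense_inverse_on_small_cohort(self, random_cohort_factory):
        # The standard bases make C_n structurally singular whenever the
        # mean model has an intercept: (M1 + M2 - 2I)1 = 0 ties the three
        # AR(1) intercept moments together, and 1'(ones-off-diagonal) =
        # (K-1)1' ties the two exchangeable ones.  A nonsingular oracle
        # check therefore uses a truncated basis (I and the off-diagonal
        # band), the analytic psi1 weight, an evaluation point where the
        # regret sign varies, and more subjects than moment conditions.
        from qifmrr import CorrelationBasis

        theta = ThetaParams(3.0, -5.0, 1.5, 0.1, 0.5)
        c = random_cohort_factory(n=20, K=3)
        Z = state_residuals(c).Z
        band = np.diag(np.ones(2), 1) + np.diag(np.ones(2), -1)
        basis = CorrelationBasis(label="ar1-truncated",
                                 matrices=(np.eye(3), band))
        _, g_n, C_n = brute_force_components(c, theta, basis, Z, "analytic")
        assert np.linalg.cond(C_n) < 1e10
        expected = g_n @ np.linalg.inv(C_n) @ g_n
        got = qif_objective(theta, c, basis, Z=Z, psi1_derivative_mode="analytic")
        assert got == pytest.approx(expected, rel=1e-8)

    def test_pseudoinverse_path_matches_numpy_pinv(self, random_cohort_factory,
                                                   theta_true):
        # the published -I weight makes C_n exactly singular; compare the
        # eigendecomposition route against numpy's SVD pseudoinverse
        c = random_cohort_factory(n=6, K=4)
        Z = state_residuals(c).Z
        basis = ar1_basis(4)
        _, g_n, C_n = brute_force_components(c, theta_true, basis, Z, "paper")
        expected = g_n @ np.linalg.pinv(C_n, rtol=1e-10) @ g_n
        got = qif_objective(theta_true, c, basis, Z=Z)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_ridge_reduces_to_qif_at_zero_lambda(self, small_generated, theta_true):
        c = small_generated.cohort
        basis = ar1_basis(c.K)
        assert ridge_objective(theta_true, c, basis, lam=0.0) == qif_objective(
            theta_true, c, basis)

    def test_penalty_arithmetic(self, small_generated, theta_true):
        c = small_generated.cohort
        basis = ar1_basis(c.K)
        q = qif_objective(theta_true, c, basis)
        rq = ridge_objective(theta_true, c, basis, lam=0.01)
        assert rq - q == pytest.approx(0.01 * (9 + 25 + 2.25 + 0.01 + 30.25))
        zero = ThetaParams(0, 0, 0, 0, 0)
        assert ridge_objective(zero, c, basis, lam=5.0) == pytest.approx(
            qif_objective(zero, c, basis))

    def test_negative_lambda_rejected(self, small_generated, theta_true):
        with pytest.raises(ValueError, match="lambda"):
            ridge_objective(theta_true, small_generated.cohort,
                            ar1_basis(small_generated.cohort.K), lam=-0.1)


@pytest.fixture(scope="module")
def recovery_fit():
    scen = SimulationScenario(n=500, rho=0.1, seed=0)
    cohort = generate_cohort(scen).cohort
    result = fit_structure(cohort, "ar1", lam=0.01, theta0=THETA_TRUE)
    return scen, cohort, result


class TestFit:
    def test_parameter_recovery(self, recovery_fit):
        """One n=500 fit lands within ~3 sampling SDs of the truth.

        The residual covariate Z has sd 0.1, so beta1's sampling SD is an
        order of magnitude larger than the other components'; tolerances
        reflect the per-component information.
        """
        _, _, result = recovery_fit
        err = np.abs(result.theta_hat.to_array() - THETA_TRUE.to_array())
        assert np.all(err < [0.15, 0.4, 0.15, 0.15, 0.15])

    def test_descent_from_start(self, recovery_fit):
        _, cohort, result = recovery_fit
        f0 = ridge_objective(THETA_TRUE, cohort, ar1_basis(cohort.K), lam=0.01)
        assert result.objective_value <= f0

    def test_reported_objective_is_recomputable(self, recovery_fit):
        _, cohort, result = recovery_fit
        recomputed = ridge_objective(result.theta_hat, cohort,
                                     ar1_basis(cohort.K), lam=0.01)
        assert result.objective_value == pytest.approx(recomputed, abs=1e-7)

    def test_deterministic(self, small_generated):
        c = small_generated.cohort
        r1 = fit_structure(c, "ar1", lam=0.01, theta0=THETA_TRUE)
        r2 = fit_structure(c, "ar1", lam=0.01, theta0=THETA_TRUE)
        assert np.array_equal(r1.theta_hat.to_array(), r2.theta_hat.to_array())
        assert r1.objective_value == r2.objective_value

    def test_requires_finite_start(self, small_generated):
        with pytest.raises(ValueError, match="finite"):
            fit(small_generated.cohort, ar1_basis(small_generated.cohort.K),
                theta0=[np.nan, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="theta0"):
            fit(small_generated.cohort, ar1_basis(small_generated.cohort.K))


class TestLambdaCV:
    def test_single_value_grid(self, small_generated):
        lam = select_lambda_cv(small_generated.cohort, "ar1", grid=[0.05],
                               folds=2, seed=1, theta0=THETA_TRUE)
        assert lam == 0.05

    def test_errors_match_naive_loop(self, small_generated):
        cohort = small_generated.cohort
        grid = [0.01, 1.0]
        folds, seed = 2, 5
        lam, errors = select_lambda_cv(cohort, "ar1", grid=grid, folds=folds,
                                       seed=seed, theta0=THETA_TRUE,
                                       return_errors=True)
        # naive reimplementation: same subject split, explicit per-fold loop
        perm = np.random.default_rng(seed).permutation(cohort.n)
        fold_ids = np.array_split(perm, folds)
        for lam_g in grid:
            fold_errs = []
            for test_idx in fold_ids:
                mask = np.ones(cohort.n, dtype=bool)
                mask[test_idx] = False
                train = Cohort(list(np.array(cohort.subject_ids)[mask]),
                               cohort.states[mask], cohort.actions[mask],
                               cohort.responses[mask])
                test = Cohort(list(np.array(cohort.subject_ids)[test_idx]),
                              cohort.states[test_idx], cohort.actions[test_idx],
                              cohort.responses[test_idx])
                zm = StateResidualModel.fit(train)
                res = fit_structure(train, "ar1", lam=lam_g, theta0=THETA_TRUE,
                                    Z=zm.residuals(train))
                pred = mean_response(zm.residuals(test), test.states,
                                     test.actions, res.theta_hat)
                fold_errs.append(np.mean((test.responses - pred) ** 2))
            assert errors[lam_g] == pytest.approx(np.mean(fold_errs), rel=1e-12)
        assert lam in grid

    def test_contract_violations(self, small_generated):
        with pytest.raises(ValueError, match="grid"):
            select_lambda_cv(small_generated.cohort, "ar1", grid=[], folds=2,
                             seed=0, theta0=THETA_TRUE)
        with pytest.raises(ValueError, match="folds"):
            select_lambda_cv(small_generated.cohort, "ar1", grid=[0.1],
                             folds=1, seed=0, theta0=THETA_TRUE)
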