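"""Reduced-SVM assembly, the finite Newton solver, and fitness evaluation.

The solver is validated against an independent generic QP solve of the
constrained primal (explicit slack variables, linear inequality
constraints, SLSQP) — a completely separate optimization path.
"""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from fitland.kernel import KernelParams, gaussian_kernel
from fitland.rsvm import (
    BasisSet,
    FitnessModel,
    SolverParams,
    TrainingPool,
    assemble_problem,
    classify,
    design_rank_success,
    fitness,
    load_model,
    save_model,
    solve_newton,
    train_model,
)


def random_instance(rng, m=None, mbar=None, dim=6):
    """Random labeled pool + basis with both classes in each."""
    m = m or int(rng.integers(20, 61))
    mbar = mbar or int(rng.integers(4, 16))
    A = rng.normal(size=(m, dim))
    labels = np.where(rng.random(m) < 0.3, -1, 1)
    if abs(labels.sum()) == m:
        labels[0] *= -1
    bidx = rng.choice(m, size=mbar, replace=False)
    if len(set(labels[bidx])) < 2:
        bidx[0] = int(np.where(labels != labels[bidx[1]])[0][0])
    pool = TrainingPool(A=A, labels=labels)
    basis = BasisSet(Abar=A[bidx], labels=labels[bidx])
    return pool, basis


def qp_oracle(problem):
    """Generic constrained QP solve of the reduced-SVM primal.

    Variables (w, y); minimize 1/2 ||w||^2 + 1/2 y' diag(c) y subject to
    H w + y >= e, y >= 0.
    """
    H, c = problem.H, problem.row_costs
    m, nv = H.shape

    def obj(z):
        w, y = z[:nv], z[nv:]
        return 0.5 * w @ w + 0.5 * c @ (y * y)

    def grad(z):
        return np.concatenate([z[:nv], c * z[nv:]])

    Amat = np.hstack([H, np.eye(m)])
    res = minimize(
        obj,
        np.zeros(nv + m),
        jac=grad,
        method="SLSQP",
        bounds=[(None, None)] * nv + [(0, None)] * m,
        constraints=[LinearConstraint(Amat, 1.0, np.inf)],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success, res.message
    return res.fun, res.x[:nv]


class TestAssembleProblem:
    def test_two_point_linear_limit_reduces_to_data_matrix(self):
        # tiny mu: kernel ~ 1 - mu ||x-y||^2; at mu -> 0 the kernel block
        # degenerates to all-ones, so H rows are d_i * [dbar_j ..., -1]
        A = np.array([[0.0, 0.0], [1.0, 0.0]])
        labels = np.array([-1, 1])
        pool = TrainingPool(A=A, labels=labels)
        basis = BasisSet(Abar=A, labels=labels)
        prob = assemble_problem(pool, basis, KernelParams(mu=1e-14))
        expected = np.array([[1.0, -1.0, 1.0], [-1.0, 1.0, -1.0]])
        np.testing.assert_allclose(prob.H, expected, atol=1e-9)

    def test_nu_positive_and_certified(self, rng):
        pool, basis = random_instance(rng)
        prob = assemble_problem(pool, basis, KernelParams(mu=0.5),
                                SolverParams(nu_factor=2.0))
        assert prob.nu > 0
        # nu = 2 ||H||_2^2 certifies I - H H'/nu positive definite
        eigs = np.linalg.eigvalsh(
            np.eye(prob.H.shape[0]) - prob.H @ prob.H.T / prob.nu
        )
        assert eigs.min() > 0

    def test_objective_matches_naive_arithmetic(self, rng):
        pool, basis = random_instance(rng, m=30, mbar=8)
        params = SolverParams(C_pos=1.5, C_neg=4.0)
        prob = assemble_problem(pool, basis, KernelParams(mu=0.5), params)
        w = rng.normal(size=prob.n_vars)
        # naive evaluation straight from the definition
        naive = 0.5 * w @ w
        for i in range(pool.m):
            ki = np.array(
                [gaussian_kernel(pool.A[i], b, prob.kernel) for b in basis.Abar]
            )
            margin = pool.labels[i] * (
                ki @ (basis.labels * w[:-1]) - w[-1]
            )
            slack = max(0.0, 1.0 - margin)
            cost = 1.5 if pool.labels[i] == 1 else 4.0
            naive += 0.5 * cost * slack**2
        assert prob.objective(w) == pytest.approx(naive, rel=1e-10)

    def test_single_class_pool_errors(self, rng):
        A = rng.normal(size=(10, 4))
        pool = TrainingPool(A=A, labels=np.ones(10, dtype=int))
        basis = BasisSet(Abar=A[:4], labels=np.array([1, 1, -1, -1]))
        with pytest.raises(ValueError, match="both"):
            assemble_problem(pool, basis, KernelParams(mu=1.0))

    def test_balanced_default_costs_follow_class_ratio(self, rng):
        pool, basis = random_instance(rng, m=40)
        prob = assemble_problem(pool, basis, KernelParams(mu=1.0))
        c_nat = prob.row_costs[pool.labels == -1][0]
        c_dec = prob.row_costs[pool.labels == 1][0]
        # native cost : decoy cost = #decoys : #natives
        assert c_nat / c_dec == pytest.approx(
            pool.n_decoys / pool.n_natives
        )


class TestNewtonSolver:
    def test_oracle_equivalence_on_random_instances(self):
        """>= 20 random instances: objective within 1e-6 relative and
        fitness values within 1e-5 of a generic QP solve."""
        rng = np.random.default_rng(20240811)
        for trial in range(20):
            pool, basis = random_instance(rng)
            params = SolverParams(cost_scale=float(rng.uniform(0.5, 5.0)))
            prob = assemble_problem(pool, basis, KernelParams(mu=0.5), params)
            state = solve_newton(prob, params)
            assert state.converged
            obj_oracle, w_oracle = qp_oracle(prob)
            rel_gap = abs(state.objective - obj_oracle) / max(1.0, abs(obj_oracle))
            assert rel_gap <= 1e-6
            # fitness values from both solutions agree
            model = FitnessModel(basis=basis, u=state.w[:-1],
                                 gamma=float(state.w[-1]), kernel=prob.kernel)
            oracle_model = FitnessModel(basis=basis, u=w_oracle[:-1],
                                        gamma=float(w_oracle[-1]),
                                        kernel=prob.kernel)
            np.testing.assert_allclose(
                fitness(model, pool.A), fitness(oracle_model, pool.A),
                atol=1e-5,
            )

    def test_objective_monotone_and_finite_termination(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pool, basis = random_instance(rng, m=int(rng.integers(50, 201)))
            prob = assemble_problem(pool, basis, KernelParams(mu=0.5))
            state = solve_newton(prob)
            assert state.converged and state.n_iter <= 100
            path = state.objective_path
            assert all(b <= a + 1e-12 for a, b in zip(path, path[1:]))

    def test_quadratic_exactness_when_active_set_is_stable(self):
        # weak costs keep every margin violated at the start and at the
        # optimum, so the first Newton step is exact and the second stops
        rng = np.random.default_rng(3)
        pool, basis = random_instance(rng, m=30, mbar=6)
        params = SolverParams(C_pos=0.01, C_neg=0.01)
        prob = assemble_problem(pool, basis, KernelParams(mu=0.5), params)
        state = solve_newton(prob, params)
        assert state.converged
        assert state.n_iter <= 2

    def test_two_point_separable_toy(self):
        pool = TrainingPool(A=np.array([[0.0, 0.0], [2.0, 0.0]]),
                            labels=np.array([-1, 1]))
        basis = BasisSet(Abar=pool.A, labels=pool.labels)
        kernel = KernelParams(mu=1.0)
        params = SolverParams(C_pos=100.0, C_neg=100.0)
        model, state = train_model(pool, basis, kernel, params)
        assert state.converged
        f = fitness(model, pool.A)
        assert f[0] < -1e-8 and f[1] > 1e-8

    def test_dual_iterate_nonnegative(self, rng):
        pool, basis = random_instance(rng)
        prob = assemble_problem(pool, basis, KernelParams(mu=0.5))
        state = solve_newton(prob)
        assert np.all(state.dual >= 0)

    def test_max_iter_flags_nonconvergence(self, rng):
        pool, basis = random_instance(rng)
        params = SolverParams(max_iter=1, grad_tol=1e-300)
        prob = assemble_problem(pool, basis, KernelParams(mu=0.5), params)
        state = solve_newton(prob, params)
        assert not state.converged

    def test_class_weight_monotonicity(self):
        """Raising the native-side cost never increases misclassified
        natives on the training pool."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            pool, basis = random_instance(rng, m=60, mbar=12)
            mis = []
            for c_neg in (0.1, 1.0, 10.0, 100.0):
                params = SolverParams(C_pos=1.0, C_neg=c_neg)
                model, _ = train_model(pool, basis, KernelParams(mu=0.5), params)
                f = fitness(model, pool.A[pool.labels == -1])
                mis.append(int(np.sum(f > 0)))
            assert all(b <= a for a, b in zip(mis, mis[1:]))


class TestFitness:
    def test_u_zero_gives_constant_minus_gamma(self, rng):
        _, basis = random_instance(rng, m=20, mbar=6)
        model = FitnessModel(basis=basis, u=np.zeros(basis.mbar), gamma=0.7,
                             kernel=KernelParams(mu=1.0))
        np.testing.assert_allclose(
            fitness(model, rng.normal(size=(5, 6))), -0.7
        )

    def test_single_term_limit_at_large_mu(self, rng):
        _, basis = random_instance(rng, m=20, mbar=6)
        u = np.zeros(basis.mbar)
        k = int(np.where(basis.labels == -1)[0][0])
        u[k] = 2.5
        model = FitnessModel(basis=basis, u=u, gamma=0.3,
                             kernel=KernelParams(mu=1e6))
        f = float(fitness(model, basis.Abar[k][None, :])[0])
        assert f == pytest.approx(-2.5 - 0.3, abs=1e-8)

    def test_matches_naive_summation(self, rng):
        pool, basis = random_instance(rng, m=20, mbar=6)
        model, _ = train_model(pool, basis, KernelParams(mu=0.5))
        X = rng.normal(size=(8, 6))
        naive = np.array([
            sum(
                basis.labels[j] * model.u[j]
                * gaussian_kernel(x, basis.Abar[j], model.kernel)
                for j in range(basis.mbar)
            ) - model.gamma
            for x in X
        ])
        np.testing.assert_allclose(fitness(model, X), naive, rtol=1e-10)

    def test_dimension_mismatch_errors(self, rng):
        pool, basis = random_instance(rng, m=20, mbar=6)
        model, _ = train_model(pool, basis, KernelParams(mu=0.5))
        with pytest.raises(ValueError, match="mismatch"):
            fitness(model, np.zeros((2, 7)))


class TestClassifyAndRank:
    def test_empty_input_errors(self, rng):
        pool, basis = random_instance(rng, m=20, mbar=6)
        model, _ = train_model(pool, basis, KernelParams(mu=0.5))
        with pytest.raises(ValueError, match="empty"):
            classify(model, np.empty((0, 6)))

    def test_design_rank_strictness(self, rng):
        _, basis = random_instance(rng, m=20, mbar=6)
        model = FitnessModel(basis=basis, u=np.zeros(basis.mbar), gamma=0.0,
                             kernel=KernelParams(mu=1.0))
        # constant-zero fitness: every comparison ties -> failure
        assert not design_rank_success(model, np.zeros(6), np.ones((3, 6)))

    def test_separable_landscape_ranks_native_first(self):
        rng = np.random.default_rng(5)
        center = rng.normal(size=6)
        natives = center + 0.05 * rng.normal(size=(10, 6))
        decoys = center + 2.0 + 0.05 * rng.normal(size=(40, 6))
        A = np.vstack([natives, decoys])
        labels = np.array([-1] * 10 + [1] * 40)
        pool = TrainingPool(A=A, labels=labels)
        basis = BasisSet(Abar=A[::3], labels=labels[::3])
        model, _ = train_model(pool, basis, KernelParams(mu=0.5))
        for k in range(10):
            assert design_rank_success(model, natives[k], decoys)


class TestSerialization:
    def test_round_trip_is_value_exact(self, rng, tmp_path):
        pool, basis = random_instance(rng, m=25, mbar=7)
        model, _ = train_model(
            pool, basis, KernelParams(mu=0.5),
            length_model=None,
            provenance={"strategy": 2, "round": 3, "seed": 99},
        )
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        np.testing.assert_array_equal(loaded.u, model.u)
        np.testing.assert_array_equal(loaded.basis.Abar, model.basis.Abar)
        np.testing.assert_array_equal(loaded.basis.labels, model.basis.labels)
        assert loaded.gamma == model.gamma
        assert loaded.kernel.mu == model.kernel.mu
        assert loaded.provenance["strategy"] == 2

    def test_identical_inputs_give_bit_identical_models(self, tmp_path):
        for d in ("a", "b"):
            rng = np.random.default_rng(123)
            pool, basis = random_instance(rng, m=25, mbar=7)
            model, _ = train_model(pool, basis, KernelParams(mu=0.5))
            save_model(model, tmp_path / d)
        assert (tmp_path / "a" / "meta.json").read_bytes() == (
            tmp_path / "b" / "meta.json"
        ).read_bytes()
        a = np.load(tmp_path / "a" / "arrays.npz")
        b = np.load(tmp_path / "b" / "arrays.npz")
        for key in a.files:
            assert a[key].tobytes() == b[key].tobytes()
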