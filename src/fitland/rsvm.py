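"""Reduced SVM training by a finite Newton method, and fitness evaluation.

The fitness function has the form

    f(x) = K(x, Abar') Dbar u - gamma

with K a Gaussian kernel, Abar a small basis set of mbar contact
vectors with class signs Dbar (natives -1, decoys +1), coefficients u
and bias gamma.  Natives should score negative (an energy: lower is
fitter), decoys positive.

Training solves the reduced SVM quadratic program: find w = [u; gamma]
minimizing

    1/2 ||w||^2  +  1/2 sum_i c_i [(1 - (H w)_i)_+]^2

where H = D [K(A, Abar') Dbar, -e] stacks the class-signed kernel rows
of the full training pool with a bias column, c_i are per-row
misclassification costs (class-weighted so errors on the minority
native class outweigh errors on decoys), and (.)_+ zeroes negative
components.  The 2-norm penalty on the slack makes the explicit
non-negativity constraint on the slack redundant, so the program
collapses to this unconstrained, strongly convex, piecewise-quadratic
problem in only mbar + 1 variables.  It is minimized by a generalized
Newton iteration: the generalized Hessian I + H' diag(c * step) H is
factored by LU, the step length follows the Armijo backtracking rule,
and the iteration terminates in a finite number of steps.  The square
m x m kernel matrix is never formed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import scipy.linalg

from fitland.contacts import LengthModel
from fitland.kernel import KernelParams, rect_kernel

NATIVE_LABEL = -1
DECOY_LABEL = 1


def _check_labeled(A: np.ndarray, labels: np.ndarray, what: str) -> None:
    if A.ndim != 2:
        raise ValueError(f"{what} matrix must be 2-D")
    if labels.shape != (A.shape[0],):
        raise ValueError(f"{what} labels must match rows of the matrix")
    if not set(np.unique(labels)) <= {-1, 1}:
        raise ValueError(f"{what} labels must be in {{-1, +1}}")


@dataclass
class TrainingPool:
    """Labeled pool of contact vectors (the data matrix of the QP)."""

    A: np.ndarray
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        _check_labeled(self.A, self.labels, "pool")
        if not self.ids:
            self.ids = [f"row{i}" for i in range(self.A.shape[0])]

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n_natives(self) -> int:
        return int(np.sum(self.labels == NATIVE_LABEL))

    @property
    def n_decoys(self) -> int:
        return int(np.sum(self.labels == DECOY_LABEL))


@dataclass
class BasisSet:
    """The reduced basis parameterizing the fitness function."""

    Abar: np.ndarray
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Abar = np.asarray(self.Abar, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        _check_labeled(self.Abar, self.labels, "basis")
        if self.Abar.shape[0] < 2:
            raise ValueError("basis needs at least 2 vectors")
        if len(set(np.unique(self.labels))) < 2:
            raise ValueError("basis must contain both classes")
        if not self.ids:
            self.ids = [f"basis{i}" for i in range(self.Abar.shape[0])]

    @property
    def mbar(self) -> int:
        return self.Abar.shape[0]


@dataclass(frozen=True)
class SolverParams:
    """Newton solver and cost configuration.

    ``C_pos`` / ``C_neg`` are the misclassification costs of the decoy
    (+1) and native (-1) rows.  When left ``None`` they default to the
    balanced weighting cost_scale * m / (2 * class size), which makes
    the cost ratio C_pos : C_neg equal to #natives : #decoys so the
    minority native class outweighs the decoys.  ``nu_factor`` (> 1)
    scales the certificate parameter nu = nu_factor * ||H||_2^2 that
    bounds the problem curvature.  ``armijo_delta`` in (0, 1/2) is the
    sufficient-decrease fraction of the backtracking line search;
    ``grad_tol`` defaults to 1e-8 * (mbar + 1).
    """

    C_pos: float | None = None
    C_neg: float | None = None
    cost_scale: float = 1.0
    nu_factor: float = 2.0
    armijo_delta: float = 0.25
    grad_tol: float | None = None
    max_iter: int = 100

    def __post_init__(self) -> None:
        for name in ("C_pos", "C_neg"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive")
        if not self.cost_scale > 0:
            raise ValueError("cost_scale must be positive")
        if not self.nu_factor > 1:
            raise ValueError("nu_factor must be > 1")
        if not 0 < self.armijo_delta < 0.5:
            raise ValueError("armijo_delta must be in (0, 1/2)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Problem:
    """Assembled reduced-SVM problem: H w >= e - y with weighted slack."""

    H: np.ndarray            # m x (mbar + 1): class-signed kernel rows + bias col
    row_costs: np.ndarray    # m
    nu: float                # nu_factor * ||H||_2^2 (SVD 2-norm)
    pool: TrainingPool
    basis: BasisSet
    kernel: KernelParams
    params: SolverParams

    @property
    def n_vars(self) -> int:
        return self.H.shape[1]

    def objective(self, w: np.ndarray) -> float:
        r = 1.0 - self.H @ w
        rp = np.maximum(r, 0.0)
        return 0.5 * float(w @ w) + 0.5 * float(self.row_costs @ (rp * rp))

    def gradient(self, w: np.ndarray) -> np.ndarray:
        r = 1.0 - self.H @ w
        rp = np.maximum(r, 0.0)
        return w - self.H.T @ (self.row_costs * rp)


@dataclass
class NewtonState:
    """Converged (or flagged) state of the Newton iteration."""

    w: np.ndarray            # primal [u; gamma]
    dual: np.ndarray         # c * (e - Hw)_+, non-negative by construction
    objective: float
    gradient: np.ndarray
    n_iter: int
    converged: bool
    objective_path: list[float] = field(default_factory=list)


def class_costs(pool: TrainingPool, params: SolverParams) -> tuple[float, float]:
    """Effective (C_pos, C_neg) after balanced-weight defaulting."""
    m = pool.m
    c_pos = params.C_pos
    c_neg = params.C_neg
    if c_pos is None:
        c_pos = params.cost_scale * m / (2.0 * pool.n_decoys)
    if c_neg is None:
        c_neg = params.cost_scale * m / (2.0 * pool.n_natives)
    return float(c_pos), float(c_neg)


def assemble_problem(
    pool: TrainingPool,
    basis: BasisSet,
    kernel: KernelParams,
    params: SolverParams | None = None,
) -> Problem:
    """Build the class-signed kernel matrix H and per-row costs.

    H = D [K(A, Abar') Dbar, -e]; the m x m dual matrix I/nu + H H' is
    never materialized — everything downstream works with H itself.
    nu is computed from the SVD 2-norm of H.
    """
    params = params or SolverParams()
    if pool.n_natives == 0 or pool.n_decoys == 0:
        raise ValueError("training pool must contain both natives and decoys")
    if pool.A.shape[1] != basis.Abar.shape[1]:
        raise ValueError("pool and basis dimension mismatch")
    if basis.mbar > pool.m:
        warnings.warn(
            f"basis ({basis.mbar}) larger than pool ({pool.m}); the reduced "
            "formulation expects mbar <= m",
            stacklevel=2,
        )
    K = rect_kernel(pool.A, basis.Abar, kernel)
    d = pool.labels.astype(float)
    H = np.empty((pool.m, basis.mbar + 1))
    H[:, :-1] = d[:, None] * K * basis.labels.astype(float)[None, :]
    H[:, -1] = -d
    c_pos, c_neg = class_costs(pool, params)
    costs = np.where(pool.labels == DECOY_LABEL, c_pos, c_neg)
    norm2 = float(np.linalg.svd(H, compute_uv=False)[0])
    nu = params.nu_factor * norm2**2
    return Problem(
        H=H, row_costs=costs, nu=nu, pool=pool, basis=basis,
        kernel=kernel, params=params,
    )


def solve_newton(
    problem: Problem,
    params: SolverParams | None = None,
    start: np.ndarray | None = None,
) -> NewtonState:
    """Minimize the piecewise-quadratic reduced-SVM objective.

    Generalized Newton iteration: at each step the linear system of the
    generalized Hessian I + H' diag(c * s) H (s the step function of
    the positive slacks: 1 where 1 - Hw > 0, else 0) is solved by LU
    with partial pivoting for the Newton direction, and the step length
    halves under the Armijo rule until the decrease exceeds
    armijo_delta times the predicted linear decrease.  Terminates when
    the gradient norm falls below grad_tol, with finite termination
    guaranteed by the piecewise-quadratic structure.
    """
    params = params or problem.params
    n = problem.n_vars
    tol = params.grad_tol if params.grad_tol is not None else 1e-8 * n
    w = np.zeros(n) if start is None else np.asarray(start, dtype=float).copy()
    if w.shape != (n,):
        raise ValueError(f"start vector must have shape ({n},)")
    H, c = problem.H, problem.row_costs
    obj = problem.objective(w)
    path = [obj]
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        r = 1.0 - H @ w
        active = r > 0
        grad = w - H.T @ (c * np.where(active, r, 0.0))
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                f"non-finite gradient at Newton iteration {n_iter}"
            )
        if float(np.linalg.norm(grad)) <= tol:
            converged = True
            break
        Ha = H[active] * np.sqrt(c[active])[:, None]
        hess = np.eye(n) + Ha.T @ Ha
        lu, piv = scipy.linalg.lu_factor(hess)
        direction = scipy.linalg.lu_solve((lu, piv), -grad)
        slope = float(grad @ direction)  # < 0: Hessian is positive definite
        step = 1.0
        for _ in range(60):
            cand = w + step * direction
            cand_obj = problem.objective(cand)
            if cand_obj <= obj + params.armijo_delta * step * slope:
                break
            step *= 0.5
        else:
            raise FloatingPointError(
                f"Armijo backtracking failed at Newton iteration {n_iter}"
            )
        w = cand
        if not np.all(np.isfinite(w)):
            raise FloatingPointError(
                f"non-finite iterate at Newton iteration {n_iter}"
            )
        obj = cand_obj
        path.append(obj)
    r = 1.0 - H @ w
    grad = problem.gradient(w)
    state = NewtonState(
        w=w,
        dual=c * np.maximum(r, 0.0),
        objective=problem.objective(w),
        gradient=grad,
        n_iter=n_iter,
        converged=converged or float(np.linalg.norm(grad)) <= tol,
        objective_path=path,
    )
    return state


@dataclass
class FitnessModel:
    """Trained fitness function f(x) = K(x, Abar') Dbar u - gamma."""

    basis: BasisSet
    u: np.ndarray
    gamma: float
    kernel: KernelParams
    length_model: LengthModel | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (self.basis.mbar,):
            raise ValueError("coefficient vector must match basis size")
        if not (np.all(np.isfinite(self.u)) and np.isfinite(self.gamma)):
            raise ValueError("model coefficients must be finite")


def train_model(
    pool: TrainingPool,
    basis: BasisSet,
    kernel: KernelParams,
    params: SolverParams | None = None,
    length_model: LengthModel | None = None,
    provenance: dict[str, Any] | None = None,
) -> tuple[FitnessModel, NewtonState]:
    """Assemble and solve the reduced SVM; return the fitness model."""
    params = params or SolverParams()
    problem = assemble_problem(pool, basis, kernel, params)
    state = solve_newton(problem, params)
    model = FitnessModel(
        basis=basis,
        u=state.w[:-1],
        gamma=float(state.w[-1]),
        kernel=kernel,
        length_model=length_model,
        provenance=dict(provenance or {}),
    )
    model.provenance.setdefault("newton_iterations", state.n_iter)
    model.provenance.setdefault("converged", bool(state.converged))
    return model, state


def fitness(model: FitnessModel, X: np.ndarray) -> np.ndarray:
    """Fitness values of contact vectors (rows of X); lower = more native."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.basis.Abar.shape[1]:
        raise ValueError(
            f"dimension mismatch: vectors {X.shape[1]} vs basis "
            f"{model.basis.Abar.shape[1]}"
        )
    K = rect_kernel(X, model.basis.Abar, model.kernel)
    return K @ (model.basis.labels.astype(float) * model.u) - model.gamma


def classify(model: FitnessModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sign classification: label +1 (decoy-like) iff fitness > 0."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty input")
    f = fitness(model, X)
    labels = np.where(f > 0, DECOY_LABEL, NATIVE_LABEL)
    return labels, f


def design_rank_success(
    model: FitnessModel, native_vector: np.ndarray, decoy_matrix: np.ndarray
) -> bool:
    """True iff the native scores strictly lowest among itself and its decoys.

    Ties count as failure: the designed sequence must be uniquely best.
    """
    f_native = float(fitness(model, np.atleast_2d(native_vector))[0])
    f_decoys = fitness(model, decoy_matrix)
    if f_decoys.size == 0:
        raise ValueError("native has no decoys to rank against")
    return bool(f_native < float(np.min(f_decoys)))


def save_model(model: FitnessModel, path: str | Path) -> None:
    """Serialize to a directory: meta.json + arrays.npz."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "fitland-model-v1",
        "kernel": {"mu": model.kernel.mu},
        "gamma": model.gamma,
        "label_convention": {"native": NATIVE_LABEL, "decoy": DECOY_LABEL},
        "length_model": (
            None
            if model.length_model is None
            else {"a": model.length_model.a, "b": model.length_model.b}
        ),
        "provenance": model.provenance,
        "basis_ids": model.basis.ids,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    np.savez(
        path / "arrays.npz",
        Abar=model.basis.Abar,
        basis_labels=model.basis.labels,
        u=model.u,
    )


def load_model(path: str | Path) -> FitnessModel:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format") != "fitland-model-v1":
        raise ValueError(f"unrecognized model container at {path}")
    arrays = np.load(path / "arrays.npz")
    basis = BasisSet(
        Abar=arrays["Abar"],
        labels=arrays["basis_labels"],
        ids=list(meta["basis_ids"]),
    )
    lm = meta["length_model"]
    return FitnessModel(
        basis=basis,
        u=arrays["u"],
        gamma=float(meta["gamma"]),
        kernel=KernelParams(mu=float(meta["kernel"]["mu"])),
        length_model=None if lm is None else LengthModel(a=lm["a"], b=lm["b"]),
        provenance=meta["provenance"],
    )
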