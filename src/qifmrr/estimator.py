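"""QIF-MRr and ridge rQIF-MRr estimation.

The estimating equations stack, for each basis matrix M_l, the score

    g_i^(l)(theta) = J_i^T D_i^{-1/2} M_l D_i^{-1/2} (Y_i - h_i(theta))

over subjects i, where J_i is the p x K Jacobian of the mean model h and
D_i the diagonal marginal-variance matrix.  With m basis matrices there are
m*p moment conditions for p parameters, so the parameters are estimated by
generalized method of moments: minimize the quadratic inference function

    Q_n(theta) = g_n^T C_n^{-1} g_n,
    g_n = (1/n) sum_i g_i,   C_n = (1/n^2) sum_i g_i g_i^T.

The ridge variant adds an L2 penalty, rQ_n = Q_n + lambda * ||theta||^2,
which stabilizes the near-singular directions that arise when regret
parameters are weakly identified.  Minimization uses derivative-free
Nelder-Mead (the mean model has an absolute-value kink in psi).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import numpy.typing as npt
from scipy.optimize import minimize

from .correlation import CorrelationBasis, basis_for_structure
from .model import (
    Cohort,
    ResidualMatrix,
    StateResidualModel,
    ThetaParams,
    mean_model_jacobian,
    mean_response,
    state_residuals,
)

__all__ = [
    "MarginalVarianceSpec",
    "QifComponents",
    "FitResult",
    "subject_score",
    "extended_score",
    "qif_objective",
    "ridge_objective",
    "fit",
    "fit_structure",
    "select_lambda_cv",
]

PINV_RTOL = 1e-10


@dataclass(frozen=True)
class MarginalVarianceSpec:
    """Marginal variances on the diagonal of D_i.

    ``identity`` (the default) sets D = I; the objective is invariant to any
    constant rescaling of D, so this covers the constant-variance case with
    no loss.  ``known_sigma2`` uses a supplied constant, ``estimated`` uses
    per-visit sample variances of the response residuals at the starting
    value, held fixed during optimization.
    """

    mode: Literal["identity", "known_sigma2", "estimated"] = "identity"
    sigma2: float | None = None

    def __post_init__(self):
        if self.mode == "known_sigma2":
            if self.sigma2 is None or self.sigma2 <= 0:
                raise ValueError("known_sigma2 mode needs sigma2 > 0")

    def d_inv_sqrt(self, cohort: Cohort, Z: npt.NDArray, theta0: ThetaParams) -> npt.NDArray:
        """1/sqrt(diagonal of D) as a length-K vector, broadcast over subjects."""
        K = cohort.K
        if self.mode == "identity":
            return np.ones(K)
        if self.mode == "known_sigma2":
            return np.full(K, 1.0 / np.sqrt(self.sigma2))
        if self.mode == "estimated":
            r = cohort.responses - mean_response(Z, cohort.states, cohort.actions, theta0)
            v = r.var(axis=0, ddof=1)
            if np.any(v <= 0):
                raise ValueError("estimated per-visit variances must be positive")
            return 1.0 / np.sqrt(v)
        raise ValueError(f"unknown marginal-variance mode {self.mode!r}")


@dataclass
class QifComponents:
    """Per-subject scores g_i, their average g_n and the GMM weight C_n."""

    g_i: npt.NDArray[np.float64]  # (n, m*p)
    g_n: npt.NDArray[np.float64]  # (m*p,)
    C_n: npt.NDArray[np.float64]  # (m*p, m*p)


@dataclass
class FitResult:
    """A minimizer of the (penalized) quadratic inference function."""

    theta_hat: ThetaParams
    objective_value: float
    lam: float
    structure: str
    converged: bool
    n_evaluations: int
    start_theta: ThetaParams
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {name: getattr(self.theta_hat, name)
             for name in ("beta0", "beta1", "psi1", "psi2", "psi3")}
        d.update(
            objective_value=self.objective_value,
            **{"lambda": self.lam},
            structure=self.structure,
            converged=self.converged,
            n_evaluations=self.n_evaluations,
            start_theta=list(self.start_theta.to_array()),
            seed=self.seed,
        )
        return d


class _QifDesign:
    """Precomputed arrays for fast repeated evaluation of the extended score.

    The per-subject score blocks never need the explicit Jacobian: with
    u_l = D^{-1/2} M_l D^{-1/2} (Y - h), component v of block l is the
    rowwise dot product of Jacobian row v with u_l, and every Jacobian row
    is a simple elementwise expression in (Z, S, A, theta).
    """

    def __init__(self, cohort: Cohort, Z: npt.NDArray, basis: CorrelationBasis,
                 dspec: MarginalVarianceSpec, theta_ref: ThetaParams,
                 psi1_derivative_mode: str = "paper"):
        if cohort.n < 2:
            raise ValueError("the GMM weight C_n needs n >= 2 subjects")
        self.S = cohort.states
        self.A = cohort.actions
        self.Y = cohort.responses
        self.Z = np.asarray(Z, dtype=float)
        if self.Z.shape != self.S.shape:
            raise ValueError("residual matrix Z must match the cohort shape")
        self.n, self.K = self.S.shape
        self.m = basis.m
        self.mode = psi1_derivative_mode
        dhalf = dspec.d_inv_sqrt(cohort, self.Z, theta_ref)  # (K,)
        # fold D^{-1/2} into the bases once: u_l = (D^{-1/2} M_l D^{-1/2}) r
        M_scaled = basis.stacked() * dhalf[None, :, None] * dhalf[None, None, :]
        # (K, m*K) layout so all m products r @ M_l run as one matmul
        self.M_flat = np.ascontiguousarray(
            M_scaled.transpose(1, 0, 2).reshape(self.K, self.m * self.K)
        )
        # reusable buffers: rows 0/1 of the Jacobian stack never change
        self._V = np.empty((self.n, self.K, 4))
        self._V[:, :, 0] = 1.0
        self._V[:, :, 1] = self.Z
        self._G = np.empty((self.n, self.m, 5))

    def _score_matrix_arr(self, x: npt.NDArray) -> npt.NDArray[np.float64]:
        beta0, beta1, psi1, psi2, psi3 = x
        S, A, Z = self.S, self.A, self.Z
        d = A - psi2 - psi3 * S
        absd = np.abs(d)
        I = np.where(d >= 0, 1.0, -1.0)
        # same evaluation order as mean_response, so a cohort built from the
        # mean model yields exactly zero residuals (and Q_n exactly 0)
        r = self.Y - (beta0 + beta1 * Z - psi1 * absd)
        u = (r @ self.M_flat).reshape(self.n, self.m, self.K)  # u[i,l] = M_l r_i
        # Jacobian rows as a (n, K, 4) stack; one batched matmul gives all
        # rowwise dot products J_v . u_l at once.
        V = self._V
        V[:, :, 2] = I
        V[:, :, 3] = S * I
        uv = u @ V  # (n, m, 4)
        G = self._G
        G[:, :, 0] = uv[:, :, 0]
        G[:, :, 1] = uv[:, :, 1]
        if self.mode == "paper":
            G[:, :, 2] = -uv[:, :, 2]
        else:
            G[:, :, 2] = -np.einsum("nk,nlk->nl", absd, u)
        G[:, :, 3] = psi1 * uv[:, :, 2]
        G[:, :, 4] = psi1 * uv[:, :, 3]
        return G.reshape(self.n, self.m * 5)

    def score_matrix(self, theta: ThetaParams) -> npt.NDArray[np.float64]:
        """(n, m*p) matrix of per-subject scores, block l major, theta order minor."""
        return self._score_matrix_arr(theta.to_array()).copy()  # detach from buffer

    def components(self, theta: ThetaParams) -> QifComponents:
        G = self.score_matrix(theta)
        g_n = G.mean(axis=0)
        C_n = G.T @ G / self.n**2
        return QifComponents(g_i=G, g_n=g_n, C_n=C_n)

    def qn_arr(self, x: npt.NDArray) -> float:
        G = self._score_matrix_arr(np.asarray(x, dtype=float))
        g = G.sum(axis=0)  # n * g_n; the 1/n factors cancel in Q_n
        C = G.T @ G
        # pseudoinverse quadratic form via the eigendecomposition of the
        # symmetric PSD weight (C_n is exactly singular under the published
        # -I regret-scale weight, whose score column is proportional to the
        # psi2 column)
        w, v = np.linalg.eigh(C)
        keep = w > PINV_RTOL * max(w[-1], 0.0)
        if not np.any(keep):
            return 0.0
        proj = v[:, keep].T @ g
        q = float(np.sum(proj**2 / w[keep]))
        return max(q, 0.0)

    def qn(self, theta: ThetaParams) -> float:
        return self.qn_arr(theta.to_array())


def _resolve_Z(cohort: Cohort, Z) -> npt.NDArray[np.float64]:
    if Z is None:
        return state_residuals(cohort, method="regressed").Z
    if isinstance(Z, ResidualMatrix):
        return Z.Z
    return np.asarray(Z, dtype=float)


def subject_score(
    trajectory: tuple,
    theta: ThetaParams,
    basis: CorrelationBasis,
    dspec: MarginalVarianceSpec = MarginalVarianceSpec(),
    psi1_derivative_mode: str = "paper",
) -> npt.NDArray[np.float64]:
    """Extended score g_i for a single subject.

    ``trajectory`` is a tuple (S, A, Y, Z) of length-K vectors.  Block l of
    the returned length m*p vector is J^T D^{-1/2} M_l D^{-1/2} (Y - h).
    """
    S, A, Y, Z = (np.asarray(x, dtype=float).reshape(1, -1) for x in trajectory)
    h = mean_response(Z, S, A, theta)
    J = mean_model_jacobian(Z, S, A, theta, psi1_derivative_mode)[0]  # (p, K)
    r = (Y - h)[0]
    K = S.shape[1]
    if dspec.mode == "identity":
        dhalf = np.ones(K)
    elif dspec.mode == "known_sigma2":
        dhalf = np.full(K, 1.0 / np.sqrt(dspec.sigma2))
    else:
        raise ValueError("per-visit estimated variances are cohort-level; "
                         "use extended_score")
    blocks = [J @ (dhalf[:, None] * M * dhalf[None, :]) @ r for M in basis.matrices]
    return np.concatenate(blocks)


def extended_score(
    cohort: Cohort,
    theta: ThetaParams,
    basis: CorrelationBasis,
    dspec: MarginalVarianceSpec = MarginalVarianceSpec(),
    Z=None,
    psi1_derivative_mode: str = "paper",
) -> QifComponents:
    """All per-subject scores, their mean g_n and the weight C_n = (1/n^2) sum g_i g_i^T."""
    Zm = _resolve_Z(cohort, Z)
    design = _QifDesign(cohort, Zm, basis, dspec, theta, psi1_derivative_mode)
    return design.components(theta)


def qif_objective(
    theta: ThetaParams,
    cohort: Cohort,
    basis: CorrelationBasis,
    dspec: MarginalVarianceSpec = MarginalVarianceSpec(),
    Z=None,
    psi1_derivative_mode: str = "paper",
) -> float:
    """Q_n = g_n^T C_n^- g_n (Moore-Penrose pseudoinverse when C_n is singular)."""
    Zm = _resolve_Z(cohort, Z)
    design = _QifDesign(cohort, Zm, basis, dspec, theta, psi1_derivative_mode)
    return design.qn(theta)


def ridge_objective(
    theta: ThetaParams,
    cohort: Cohort,
    basis: CorrelationBasis,
    dspec: MarginalVarianceSpec = MarginalVarianceSpec(),
    lam: float = 0.0,
    Z=None,
    psi1_derivative_mode: str = "paper",
) -> float:
    """rQ_n = Q_n + lambda * sum_v theta_v^2; equals Q_n exactly at lambda = 0."""
    if lam < 0:
        raise ValueError(f"ridge penalty requires lambda >= 0, got {lam}")
    q = qif_objective(theta, cohort, basis, dspec, Z, psi1_derivative_mode)
    return q + lam * float(np.sum(theta.to_array() ** 2))


def fit(
    cohort: Cohort,
    basis: CorrelationBasis,
    dspec: MarginalVarianceSpec = MarginalVarianceSpec(),
    lam: float = 0.0,
    theta0: ThetaParams | Sequence[float] | None = None,
    Z=None,
    psi1_derivative_mode: str = "paper",
    optimizer_options: dict | None = None,
    seed: int | None = None,
) -> FitResult:
    """Minimize the (penalized) quadratic inference function by Nelder-Mead.

    The optimizer runs once from ``theta0`` and restarts once from the first
    solution (a cheap guard against premature simplex collapse at the regret
    kink).  Deterministic given (cohort, theta0, options).
    """
    if theta0 is None:
        raise ValueError("fit requires explicit starting values theta0")
    if lam < 0:
        raise ValueError(f"ridge penalty requires lambda >= 0, got {lam}")
    if not isinstance(theta0, ThetaParams):
        theta0 = ThetaParams.from_array(theta0)
    if not np.all(np.isfinite(theta0.to_array())):
        raise ValueError("starting values must be finite")

    Zm = _resolve_Z(cohort, Z)
    design = _QifDesign(cohort, Zm, basis, dspec, theta0, psi1_derivative_mode)
    theta_arr0 = theta0.to_array()

    def objective(x):
        return design.qn_arr(x) + lam * float(x @ x)

    f0 = objective(theta_arr0)
    if not np.isfinite(f0):
        raise FloatingPointError(
            f"objective is not finite at the starting values theta0={theta_arr0}"
        )

    options = dict(xatol=1e-8, fatol=1e-8, maxfev=5000, maxiter=5000)
    if optimizer_options:
        options.update(optimizer_options)
    res = minimize(objective, theta_arr0, method="Nelder-Mead", options=options)
    nfev = res.nfev
    # restart from the first solution with a small simplex: guards against
    # premature collapse without re-exploring from scratch
    delta = np.where(res.x != 0, 1e-3 * np.abs(res.x), 1e-4)
    simplex = np.vstack([res.x, res.x + np.diag(delta)])
    res2 = minimize(objective, res.x, method="Nelder-Mead",
                    options={**options, "initial_simplex": simplex})
    nfev += res2.nfev
    best = res2 if res2.fun <= res.fun else res
    return FitResult(
        theta_hat=ThetaParams(*best.x),
        objective_value=float(best.fun),
        lam=lam,
        structure=basis.label,
        converged=bool(res2.success),
        n_evaluations=int(nfev),
        start_theta=theta0,
        seed=seed,
    )


def fit_structure(
    cohort: Cohort,
    structure: str,
    dspec: MarginalVarianceSpec = MarginalVarianceSpec(),
    lam: float = 0.0,
    theta0: ThetaParams | Sequence[float] | None = None,
    Z=None,
    psi1_derivative_mode: str = "paper",
    optimizer_options: dict | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit with the basis for a named structure token (``ar1`` | ``exchangeable`` | ``unspecified``).

    The ``unspecified`` structure needs residuals to build its empirical
    basis matrix U_hat; these are taken at a pilot fit under the
    independence (identity-only) basis and then held fixed.
    """
    Zm = _resolve_Z(cohort, Z)
    if structure == "unspecified":
        pilot_basis = CorrelationBasis(label="independence", matrices=(np.eye(cohort.K),))
        pilot = fit(cohort, pilot_basis, dspec, lam, theta0, Z=Zm,
                    psi1_derivative_mode=psi1_derivative_mode,
                    optimizer_options=optimizer_options)
        resid = cohort.responses - mean_response(
            Zm, cohort.states, cohort.actions, pilot.theta_hat
        )
        basis = basis_for_structure("unspecified", cohort.K, residuals=resid)
    else:
        basis = basis_for_structure(structure, cohort.K)
    return fit(cohort, basis, dspec, lam, theta0, Z=Zm,
               psi1_derivative_mode=psi1_derivative_mode,
               optimizer_options=optimizer_options, seed=seed)


def select_lambda_cv(
    cohort: Cohort,
    structure: str,
    dspec: MarginalVarianceSpec = MarginalVarianceSpec(),
    grid: Sequence[float] = (0.0, 1e-3, 1e-2, 1e-1, 1.0),
    folds: int = 5,
    seed: int = 0,
    theta0: ThetaParams | Sequence[float] | None = None,
    psi1_derivative_mode: str = "paper",
    optimizer_options: dict | None = None,
    return_errors: bool = False,
):
    """Subject-level k-fold cross-validation of the ridge tuning parameter.

    For each candidate lambda the model is fitted on the training folds
    (state-residual regressions refitted on the training subjects and
    applied to the held-out subjects) and scored by mean squared prediction
    error of the mean model on the held-out fold.  Returns the grid value
    with the smallest mean CV error; ties break toward the smallest lambda.
    """
    grid = sorted(float(l) for l in grid)
    if len(grid) == 0:
        raise ValueError("lambda grid must be non-empty")
    if any(l < 0 for l in grid):
        raise ValueError("lambda grid values must be >= 0")
    if not (2 <= folds <= cohort.n):
        raise ValueError(f"folds must be in [2, n={cohort.n}], got {folds}")
    if theta0 is None:
        raise ValueError("select_lambda_cv requires starting values theta0")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n)
    fold_ids = np.array_split(perm, folds)
    errors = np.zeros((len(grid), folds))
    for k, test_idx in enumerate(fold_ids):
        train_mask = np.ones(cohort.n, dtype=bool)
        train_mask[test_idx] = False
        train = Cohort(
            subject_ids=[cohort.subject_ids[i] for i in np.flatnonzero(train_mask)],
            states=cohort.states[train_mask],
            actions=cohort.actions[train_mask],
            responses=cohort.responses[train_mask],
        )
        test = Cohort(
            subject_ids=[cohort.subject_ids[i] for i in test_idx],
            states=cohort.states[test_idx],
            actions=cohort.actions[test_idx],
            responses=cohort.responses[test_idx],
        )
        zmodel = StateResidualModel.fit(train)
        Z_train = zmodel.residuals(train)
        Z_test = zmodel.residuals(test)
        for gi, lam in enumerate(grid):
            result = fit_structure(train, structure, dspec, lam, theta0, Z=Z_train,
                                   psi1_derivative_mode=psi1_derivative_mode,
                                   optimizer_options=optimizer_options)
            pred = mean_response(Z_test, test.states, test.actions, result.theta_hat)
            errors[gi, k] = float(np.mean((test.responses - pred) ** 2))
    mean_err = errors.mean(axis=1)
    best = grid[int(np.argmin(mean_err))]  # argmin takes the first = smallest lambda on ties
    if return_errors:
        return best, dict(zip(grid, mean_err))
    return best
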