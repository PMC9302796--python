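"""Myopic regret-regression (MRr) mean model for dynamic treatment regimes.

A trajectory records, at visits j = 1..K, a scalar state ``S_j``, an action
``A_j`` and a response ``Y_j``.  The MRr mean model for the response is

    h_j = beta0 + beta1 * Z_j - psi1 * |A_j - psi2 - psi3 * S_j|

where ``Z_j = S_j - E(S_j | history)`` is the state residual and the
absolute-value term is the *regret*: the expected loss in response from
taking ``A_j`` instead of the optimal action ``psi2 + psi3 * S_j``.  The
regret vanishes at the optimal action and is positive elsewhere, so the
fitted ``psi`` parameters encode the optimal dynamic treatment regime.

Only the scalar-state, one-action-per-visit model is implemented; states and
actions are assumed complete (no dropout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import numpy.typing as npt

__all__ = [
    "Cohort",
    "ThetaParams",
    "ResidualMatrix",
    "StateResidualModel",
    "conditional_state_mean",
    "state_residuals",
    "regret",
    "regret_sign",
    "optimal_action",
    "mean_response",
    "mean_model_jacobian",
]

THETA_NAMES = ("beta0", "beta1", "psi1", "psi2", "psi3")


@dataclass(frozen=True)
class ThetaParams:
    """Stacked mean-model parameters, always ordered (beta0, beta1, psi1, psi2, psi3).

    ``beta0`` is the response intercept, ``beta1`` the coefficient on the
    state residual Z_j, ``psi1 >= 0`` the regret scale, and ``psi2 + psi3*S``
    the optimal action at state S.
    """

    beta0: float
    beta1: float
    psi1: float
    psi2: float
    psi3: float

    p: int = field(default=5, init=False, repr=False)

    def __post_init__(self):
        for name in THETA_NAMES:
            object.__setattr__(self, name, float(getattr(self, name)))

    def to_array(self) -> npt.NDArray[np.float64]:
        return np.array([self.beta0, self.beta1, self.psi1, self.psi2, self.psi3])

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ThetaParams":
        arr = np.asarray(theta, dtype=float).ravel()
        if arr.size != 5:
            raise ValueError(f"theta must have 5 components, got {arr.size}")
        return cls(*arr)

    @property
    def psi(self) -> tuple[float, float, float]:
        return (self.psi1, self.psi2, self.psi3)


@dataclass
class Cohort:
    """n subjects x K visits of (state, action, response) trajectories.

    All three matrices share shape (n, K) with no missing entries.  Visit
    indices are 1-based in user-facing documentation and files; arrays are
    0-based internally.
    """

    subject_ids: list
    states: npt.NDArray[np.float64]
    actions: npt.NDArray[np.float64]
    responses: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.actions = np.asarray(self.actions, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        shape = self.states.shape
        if self.states.ndim != 2:
            raise ValueError("state/action/response matrices must be 2-D (n, K)")
        if self.actions.shape != shape or self.responses.shape != shape:
            raise ValueError(
                f"shape mismatch: states {shape}, actions {self.actions.shape}, "
                f"responses {self.responses.shape}"
            )
        n, K = shape
        if n < 1 or K < 2:
            raise ValueError(f"need n >= 1 subjects and K >= 2 visits, got n={n}, K={K}")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must equal number of rows")
        for name, mat in (("states", self.states), ("actions", self.actions),
                          ("responses", self.responses)):
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"{name} contains missing or non-finite entries")

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def K(self) -> int:
        return self.states.shape[1]


@dataclass
class ResidualMatrix:
    """State residuals Z_ij = S_ij - E(S_ij | history), with provenance tag."""

    Z: npt.NDArray[np.float64]
    method_tag: Literal["known_mean", "regressed"]


def conditional_state_mean(prev_state, prev_action):
    """Conditional mean of the next state given the previous state and action.

    The simulation scenario's state transition: m_j = 0.5 + 0.2*S_{j-1} - 0.07*A_{j-1}.
    Accepts scalars or arrays (broadcasting).
    """
    return 0.5 + 0.2 * np.asarray(prev_state, dtype=float) - 0.07 * np.asarray(
        prev_action, dtype=float
    )


@dataclass
class StateResidualModel:
    """Per-visit least-squares model of S_j on (S_{j-1}, A_{j-1}) with intercept.

    Fitted on one cohort and applicable to another (e.g. a held-out
    cross-validation fold): visit 1 uses the training grand mean of S_1,
    visits j >= 2 use the training regression coefficients.
    """

    mean_s1: float
    coefs: npt.NDArray[np.float64]  # (K-1, 3): intercept, S_{j-1}, A_{j-1}

    @classmethod
    def fit(cls, cohort: Cohort) -> "StateResidualModel":
        if cohort.n <= 3:
            raise ValueError(
                "regressed residuals need n > 3 subjects for the per-visit "
                f"least-squares fits (got n={cohort.n})"
            )
        S, A = cohort.states, cohort.actions
        coefs = np.empty((cohort.K - 1, 3))
        ones = np.ones(cohort.n)
        for j in range(1, cohort.K):
            X = np.column_stack([ones, S[:, j - 1], A[:, j - 1]])
            coefs[j - 1], *_ = np.linalg.lstsq(X, S[:, j], rcond=None)
        return cls(mean_s1=float(S[:, 0].mean()), coefs=coefs)

    def residuals(self, cohort: Cohort) -> npt.NDArray[np.float64]:
        S, A = cohort.states, cohort.actions
        Z = np.empty_like(S)
        Z[:, 0] = S[:, 0] - self.mean_s1
        for j in range(1, cohort.K):
            c = self.coefs[j - 1]
            Z[:, j] = S[:, j] - (c[0] + c[1] * S[:, j - 1] + c[2] * A[:, j - 1])
        return Z


def state_residuals(
    cohort: Cohort,
    method: Literal["known_mean", "regressed"] = "regressed",
    scenario=None,
) -> ResidualMatrix:
    """State residuals Z_j = S_j - E(S_j | past states and actions).

    ``method="regressed"`` (the estimation route) regresses each S_j on
    (S_{j-1}, A_{j-1}) with intercept, per visit, and takes visit-1 residuals
    about the grand mean of S_1; OLS residuals have exactly zero column means.
    ``method="known_mean"`` uses the generative transition mean (requires a
    :class:`~qifmrr.simulation.SimulationScenario` supplying it) and is the
    oracle route used by the simulator and in tests.
    """
    if method == "known_mean":
        if scenario is None:
            raise ValueError("known_mean residuals require a scenario with the true transition")
        S, A = cohort.states, cohort.actions
        Z = np.empty_like(S)
        Z[:, 0] = S[:, 0] - scenario.state_intercept
        m = scenario.transition_mean(S[:, :-1], A[:, :-1])
        Z[:, 1:] = S[:, 1:] - m
        return ResidualMatrix(Z=Z, method_tag="known_mean")
    if method == "regressed":
        return ResidualMatrix(Z=StateResidualModel.fit(cohort).residuals(cohort),
                              method_tag="regressed")
    raise ValueError(f"unknown residual method {method!r}")


def regret(action, state, psi) -> npt.NDArray[np.float64]:
    """Regret psi1 * |a - psi2 - psi3*s|: expected response loss from action a at state s.

    Non-negative whenever psi1 >= 0, zero exactly at the optimal action.
    """
    psi1, psi2, psi3 = psi
    return psi1 * np.abs(np.asarray(action, dtype=float) - psi2 - psi3 * np.asarray(state, dtype=float))


def regret_sign(action, state, psi):
    """Sign indicator of a - psi2 - psi3*s: +1 on [0, inf) (boundary included), -1 below."""
    _, psi2, psi3 = psi
    d = np.asarray(action, dtype=float) - psi2 - psi3 * np.asarray(state, dtype=float)
    return np.where(d >= 0, 1.0, -1.0)


def optimal_action(state, psi):
    """The action psi2 + psi3*s minimizing the regret (which it sends to zero)."""
    _, psi2, psi3 = psi
    return psi2 + psi3 * np.asarray(state, dtype=float)


def mean_response(Z, states, actions, theta: ThetaParams) -> npt.NDArray[np.float64]:
    """Mean response h = beta0 + beta1*Z - regret(A, S, psi), elementwise on (n, K) arrays."""
    Z = np.asarray(Z, dtype=float)
    S = np.asarray(states, dtype=float)
    A = np.asarray(actions, dtype=float)
    if not (Z.shape == S.shape == A.shape):
        raise ValueError(
            f"shape mismatch: Z {Z.shape}, states {S.shape}, actions {A.shape}"
        )
    return theta.beta0 + theta.beta1 * Z - regret(A, S, theta.psi)


def mean_model_jacobian(
    Z,
    states,
    actions,
    theta: ThetaParams,
    psi1_derivative_mode: Literal["paper", "analytic"] = "paper",
) -> npt.NDArray[np.float64]:
    """Per-subject Jacobian of the mean response, shape (n, p, K).

    Rows follow the (beta0, beta1, psi1, psi2, psi3) order:

    * dh/dbeta0 = 1
    * dh/dbeta1 = Z
    * dh/dpsi1  = -I  (mode="paper", the published weight) or
      -|A - psi2 - psi3*S| (mode="analytic", the exact derivative)
    * dh/dpsi2  = psi1 * I
    * dh/dpsi3  = psi1 * S * I

    where I is the regret sign indicator.  Either psi1 row yields a valid
    estimating-function weight; "paper" is the default so that published
    simulation summaries are reproduced.
    """
    Z = np.asarray(Z, dtype=float)
    S = np.asarray(states, dtype=float)
    A = np.asarray(actions, dtype=float)
    I = regret_sign(A, S, theta.psi)
    n, K = S.shape
    J = np.empty((n, 5, K))
    J[:, 0, :] = 1.0
    J[:, 1, :] = Z
    if psi1_derivative_mode == "paper":
        J[:, 2, :] = -I
    elif psi1_derivative_mode == "analytic":
        J[:, 2, :] = -np.abs(A - theta.psi2 - theta.psi3 * S)
    else:
        raise ValueError(f"unknown psi1_derivative_mode {psi1_derivative_mode!r}")
    J[:, 3, :] = theta.psi1 * I
    J[:, 4, :] = theta.psi1 * S * I
    return J
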