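"""Synthetic trajectory generator and Monte Carlo replication harness.

The generator emulates the standard benchmark scenario for regret-based
dynamic-treatment-regime estimators:

* K = 10 visits; first state S_1 ~ N(0.5, 0.01);
* state transition S_j ~ N(m_j, 0.01), m_j = 0.5 + 0.2 S_{j-1} - 0.07 A_{j-1};
* actions A_j drawn uniformly from {0, 1, 2, 3}, independent across visits;
* response Y_j = beta0 + beta1 Z_j - psi1|A_j - psi2 - psi3 S_j| + eps_j with
  Z_j the true state residual S_j - m_j (m_1 = 0.5), truth
  beta = (3, -5), psi = (1.5, 0.1, 5.5);
* errors eps_i = sigma_Y * C W_i with C the lower Cholesky factor of an
  AR(1) correlation matrix (rho in {0.1, 0.5, 0.95}), W_i ~ N(0, I), and
  sigma_Y^2 = 0.64, so var(eps) = sigma_Y^2 * Sigma.

The replication harness fits QIF-MRr (lambda = 0) or rQIF-MRr per replicate
from the true parameters and summarizes the estimates by Mean, SE (sample
standard deviation) and RMSE about the truth — one summary block per table
cell of a simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import numpy.typing as npt
import pandas as pd

from .correlation import ar1_correlation
from .estimator import FitResult, MarginalVarianceSpec, fit_structure
from .model import THETA_NAMES, Cohort, ThetaParams, regret

__all__ = [
    "SimulationScenario",
    "GeneratedCohort",
    "ReplicationSummary",
    "correlated_errors",
    "generate_cohort",
    "run_replication",
    "replicate_table",
    "TABLE_GRIDS",
]

THETA_TRUE = ThetaParams(3.0, -5.0, 1.5, 0.1, 5.5)


@dataclass(frozen=True)
class SimulationScenario:
    """Generative conditions for one simulated cohort."""

    n: int = 500
    K: int = 10
    rho: float = 0.1
    sigma2_Y: float = 0.64
    state_var: float = 0.01
    state_intercept: float = 0.5
    state_coef: float = 0.2
    action_coef: float = -0.07
    action_set: tuple = (0, 1, 2, 3)
    theta_true: ThetaParams = THETA_TRUE
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_Y <= 0 or self.state_var <= 0:
            raise ValueError("variances must be positive")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.K < 2:
            raise ValueError(f"need K >= 2 visits, got {self.K}")
        if self.n < 1:
            raise ValueError(f"need n >= 1 subjects, got {self.n}")

    def transition_mean(self, prev_state, prev_action):
        """m_j = state_intercept + state_coef*S_{j-1} + action_coef*A_{j-1}."""
        return (self.state_intercept + self.state_coef * np.asarray(prev_state)
                + self.action_coef * np.asarray(prev_action))


@dataclass
class GeneratedCohort:
    """A simulated cohort plus its generative side products."""

    cohort: Cohort
    true_residuals: npt.NDArray[np.float64]   # Z_ij = S_ij - m_ij
    true_means: npt.NDArray[np.float64]       # m_ij (m_1 = state intercept)
    errors: npt.NDArray[np.float64]           # correlated response errors


def correlated_errors(rho: float, K: int, sigma2_Y: float, n: int,
                      rng: np.random.Generator | int) -> npt.NDArray[np.float64]:
    """n independent rows of eps = sigma * C W, C the AR(1) Cholesky factor, W ~ N(0, I)."""
    if sigma2_Y <= 0:
        raise ValueError("sigma2_Y must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    C = np.linalg.cholesky(ar1_correlation(rho, K))
    W = rng.standard_normal((n, K))
    return np.sqrt(sigma2_Y) * W @ C.T


def generate_cohort(scenario: SimulationScenario,
                    rng: np.random.Generator | None = None) -> GeneratedCohort:
    """Draw one cohort from the scenario (reproducible from scenario.seed)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n, K = scenario.n, scenario.K
    sd_state = np.sqrt(scenario.state_var)
    A = rng.choice(np.asarray(scenario.action_set, dtype=float), size=(n, K))
    S = np.empty((n, K))
    m = np.empty((n, K))
    m[:, 0] = scenario.state_intercept
    S[:, 0] = m[:, 0] + sd_state * rng.standard_normal(n)
    for j in range(1, K):
        m[:, j] = scenario.transition_mean(S[:, j - 1], A[:, j - 1])
        S[:, j] = m[:, j] + sd_state * rng.standard_normal(n)
    Z = S - m
    eps = correlated_errors(scenario.rho, K, scenario.sigma2_Y, n, rng)
    th = scenario.theta_true
    Y = th.beta0 + th.beta1 * Z - regret(A, S, th.psi) + eps
    cohort = Cohort(subject_ids=list(range(1, n + 1)), states=S, actions=A, responses=Y)
    return GeneratedCohort(cohort=cohort, true_residuals=Z, true_means=m, errors=eps)


@dataclass
class ReplicationSummary:
    """Per-parameter Mean / SE / RMSE over replicates — one table block.

    Mean is the replicate average of the estimates, SE their sample
    standard deviation (denominator R-1) and RMSE the root mean squared
    deviation from the true value, so RMSE^2 = bias^2 + SE^2 (R-1)/R.
    """

    table: pd.DataFrame                 # index beta0..psi3, columns mean/se/rmse
    method: str
    structure: str
    rho: float
    n: int
    replicates: int
    lam: float
    seed: int
    scheme: str
    n_excluded: int = 0
    estimates: npt.NDArray[np.float64] | None = field(default=None, repr=False)

    def metadata(self) -> dict:
        return dict(method=self.method, structure=self.structure, rho=self.rho,
                    n=self.n, replicates=self.replicates,
                    **{"lambda": self.lam}, seed=self.seed, scheme=self.scheme,
                    n_excluded=self.n_excluded)


def summarize_estimates(estimates: npt.NDArray[np.float64],
                        theta_true: ThetaParams) -> pd.DataFrame:
    """Mean/SE/RMSE table from an (R, p) array of replicate estimates."""
    truth = theta_true.to_array()
    mean = estimates.mean(axis=0)
    se = estimates.std(axis=0, ddof=1)
    rmse = np.sqrt(np.mean((estimates - truth) ** 2, axis=0))
    return pd.DataFrame({"mean": mean, "se": se, "rmse": rmse}, index=list(THETA_NAMES))


def run_replication(
    scenario: SimulationScenario,
    method: Literal["qif", "rqif"] = "qif",
    structure: str = "ar1",
    replicates: int = 1000,
    lam: float = 0.01,
    resample_scheme: Literal["fresh", "bootstrap"] = "fresh",
    seed: int = 0,
    dspec: MarginalVarianceSpec = MarginalVarianceSpec(),
    psi1_derivative_mode: str = "paper",
    optimizer_options: dict | None = None,
    max_failure_fraction: float = 0.05,
) -> ReplicationSummary:
    """Monte Carlo replication of one fit, summarized as Mean/SE/RMSE.

    ``fresh`` draws a new cohort per replicate; ``bootstrap`` draws one
    master cohort and resamples its subjects with replacement per replicate.
    Each replicate starts the optimizer at the true parameters.  Replicates
    whose optimizer fails to converge are excluded and counted; more than
    ``max_failure_fraction`` failures aborts the run.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for an SE")
    if method == "qif":
        lam = 0.0
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(replicates + 1)
    master = None
    if resample_scheme == "bootstrap":
        master = generate_cohort(scenario, np.random.default_rng(child_seeds[-1]))
    elif resample_scheme != "fresh":
        raise ValueError(f"unknown resample scheme {resample_scheme!r}")

    theta0 = scenario.theta_true
    estimates = []
    n_excluded = 0
    for r in range(replicates):
        rng = np.random.default_rng(child_seeds[r])
        if resample_scheme == "fresh":
            cohort = generate_cohort(scenario, rng).cohort
        else:
            idx = rng.integers(0, scenario.n, size=scenario.n)
            mc = master.cohort
            cohort = Cohort(subject_ids=list(range(1, scenario.n + 1)),
                            states=mc.states[idx], actions=mc.actions[idx],
                            responses=mc.responses[idx])
        try:
            result = fit_structure(cohort, structure, dspec, lam, theta0,
                                   psi1_derivative_mode=psi1_derivative_mode,
                                   optimizer_options=optimizer_options)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            n_excluded += 1
            continue
        if not result.converged:
            n_excluded += 1
            continue
        estimates.append(result.theta_hat.to_array())
    if n_excluded > max_failure_fraction * replicates:
        raise RuntimeError(
            f"{n_excluded}/{replicates} replicates failed or did not converge"
        )
    est = np.asarray(estimates)
    return ReplicationSummary(
        table=summarize_estimates(est, scenario.theta_true),
        method=method, structure=structure, rho=scenario.rho, n=scenario.n,
        replicates=replicates, lam=lam, seed=seed, scheme=resample_scheme,
        n_excluded=n_excluded, estimates=est,
    )


# Published-grid layout: the correctly-specified study crosses methods with
# correlation levels and sample sizes under the AR(1) structure; the
# misspecification studies fix rho and cross structures with methods.
TABLE_GRIDS = {
    "T1": dict(rhos=(0.1, 0.5, 0.95), structures=("ar1",)),
    "T2": dict(rhos=(0.1,), structures=("ar1", "exchangeable", "unspecified")),
    "T3": dict(rhos=(0.5,), structures=("ar1", "exchangeable", "unspecified")),
    "T4": dict(rhos=(0.95,), structures=("ar1", "exchangeable", "unspecified")),
}
TABLE_SAMPLE_SIZES = (25, 500)
TABLE_METHODS = ("qif", "rqif")
TABLE_LAMBDA = 0.01


def replicate_table(
    table_id: str,
    replicates: int = 1000,
    seed: int = 0,
    sample_sizes: tuple = TABLE_SAMPLE_SIZES,
    lam: float = TABLE_LAMBDA,
    resample_scheme: str = "fresh",
    base_scenario: SimulationScenario = SimulationScenario(),
    optimizer_options: dict | None = None,
) -> list[ReplicationSummary]:
    """Run the full grid behind one simulation table (machine twin of a table).

    T1 is the correctly specified study (AR(1) truth and working structure,
    both methods, rho in {0.1, 0.5, 0.95}, n in {25, 500}); T2-T4 fix one
    rho each and cross the three working structures with both methods.
    """
    if table_id not in TABLE_GRIDS:
        raise ValueError(f"table_id must be one of {sorted(TABLE_GRIDS)}, got {table_id!r}")
    grid = TABLE_GRIDS[table_id]
    summaries = []
    ss = np.random.SeedSequence(seed)
    cells = [(rho, n, method, structure)
             for rho in grid["rhos"]
             for structure in grid["structures"]
             for method in TABLE_METHODS
             for n in sample_sizes]
    for cell_seed, (rho, n, method, structure) in zip(ss.spawn(len(cells)), cells):
        scenario = replace(base_scenario, rho=rho, n=n)
        summaries.append(run_replication(
            scenario, method=method, structure=structure, replicates=replicates,
            lam=lam, resample_scheme=resample_scheme,
            seed=int(cell_seed.generate_state(1)[0] % (2**31)),
            optimizer_options=optimizer_options,
        ))
    return summaries
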