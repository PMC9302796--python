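# qifmrr

Quadratic inference functions for myopic regret-regression: estimation of
optimal dynamic treatment regimes (DTRs) from longitudinal trajectories.

A dynamic treatment regime maps a patient's evolving state and treatment
history to the next treatment. `qifmrr` estimates the parameters of the
optimal regime from cohorts of (state, action, response) trajectories —
n subjects observed at visits j = 1..K — under the myopic
regret-regression mean model

    E(Y_j | history) = β₀ + β₁ Z_j − ψ₁ |A_j − ψ₂ − ψ₃ S_j|,

where Z_j is the state residual S_j − E(S_j | history) and the
absolute-value term is the *regret*: the expected response lost by taking
action A_j instead of the optimal action ψ₂ + ψ₃S_j. Within-subject
correlation is handled with quadratic inference functions (QIF): the
inverse working correlation matrix is expanded in basis matrices,
R⁻¹(ρ) ≈ Σ_l τ_l M_l, and the parameters minimize the GMM objective

    Q_n(β, ψ) = g_nᵀ C_n⁻ g_n

built from the stacked estimating equations g_i^(l) = J_iᵀ M_l (Y_i − h_i)
(QIF-MRr), or its ridge-penalized version Q_n + λ‖(β, ψ)‖² (rQIF-MRr).
The GMM weight C_n is structurally singular for this model family — see
`docs/methods.md` — which is exactly why the ridge variant exists; the
objective uses a pseudoinverse throughout. Working correlation structures:
AR(1), exchangeable, and an "unspecified" structure whose second basis
matrix is the empirical residual covariance.

The package also ships the benchmark trajectory simulator (normal states,
uniform discrete actions, AR(1)-correlated Gaussian response errors) and a
Monte Carlo replication harness that reproduces simulation-study tables of
per-parameter Mean / SE / RMSE.

## Worked example

```python
from qifmrr import (SimulationScenario, generate_cohort, fit_structure,
                    ThetaParams)

truth = ThetaParams(3.0, -5.0, 1.5, 0.1, 5.5)
scenario = SimulationScenario(n=500, rho=0.1, seed=42)
cohort = generate_cohort(scenario).cohort

result = fit_structure(cohort, "ar1", lam=0.01, theta0=truth)
print(result.theta_hat)
print(round(result.objective_value, 4), result.converged)
```

prints

```
ThetaParams(beta0=3.0039402747511073, beta1=-5.038216376598258, psi1=1.5365603534530479, psi2=0.1063008717265172, psi3=5.456613367366384)
11.1231 True
```

i.e. at n = 500 the ridge fit recovers the generative parameters to within
a few hundredths (β₁, whose covariate Z has standard deviation 0.1, is the
noisiest component), and the fitted regime recommends action
ψ̂₂ + ψ̂₃·S ≈ 0.106 + 5.457·S at state S. The objective value ~11 matches
its χ²-type expectation: 15 moment conditions minus the rank deficiency of
the GMM weight.

The same pipeline from the shell:

```sh
qifmrr simulate --n 500 --rho 0.1 --seed 42 --out traj.csv
qifmrr fit --input traj.csv --structure ar1 --lambda 0.01 \
       --theta0 3,-5,1.5,0.1,5.5 --out fit.json
qifmrr replicate --table T1 --reps 1000 --seed 7 --out tables/
```

`replicate` writes one Mean/SE/RMSE CSV per table cell (4 decimals, full
precision plus provenance in JSON sidecars). Trajectory files are
long-format CSV with columns `subject,visit,state,action,response`,
visits 1-based and complete for every subject.

`simulate` also accepts a YAML scenario file via `--config` (command-line
flags override it); keys mirror `SimulationScenario`:

```yaml
n: 500            # subjects
K: 10             # visits
rho: 0.5          # AR(1) error correlation, |rho| < 1
sigma2_Y: 0.64    # response error variance
state_var: 0.01   # state noise variance
state_intercept: 0.5
state_coef: 0.2
action_coef: -0.07
action_set: [0, 1, 2, 3]
theta_true: [3, -5, 1.5, 0.1, 5.5]
seed: 42
```

Exit codes: 0 success, 1 user/schema error, 2 numerical failure.

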