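# Methods

## Model

A cohort records, for subjects i = 1..n at visits j = 1..K, a scalar state
S_j, an action A_j and a response Y_j. The myopic regret-regression (MRr)
mean model is

    h_j = β₀ + β₁ Z_j − ψ₁ |A_j − ψ₂ − ψ₃ S_j|,

where Z_j = S_j − E(S_j | past states and actions) is the state residual and
ψ₁|A_j − ψ₂ − ψ₃S_j| is the regret — the expected loss in response from
taking A_j instead of the optimal action ψ₂ + ψ₃S_j. Fitting (β, ψ) thus
simultaneously estimates the mean response and the optimal dynamic treatment
regime. Parameters are always stacked in the order (β₀, β₁, ψ₁, ψ₂, ψ₃).

Assumptions inherited from the regret-regression framework: consistency of
the observed outcomes with the potential outcomes, no unmeasured
confounders, positivity, complete trajectories (no dropout), scalar state
and one action per visit. The general form with history-dependent
coefficient vectors β_j(history) is an extension point, not implemented.

## Estimation: quadratic inference functions

Within-subject correlation is handled QIF-style: the inverse working
correlation is expanded in known basis matrices, R⁻¹(ρ) ≈ Σ_l τ_l M_l, and
the τ_l are never estimated. With J_i the p×K Jacobian of h and D_i the
diagonal marginal-variance matrix, the per-subject extended score stacks

    g_i^(l) = J_iᵀ D_i^{−1/2} M_l D_i^{−1/2} (Y_i − h_i),   l = 1..m,

giving m·p moment conditions for p = 5 parameters. The GMM objective is

    Q_n = g_nᵀ C_n⁻ g_n,   g_n = (1/n) Σ g_i,   C_n = (1/n²) Σ g_i g_iᵀ,

minimized over (β, ψ); the ridge variant minimizes rQ_n = Q_n + λ‖θ‖².

Bases: AR(1) uses (I, the two main off-diagonals, the (1,1)/(K,K) corners);
exchangeable uses (I, all-ones-minus-I); "unspecified" uses (I, Û) with
Û = (1/n) Σ r_i r_iᵀ the empirical residual second-moment matrix, computed
at a pilot independence-basis fit and then held fixed (the alternative —
recomputing Û at every objective evaluation — makes the objective depend on
θ through its own weight and is not what a two-step GMM does). The τ
formulas are implemented purely as a verification surface: tests check that
Σ τ_l(ρ) M_l reproduces the numeric inverse of R(ρ) to 1e−10.

### Structural singularity

C_n is rank-deficient *by construction* in this model family, on three
independent counts:

1. The published regret-scale weight ∂h/∂ψ₁ = −I (I the regret sign) makes
   the ψ₁ score column exactly −1/ψ₁ times the ψ₂ column (whose weight is
   ψ₁I). The true derivative of the mean model is −|A − ψ₂ − ψ₃S|; both are
   offered (`psi1_derivative_mode="paper" | "analytic"`), with "paper" the
   default so that published tables are reproduced.
2. For the AR(1) basis, (M₁ + M₂ − 2I)·1 = 0, so the three intercept-row
   moments are linearly dependent for every K.
3. For the exchangeable basis, 1ᵀ(E − I) = (K−1)·1ᵀ, with the same effect.

This is evidently the singularity that motivates the ridge penalty. The
objective therefore uses the Moore–Penrose pseudoinverse of C_n throughout
(eigendecomposition with relative cutoff 1e−10), which coincides with the
plain inverse whenever C_n is nonsingular and keeps Q_n finite and ≥ 0
otherwise. Exactly zero scores return Q_n = 0.

### Optimization

Minimization is derivative-free Nelder–Mead (the regret kink makes the
objective non-smooth in ψ): tolerance 1e−8 on both objective and
parameters, at most 5000 evaluations, then one restart from the first
solution with a small (0.1%) simplex as a guard against premature simplex
collapse. Starting values must be given explicitly; the replication harness
starts at the true parameters. Fits are deterministic given (cohort, θ₀,
options). A non-finite objective at θ₀ fails immediately.

State residuals: the estimation route regresses each S_j on
(S_{j−1}, A_{j−1}) with intercept, per visit, visit 1 using the grand mean
of S₁ (OLS residuals then have exactly zero column means); the generative
route uses the true transition mean and is available for oracle tests.
Cross-validation refits the residual regressions on the training folds and
applies them to held-out subjects — the residual model is part of the
pipeline being validated.

Marginal variances D_i: identity by default. Q_n is exactly invariant to
any uniform rescaling of D (tested at factors 0.1 and 64), so identity
covers the constant-variance design with no loss; a known-σ² mode and a
per-visit estimated mode (sample variances of the response residuals at θ₀,
held fixed) are provided.

λ selection: subject-level k-fold cross-validation (default k = 5, seeded
splits), scoring mean squared prediction error of the mean model on the
held-out fold; ties break toward the smallest λ. See "Known limitations"
for what this can and cannot resolve.

## Synthetic data

The generator emulates the standard benchmark scenario for regret-based
DTR estimators, with defaults fixed at the study's values:

| quantity | default |
|---|---|
| visits K | 10 |
| first state | S₁ ~ N(0.5, 0.01) |
| transition | S_j ~ N(0.5 + 0.2S_{j−1} − 0.07A_{j−1}, 0.01) |
| actions | uniform on {0, 1, 2, 3}, independent across visits |
| truth θ | β = (3, −5), ψ = (1.5, 0.1, 5.5) |
| response noise | σ²_Y = 0.64, AR(1) correlation, ρ ∈ {0.1, 0.5, 0.95} |

Errors are drawn as ε = σ_Y·C·W with C the lower Cholesky factor of the
AR(1) correlation matrix and W standard normal, so var(ε) = σ²_Y Σ exactly.
The Z_j used to *build* Y is the true residual S_j − m_j; the Z_j used in
*fitting* follows the residual-method option (regressed by default).

What the generator does not emulate: dropout/censoring, mixed
discrete-continuous states (as in anticoagulation data, where S_j has an
atom at zero), misspecified mean models, or non-Gaussian noise. Passing
tests therefore demonstrate correctness of the machinery under the
benchmark design, not robustness on messy clinical data.

## Replication harness

`run_replication` fits one method per replicate and reports, per parameter,
Mean (replicate average), SE (sample standard deviation, denominator R−1)
and RMSE (root mean squared deviation from the truth), so that
RMSE² = bias² + SE²·(R−1)/R holds exactly — the same identity the published
tables satisfy to the fourth decimal. Two resampling schemes: `fresh`
(a new cohort per replicate; the default, since the published means center
on the truth, which only fresh simulation guarantees) and `bootstrap`
(one master cohort, subjects resampled with replacement). Per-replicate
seeds are spawned from one master seed, so any replicate is re-runnable in
isolation. Optimizer failures are excluded and counted, never imputed; more
than 5% failures aborts the run. `replicate_table` runs the published grid:
T1 crosses both methods with ρ ∈ {0.1, 0.5, 0.95} and n ∈ {25, 500} under
AR(1); T2–T4 fix one ρ each and cross the three working structures with
both methods.

## Problem sizes used in the shipped checks

Monte Carlo sizes in the test suite and the acceptance script are scaled
for a single-CPU desk run, chosen once from the sampling-error budget: a
mean over R replicates carries MC error SE/√R, so 200–500 replicates put
that error an order of magnitude below the quantities' own variability.
The acceptance script uses 500 replicates for n = 25 cells, 200 for n = 500
cells and 10 seeded runs for the CV mode; the table-reproduction test uses
200 replicates with correspondingly widened tolerances; the consistency
smoke test uses 25 replicates at n = 2000.

## Known limitations

- The published study's SE/RMSE values at n = 25 and n = 500 are nearly
  identical, which no √n-consistent estimator can produce, and some printed
  SEs lie below the information bound implied by the stated design (e.g.
  SE(β₁) = 0.196 at n = 25, versus ≈ 0.5 from sd(Z) = 0.1, σ_Y = 0.8 and
  250 observations). This package reproduces the published Monte Carlo
  *means* at n = 25 and is nearly unbiased at n = 500, but reports the
  statistically consistent dispersion: its SEs shrink like 1/√n.
- At n = 500 the ridge term is negligible against the QIF curvature:
  held-out prediction error is flat in λ to ~1e−4 relative, so
  cross-validation cannot meaningfully resolve λ on that scenario and the
  selected value is noise-driven. The penalty's practical value here is
  numerical (regularizing the structurally singular weight) rather than
  predictive.
- ψ₂ and ψ₃ are weakly separated under the benchmark design (states
  concentrate near 0.5 with variance 0.01, so ψ₂ + ψ₃S is nearly a single
  degree of freedom); their individual estimates are accordingly noisy at
  n = 25.
- Analytic/asymptotic standard errors are out of scope; only replication
  SEs are produced.
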