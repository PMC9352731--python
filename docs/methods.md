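# Methods

## Model

Each synaptic connection occupies one of `S` discrete strength states and
performs a random walk with reflecting boundaries. The transition matrix
is tridiagonal with up-moves `x_{i+1} y_i`, down-moves `x_i y_i` and the
diagonal absorbing the remainder. Two properties drive everything else:

1. **Detailed balance by construction.** `x_i P[i,i+1] = x_{i+1} P[i+1,i]`
   is a product identity, so `x` is stationary for any admissible `y`.
   The equilibrium (matched to empirical spine-size distributions) and
   the dynamics (the `y_j`) are therefore independently tunable. A spec is
   admissible when every row's off-diagonal mass is ≤ 1; validation
   reports the offending row otherwise.
2. **Reversibility.** The chain's spectrum is real; we compute it by
   symmetrizing with `diag(x)^{1/2}` and using a symmetric eigensolver,
   which avoids spurious complex parts entirely.

Derived quantities:

- Lifetimes `1/(1 − P[i,i])`; an absorbing state yields an explicit
  `inf` sentinel, never an overflow.
- Fundamental matrix `Z = (I − P + X)^{-1}` (the classical ergodic-chain
  form, with `X` the rank-one matrix of stationary rows), first-passage
  times `t_ij = (z_jj − z_ij)/x_j`, and asymptotic occupancy variances
  `σ_j² = 2 x_j z_jj − x_j − x_j²`. All three are validated against
  Monte-Carlo simulation in the test suite; the system is solved directly,
  and a condition number above 1e14 raises rather than returning noise.
- Convergence to equilibrium decays asymptotically as `a_2 λ_2^t`; the
  tail coefficient is estimated by log-linear regression over a window in
  which the second eigen-mode dominates (start at 14 e-foldings of the
  gap `ln λ_2 − ln λ_3`, so subdominant modes are ~1e-6 relative).

States are 1-based everywhere a user sees them; arrays are 0-based
internally and that convention never leaks through the API.

## Learning, inhibition, retrieval

Learning promotes state-1 connections to state 2 with probability
`p_{1,2} μ` per unit of study time and touches nothing else; this keeps
the model minimal (promotion of higher states would add parameters
without changing the qualitative laws). Learning episodes are treated as
fast relative to spontaneous drift (minutes–hours vs days), so the chain
is frozen during an episode by default; an interleaved mode (one drift
step per learning unit) exists for schedules where that separation fails.

Weights are affine in the state index, `w(i) = α(i−1)/(S−1)`, `w(1)=0`.
Feedforward inhibition places the firing threshold halfway into the
expected learning increment:

    F = A_active (S−1)^{-1} ( x_1 p_{1,2} μ / 2 + Σ (i−1) x_i )

For partial cues `F` scales linearly with the number of active inputs —
the minimal reading of an inhibition that "grows with the active input
count". An alternative `two_sigma` policy (equilibrium net plus two
weighted standard deviations from the asymptotic occupancy variances) is
selectable; its small spurious-activation fraction is measured in tests,
not asserted, because it depends strongly on `A` and the equilibrium
shape. Binary activations only; graded readout and pattern-interference
studies are out of scope.

## Trace strength and the experiment drivers

The default retention metric is the excess expected net input
`Δnet(t) = A Σ w(i)(vP^t − x)_i`, which is linear in μ and equals
`x_1 p_{1,2} μ A/(S−1)` at `t = 0`. A simulated `fraction_active` readout
exists through the retrieval circuit for stochastic experiments.

- **Jost's laws.** Equal-strength matching is operationalized by
  bisection on μ (relative tolerance 1e-10): the young/massed trace's
  learning rate is tuned so both traces have identical strength at the
  matching time. Strength after a single episode is monotone in μ, so
  bisection is exact; a target above the μ = 1 maximum raises an explicit
  calibration error.
- **Spacing.** Spaced = k episodes separated by `gap` drift steps (no
  drift after the last); massed = k consecutive units, μ re-calibrated to
  match strength immediately after the final episode.
- **Lesioning.** Diffuse damage deletes a state-i connection (i ≥ 2, back
  to state 1) with probability `q_i`, non-increasing in i. The built-in
  family is `q_i = q_base (1 − w(i))^γ` (default γ = 1; γ = 0 is the
  uniform-lesion control). Post-lesion strength is measured against the
  *lesioned* equilibrium baseline — the insult hits background
  connections too, and inhibition recalibrates to it; this choice makes a
  total lesion (`q ≡ 1` above state 1) erase every trace exactly.
  Recall probabilities come from a logistic link
  `p = 1/(1 + exp(−(β₀ + β₁·strength)))` with defaults β₀ = −2.2,
  β₁ = 6.0, chosen so that a freshly learned trace at the canonical
  settings (μ = 1, A = 100, strength 0.72) recalls at ≈ 0.9 and a fully
  forgotten one at ≈ 0.1. The relative retrograde gradient is
  `log(p_patient)/log(p_control)`; probabilities are floored at 1e-6
  before the log, with a warning, and ages where the control is exactly 1
  are excluded.

## Synthetic data and what it does not emulate

The fixture generator discretizes exponential / gamma / lognormal spine-
size families over `S` bins and pairs them with geometrically decreasing
plasticity — the regime the theory addresses (stable strong spines). The
canonical 5-state chain is frozen as
`x = (0.60, 0.24, 0.10, 0.02, 0.04)`, `y = (0.20, 0.10, 0.02, 0.005)`:
most mass in the lowest states, top-state lifetime exactly 10,000 days,
λ₂ ≈ 0.99991 (multi-year forgetting). Synthetic retention datasets are
two-group (control/lesioned) binomial observations of the model's own
recall probabilities at log-spaced memory ages of 3–1000 days with 50
items per point — a plausible longitudinal design, but still
model-generated data: passing the recovery tests demonstrates pipeline
correctness and identifiability, not that real forgetting follows this
chain. Real retention data add retrieval-strategy, item-difficulty and
sampling structure that the binomial link ignores.

## Fitting

Free parameters are a declared subset of {μ, q_base, γ, β₀, β₁}, fitted
by bounded Nelder-Mead from 10 seeded multi-starts (small parameter
count; the objective is cheap because the per-age excess distributions
are precomputed once and strength is linear in μ). The default objective
is SSE on the relative retrograde gradient — the quantity amnesia studies
plot — with SSE on the raw retention curves as an option. The two are
complementary: the relative gradient pins down the lesion parameters but,
being a ratio, carries little information about μ once observation noise
is present; parameter-recovery experiments for μ therefore use the
retention objective. Non-convergence is reported on the result object
(best point returned), never raised.

## Numerical policy

Tolerances are centralized in one frozen config: stationarity and row
sums 1e-12, detailed balance 1e-14, fundamental-matrix residual 1e-10,
probability floor 1e-6. Matrix powers use repeated squaring; eigenvalues
use the symmetrized solver; Monte-Carlo oracles run 1e4–1e5 trajectories
and compare at 3–4 standard errors. Property tests over chain grids probe
ages scaled to each chain's relaxation time `1/(1 − λ₂)` — at ages far
beyond it a trace's residual strength is below double-precision
resolution and ratios of such residuals are meaningless.

## Known limitations

- Strictly tridiagonal, discrete-time, discrete-state dynamics; no
  continuous (Brownian) variant and no jump transitions.
- Learning affects only the 1→2 transition; repetition effects above
  state 2 are not modeled.
- The strength→recall link is a declared convenience (logistic or the
  retrieval circuit); fits to published patient datasets are out of
  scope, and the fitting machinery is validated by parameter recovery on
  synthetic data only.
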