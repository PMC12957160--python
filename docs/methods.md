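# Methods

This note documents the model, the numerics, and the design choices
behind `fracalz`, in the order a reader meets them in the code.

## Model and assumptions

The five-compartment model (README) treats amyloid-driven neuronal
infection like a transmission process: amyloid "infects" functional
neurons (rate α), infected neurons secrete amyloid (γ), amyloid seeds
tau (κ), and microglia clear infected neurons, amyloid and tau
(β₁, β₂, β₃) while dying at rate φ₃.  All states are concentrations
(g/ml); all rates are per day.  The baseline parameter set
(`TABLE1_PARAMS`) describes an early-pathology regime with
A_β(0) = T_μ(0) = 10⁻⁶ g/ml; one source table lists φ₁ "per year",
but every simulation horizon in this package is in days and φ₁ is
treated as per-day for consistency with all other rates.  A second
preset (`CHAOS_PARAMS`) is the slow-neuron-death / high-production
regime used in the gain-stabilization worked example.

Time derivatives are Caputo-fractional of order σ ∈ (0, 1].  The
Caputo choice (rather than Riemann–Liouville) is what permits ordinary
initial conditions: the derivative of a constant is zero, so
equilibria of the integer-order model are equilibria of the
fractional one.

The controlled model multiplies the amyloid source γI_N by (1 − z₁)
and the infection term αF_N A_β by (1 − z₂), z₁, z₂ ∈ [0, 1].  No
canonical controlled equations exist for this model; this
multiplicative placement is the minimal interpretation of "intervene
on amyloid accumulation / neurodegeneration" and is confined to
`model.controlled_rhs`, so alternative placements are one function
away.

## Grünwald–Letnikov discretization

On a uniform grid t_i = ih the Caputo derivative is approximated by

    D^σ u(t_n) ≈ h^(−σ) Σ_{k=0..n} w_k (u_{n−k} − u_0),
    w_0 = 1,  w_k = w_{k−1} (1 − (σ+1)/k),

the signed fractional-binomial convolution; the u₀ shift realizes the
Caputo derivative for nonzero initial data.  The explicit stepper sets
the discrete derivative at t_n equal to f(t_{n−1}, u_{n−1}) and
solves for u_n; at σ = 1 the weights collapse to (1, −1, 0, …) and
the update telescopes to explicit Euler (the implementation runs the
reduced recursion there, so the equivalence is exact in floating
point, not just algebraically).

Two deliberate numerical choices:

* **Taylor-consistent first step.**  The raw GL first step
  u₁ = u₀ + h^σ f(u₀) misses the 1/Γ(σ+1) factor of the fractional
  Taylor expansion; because solutions of fractional ODEs behave like
  t^σ near t = 0, that inconsistency drags max-norm convergence down
  to order σ (and in the h-range 0.005–0.02 the measured error for
  σ = 0.5 is not even monotone in h).  The default first step is
  u₁ = u₀ + h^σ/Γ(σ+1) f(u₀), which restores uniform first-order
  convergence (measured orders 0.96–1.02 for σ ∈ {0.5, 0.7, 0.9} on
  the linear decay problem); `taylor_start=False` recovers the raw
  update.  At σ = 1 the two coincide.
* **Semi-implicit positivity-preserving variant.**  The amyloid
  clearance rate d_β + κ = 9.535/day makes the system stiff on
  day-scale grids: the explicit scheme requires roughly
  h^σ λ < 2^σ and diverges at h = 0.1 for σ = 0.7 (and overshoots
  negative for σ = 0.8, 0.9).  The model right-hand side splits
  naturally as rhs_i = P_i − D_i u_i with P, D ≥ 0 for non-negative
  states; treating the loss implicitly,
  u_n = (u₀ + h^σ P − Σ_{k≥1} w_k (u_{n−k} − u₀)) / (1 + h^σ D),
  keeps every component non-negative unconditionally (induction using
  w_k ≤ 0 for k ≥ 1 and Σ_{k≤n} w_k > 0) — the discrete analogue of
  the model's Mittag-Leffler positivity bounds.  The high-level
  `simulate()` defaults to this stepper; the explicit scheme remains
  the reference for convergence and Euler-equivalence checks and is
  fine on non-stiff problems.

Full memory is kept by default (an O(n²) convolution; a 200-day run
at h = 0.1 takes ~0.1 s).  An optional `memory_length` truncates to
the most recent lags (short-memory principle); truncation error decays
like |w_L| ~ L^(−1−σ).

The Mittag-Leffler function E_σ(z) = Σ z^j/Γ(σj+1) is evaluated by
its power series (tolerance 10⁻¹², cap 1000 terms, convergence
checked); it is intended for the decay branch z ≤ 0 of moderate |z|,
where double precision suffices, and E_σ(−λt^σ) is the closed-form
oracle for the linear test equation throughout the test suite.

## Stability analysis

The disease-free equilibrium is (Π_N/φ₁, 0, 0, 0, 0).  The endemic
construction takes the infected-neuron level I_N\* as an input (the
cascade fixes A_β\*, T_μ\* and F_N\* from it; F_N\* is obtained by
solving its own equilibrium equation directly rather than
transcribing a closed form, and is verified by residual);
`solve_endemic_level` finds the self-consistent I_N\* by bracketing
when R₀ > 1.  R₀ comes from the next-generation matrix K = FV⁻¹ and
is cross-checked against the numeric spectral radius of K in the
tests.

The local-stability Jacobian is the 4×4 block on
(F_N, I_N, A_β, T_μ) — at the disease-free point M_ρ\* = 0 decouples
the microglial column, and a finite-difference audit
(`jacobian_fd_audit`) confirms the printed block equals the full
5-state linearization restricted to those coordinates.  Diagonal
gains ω₁..ω₄ model proportional output feedback; ω₅ is accepted for
interface compatibility but the 4×4 matrix has no slot for it.

The gain worked example (gains 1–4, `CHAOS_PARAMS`) is
block-triangular, forcing the roots −1.00003 and −4.302 exactly.  The
remaining 2×2 block has trace −14.53519 and negative determinant, so
its eigenvalues are real of opposite sign (≈ −25.844 and ≈ +11.309).
A published four-root list for this matrix contains instead
−25.8118817… and −11.3265217…, which do not sum to the trace and have
the wrong sign pattern; `gain_example_report` reproduces the two
forced roots and flags the others as inconsistent rather than
matching them.  Eigenvalues are always reported sorted by ascending
magnitude with ties broken by ascending real part, for deterministic
comparisons.

## Logarithmic sensitivity

S_log(t) = (ln y₊ − ln y₋) / (2 ln(1+δ)) from two full model runs at
p(1±δ), default δ = 0.1.  For a pure power law y = Cp^k the statistic
equals k·ln((1+δ)/(1−δ))/(2 ln(1+δ)) — exactly k only in the δ → 0
limit (bias ≈ kδ/2 at finite δ); the tests assert both the exact
finite-δ value and the small-δ limit.  Nodes where either perturbed
output is non-positive are masked (NaN + a `defined` mask), never
zeroed: the logarithm simply does not exist there.  Initial-condition
elasticities are supported by applying the same multiplicative
perturbation to one component of u₀.

## Physics-informed networks

One architecture serves three variants: a fully connected tanh MLP
(default 4 hidden layers × 64 units, Xavier-uniform init, seeded)
mapping normalized time t/T to 7 outputs — the five states (linear
outputs, scaled per state by the observation range so all state
channels train on comparable footing) and the two controls (logistic,
hence in (0, 1) by construction).

* **fractional** — minimizes L_data + λ_phys · L_phys where the
  residual uses the GL convolution at the configured σ;
* **integer** — identical but σ forced to 1 (backward-difference
  residual);
* **baseline** — λ_phys = 0; its control outputs receive no gradient
  and the model rates never enter (verified by a test that swaps the
  rates and compares outputs bitwise).

L_data is the mean squared 5-vector misfit over the data nodes (the
reference grid, optionally subsampled; t = 0 is a data node, so the
initial condition is enforced softly).  L_phys is the mean squared
residual norm over the collocation nodes t₁..t_N — node 0 is excluded
because the memory convolution is empty there and the residual
degenerates to −f(u₀).  λ_phys defaults to 1.  Controls are
constrained only through the physics residual; they receive no data
supervision.

No autodiff framework is used.  The GL convolution is linear, so its
adjoint is the transposed Toeplitz convolution; the right-hand-side
Jacobians in state and control are analytic (`model.rhs_jacobian_*`);
backprop through the MLP is written out and the whole gradient is
verified against finite differences to ~10⁻¹⁰ in a test.  The
optimizer is full-batch Adam (default lr 2·10⁻³); the iteration
budget defaults to 2000, which on one CPU trains a 400-node problem
in a few seconds.

Observation noise is additive Gaussian per state with standard
deviation = level × max|clean series| (the "intensity" anchor is the
per-variable dynamic range; recorded in the result).  The Monte-Carlo
benchmark trains every variant × noise level × replicate from a
distinct recorded seed and aggregates final-loss and per-state-MSE
statistics (sample sd, n−1 denominator).  The per-state MSE is
measured against the *clean* reference, so it reflects recovery of
the true dynamics rather than fit to noise.  The robustness ratio is
mean final loss at the highest level over mean final loss at zero
noise.

A structural caveat the benchmark itself exposes: when both PINN
variants are trained to (near) convergence, their high-noise losses
meet the same observation-noise floor, so the ratio is governed by
the zero-noise denominators — and there the integer variant's
irreducible physics-mismatch floor *deflates* its ratio.  A smaller
robustness ratio for the fractional variant therefore cannot be
expected from this design; the benchmark reports what it measures,
and the corresponding ordering check in the acceptance suite
documents the discrepancy honestly instead of being tuned to pass.

## Control scenarios

The cost functional is ∫(w_I I_N + w_A A_β + w_T T_μ + c₁z₁² +
c₂z₂²) dt by trapezoid rule (defaults w = 1, c = 0.01, all
configurable — no canonical cost exists for this model, so these are
package choices).  Controls are piecewise constant on 10 equal
windows, squashed to [0, 1] on a logit scale, and optimized by
Nelder-Mead starting from the best of {all-0, all-0.5, all-1, seeded
random}; because the constant schedules are in the candidate set, the
optimized cost can never exceed theirs, and the reported history is
the non-increasing best-so-far cost.  Direct parameterized
optimization was chosen over Pontryagin forward–backward sweeps
because no adjoint system or Hamiltonian is available for the
fractional controlled model here, and the 20-dimensional direct
problem is trivial for a derivative-free method.

In the baseline early-pathology regime the burden terms are ~10⁻⁵, so
the optimizer correctly returns near-zero dosing; the strategy
orderings (terminal F_N, amyloid burden, cost) then hold weakly.  A
regime with α large enough that R₀ > 1 makes the trade-off
non-trivial, and a test verifies that cheaper effort then buys
visibly stronger dosing.

## Synthetic data

`fixtures.generate_fixtures` writes the seeded bundle everything else
can be tested against: clean references for σ ∈ {0.7, 0.8, 0.9, 1.0}
and horizons {200, 500} days at h = 0.5 (stable stepper), noisy
copies of the σ = 0.9/200-day reference at intensities 0–20%, and an
11-node linear fixture with its Mittag-Leffler closed form.  The
manifest stores SHA-256 checksums of the CSV text; values are
rendered at 17 significant digits, so the round-trip is bit-lossless
and checksums are stable wherever double arithmetic is IEEE-754.

What the generator emulates: GL-solved trajectories of this model
under known rates with additive, state-scaled Gaussian observation
noise.  What it does not: measurement schedules of real biomarker
studies (sparse, irregular, censored), model misspecification,
inter-subject variability, or non-Gaussian assay noise.  Tests
passing on these fixtures demonstrate internal consistency of the
solver/learning pipeline, not clinical validity.

## Problem sizes and tolerances

Defaults used by the test and acceptance suites: solver grids up to
2001 nodes (200 days at h = 0.1); convergence checks on h ∈ {0.02,
0.01, 0.005}; PINN profile 2000 iterations on 401-node grids with 3
replicates per benchmark cell; control optimization ≤ 200
Nelder-Mead iterations on 10 windows.  These sizes keep the full
suite under half a minute plus ~2 minutes for the learning benchmark
while leaving every qualitative conclusion unchanged at larger sizes.
Key tolerances: Mittag-Leffler series 10⁻¹²; equilibrium residuals
10⁻¹⁰ (relative); R₀ closed form vs. spectral radius 10⁻¹²;
eigenvalue-sum-vs-trace 10⁻⁸.

## Known limitations

* The explicit GL scheme is conditionally stable; use the default
  semi-implicit stepper for coarse grids on this (stiff) model.
* First-order accuracy only; no predictor–corrector or spectral
  fractional solvers.
* The Mittag-Leffler evaluator targets the moderate-|z| decay branch;
  large |z| needs asymptotic or integral representations it does not
  implement.
* The PINN gradient path assumes the uniform collocation grid equals
  the reference grid; scattered collocation would require a different
  quadrature of the memory integral.
* Elasticities are undefined where outputs vanish; curves carry
  explicit masks instead of imputed zeros.
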