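# Methods

This note records the model, the numerical choices, and the places where the
design was genuinely open, so that results produced with `glvsim` can be
interpreted — and, where necessary, distrusted — correctly.

## Community construction

One replicate community is assembled in four steps.

1. **Interaction matrix.** `A` is `S×S` with `a_ii = -1` exactly. The number
   of nonzero off-diagonal entries is *exactly* `round(c·S·(S-1))` (half
   away from zero), their positions drawn uniformly without replacement;
   this realizes the connectance as a count, not as a per-entry Bernoulli
   probability. Each selected entry is an independent `N(0, σ²)` draw —
   `a_ij` and `a_ji` are independent, so the interaction type of a pair
   (competition, antagonism, mutualism, commensalism, amensalism) emerges
   from the sign pattern. σ is interpreted as the **standard deviation** of
   the draws (default 0.2): with σ as SD the May-type stability transition
   of the default scenario sits at richness of a few tens, whereas reading
   σ as a variance (SD ≈ 0.45) would make even 10-species communities
   predominantly unstable, which is inconsistent with the regime the
   experiments are designed to explore.
2. **Equilibrium.** `ln N_i* ~ N(0,1)` i.i.d.; mean abundance `e^(1/2)`,
   median 1.
3. **Growth rates.** `r = -(A @ N*)` — computed as the negation of the same
   floating-point product used by the right-hand side, so the equilibrium
   residual `A N* + r` is zero *to the last bit* and `RHS(N*) = 0` holds
   exactly for both dynamics.
4. **Initial condition.** `N_p,i = |N_i* + ε_i|`, `ε_i ~ N(0, 0.02²)`. The
   absolute value handles the rare sign flip for very small equilibrium
   abundances; no other rejection is applied.

Sign-constrained scenarios (`all_negative` / `all_positive`) keep the
magnitude `|N(0, σ²)|` of each draw (half-Gaussian) and impose the scenario
sign. The half-Gaussian is a modelling choice: it preserves the magnitude
distribution of the mixed case, making the scenarios comparable in
interaction strength; nothing in the construction forces it.

## Stability

The Jacobian at an interior GLV equilibrium collapses to
`J = diag(N*) A` (the bracket vanishes). Local stability is decided
spectrally: stable iff every eigenvalue has real part `< -tol` with
`tol = 10⁻⁹`. This is mathematically equivalent to the Routh–Hurwitz
conditions but numerically robust at `S` up to a few hundred, where
polynomial-coefficient tables are not. Verdicts with `|max Re λ| ≤ tol` are
flagged marginal rather than silently binned; random sampling makes exact
criticality measure-zero, but floating point does not.

## Integration and stopping rules

Trajectories are integrated with LSODA (adaptive, stiffness-switching),
`rtol = 10⁻⁸`, `atol = 10⁻¹⁰` by default, with the analytic Jacobian
supplied. The tight tolerances matter: survivor classification at the
`10⁻⁴` threshold and convergence detection at `10⁻⁵` sit many orders below
typical abundances.

* **Blow-up** (unbounded model only): a terminal event on
  `max_i N_i - 1000` crossing upward, root-located so the stopping time is
  accurate to solver precision rather than to an output grid.
* **Convergence**: a terminal event on `max_i |dN_i/dt| - 10⁻⁵` crossing
  downward, i.e. the first time the whole community is at numerical rest.
  Event location (continuous in time) is used instead of polling at fixed
  checkpoints; a trajectory creeping through a near-saddle state with all
  derivatives below the tolerance is declared converged there, which any
  fixed-schedule test is equally exposed to.
* **Time limit**: `t = 1000` model time units ("1000 steps" is read as the
  integration horizon, not solver steps).

The state is formally confined to the box `0 ≤ N_i ≤ Nmax` (the faces are
invariant manifolds of the exact flow), but the raw vector field is
anti-dissipative just outside it: below zero a positive bracket drives the
state to −∞, and above the ceiling the attenuation factor flips sign with
the same effect, so a rounding-level excursion can run away. The
solver-facing right-hand side therefore evaluates at the state *projected*
onto the box. Inside the box nothing changes; an excursion is pinned where
it crossed. Reported final states clamp negatives in `[-10⁻⁶, 0]` to zero
(decaying populations settle at the scale of `atol`, far below both this
floor and the extinction threshold) and error out below the floor;
ceiling overshoot is clamped to `Nmax`.

A consequence of the numerical extinction floor: once an abundance falls
below ~`atol` the integrator cannot distinguish it from zero, so a species
that would — in exact arithmetic — later regrow from, say, `10⁻³⁰` after
its competitors collapse stays extinct. Any fixed-precision integration of
these dynamics shares this property; survivor counts should be read with
this in mind.

Species are counted "at the ceiling" when `N_i ≥ 0.999·Nmax`: the bounded
model approaches `Nmax` only asymptotically, so an exact-equality count
would be empty.

A "returned to equilibrium" flag is set when a converged run ends within
`10·perturb_sd` (sup-norm) of `N*`; with the zero-perturbation edge case the
tolerance falls back to `10⁻⁸`.

## Experiments and summaries

Each replicate's random stream is derived from
`SeedSequence([root_seed, S, replicate_id])`, so any single replicate can be
reproduced in isolation and sweep results are independent of execution
order (replicates may in principle run concurrently; the implementation is
serial).

The interaction-selection statistic is the mean of the *nonzero
off-diagonal* coefficients of the survivor submatrix minus the same mean
over the full matrix. The constant diagonal is excluded because it carries
no information; structural zeros are excluded because they would dilute the
statistic with non-interactions. Both exclusions are interpretive choices —
the statistic could defensibly include structural zeros — and the
convention is fixed here and used consistently. Replicates with fewer than
two survivors, or whose survivor submatrix carries no realized link, yield
a missing value that is excluded from (not zeroed into) means.

All-positive bounded runs are classified as `all_alive` (`n_alive = S`),
`near_total_extinction` (`n_alive ≤ 0.1·S`; the 10% cutoff operationalizes
"almost all species extinct" and is exposed in the configuration), or
`other`. Outcome frequencies condition on replicates whose initial
equilibrium is unstable; stable replicates trivially return to `N*` with no
extinctions.

## Two-species phase-plane analysis

For a self-limited pair (`a11, a22 < 0`) all equilibria are located in
closed form: origin, single-species carrying capacities, the interior
isocline intersection (solving `r + A N = 0`), and — for the bounded model —
the ceiling points obtained by pinning one species at `Nmax` and solving the
partner's bracket (including the double ceiling `(Nmax, Nmax)`, where both
attenuation factors vanish). Each point is classified from the Jacobian of
the governing system evaluated *at that point* (not the interior closed
form); non-hyperbolic points are reported as `marginal`, never silently
assigned. Strong mutualism (`a12·a21 > a11·a22`) makes the interior point a
saddle; under the bounded model the double-ceiling point is then the stable
state that replaces blow-up.

## What the generator does and does not emulate

The synthetic communities are the study conditions themselves: richness
10–250, connectance 0.7, interaction SD 0.2, lognormal(0,1) equilibria,
perturbation SD 0.02, thresholds 1000 / 10⁻⁴ / 10⁻⁵, horizon 1000, ceiling
1000. They are *not* calibrated to any empirical web: no degree structure,
no bipartite or cascade topology, no correlation between `a_ij` and `a_ji`,
no dual interactions, no demographic or environmental noise. Passing tests
therefore establish properties of this random-community ensemble, not of
any particular natural system.

## Problem sizes used in the test suite

The headline experiments use 1000 replicates per richness up to S = 350;
the test suite runs scaled-down versions chosen to exercise the same
regimes: 400 pooled communities for the below-transition stability
proportion (100 at each S in 10–40), 200 unstable replicates at S = 100 for
the all-positive fate split, 50 replicates at each S in {100, 150, 200} for
the competitive persistence cap, and a shared bounded mixed-sign sweep
(S ∈ {60, 100, 140}, 10 replicates, horizon cut to 200 time units — long
after typical convergence at t ≈ 10–30 — so that the rare replicate that
keeps oscillating near the ceiling has bounded cost) for trend-level
properties.

## Known limitations and observed discrepancies

* **Stability proportion below the transition.** Under the default sampling
  scheme the measured proportion of locally stable communities is ≈ 1.0 at
  S = 10–20 but ≈ 0.88 at S = 30 and ≈ 0.63 at S = 40 (it is ≈ 0.89 pooled
  over 100 replicates at each S in {10, 20, 30, 40}). This is what
  random-matrix theory predicts: the circular-law criterion
  `σ·sqrt(S·c) < 1` puts the onset of instability at `S ≈ 1/(c·σ²) ≈ 36`
  for c = 0.7, σ = 0.2, so a proportion of exactly 1 through S = 40 is not
  attainable with this ensemble. Descriptions of the transition as sitting
  near S ≈ 50 match the *midpoint* of the measured fall-off (≈ 45–50), not
  the point where it begins.
* **Non-converged runs.** A minority of large mixed-sign communities
  (roughly 10–15% of unbounded replicates at S = 100; rarer when bounded)
  neither converge nor blow up by t = 1000, sustaining slow competitive
  sorting or fast small-amplitude oscillation among ceiling species. They
  are reported as `time_limit` with survivors counted at the final state.
* The blow-up threshold and the ceiling coincide at 1000 by default, so the
  bounded model cannot blow up; a user raising `Nmax` above
  `blow_up_threshold` would change that interpretation, and the
  configuration validation forbids it.
* Basin geometry, reactivity, structural stability and noise-driven
  dynamics are out of scope.
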