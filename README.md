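# glvsim

A simulator for the viability of large random model ecosystems under
generalized Lotka–Volterra (GLV) dynamics.

Classical random-matrix arguments equate ecosystem viability with the local
stability of an equilibrium: build a random community, linearize at its
equilibrium, and declare it non-viable when some Jacobian eigenvalue has a
positive real part — which happens ever more often as richness and
connectance grow. `glvsim` follows the *trajectories* instead. A community
that escapes an unstable equilibrium may lose species, blow up, or settle
into a smaller (or ceiling-limited) community that persists indefinitely —
and only total extinction is genuinely non-viable. The package is for
theoretical ecologists who want to reproduce, probe, or extend this style of
random-community experiment.

## Model

Communities of `S` species follow the GLV equations

```
dN_i/dt = N_i ( r_i + Σ_j a_ij N_j )
```

with a per-capita interaction matrix `A = (a_ij)` sampled at random:
diagonal fixed at `a_ii = -1` (intraspecific competition), exactly
`round(c·S·(S-1))` off-diagonal entries nonzero (connectance `c`), each an
independent draw from `N(0, σ²)`. Equilibrium abundances are sampled as
`ln N_i* ~ N(0, 1)` and the growth rates are *defined* by `r = -A N*`, so
`N*` is an interior equilibrium by construction. Stability is read off the
spectrum of the Jacobian `J = diag(N*) A` (equivalent to the Routh–Hurwitz
criterion). Initial conditions perturb `N*` with additive Gaussian noise
(SD 0.02, reflected to stay positive) and trajectories are integrated with
LSODA until one of three stopping rules fires: any abundance crosses 1000
(blow-up, unbounded model only), `max_i |dN_i/dt| < 10⁻⁵` (converged), or
`t = 1000` (time limit). Species with final abundance `> 10⁻⁴` count as
alive.

The *bounded* variant multiplies each equation by `(Nmax - N_i)/Nmax`
(default `Nmax = 1000`), which caps every abundance at `Nmax` while
preserving every interior equilibrium; it replaces unlimited growth with
convergence to ceiling equilibria. Sign-constrained scenarios force all
interspecific coefficients negative (pure competition/amensalism) or
positive (pure mutualism/commensalism) with half-Gaussian magnitudes.

A two-species phase-plane module (`glvsim.phaseplane`) analyzes the original
vs. bounded models analytically: isoclines, all equilibria including ceiling
points such as `(Nmax, Nmax)`, and their linear classification.

## Worked example

Sweep three richness levels with five random communities each:

```
$ glvsim sweep --s-grid 20,60,100 --n-reps 5 --seed 1 --out-dir demo
```

`demo/summary.csv` then contains (among other columns):

```
  S  n_reps  prop_stable  prop_blow_up  mean_n_alive
 20       5            1             0          20.0
 60       5            0             0          42.4
100       5            0             1          55.0
```

At `S = 20` every sampled equilibrium is locally stable and all species
persist. By `S = 60` local stability is gone, yet the communities do not
die: on average 42 of 60 species survive in a new equilibrium. At `S = 100`
every replicate had at least one species blow up past 1000 — unstable, but
emphatically not extinct.

The same pipeline for a single hand-built community (here a strongly
mutualistic pair whose interior equilibrium is a saddle, under the bounded
model):

```
$ printf -- "-1.0,2.0\n2.0,-1.0\n" > A.csv
$ printf "1.0\n1.0\n" > Nstar.csv
$ glvsim --quiet simulate-one --matrix A.csv --equilibrium Nstar.csv --bounded --nmax 1000 --seed 1
{
  "S": 2,
  "is_stable": false,
  "max_real_part": 1.0000000000000004,
  "stop_reason": "converged",
  "n_alive": 2,
  "n_at_ceiling": 2,
  ...
}
```

The saddle (`max Re λ = 1`) is escaped and both species ride up to the
abundance ceiling: the locally unstable pair is perfectly viable.
`glvsim phase-plane` exports the corresponding isoclines, equilibria and
vector field as CSV for plotting, and `glvsim scenario` runs the
sign-constrained sweeps.

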