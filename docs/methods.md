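# Methods

## Model and assumptions

The induced defense is a deterministic, well-mixed ODE model of Imd
signaling in the fly gut (nine variables, see README for the equations).
Key assumptions:

* Bacteria grow exponentially at rate `k0` inside the gut and are killed
  by mass action with AMPs (`A·B`). Peptidoglycan release is tied to
  proliferation (`α·k0·B`), so non-replicating bacteria do not trigger
  signaling.
* Relish-dependent transcription uses a saturating occupancy function
  `N/(N + Zn)` with Hill coefficient 1; `Zn` and `Zs` are scalar binding
  energies (inversely proportional to binding probability), not Hill
  exponents. The repressosome acts purely competitively, adding
  `Zn·S/Zs` to the denominator of the AMP production term — it lowers
  AMP output without consuming Relish.
* R, N, L, P, S, A share one degradation rate `λ2`. A per-species
  override exists (`ImdParameters(degradation_rates={...})`) but every
  default and experiment uses the shared rate.
* The constitutive strategy is the same bacterial equation with `A`
  frozen; no signaling machinery, hence no signaling cost.

Initial conditions are all-zero (a naive host) unless overridden; this
also makes the zero-input behavior analytically checkable (only `R`
relaxes, to `R0/λ2`).

## Numerical integration

Both models use fixed-step explicit schemes: Euler with `h = 0.01` by
default, classical RK4 as a higher-order cross-check. A fixed step was
chosen deliberately — the random-walk influx is piecewise constant with
discontinuities every time unit, which adaptive stiff solvers handle
poorly and which makes fixed-step results exactly reproducible. Euler at
`h = 0.01` agrees with RK4 at `h = 0.001` to better than 1% on every
component for the standard sinusoidal benchmark (ω=1, Φ=0.01,
t ∈ [0,100]), and with an independent adaptive LSODA integration in the
test suite.

Euler steps can undershoot zero; every component is floored at zero
after each step (`clip_negative`, on by default) and the number of clip
events is reported on the trajectory. Time averages are arithmetic means
over recorded points (stride 1 by default, initial state included);
recording with stride `s` biases averages by at most
`h·s·max|d/dt|`.

Trajectory kernels are numba-compiled; a walk of 5,000 unit steps
integrates in a few milliseconds, and the constitutive grid scan (200
AMP levels) shares a single sweep per walk.

## Environments and encounters

Environments are 100×100 toroidal lattices carrying `d` colonies grouped
around `p` cluster centers (a Thomas-style cluster process): centers
uniform, colonies assigned to centers as evenly as possible, positions
Gaussian around the center (`cluster_sd = 3` cells by default, chosen to
give visually tight but not degenerate patches) and rounded with wrap.
`p = 1` is maximal heterogeneity; `p = d` reduces to independent uniform
placement. Colonies may stack in one cell; counts are conserved. The
mean toroidal nearest-neighbor distance serves as the clustering
statistic and increases monotonically in `p` (Monte-Carlo checked).

The fly is an unbiased von Neumann random walker (toroidal, uniform
start, no burn-in; sojourns are long enough that start effects are
negligible). While it occupies a cell with colonies it ingests
`dose × colony_count` bacteria per unit time (`dose = 1` by default, the
same scale as the sinusoidal amplitude ω=1 used during optimization);
otherwise influx is zero. Colonies are not depleted — the simplest
Markovian coupling, avoiding an extra regrowth mechanism. One walk step
is one time unit, integrated with 100 Euler substeps.

## Fitness

Per-walk component means feed the exponential fitness functions; across
a batch of walks the strategy fitness is the **mean of per-walk fitness
values**, not the fitness of pooled means (the exponential is convex, so
the order matters and is asserted in a test). The full-cost induced
fitness prices B, N, L, P, S and A but not G, R or C — free
peptidoglycan, unengaged receptors and transient complexes carry no
cost. The `amp_only` mode (`exp(−(wA·Ā + wB·B̄))`) isolates
immunopathology versus bacterial-load costs; `full_cost` forces unit
weights. The constitutive cost term is the constant `A` itself (its time
average, trivially).

## Optimization

The 11 free induced parameters (`λ2, λ3, R0, β1–β6, Zn, Zs`) are tuned
by an accept-if-better multiplicative random walk: one uniformly chosen
parameter per proposal is multiplied by `exp(u)`, `u ~ U(−s, s)` with
`s = 0.5`; proposals outside `[10⁻⁴, 10²]` are rejected, starts are
log-uniform in `[0.01, 10]`, and several restarts are kept
(best-of-restarts). The objective is fitness under the deterministic
sinusoid over `t_end = 10π/Φ` capped at 2,000 time units — at least
three half-periods at Φ = 0.01 while keeping one evaluation at ~10 ms.
Optimizing against the predictable oscillation and then testing under
stochastic walks mirrors how plastic responses evolve under predictable
fluctuations. On a reduced two-parameter landscape the climb reaches the
optimum of an exhaustive 41×41 log-grid oracle (within 5%; in practice
it slightly beats the grid).

The constitutive level is an exhaustive scan of A ∈ {0.01, …, 2.00}
(step 0.01, Euler h = 0.01), averaging fitness across walks; ties break
toward the smaller (cheaper) level. For a fly inhabiting several
environments the scan maximizes the probability-weighted mean of the
per-environment fitness curves — one AMP level must serve them all.

## Experiments

* **Fitness grids / PIW.** One environment realization per (d, p) cell
  (regeneration per walk available via the library), both strategies
  traverse it with the same walk seeds, the constitutive side uses its
  per-environment optimum. PIW is the fraction of cells with strictly
  `F_induced > F_constitutive`; ties count against induction
  (conservative, and measure-zero in floating point).
* **Multi-environment fluctuation.** The pool holds only environments
  in which the constitutive strategy wins in isolation. Each of the
  10,000 (500 at desk scale) repeats draws `j` environments without
  replacement; induced fitness is the mean of per-environment fitness,
  the constitutive opponent is re-optimized for the mixture. The
  two-environment variant weights the draw (q, 1−q).
* **Perturbations.** `γ` rescales β3 and β4 together (input-level
  feedback strength), `δ` rescales `Zs` (output-level repression, with
  δ=1 always in the scan; larger δ = weaker binding). With β5 = 0 the
  repressosome is never produced and fitness is bitwise invariant in δ,
  which validates the scan plumbing.

## Problem sizes

Full-scale runs use 1,000 walks of 100,000 steps per environment; the
test suite and acceptance script run the same pipeline at desk scale —
100 walks × 5,000 steps for environment evaluations, 500 resampling
repeats, 200 generator seeds, 2,000×3 hill-climb proposals — sizes at
which every qualitative result reported here is stable under seed
changes. The packaged multi-environment experiment uses six uniform
(p = d) environments with d ∈ {1000, …, 8000} at k0 = 0.1: uniform
high-density cells are the constitutive-favored regime, and their
optimal AMP levels span A* ≈ 0.4–1.0, giving the strongly differing
per-environment optima the fluctuation mechanism needs. With that pool,
PIW rises from 0 at j = 1 to 1 at j = 5.

## What the generator does and does not emulate

Synthetic environments capture two axes of real bacterial landscapes —
overall density and spatial aggregation — on a torus with static
colonies. They do not model colony growth or depletion, chemotaxis,
biased movement, multiple bacterial species, or within-gut spatial
structure; the kinetics are deterministic ODEs, not stochastic chemical
kinetics. Passing tests therefore demonstrate the comparative logic of
induced versus constitutive strategies under encounter uncertainty, not
quantitative predictions for any particular host–pathogen pair.

## Known limitations and open choices

* The Hill-coefficient reading of the occupancy terms (`n = 1`) is one
  of two defensible interpretations; exponents other than 1 would need a
  one-line kernel change.
* The optimizer is a local stochastic search; restarts mitigate but do
  not eliminate landscape multimodality. Optimized parameter values are
  seed-dependent even when the achieved fitness is stable, so analyses
  treat them as *an* optimum, not *the* optimum.
* Degenerate inputs: `t_end = 0` yields a single-point trajectory;
  sterile environments give exactly-zero means (induced fitness exactly
  1); extreme parameter corners can overflow Euler steps, which is
  detected and reported (or rejected, inside the optimizer) rather than
  silently clipped.
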