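# imdsim

Mechanistic simulation of **induced versus constitutive immune defense**,
built on the *Drosophila melanogaster* Imd (immune deficiency) signaling
pathway. The package asks a classic question in evolutionary immunology —
when should a host keep its defenses always on, and when should it induce
them on demand? — with a model detailed enough to resolve the three
negative feedback loops that shape real induced responses.

## The model

The induced strategy is a system of nine coupled ODEs describing gut
bacteria `B`, free peptidoglycan `G`, surface receptors `R`, the
receptor–peptidoglycan complex `C`, active Relish (NF-κB) `N`, the
peptidoglycan scavenger PGRP-LB `L`, Pirk `P`, the repressosome complex
`S`, and antimicrobial peptides `A`:

```
dB/dt = f(t) + k0·B − A·B
dG/dt = α·k0·B − L·G − R·G + P·C + λ3·C − λ1·G
dR/dt = R0 + β1·N/(N+Zn) − P·R − R·G + λ3·C − λ2·R
dC/dt = R·G − P·C − λ3·C
dN/dt = β2·C − λ2·N
dL/dt = β3·N/(N+Zn) − λ2·L
dP/dt = β4·N/(N+Zn) − λ2·P
dS/dt = β5·N/(N+Zn) − λ2·S
dA/dt = β6·N/(N + Zn + Zn·S/Zs) − λ2·A
```

`f(t)` is the bacterial influx as the fly moves through its world: either
a deterministic oscillation `f(t) = ω·sin(tΦ)²` or a piecewise-constant
series produced by a random walk across a lattice of bacterial colonies
with chosen density `d` and patchiness `p`. The three negative feedbacks
are PGRP-LB (scavenges the ligand), Pirk (removes receptors and
complexes) and the repressosome (competes with Relish at AMP promoters
with binding energy `Zs`). The constitutive strategy fixes `A` to a
constant, leaving only the bacterial equation.

Fitness decays exponentially with the time-averaged burden of infection
plus immunity: `F_induced = exp(−(B̄+N̄+L̄+P̄+S̄+Ā))` and
`F_constitutive = exp(−(B̄+A))`. Strategies are compared by
`ΔF = F_constitutive − F_induced` and, across many environments, by the
**proportion of induced wins (PIW)**. The induced strategy's 11 free
parameters are tuned by a stochastic hill-climb under sinusoidal input;
the constitutive level is an exhaustive grid search over A ∈ 0.01…2.

## Worked example

```python
import imdsim as im

# an optimized induced strategy for intermediate encounter frequency
strategy = im.optimize_induced(
    phi=0.01, k0=0.1, alpha=2.0,
    cfg=im.OptimizerConfig(n_iterations=400, n_restarts=2, seed=101),
)
print(f"induced fitness under sinusoidal input: {strategy.fitness:.3f}")

# a patchy and a uniform environment at the same colony density
for p in (1, 2000):
    env = im.generate_environment(
        im.EnvironmentSpec(density=2000, patchiness=p, seed=7))
    walks = im.WalkConfig(n_steps=5000, n_walks=100, seed=11)
    res = im.evaluate_environment(strategy, k0=0.1, env=env, walk_cfg=walks)
    print(f"p={p:>4}:  F_induced={res['F_induced']:.3f}  "
          f"F_constitutive={res['F_constitutive']:.3f}  "
          f"delta_F={res['delta_F']:+.3f}")
```

prints

```
induced fitness under sinusoidal input: 0.241
p=   1:  F_induced=0.847  F_constitutive=0.536  delta_F=-0.311
p=2000:  F_induced=0.361  F_constitutive=0.369  delta_F=+0.008
```

With the same 2,000 colonies, a single tight patch (`p=1`) means long
bacteria-free stretches punctuated by bursts — the induced defense stays
cheap between bursts and wins decisively (ΔF < 0). Spreading the
colonies uniformly (`p=d`) makes encounters constant and predictable,
and the always-on defense edges ahead (ΔF > 0).

A command-line interface mirrors the library
(`imdsim simulate|optimize-induced|optimize-constitutive|simulate-walks|run-grid|piw|multi-env|gamma-scan|delta-scan`);
run `imdsim --help` for details.

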