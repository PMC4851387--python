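# togglepop

Analysis of quorum-coupled genetic toggle-switch populations: bistability,
orthant monotonicity, equilibrium continuation with bifurcation detection,
and "majority-vote" self-correction experiments.

Two architectures are modeled. The **S (symmetric) design** couples two
mutually repressing genes (`x`, `y`) through a pair of quorum-sensing
autoinducers (`g`, `r` intracellular, `g_e`, `r_e` extracellular), one arm
per gene; its signed species-influence graph is balanced and strongly
connected, so the population model is strongly monotone and generic
trajectories converge to equilibria. The **A (asymmetric) design** carries
a single quorum-sensing arm and is not monotone. A population of `N` cells
has `4N + 2` state variables (S) or `3N + 1` (A); all cells exchange
autoinducer with a shared medium through a mean-field term weighted by the
population density.

## What the package computes

- `togglepop.models` — vector fields and dense analytic Jacobians of both
  population models, mirror (green/red) symmetry maps, forward-invariant
  box bounds.
- `togglepop.params` — dimensionless parameter presets (`reference`,
  `modified`) and the dimensional-to-dimensionless scaling map.
- `togglepop.monotone` — signed influence graphs, balance (2-coloring)
  with odd-cycle witnesses, strong connectivity, Kamke order-preservation
  harness, monotone parametric-shift checks, oscillation probe.
- `togglepop.equilibria` — damped-Newton equilibrium refinement,
  multistart enumeration, single-toggle bistability region scans over the
  `(a1, a2)` plane, and the N-independent spectrum reduction: the full
  population Jacobian's eigenvalues are reproduced by auxiliary systems of
  2 (homogeneous), 3 ((1:1)-mixed) or 4 ((N1:N2)-mixed) toggles.
- `togglepop.continuation` — pseudo-arclength continuation with fold (LP)
  and branch-point (BP) detection, bisection localization to 1e-4, and
  branch switching along the critical eigenvector. At reference
  parameters the symmetric (1:1)-mixed state loses stability at a
  symmetry-breaking BP near `d ≈ 1.42` and the asymmetric branches fold
  near `d ≈ 2.07`.
- `togglepop.experiments` — seeded flip-and-jitter initial-condition
  generation, the three-step self-correction protocol, and random
  convergence probes.

## CLI

Each subcommand writes CSV/JSON artifacts plus a `manifest.json` (config
echo, version, seed) into `--out`:

```sh
togglepop monotone --model S --out out/monotone       # partition + DOT graph
togglepop monotone --model A --out out/monA           # odd-cycle witness
togglepop equilibria --model S --d 0 --out out/eq     # single-toggle states
togglepop continue --model S --ratio 1:1 --param d --from 0.1 --to 3 \
    --out out/branch                                  # BP + LP event log
togglepop region --model A --gamma 0 --out out/region # bistability scan
togglepop reduction-check --ratio 9:1 --n-cells 10 --out out/red
togglepop self-correct --model S --d-values 0.01,10,100 --out out/sc
togglepop simulate --model S --n-cells 2 --out out/sim
```

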