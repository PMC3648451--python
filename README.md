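# comswitch

Multi-scale agent-based simulation of the competence switch in *Bacillus
subtilis*.

In a genetically identical *B. subtilis* culture, 10–20% of cells enter a
transient DNA-uptake state (**competence**) during stationary phase. The
switch is driven by the bistable expression of the master regulator **ComK**:
ComK activates its own promoter (as dimers and a two-dimer tetramer,
stimulated by DegU), is silenced by repressors, and is degraded by the
MecA/ClpC/ClpP protease complex; the small protein **ComS** — produced in
response to the quorum-sensing pheromone **ComX** — competes with ComK for
MecA and thereby shields ComK from degradation. `comswitch` models this
network *without rate equations*: every molecule is an agent on a 3-D
occupancy lattice (40×40×40) performing a random walk, and every reaction is
a per-tick probability fired on chance encounters. Each such intracellular
model is itself an agent on a 2-D culture plate (40×40) with diffusing
nutrient and ComX-peptide fields, logistic energy dynamics
(`m ← m + μm − μm²/k`, μ = 0.0058, k = 16), chemotaxis, division with
spatial partitioning of molecular contents, and death.

The package is for computational/systems biologists who want to study how
**spatial-temporal noise** — where molecules happen to be, and whom they
happen to meet — produces phenotype switching, how growth-phase dynamics
gate it, and how molecular inheritance at division biases it, using an
explicitly stochastic, individual-molecule formulation rather than
Gillespie-style well-mixed kinetics.

## Worked example

Spontaneous competence from spatial noise alone — identical molecule counts,
different random placements (`examples/intracellular_competence.py` runs the
10-replicate version of this):

```python
from comswitch import intracellular_replicates

res = intracellular_replicates(n=100, ticks=10_000, base_seed=1)
print(res.n_competent, "/", res.n_replicates, "replicates competent")
print(res.summary.final_comk.describe())
```

Output from this exact call:

```
3 / 100 replicates competent
count    100.000000
mean       8.330000
std        4.182829
min        1.000000
25%        6.000000
50%        7.000000
75%       10.000000
max       24.000000
Name: final_comk, dtype: float64
```

All 100 replicates start with the maximal initial quantities
(ComK = ComS = ComX = DegU = 12) and identical probabilities; only the
random spatial placement and scheduling differ. Most runs hover near the
production–degradation balance (median 7 ComK), but the distribution is
right-skewed: a small minority ignites the ComK positive-feedback loop and
crosses the competence threshold (> 20 ComK) — here 3 of 100, matching the
few-percent spontaneous rate expected without growth, starvation, or
quorum input.

Other entry points (see `examples/`):

* `examples/random_walk_and_diffusion.py` — the spatial substrate: excluded-
  volume Brownian motion and conservative field diffusion.
* `examples/culture_growth_curve.py` — a 20-cell seed growing through lag,
  exponential, stationary and death phases on a finite plate.
* `examples/lineage_inheritance.py` — division trees in Newick format and
  the earlier competence onset of daughters that inherited ComK.

A thin CLI wraps the same functions: `comswitch run`, `comswitch replicate`,
`comswitch analyze` (see `--help`).

## Layout

| module | contents |
| --- | --- |
| `comswitch.lattice` | occupancy grids, Moore neighborhoods, random walks |
| `comswitch.rules` | species codes and the rule-probability table |
| `comswitch.intracellular` | the 3-D regulatory-network ABM (+ numba kernel in `_kernel`) |
| `comswitch.culture` | value layers, energy equation, cell rules, shove, division |
| `comswitch.config` / `engine` | serializable configuration and the two-tier scheduler |
| `comswitch.observers` | growth curves, phase segmentation, lineage capture, Newick |
| `comswitch.experiments` | replicate batteries and the inheritance statistics |

`docs/methods.md` documents the model, its assumptions, parameter defaults,
and known limitations.
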