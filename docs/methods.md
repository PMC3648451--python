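# Methods

## The model

`comswitch` is a two-tier, discrete-time, discrete-space stochastic model of
competence switching in *Bacillus subtilis*.

**Intracellular tier.** One cell's regulatory state is a set of molecular
agents — ComK, ComS, ComX, DegU, MecA, ClpC/ClpP (one agent, "ClpCP"),
ribosomes, generic repressors, and comK/comS transcripts — on a 40×40×40
occupancy lattice with reflecting boundaries and single occupancy per site.
The lattice stands for the nucleoid-proximal region of the cell; its volume
is constant. Each tick, every agent and promoter is visited once in a fresh
random order and attempts each of its rules once:

* **move** — one uniformly drawn Moore neighbor (26 in the interior, fewer
  at walls); the step is taken only if the target site is free. Bound
  complexes (ComK homodimers, ClpCP·MecA with or without a substrate,
  ribosome·mRNA) occupy one site and move as a unit.
* **bind** — the agent inspects *one* uniformly random neighboring site; if
  its occupant has a defined interaction, a single uniform draw against the
  rule probability decides: ComK+ComK→dimer (0.8), ribosome+mRNA (0.9),
  ClpCP+MecA (0.5), protease-complex capture of ComK (0.6) or ComS (0.7),
  repressor/DegU/ComX→promoter (0.5 each), ComK dimer→comK promoter (0.5,
  or 0.8 when DegU is present). A ClpCP·MecA·ComK complex that encounters
  free ComS swaps substrates unconditionally (ComS binds MecA more tightly;
  the freed ComK takes the ComS's vacated site, conserving both counts and
  occupancy). The alternative reading — scanning the whole neighbor shell
  per attempt — is available (`bind_scan="all"`) but is not the default:
  it drives per-transcript protein yields into the hundreds and makes
  runaway ComK production the typical outcome rather than the rare one.
* **transcription** (promoters) — per-tick success probability 10⁻⁴ bare,
  10⁻³ with one bound ComK dimer, 0.5 with the tetramer (two dimers), and
  0.5 for the comS promoter when ComX is bound; a bound repressor blocks
  transcription entirely. On success an mRNA agent appears at a free
  adjacent site and all bound activators are released.
* **translation** — a ribosome·mRNA complex produces the matching protein
  (ComK or ComS) at a free adjacent site with probability 0.5 per tick; on
  success the ribosome releases the transcript (it may rebind at 0.9 on a
  later encounter). With encounter-limited rebinding a single transcript
  typically yields on the order of ten proteins over its lifetime.
* **death** — an unbound transcript decays at 10⁻⁴ per tick (bound
  transcripts are protected); a protease complex destroys its held
  substrate at 0.5 per tick; promoter-bound repressor and DegU dissociate
  at 10⁻⁴ per tick.

A cell is **competent** as soon as more than `competence_threshold`
(default 20) ComK monomer units exist — free monomers, dimer members, and
protease-bound ComK all count — and the flag never reverts. The threshold
is the model's deliberately small stand-in for the ~50,000 dimers of a real
competent cell; it is an estimated parameter, exposed in the configuration.

**Promoter representation.** The published agent inventory lists 12
promoter agents alongside one comK and one comS transcription unit. We
model one *multi-slot promoter region* per gene (comK: repressor slot, DegU
slot, two ComK-dimer slots; comS: repressor slot, ComX slot) and read the
count of 12 as the individual binding sites of those two regions. This is
forced by self-consistency: each transcribing promoter contributes
basal/decay ≈ 1 standing transcript, so six transcribing comK promoters
would hold ~6 comK mRNAs and drive steady-state ComK far above the
competence threshold in every run, whereas one region per gene keeps ~1
standing comK transcript and makes spontaneous competence the rare event it
must be. `n_promoters` is configurable for experiments with other splits.

**Culture tier.** Cells live on a 40×40 plate (reflecting, single
occupancy) shared with two non-negative fields, nutrients and ComX peptide,
updated synchronously each tick by a conservative Moore-neighborhood
diffusion rule, `new_i = old_i + (D/8)·Σ_j(old_j − old_i)` with D = 0.1
(equal-weight flux form; in the interior this is exactly
`old + D·(mean_of_neighbors − old)`, at the boundary absent neighbors
contribute zero flux, so total mass is conserved and uniform fields are
exact fixed points). Cell energy `m` follows a logistic map split across
two rules: consuming one nutrient (every tick when the local value is ≥ 1)
adds `μm`; the move rule charges `μm²/k` each tick. μ = 0.0058, k = 16,
m₀ = 5. Under continuous feeding the combined map has its unique positive
fixed point at k, and a fed cell starting at m = 8 first exceeds the
division threshold 15 after ≈ 467 ticks (the continuous-logistic estimate
`(1/μ)·ln(15·8/8)`). When local nutrients fall below 1 the cell starves:
the growth update is replaced by a drain of `d/(k/2)` per tick
(d = 0.002), and each starving tick one randomly selected intracellular
repressor is removed with probability 0.001 — the nutrient-limitation
signal that derepresses comK. Chemotaxis (relocation to a strictly richer
free neighbor) is gated at 0.5 per tick; peptide exchange runs on cadences
(absorb one ComX peptide every 50 ticks at 0.8, which injects a ComX agent
into the intracellular model; secrete one every 100 ticks at 0.8). A
non-competent cell with energy above 15 divides with probability 0.8 per
tick — competent cells never divide; cells below 0.5 energy die at 10⁻⁴
per tick, and mid-energy cells (0.5–7.5) additionally die at 10⁻⁴ on a
50-tick cadence. Dying cells return their remaining energy to the local
nutrient field.

**Division and inheritance.** A dividing cell is bisected by a randomly
oriented axis-aligned plane through the lattice center. ComK, ComS, ComX
and transcripts on the daughter side transfer to the daughter (dimers move
wholesale by their site; protease- and ribosome-bound substrates are first
released and partition by their complex's site); both cells re-place their
partitioned molecules uniformly at random. The daughter receives a fresh
machinery complement (80 ribosomes, 20 MecA, 20 ClpCP, 2 repressors) and a
promoter set identical in composition to the parent's — gene segregation is
deterministic, as in real chromosome replication, so every cell always
holds a full complement. Energy is halved between parent and daughter; the
daughter lands on a random adjacent site, displacing incumbents through a
rippling shove that terminates at the nearest free site. The lineage store
records, per cell, the division tick, inherited ComK protein and comK
transcript counts, and the competence onset tick; trees export to Newick
with branch length = ticks from division to competence (0 for cells that
never switched) and labels `c<id>_k<transcripts>_p<proteins>`.

**Scheduling and randomness.** One global tick = both layers diffuse, then
cells act in a freshly shuffled order; each cell attempts its culture rules
in a freshly shuffled order and then advances its intracellular model one
tick (internally a fresh permutation over agents and promoters). Agents and
cells created during a tick act from the next tick; competence and division
decisions read end-of-previous-tick state. Since molecular agents of
different cells never interact, per-cell contiguous execution is
dynamically equivalent to a single global shuffle over all molecular
agents, at far lower bookkeeping cost. All randomness derives from one
master `SeedSequence` through named substreams (placement, culture rules,
scheduler, one per intracellular model; daughters spawn from their parent
model's sequence), so any run is bit-reproducible from `(config, seed)`.
The intracellular per-tick loop is compiled with numba; the Python-level
single-operation methods call the same compiled helpers, so tests exercise
exactly the simulated rules.

## Experiments and problem sizes

* **Intracellular replicates** (`intracellular_replicates`): n independent
  models with ComK = ComS = ComX = DegU = 12 (the maxima of the published
  initial-quantity ranges), differing only in placement/scheduling
  randomness, run for a default budget of 10,000 ticks. With the shipped
  defaults a few percent of replicates cross the competence threshold, the
  final-ComK distribution is strongly right-skewed, and roughly one comK
  transcript is present at any time.
* **Culture runs**: the full-scale configuration (40×40 plate, 375
  nutrients/site — calibrated so the 20-cell seed plateaus at ~850–900
  cells, at ~720 nutrient units per division including maintenance —
  43,000 ticks) reproduces the canonical growth curve with
  a plateau of several hundred cells; a complete run takes hours and is not
  exercised by the test suite. The **reduced profile** (`scaled_config()`:
  20×20 plate, 150 nutrients/site, death-rate constant scaled tenfold to
  0.02, 8,000 ticks) compresses the colony dynamics to desk scale: ~80-cell
  plateau, all four growth phases within the horizon. The compression has a
  known cost: stationary-phase competence is driven by the slow autocatalytic
  ignition of the comK positive-feedback loop, which accumulates to a
  10–20% competent fraction only over the full tens of thousands of
  stationary ticks; a severalfold shorter stationary phase therefore shows
  the colony dynamics faithfully but yields few or no competence events,
  and the inheritance comparison needs the full horizon to populate both
  groups. Time, not plate size or nutrient load, is the binding variable
  for competence statistics.
* **Inheritance analysis** (`inheritance_analysis`): competent daughters
  are grouped by inherited ComK protein (nonzero vs zero); the latency from
  division to competence onset is compared by Welch's t-test (default) or a
  rank-sum alternative. Grouping uses protein counts only; transcript
  counts are recorded but do not define groups.

## Numerical and design notes

* Reflecting boundaries everywhere; a blocked move is a legal no-op.
* Complexes occupy one lattice site (the initiating agent's); members are
  carried along and released to distinct free sites, preserving single
  occupancy exactly (occupancy bookkeeping is assertable per tick and
  checked in tests).
* The protease engages substrates only as the assembled ClpCP·MecA complex,
  and only free ComK/ComS monomers are captured; ComK locked in dimers is
  degradation-protected, which produces the slow upward ComK ratchet that
  underlies late-arising competence.
* The metabolic cost is charged every tick (the 0.5 move probability gates
  only the chemotaxis relocation); in starvation the drain replaces the
  growth terms entirely rather than stacking with them.
* The repressor-removal probability is 0.001 per starving tick (the
  move-rule estimate; an alternative 10⁻⁴ appears in the published rule
  table and is reachable via configuration).
* Degenerate inputs: a fully packed neighborhood defers translation release
  and mRNA placement to a later tick; a completely full plate skips
  division; `max_ticks = 0` yields only the initial census.
* Growth-phase segmentation thresholds the smoothed cell count on its rise
  (10% of amplitude) and fall (5% of peak); "end of stationary" is the last
  tick before the sustained decline. This is an analysis convenience, not
  part of the model.

## Limitations

The model omits downstream competence genes and actual DNA uptake, explicit
Rok/AbrB/CodY repressors (one generic repressor species stands for all
three), RNA-polymerase and elongation, the ComP/ComA phospho-relay (ComX
acts directly on the comS promoter), and off-lattice or excluded-volume
physics beyond single occupancy. Molecule numbers are orders of magnitude
below biological counts by construction; ratios, not absolute quantities,
carry the behavior. Synthetic data produced by the generator (growth
curves, lineages) therefore demonstrate internal consistency of the
mechanism — spatial noise, dilution, inheritance — not quantitative
agreement with any particular laboratory culture.
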