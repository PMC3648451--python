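"""Spontaneous competence from spatial noise alone.

Runs a handful of intracellular-only replicates with *identical* maximal
initial molecule counts (ComK = ComS = ComX = DegU = 12); the only difference
between replicates is where the molecules happen to start and in which order
they act. Most stay in the low-ComK (vegetative) state; occasionally one
ignites the ComK positive-feedback loop and crosses the competence threshold
of 20 ComK — the model's account of phenotypic noise.

The full published experiment is 100 replicates x 10,000 ticks (several
minutes); this demo runs 10 so it finishes quickly. Expect roughly 3-5%
competent at full scale.
"""

from comswitch import intracellular_replicates

res = intracellular_replicates(n=10, ticks=10_000, base_seed=1, progress=False)
print(res.summary.to_string(index=False))
print(f"\ncompetent replicates: {res.n_competent}/{res.n_replicates} "
      f"(threshold: ComK > {res.threshold})")
print("final_comk is right-skewed: a minority of runs diverges to high ComK "
      "while the rest hover near the degradation-production balance.")
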