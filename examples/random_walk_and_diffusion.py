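"""Spatial substrate demo: excluded-volume random walks and layer diffusion.

Shows the two physical transport processes of the model: Brownian motion of
molecular agents on the 3-D interior lattice (mean squared displacement grows
linearly with time) and the conservative Moore-neighborhood diffusion of a
nutrient field on the 2-D plate.
"""

import numpy as np

from comswitch import Grid, ValueLayer

rng = np.random.default_rng(0)

# --- random walk: MSD of 500 lone walkers ---------------------------------
start = (40, 40, 40)
t_max = 80
msd = np.zeros(t_max)
for _ in range(500):
    g = Grid((81, 81, 81))
    g.place(0, start)
    for t in range(t_max):
        pos = g.random_walk_step(0, rng)
        msd[t] += sum((a - b) ** 2 for a, b in zip(pos, start))
msd /= 500
print("random walk MSD (expected slope 2.0 per tick for a uniform Moore step):")
for t in (9, 19, 39, 79):
    print(f"  t={t + 1:3d}  msd={msd[t]:7.1f}  msd/t={msd[t] / (t + 1):.2f}")

# --- diffusion: a nutrient spike spreads, mass is conserved ----------------
layer = ValueLayer((40, 40), initial=0.0, diffusion_constant=0.1)
layer.values[20, 20] = 1000.0
total0 = layer.total()
for step in (1, 10, 100, 1000):
    target = step
    done = 0
    while done < target:
        layer.diffusion_step()
        done += 1
    peak = layer.values.max()
    print(f"after {step:5d} more steps: peak={peak:9.3f}  "
          f"total={layer.total():.6f} (started {total0:.0f})")
# The peak value decays toward the uniform level 1000/1600 = 0.625 while the
# total never changes: diffusion only moves mass down the gradient.
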