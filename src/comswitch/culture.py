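"""The 2-D culture tier: diffusing fields, cell energy, and cell rules.

Cells live on a 40x40 plate shared with two continuous concentration fields
(a nutrient layer and the ComX quorum-sensing peptide layer), both updated by
a discrete Moore-neighborhood diffusion rule. Each cell carries an embedded
:class:`~comswitch.intracellular.IntracellularModel`; the culture rules
(chemotaxis, consumption, peptide exchange, division, death) couple the two
tiers: consumed peptide molecules become intracellular ComX agents, and
starvation removes intracellular repressors.

Energy follows a discrete logistic map split across two rules: consuming a
nutrient grants ``mu*m``; the move rule charges the metabolic cost
``mu*m^2/k`` every tick. Under continuous feeding the net map
``m <- m + mu*m - mu*m^2/k`` has its unique positive fixed point at the
energy ceiling ``k``; a cell divides when ``m`` exceeds the division
threshold (one unit below ``k``). When local nutrients fall below 1 the cell
starves and instead drains ``d/(k/2)`` per tick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .intracellular import IntracellularModel
from .lattice import Grid, moore_offsets


# -- diffusing concentration fields -----------------------------------------

class ValueLayer:
    """A non-negative 2-D concentration field with Moore-neighborhood
    diffusion on a closed (reflecting) plate.

    The update is the pairwise flux form
    ``new_i = old_i + (D/8) * sum_j (old_j - old_i)`` over the clipped Moore
    neighborhood, computed synchronously from the pre-step field. In the
    interior this equals ``old + D*(neighborhood_mean - old)``; missing
    neighbors at the boundary contribute zero flux, so total mass is
    conserved and a uniform field is an exact fixed point.
    """

    def __init__(self, dims: tuple[int, int], initial: float = 0.0,
                 diffusion_constant: float = 0.1):
        if not (0.0 <= diffusion_constant <= 1.0):
            raise ValueError("diffusion constant must be in [0, 1]")
        if initial < 0:
            raise ValueError("concentrations must be non-negative")
        self.dims = tuple(int(d) for d in dims)
        self.D = float(diffusion_constant)
        self.values = np.full(self.dims, float(initial), dtype=np.float64)

    @staticmethod
    def _shift(n: int, d: int) -> tuple[slice, slice]:
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    def diffusion_step(self) -> None:
        v = self.values
        if np.any(v < 0):
            raise ValueError("negative concentration in value layer")
        flux = np.zeros_like(v)
        n0, n1 = self.dims
        for dx, dy in moore_offsets(2):
            c0, s0 = self._shift(n0, dx)
            c1, s1 = self._shift(n1, dy)
            flux[c0, c1] += v[s0, s1] - v[c0, c1]
        self.values = v + (self.D / 8.0) * flux

    def total(self) -> float:
        return float(self.values.sum())

    def save_txt(self, path) -> None:
        """Dump the field as a plain-text matrix (one row per grid row)."""
        np.savetxt(path, self.values, fmt="%.6g")

    @classmethod
    def load_txt(cls, path, diffusion_constant: float = 0.1) -> "ValueLayer":
        values = np.loadtxt(path, ndmin=2)
        layer = cls(values.shape, 0.0, diffusion_constant)
        layer.values = values.astype(np.float64)
        return layer


# -- cell agents -------------------------------------------------------------

@dataclass
class CellAgent:
    """One bacterium on the plate, wrapping its intracellular model."""

    cell_id: int
    pos: tuple[int, int]
    energy: float
    model: IntracellularModel
    birth_tick: int = 0
    parent_id: Optional[int] = None
    starving: bool = False
    alive: bool = True

    @property
    def competent(self) -> bool:
        # the cell-level phenotype mirrors the intracellular flag
        return self.model.competent


# -- energy arithmetic (the growth equation) ---------------------------------

def energy_gain(m: float, mu: float) -> float:
    """Energy gained by consuming one nutrient molecule."""
    return mu * m


def energy_cost(m: float, mu: float, k: float) -> float:
    """Per-tick metabolic cost charged by the move rule."""
    return mu * m * m / k


def starvation_drain(d: float, k: float) -> float:
    """Per-tick energy loss once local nutrients are exhausted."""
    return d / (k / 2.0)


def logistic_energy_map(m: float, mu: float, k: float) -> float:
    """The combined fed-cell update ``m + mu*m - mu*m^2/k``; its unique
    positive fixed point is ``m = k``."""
    return m + mu * m - mu * m * m / k


def ticks_to_exceed(m0: float, threshold: float, mu: float, k: float,
                    max_ticks: int = 10_000_000) -> int:
    """Iterate the fed-cell map until the division threshold is exceeded."""
    m = float(m0)
    for t in range(1, max_ticks + 1):
        m = logistic_energy_map(m, mu, k)
        if m > threshold:
            return t
    raise RuntimeError("threshold never exceeded")


# -- cell rules ---------------------------------------------------------------

def chemotaxis_move(cell: CellAgent, nutrients: ValueLayer, grid: Grid,
                    rng: np.random.Generator, cfg) -> bool:
    """The cell move rule.

    The metabolic cost applies on every execution (every tick, unless the
    cell is starving, whose drain replaces the growth equation entirely);
    while starving, one randomly selected intracellular repressor is removed
    if a 0.001 draw succeeds. The chemotaxis step itself is gated at
    ``p_move``: with nutrients (>= 1) at the current site the cell stays,
    otherwise it moves to a uniformly chosen free neighbor with strictly
    higher nutrient concentration (staying if there is none).
    """
    if not cell.starving:
        cell.energy -= energy_cost(cell.energy, cfg.mu, cfg.k_max)
    elif rng.random() < cfg.p_repressor_removal:
        cell.model.remove_random_repressor(rng)
    if rng.random() >= cfg.p_move:
        return False
    here = float(nutrients.values[cell.pos])
    if here >= cfg.starvation_level:
        return False
    options = [
        q for q in grid.neighbors(cell.pos)
        if grid.is_free(q) and float(nutrients.values[q]) > here
    ]
    if not options:
        return False
    target = options[int(rng.integers(len(options)))]
    grid.move(cell.cell_id, target)
    cell.pos = target
    return True


def consume_nutrients(cell: CellAgent, nutrients: ValueLayer, cfg) -> None:
    """Consume one nutrient molecule (energy gain ``mu*m``), or starve.

    Below one nutrient at the cell's site the growth equation is replaced by
    the starvation drain ``d/(k/2)``.
    """
    local = float(nutrients.values[cell.pos])
    if local >= cfg.starvation_level:
        nutrients.values[cell.pos] = local - 1.0
        cell.energy += energy_gain(cell.energy, cfg.mu)
        cell.starving = False
    else:
        cell.starving = True
        cell.energy = max(0.0, cell.energy - starvation_drain(cfg.death_rate, cfg.k_max))


def consume_peptide(cell: CellAgent, peptides: ValueLayer, tick: int,
                    rng: np.random.Generator, cfg) -> bool:
    """Every ``consume_peptide_period`` ticks, absorb one ComX peptide with
    probability 0.8; the absorbed molecule becomes an intracellular ComX
    agent (the quorum signal entering the network)."""
    if tick % cfg.consume_peptide_period != 0:
        return False
    if float(peptides.values[cell.pos]) < 1.0:
        return False
    if rng.random() >= cfg.p_consume_peptide:
        return False
    peptides.values[cell.pos] -= 1.0
    cell.model.inject_comx()
    return True


def generate_peptide(cell: CellAgent, peptides: ValueLayer, tick: int,
                     rng: np.random.Generator, cfg) -> bool:
    """Every ``generate_peptide_period`` ticks, secrete one ComX peptide with
    probability 0.8 (independent of the cell's internal ComX agents)."""
    if tick % cfg.generate_peptide_period != 0:
        return False
    if rng.random() >= cfg.p_generate_peptide:
        return False
    peptides.values[cell.pos] += 1.0
    return True


def life_step(cell: CellAgent, rng: np.random.Generator, cfg) -> str:
    """Division/death decision: returns ``"divide"``, ``"die"`` or ``"none"``.

    A cell divides (probability ``p_divide`` per tick) once its energy
    exceeds the division threshold — unless it is competent: competent cells
    do not divide. A cell whose energy has collapsed below
    ``low_energy_level`` is removed with a small per-tick probability.
    """
    if (cell.energy > cfg.division_threshold and not cell.competent
            and rng.random() < cfg.p_divide):
        return "divide"
    if cell.energy < cfg.low_energy_level and rng.random() < cfg.p_low_energy_death:
        return "die"
    return "none"


def density_death_step(cell: CellAgent, tick: int,
                       rng: np.random.Generator, cfg) -> bool:
    """Random die-off of mid-energy cells, attempted on a 50-tick cadence."""
    if tick % cfg.density_death_period != 0:
        return False
    lo, hi = cfg.density_death_window
    if not (lo <= cell.energy <= hi):
        return False
    return rng.random() < cfg.p_density_death


def shove(grid: Grid, site: tuple[int, int], rng: np.random.Generator,
          max_steps: Optional[int] = None) -> list[int]:
    """Resolve double occupancy at ``site`` by rippling displacements.

    The incumbent at ``site`` is displaced one step to a neighboring site: a
    uniformly chosen free neighbor if any exists, otherwise a uniformly
    chosen occupied neighbor whose occupant is shoved in turn. The ripple
    terminates when a free site absorbs it; the vacated origin stays
    reserved for the newcomer and never re-absorbs the ripple. Returns the
    occupant ids that moved, in ripple order; the caller places the new
    occupant at ``site`` afterwards.
    """
    moved: list[int] = []
    in_hand = grid.occupant(site)
    if in_hand is None:
        return moved
    grid.remove(in_hand)
    origin = tuple(site)
    here = origin
    limit = max_steps if max_steps is not None else 10 * grid.nsites
    for _ in range(limit):
        neigh = [q for q in grid.neighbors(here) if q != origin]
        free = [q for q in neigh if grid.is_free(q)]
        if free:
            target = free[int(rng.integers(len(free)))]
            grid.place(in_hand, target)
            moved.append(in_hand)
            return moved
        target = neigh[int(rng.integers(len(neigh)))]
        displaced = grid.occupant(target)
        grid.remove(displaced)
        grid.place(in_hand, target)
        moved.append(in_hand)
        in_hand = displaced
        here = target
    raise RuntimeError("shove did not terminate")  # pragma: no cover


def divide_inheritance(model: IntracellularModel,
                       rng: Optional[np.random.Generator] = None):
    """Partition the parent's ComK/ComS/ComX/transcripts through a random
    central plane; see :meth:`IntracellularModel.divide`."""
    return model.divide(rng)
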