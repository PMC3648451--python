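"""Simulation configuration: every tunable parameter in one serializable
record, with defaults reproducing the published parameter set.

``default_config()`` is the full-scale experiment (40x40 plate, ~43,000-tick
horizon). ``scaled_config()`` is a reduced profile (20x20 plate, less
nutrient, compressed starvation timescale, ~8,000 ticks) that preserves the
qualitative behavior — four growth phases, stationary-phase competence in the
10-20% band, inheritance effect — at desk-scale cost; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .rules import RuleTable


@dataclass
class SimulationConfig:
    # -- intracellular tier -------------------------------------------
    intracellular_dims: tuple[int, int, int] = (40, 40, 40)
    n_promoters: int = 2           # promoter regions: one per gene
    n_repressors: int = 2
    n_ribosomes: int = 80
    n_meca: int = 20
    n_clpcp: int = 20
    init_range: tuple[int, int] = (0, 12)  # uniform draw for ComK/ComS/ComX/DegU
    comk: Optional[int] = None     # fixed overrides (None = draw)
    coms: Optional[int] = None
    comx: Optional[int] = None
    degu: Optional[int] = None
    competence_threshold: int = 20
    bind_scan: str = "one"     # neighbors inspected per bind attempt: one | all
    rules: RuleTable = field(default_factory=RuleTable)

    # -- culture tier --------------------------------------------------
    culture_dims: tuple[int, int] = (40, 40)
    n_cells: int = 20
    m0: float = 5.0                # initial cell energy
    mu: float = 0.0058             # growth rate
    k_max: float = 16.0            # energy ceiling
    death_rate: float = 0.002      # d; starvation drain is d/(k/2)
    division_threshold: float = 15.0
    p_divide: float = 0.8
    p_move: float = 0.5            # chemotaxis relocation gate
    starvation_level: float = 1.0
    low_energy_level: float = 0.5
    p_low_energy_death: float = 1e-4
    density_death_window: tuple[float, float] = (0.5, 7.5)
    p_density_death: float = 1e-4
    density_death_period: int = 50
    consume_peptide_period: int = 50
    p_consume_peptide: float = 0.8
    generate_peptide_period: int = 100
    p_generate_peptide: float = 0.8
    p_repressor_removal: float = 1e-3
    diffusion_constant: float = 0.1
    # calibrated so a 20-cell seed on the 40x40 plate plateaus at ~850-900
    # cells (~720 nutrient units are spent per division incl. maintenance)
    nutrient_per_site: float = 375.0
    peptide_per_site: float = 0.0

    # -- run control -----------------------------------------------------
    seed: int = 0
    max_ticks: int = 43_000
    record_cell_series: bool = False

    # scheduling metadata (fixed implementation contracts, echoed for
    # provenance): diffusion runs before agent rules each tick; RNG is
    # numpy PCG64 with named SeedSequence substreams.
    diffusion_first: bool = True
    rng_algorithm: str = "PCG64"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = [
            self.p_divide, self.p_move, self.p_low_energy_death,
            self.p_density_death, self.p_consume_peptide,
            self.p_generate_peptide, self.p_repressor_removal,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("culture rule probabilities must lie in [0, 1]")
        if not (0.0 <= self.diffusion_constant <= 1.0):
            raise ValueError("diffusion constant must lie in [0, 1]")
        counts = [self.n_promoters, self.n_repressors, self.n_ribosomes,
                  self.n_meca, self.n_clpcp, self.n_cells]
        if any(c < 0 for c in counts):
            raise ValueError("agent counts must be non-negative")
        if self.init_range[0] < 0 or self.init_range[1] < self.init_range[0]:
            raise ValueError(f"bad init_range {self.init_range}")
        if self.nutrient_per_site < 0 or self.peptide_per_site < 0:
            raise ValueError("initial layer values must be non-negative")
        if self.max_ticks < 0:
            raise ValueError("max_ticks must be non-negative")
        if self.bind_scan not in ("one", "all"):
            raise ValueError("bind_scan must be 'one' or 'all'")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["rules"] = self.rules.to_dict()
        for k in ("intracellular_dims", "culture_dims", "init_range",
                  "density_death_window"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["rules"] = RuleTable.from_dict(d.get("rules", {}))
        for k in ("intracellular_dims", "culture_dims", "init_range",
                  "density_death_window"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def default_config(**overrides) -> SimulationConfig:
    """The full-scale published conditions (two-month-run scale)."""
    return SimulationConfig(**overrides)


def scaled_config(**overrides) -> SimulationConfig:
    """Reduced culture profile for desk-scale runs.

    Plate area and nutrient load are cut so the colony plateaus at ~80-90
    cells within ~2,000 ticks, and the death-rate constant is scaled
    up tenfold so the starvation drain traverses stationary phase within the
    8,000-tick horizon (full-scale: ~30,000 starving ticks). Intracellular
    parameters are untouched.
    """
    kw = dict(
        culture_dims=(20, 20),
        nutrient_per_site=150.0,
        death_rate=0.02,
        max_ticks=8_000,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)
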