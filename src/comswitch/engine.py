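"""Discrete-time engine coupling the culture and intracellular tiers.

One global tick: both value layers diffuse, then every live cell (visited in
a freshly shuffled order) attempts each of its culture rules once — in a
freshly shuffled per-cell rule order — and advances its embedded
intracellular model by one tick (itself a fresh random permutation over that
cell's molecular agents and promoters). Cells created during a tick act from
the next tick; division and competence decisions read end-of-previous-tick
state. Molecular agents of different cells never interact, so per-cell
contiguous execution is dynamically equivalent to one global shuffle.

Randomness is organized as named ``SeedSequence`` substreams (placement,
culture rules, scheduler shuffles, one stream per intracellular model, with
daughters spawning from their parent model's sequence), so a run is
bit-reproducible from ``(config, seed)`` alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .culture import (
    CellAgent,
    ValueLayer,
    chemotaxis_move,
    consume_nutrients,
    consume_peptide,
    density_death_step,
    generate_peptide,
    life_step,
    shove,
)
from .intracellular import IntracellularModel
from .lattice import Grid
from .observers import LineageStore, TimeSeriesRecord, records_to_frame, write_growth_curve

_RULES = ("move", "consume_nutrients", "consume_peptide",
          "generate_peptide", "life", "density_death")
_RULE_ORDERS = list(itertools.permutations(range(len(_RULES))))


@dataclass
class RunRecord:
    """Everything a culture run produces."""

    config: SimulationConfig
    records: list[TimeSeriesRecord]
    lineage: LineageStore
    final_tick: int
    n_divisions: int = 0
    n_deaths: int = 0
    cell_series: dict[int, list[tuple[int, int, int]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def save(self, outdir: str | Path) -> None:
        """Write growth curve, lineage table and the resolved config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_growth_curve(self.records, outdir / "growth_curve.csv")
        self.lineage.save(outdir / "lineage.csv")
        self.config.save(outdir / "config.yaml")


class Simulation:
    """Run state of the two-tier model (the culture tier plus one embedded
    intracellular model per cell)."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        cfg = config
        master = np.random.SeedSequence(cfg.seed)
        ss_place, ss_culture, ss_sched, self._ss_intra = master.spawn(4)
        self._placement_rng = np.random.default_rng(ss_place)
        self._culture_rng = np.random.default_rng(ss_culture)
        self._sched_rng = np.random.default_rng(ss_sched)

        self.grid = Grid(cfg.culture_dims)
        self.nutrients = ValueLayer(cfg.culture_dims, cfg.nutrient_per_site,
                                    cfg.diffusion_constant)
        self.peptides = ValueLayer(cfg.culture_dims, cfg.peptide_per_site,
                                   cfg.diffusion_constant)
        self.cells: dict[int, CellAgent] = {}
        self.lineage = LineageStore()
        self.records: list[TimeSeriesRecord] = []
        self.cell_series: dict[int, list[tuple[int, int, int]]] = {}
        self.tick_count = 0
        self.n_divisions = 0
        self.n_deaths = 0
        self._next_id = 0

        if cfg.n_cells > self.grid.nsites:
            raise ValueError("more initial cells than plate sites")
        model_seqs = self._ss_intra.spawn(cfg.n_cells)
        for i in range(cfg.n_cells):
            model = self._make_model(model_seqs[i])
            pos = self.grid.draw_free_site(self._placement_rng)
            cell = CellAgent(self._next_id, pos, cfg.m0, model)
            self.grid.place(cell.cell_id, pos)
            self.cells[cell.cell_id] = cell
            self.lineage.add_founder(
                cell.cell_id, 0,
                model.comk_count(),
                model.species_counts()["mRNA_comK"],
                model.coms_count(),
            )
            self._next_id += 1
        self._record()

    def _make_model(self, seedseq) -> IntracellularModel:
        cfg = self.config
        return IntracellularModel(
            dims=cfg.intracellular_dims,
            rules=cfg.rules,
            n_promoters=cfg.n_promoters,
            n_repressors=cfg.n_repressors,
            n_ribosomes=cfg.n_ribosomes,
            n_meca=cfg.n_meca,
            n_clpcp=cfg.n_clpcp,
            comk=cfg.comk, coms=cfg.coms, comx=cfg.comx, degu=cfg.degu,
            init_range=cfg.init_range,
            competence_threshold=cfg.competence_threshold,
            bind_scan=cfg.bind_scan,
            seedseq=seedseq,
        )

    # -- queries -------------------------------------------------------
    @property
    def live_cells(self) -> list[CellAgent]:
        return [c for c in self.cells.values() if c.alive]

    def n_live(self) -> int:
        return sum(1 for c in self.cells.values() if c.alive)

    def n_competent(self) -> int:
        return sum(1 for c in self.cells.values() if c.alive and c.competent)

    # -- stepping ------------------------------------------------------
    def tick(self) -> None:
        cfg = self.config
        t = self.tick_count
        self.nutrients.diffusion_step()
        self.peptides.diffusion_step()

        ids = np.fromiter(
            (i for i, c in self.cells.items() if c.alive), dtype=np.int64,
        )
        if ids.size:
            ids = ids[self._sched_rng.permutation(ids.size)]
        for cid in ids:
            cell = self.cells[int(cid)]
            if not cell.alive:
                continue
            order = _RULE_ORDERS[int(self._culture_rng.integers(len(_RULE_ORDERS)))]
            for r in order:
                rule = _RULES[r]
                if rule == "move":
                    chemotaxis_move(cell, self.nutrients, self.grid,
                                    self._culture_rng, cfg)
                elif rule == "consume_nutrients":
                    consume_nutrients(cell, self.nutrients, cfg)
                elif rule == "consume_peptide":
                    consume_peptide(cell, self.peptides, t, self._culture_rng, cfg)
                elif rule == "generate_peptide":
                    generate_peptide(cell, self.peptides, t, self._culture_rng, cfg)
                elif rule == "life":
                    decision = life_step(cell, self._culture_rng, cfg)
                    if decision == "divide":
                        self._divide(cell)
                    elif decision == "die":
                        self._remove(cell)
                elif rule == "density_death":
                    if density_death_step(cell, t, self._culture_rng, cfg):
                        self._remove(cell)
                if not cell.alive:
                    break
            if not cell.alive:
                continue
            was_competent = cell.model.competent
            cell.model.tick(1)
            if cell.model.competent and not was_competent:
                self.lineage.mark_competent(cell.cell_id, self.tick_count + 1)
            if cfg.record_cell_series:
                self.cell_series.setdefault(cell.cell_id, []).append(
                    (t + 1, cell.model.comk_count(), cell.model.coms_count())
                )
        self.tick_count += 1
        self._record()

    def _divide(self, parent: CellAgent) -> None:
        if self.grid.n_free() == 0:
            return  # plate completely full: no room for a daughter
        daughter_model, inherited = parent.model.divide()
        parent.energy *= 0.5
        neigh = self.grid.neighbors(parent.pos)
        target = neigh[int(self._culture_rng.integers(len(neigh)))]
        if not self.grid.is_free(target):
            moved = shove(self.grid, target, self._culture_rng)
            for cid in moved:
                self.cells[cid].pos = self.grid.positions[cid]
        daughter = CellAgent(
            self._next_id, tuple(target), parent.energy, daughter_model,
            birth_tick=self.tick_count, parent_id=parent.cell_id,
        )
        self._next_id += 1
        self.grid.place(daughter.cell_id, target)
        self.cells[daughter.cell_id] = daughter
        self.lineage.add_division(
            parent.cell_id, daughter.cell_id, self.tick_count,
            inherited["comk_proteins"], inherited["comk_transcripts"],
            inherited["coms_proteins"],
        )
        self.n_divisions += 1

    def _remove(self, cell: CellAgent) -> None:
        # a dying cell returns its remaining energy to the local nutrients
        self.nutrients.values[cell.pos] += max(0.0, cell.energy)
        self.grid.remove(cell.cell_id)
        cell.alive = False
        self.lineage.mark_death(cell.cell_id, self.tick_count)
        self.n_deaths += 1

    def _record(self) -> None:
        self.records.append(TimeSeriesRecord(
            tick=self.tick_count,
            cells=self.n_live(),
            competent=self.n_competent(),
            nutrient_total=self.nutrients.total(),
            peptide_total=self.peptides.total(),
        ))

    def save_layers(self, outdir: str | Path) -> None:
        """Plain-text dumps of the current nutrient and peptide fields."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nutrients.save_txt(outdir / "nutrients.txt")
        self.peptides.save_txt(outdir / "peptides.txt")

    def run(self, max_ticks: Optional[int] = None, progress: bool = False) -> RunRecord:
        """Run until ``max_ticks`` (default: the configured horizon) or
        culture extinction, recording one census per tick."""
        horizon = self.config.max_ticks if max_ticks is None else max_ticks
        iterator = range(self.tick_count, horizon)
        if progress:  # pragma: no cover - cosmetic
            from tqdm import tqdm  # type: ignore[import-not-found]

            iterator = tqdm(iterator, desc="ticks")
        for _ in iterator:
            if self.n_live() == 0:
                break
            self.tick()
        return RunRecord(
            config=self.config,
            records=self.records,
            lineage=self.lineage,
            final_tick=self.tick_count,
            n_divisions=self.n_divisions,
            n_deaths=self.n_deaths,
            cell_series=self.cell_series,
        )


def run(config: SimulationConfig, max_ticks: Optional[int] = None,
        progress: bool = False) -> RunRecord:
    """Build and run a full two-tier simulation from a config."""
    return Simulation(config).run(max_ticks=max_ticks, progress=progress)
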