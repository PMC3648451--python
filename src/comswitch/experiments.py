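"""The three reported computational experiments and their statistics.

1. ``intracellular_replicates`` — many intracellular-only runs that differ
   *only* in the random spatial placement and scheduling stream, all starting
   from identical maximal molecule counts; measures the spontaneous
   competence rate driven purely by spatial-temporal noise.
2. ``multiscale_replicates`` — full two-tier culture runs; measures final
   cell counts, the growth-curve phases, and the competent fraction at the
   end of stationary phase.
3. ``inheritance_analysis`` — groups competent daughters by whether they
   inherited any ComK protein at division and compares time from division to
   competence onset between the groups (Welch's t-test by default, a
   rank-based alternative on request).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig, default_config
from .engine import RunRecord, Simulation
from .intracellular import IntracellularModel
from .observers import end_of_stationary, phase_names

DEFAULT_INTRACELLULAR_TICKS = 10_000


@dataclass
class ReplicateSet:
    """Summary of a batch of intracellular-only replicates."""

    summary: pd.DataFrame
    ticks: int
    threshold: int
    trajectories: Optional[list[tuple[np.ndarray, np.ndarray]]] = None

    @property
    def n_replicates(self) -> int:
        return len(self.summary)

    @property
    def n_competent(self) -> int:
        return int(self.summary["competent"].sum())

    @property
    def competent_fraction(self) -> float:
        return self.n_competent / self.n_replicates


def intracellular_replicates(
    n: int = 100,
    ticks: int = DEFAULT_INTRACELLULAR_TICKS,
    base_seed: int = 0,
    config: Optional[SimulationConfig] = None,
    comk: int = 12,
    coms: int = 12,
    comx: int = 12,
    degu: int = 12,
    record_trajectories: bool = False,
    progress: bool = False,
) -> ReplicateSet:
    """Run ``n`` intracellular-only replicates at fixed initial quantities.

    Every replicate uses identical parameters and molecule counts (by
    default the maxima of the initial-quantity table, the published Results
    setting); only the placement/scheduling randomness differs. A replicate
    is competent if its ComK count ever exceeded the threshold.
    """
    cfg = config if config is not None else default_config()
    seqs = np.random.SeedSequence(base_seed).spawn(n)
    rows = []
    trajs: list[tuple[np.ndarray, np.ndarray]] = []
    iterator = range(n)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm  # type: ignore[import-not-found]

        iterator = tqdm(iterator, desc="replicates")
    for i in iterator:
        model = IntracellularModel(
            dims=cfg.intracellular_dims,
            rules=cfg.rules,
            n_promoters=cfg.n_promoters,
            n_repressors=cfg.n_repressors,
            n_ribosomes=cfg.n_ribosomes,
            n_meca=cfg.n_meca,
            n_clpcp=cfg.n_clpcp,
            comk=comk, coms=coms, comx=comx, degu=degu,
            init_range=cfg.init_range,
            competence_threshold=cfg.competence_threshold,
            bind_scan=cfg.bind_scan,
            seedseq=seqs[i],
        )
        out = model.run(ticks, record=record_trajectories)
        if record_trajectories:
            trajs.append(out)
        rows.append(dict(
            replicate=i,
            competent=model.competent,
            competence_tick=model.competence_tick,
            final_comk=model.comk_count(),
            final_coms=model.coms_count(),
        ))
    return ReplicateSet(
        summary=pd.DataFrame(rows),
        ticks=ticks,
        threshold=cfg.competence_threshold,
        trajectories=trajs if record_trajectories else None,
    )


@dataclass
class MultiscaleSummary:
    """Per-run statistics of a full two-tier culture simulation."""

    seed: int
    final_tick: int
    final_cells: int
    max_cells: int
    final_competent: int
    stationary_end: int
    cells_at_stationary_end: int
    competent_at_stationary_end: int
    phases: list[str] = field(default_factory=list)

    @property
    def competent_fraction(self) -> float:
        if self.cells_at_stationary_end == 0:
            return 0.0
        return self.competent_at_stationary_end / self.cells_at_stationary_end


def summarize_run(record: RunRecord, seed: int) -> MultiscaleSummary:
    df = record.to_frame()
    counts = df["cells"].to_numpy()
    t_end = end_of_stationary(counts)
    return MultiscaleSummary(
        seed=seed,
        final_tick=record.final_tick,
        final_cells=int(counts[-1]),
        max_cells=int(counts.max()),
        final_competent=int(df["competent"].iloc[-1]),
        stationary_end=int(t_end),
        cells_at_stationary_end=int(counts[t_end]),
        competent_at_stationary_end=int(df["competent"].iloc[t_end]),
        phases=phase_names(counts),
    )


def multiscale_replicates(
    n: int = 6,
    config: Optional[SimulationConfig] = None,
    base_seed: int = 0,
    max_ticks: Optional[int] = None,
    progress: bool = False,
) -> tuple[list[MultiscaleSummary], list[RunRecord]]:
    """Run ``n`` independent full culture simulations."""
    cfg = config if config is not None else default_config()
    summaries, records = [], []
    for i in range(n):
        seed = int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31))
        sim = Simulation(cfg.replace(seed=seed))
        rec = sim.run(max_ticks=max_ticks, progress=progress)
        records.append(rec)
        summaries.append(summarize_run(rec, seed))
    return summaries, records


# -- inheritance / heritability ----------------------------------------------

@dataclass
class InheritanceResult:
    """Division-to-competence latencies grouped by ComK inheritance."""

    n_inherited: int
    n_noninherited: int
    mean_inherited: float
    sd_inherited: float
    mean_noninherited: float
    sd_noninherited: float
    statistic: float
    pvalue: float
    test: str

    @property
    def empty(self) -> bool:
        return self.n_inherited == 0 or self.n_noninherited == 0

    @property
    def inherited_earlier(self) -> bool:
        return self.mean_inherited < self.mean_noninherited


def inheritance_analysis(lineage, test: str = "welch") -> InheritanceResult:
    """Compare competence latency between daughters that inherited nonzero
    ComK protein and those that inherited none.

    ``lineage`` is a :class:`~comswitch.observers.LineageStore` or its
    dataframe. Only cells born by division that eventually switched are
    scored; latency is ``competence_tick - birth_tick``. Grouping uses the
    inherited *protein* count only (transcripts are reported in the lineage
    table but do not define the groups).
    """
    df = lineage if isinstance(lineage, pd.DataFrame) else lineage.to_dataframe()
    d = df[df["parent_id"].notna() & df["competence_tick"].notna()].copy()
    d["latency"] = d["competence_tick"] - d["birth_tick"]
    g1 = d.loc[d["inherited_comk"] > 0, "latency"].to_numpy(float)
    g0 = d.loc[d["inherited_comk"] == 0, "latency"].to_numpy(float)

    def _ms(x):
        if x.size == 0:
            return float("nan"), float("nan")
        return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    m1, s1 = _ms(g1)
    m0, s0 = _ms(g0)
    if g1.size < 2 or g0.size < 2:
        stat, p = float("nan"), float("nan")
    elif test == "welch":
        stat, p = stats.ttest_ind(g1, g0, equal_var=False)
    elif test == "ranksum":
        stat, p = stats.mannwhitneyu(g1, g0, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return InheritanceResult(
        n_inherited=int(g1.size),
        n_noninherited=int(g0.size),
        mean_inherited=m1, sd_inherited=s1,
        mean_noninherited=m0, sd_noninherited=s0,
        statistic=float(stat), pvalue=float(p), test=test,
    )


def parameter_sweep(base: SimulationConfig, grid: dict[str, list],
                    seeds: list[int]):
    """Cartesian sweep driver over config fields (no objective function):
    yields ``(overrides, config)`` for each combination x seed."""
    import itertools as it

    keys = list(grid)
    for combo in it.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        for s in seeds:
            yield overrides, base.replace(seed=s, **overrides)
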