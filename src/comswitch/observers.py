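"""Measurement and persistence: time series, growth curves, growth-phase
segmentation, and division-lineage capture with Newick export."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

GROWTH_CURVE_COLUMNS = ["tick", "cells", "competent", "nutrient_total", "peptide_total"]


@dataclass
class TimeSeriesRecord:
    tick: int
    cells: int
    competent: int
    nutrient_total: float
    peptide_total: float


def records_to_frame(records: list[TimeSeriesRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=GROWTH_CURVE_COLUMNS)


def write_growth_curve(records: list[TimeSeriesRecord], path: str | Path) -> None:
    if not records:
        raise ValueError("no records to write")
    records_to_frame(records).to_csv(path, index=False)


def read_growth_curve(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- lineage capture ---------------------------------------------------------

@dataclass
class LineageNode:
    """One cell's record in the division tree.

    ``inherited_comk``/``inherited_transcripts`` are the ComK protein and
    comK transcript counts received at division (founders record their
    initial draw); ``competence_tick`` is set once, when the competence flag
    first fires.
    """

    cell_id: int
    parent_id: Optional[int]
    birth_tick: int
    inherited_comk: int
    inherited_transcripts: int
    inherited_coms: int = 0
    competence_tick: Optional[int] = None
    death_tick: Optional[int] = None
    children: list[int] = field(default_factory=list)


class LineageStore:
    """The division tree of a culture run (every division appears once)."""

    def __init__(self) -> None:
        self.nodes: dict[int, LineageNode] = {}

    def add_founder(self, cell_id: int, birth_tick: int, comk: int,
                    transcripts: int, coms: int = 0) -> LineageNode:
        return self._add(cell_id, None, birth_tick, comk, transcripts, coms)

    def add_division(self, parent_id: int, child_id: int, tick: int,
                     inherited_comk: int, inherited_transcripts: int,
                     inherited_coms: int = 0) -> LineageNode:
        node = self._add(child_id, parent_id, tick, inherited_comk,
                         inherited_transcripts, inherited_coms)
        self.nodes[parent_id].children.append(child_id)
        return node

    def _add(self, cell_id, parent_id, tick, comk, transcripts, coms):
        if cell_id in self.nodes:
            raise ValueError(f"cell {cell_id} already recorded")
        node = LineageNode(cell_id, parent_id, tick, comk, transcripts, coms)
        self.nodes[cell_id] = node
        return node

    def mark_competent(self, cell_id: int, tick: int) -> None:
        node = self.nodes[cell_id]
        if node.competence_tick is None:
            if tick < node.birth_tick:
                raise ValueError("competence before birth")
            node.competence_tick = tick

    def mark_death(self, cell_id: int, tick: int) -> None:
        self.nodes[cell_id].death_tick = tick

    def founders(self) -> list[int]:
        return [i for i, n in self.nodes.items() if n.parent_id is None]

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["cell_id", "parent_id", "birth_tick", "inherited_comk",
                "inherited_transcripts", "inherited_coms",
                "competence_tick", "death_tick"]
        rows = [{c: getattr(n, c) for c in cols} for n in self.nodes.values()]
        return pd.DataFrame(rows, columns=cols)

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "LineageStore":
        df = pd.read_csv(path)
        store = cls()
        for row in df.itertuples(index=False):
            parent = None if pd.isna(row.parent_id) else int(row.parent_id)
            node = LineageNode(
                int(row.cell_id), parent, int(row.birth_tick),
                int(row.inherited_comk), int(row.inherited_transcripts),
                int(row.inherited_coms),
                None if pd.isna(row.competence_tick) else int(row.competence_tick),
                None if pd.isna(row.death_tick) else int(row.death_tick),
            )
            store.nodes[node.cell_id] = node
            if parent is not None:
                store.nodes[parent].children.append(node.cell_id)
        return store


def lineage_to_newick(store: LineageStore, founder: Optional[int] = None) -> str:
    """Serialize one founder's division subtree as a Newick string.

    Node labels are alphanumeric-safe tokens ``c<id>_k<transcripts>_p<proteins>``
    encoding the inherited comK transcript and ComK protein counts; the branch
    length of a competent cell is the number of ticks from its birth
    (division) to competence onset, and 0 for cells that never switched.
    """
    if founder is None:
        founders = store.founders()
        if len(founders) != 1:
            raise ValueError("specify a founder (store has several)")
        founder = founders[0]
    root = store.nodes[founder]

    # cycle guard: walk with an explicit stack and a visited set
    visited: set[int] = set()

    def render(node: LineageNode) -> str:
        if node.cell_id in visited:
            raise ValueError("lineage store contains a cycle")
        visited.add(node.cell_id)
        label = f"c{node.cell_id}_k{node.inherited_transcripts}_p{node.inherited_comk}"
        if node.competence_tick is not None:
            length = node.competence_tick - node.birth_tick
        else:
            length = 0
        if node.children:
            inner = ",".join(render(store.nodes[c]) for c in node.children)
            return f"({inner}){label}:{length}"
        return f"{label}:{length}"

    return render(root) + ";"


def parse_newick(text: str) -> dendropy.Tree:
    """Round-trip helper: parse a Newick string with dendropy."""
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


# -- growth-phase segmentation ------------------------------------------------

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    w = min(window, len(x))
    kernel = np.ones(w) / w
    pad = np.r_[np.full(w - 1, x[0]), x, np.full(w - 1, x[-1])]
    sm = np.convolve(pad, kernel, mode="same")
    return sm[w - 1 : w - 1 + len(x)]


def detect_growth_phases(counts, smooth_window: int = 301,
                         rise_frac: float = 0.10,
                         fall_frac: float = 0.05) -> list[tuple[str, int, int]]:
    """Segment a cell-count series into the canonical culture phases.

    The smoothed curve is thresholded on its rise and fall: lag ends when the
    count has climbed ``rise_frac`` of the total amplitude above its start,
    the exponential phase ends when it comes within ``rise_frac`` of the
    peak, and a death phase opens at the last time the curve sits within
    ``fall_frac`` of the peak — provided it has decayed by more than
    ``fall_frac`` by the end (sustained negative slope). Returns
    ``[(name, start, end), ...]`` with contiguous half-open tick ranges.
    """
    x = np.asarray(counts, dtype=float)
    if len(x) < 3:
        return [("lag", 0, len(x))]
    s = _smooth(x, smooth_window)
    peak = float(s.max())
    n0 = float(s[0])
    amp = peak - n0
    if amp <= 0:
        return [("lag", 0, len(x))]
    t1 = int(np.argmax(s > n0 + rise_frac * amp))
    t2 = int(np.argmax(s > peak - rise_frac * amp))
    phases = [("lag", 0, t1), ("exponential", t1, t2)]
    declined = s[-1] < peak * (1.0 - fall_frac)
    if declined:
        above = np.flatnonzero(s >= peak * (1.0 - fall_frac))
        t3 = int(above[-1]) + 1
        phases += [("stationary", t2, t3), ("death", t3, len(x))]
    else:
        phases.append(("stationary", t2, len(x)))
    return [(name, a, b) for name, a, b in phases if b > a]


def phase_names(counts, **kw) -> list[str]:
    return [name for name, _, _ in detect_growth_phases(counts, **kw)]


def end_of_stationary(counts, **kw) -> int:
    """Last tick before the sustained decline of the death phase (the end of
    the series when no death phase is detected)."""
    for name, start, end in detect_growth_phases(counts, **kw):
        if name == "stationary":
            return end - 1
    return len(np.asarray(counts)) - 1
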