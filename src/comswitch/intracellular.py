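"""The 3-D agent-based model of the ComK/ComS competence regulatory network.

A single bacterium's regulatory state is a population of molecular agents
(ComK, ComS, ComX, DegU, MecA, ClpCP, ribosomes, repressors, transcripts) and
immobile promoter agents on a 40x40x40 occupancy lattice. Agents random-walk,
bind stochastically (homodimerisation, protease assembly and substrate
capture, ribosome loading, promoter occupancy), transcribe, translate and
degrade according to a fixed probability table; the cell is scored competent
as soon as more than ``competence_threshold`` ComK monomer units exist
(counting dimer members and protease-bound ComK), and the flag never reverts.

The heavy per-tick loop lives in :mod:`comswitch._kernel`; this class owns
the state arrays, exposes readable single-operation methods that call the
same jitted helpers (so unit tests exercise exactly the simulated rules), and
implements division with molecular inheritance.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import _kernel as kn
from .lattice import neighbor_table
from .rules import (
    RuleTable,
    COMK, COMS, COMX, DEGU, MECA, CLPCP, RIBOSOME, REPRESSOR,
    MRNA_COMK, MRNA_COMS,
    GENE_COMK, GENE_COMS,
    COMK_DIMER, CLPCP_MECA, CLPCP_MECA_COMK, CLPCP_MECA_COMS, RIBOSOME_MRNA,
    SPECIES_NAMES,
)

PARTITIONED = (COMK, COMS, COMX, MRNA_COMK, MRNA_COMS)

_INIT_CAP = 1024


class ConfigError(ValueError):
    pass


class IntracellularModel:
    """One cell's intracellular competence network on a 3-D lattice.

    Machinery counts follow the published initial-quantity table: 2 generic
    repressors, 80 ribosomes, 20 MecA, 20 ClpCP, no transcripts, and
    ComK/ComS/ComX/DegU counts each drawn uniformly from ``init_range``
    unless fixed explicitly. ``n_promoters`` counts immobile multi-slot
    promoter-region agents, half per gene; the default is one region per
    gene (a comK region with repressor + DegU + two ComK-dimer slots, a comS
    region with repressor + ComX slots), which keeps the standing comK
    transcript number near one — the regime in which spontaneous competence
    is the rare event it should be.
    """

    def __init__(
        self,
        *,
        dims: tuple[int, int, int] = (40, 40, 40),
        rules: Optional[RuleTable] = None,
        n_promoters: int = 2,
        n_repressors: int = 2,
        n_ribosomes: int = 80,
        n_meca: int = 20,
        n_clpcp: int = 20,
        comk: Optional[int] = None,
        coms: Optional[int] = None,
        comx: Optional[int] = None,
        degu: Optional[int] = None,
        init_range: tuple[int, int] = (0, 12),
        competence_threshold: int = 20,
        bind_scan: str = "one",
        seed: Optional[int] = None,
        seedseq: Optional[np.random.SeedSequence] = None,
        _empty: bool = False,
    ):
        if n_promoters % 2 != 0:
            raise ConfigError("n_promoters must be even (half comK, half comS)")
        lo, hi = init_range
        for name, v in (("comk", comk), ("coms", coms), ("comx", comx), ("degu", degu)):
            if v is not None and not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside configured range {init_range}")
        self.dims = tuple(int(d) for d in dims)
        self.nsites = int(np.prod(self.dims))
        self.rules = rules if rules is not None else RuleTable()
        self.competence_threshold = int(competence_threshold)
        self.machinery = dict(
            n_promoters=n_promoters,
            n_repressors=n_repressors,
            n_ribosomes=n_ribosomes,
            n_meca=n_meca,
            n_clpcp=n_clpcp,
        )
        self.init_range = (int(lo), int(hi))
        if seedseq is None:
            seedseq = np.random.SeedSequence(seed)
        self.seedseq = seedseq
        self.rng = np.random.default_rng(seedseq)

        if bind_scan not in ("one", "all"):
            raise ConfigError("bind_scan must be 'one' or 'all'")
        self.bind_scan = bind_scan
        self._alloc(_INIT_CAP, n_promoters)
        self.meta[kn.M_THRESH] = self.competence_threshold
        self.meta[kn.M_CTICK] = -1
        self.meta[kn.M_SCANALL] = 1 if bind_scan == "all" else 0

        # immobile promoter agents: placed once, never moved
        genes = [GENE_COMK] * (n_promoters // 2) + [GENE_COMS] * (n_promoters // 2)
        for p, g in enumerate(genes):
            s = int(kn.place_free(self._st, self.rng))
            self.pgene[p] = g
            self.ppos[p] = s
            self.occ[s] = kn.PBASE + p

        if _empty:
            self.initial_counts = {}
            return

        draw = lambda v: int(v) if v is not None else int(self.rng.integers(lo, hi + 1))
        counts = [
            (REPRESSOR, n_repressors),
            (RIBOSOME, n_ribosomes),
            (MECA, n_meca),
            (CLPCP, n_clpcp),
            (COMK, draw(comk)),
            (COMS, draw(coms)),
            (COMX, draw(comx)),
            (DEGU, draw(degu)),
        ]
        self.initial_counts = {SPECIES_NAMES[s]: n for s, n in counts}
        for s, n in counts:
            for _ in range(n):
                self.place_agent(s)

    # -- state arrays --------------------------------------------------
    def _alloc(self, cap: int, n_prom: int) -> None:
        self.sp = np.zeros(cap, np.int8)
        self.alive = np.zeros(cap, np.uint8)
        self.apos = np.full(cap, -1, np.int32)
        self.acomp = np.full(cap, -1, np.int32)
        self.aprom = np.full(cap, -1, np.int32)
        self.born = np.full(cap, -1, np.int32)
        self.ckind = np.full(cap, -1, np.int8)
        self.cmem = np.full((cap, 3), -1, np.int32)
        self.cpos = np.full(cap, -1, np.int32)
        self.cprom = np.full(cap, -1, np.int32)
        self.pgene = np.zeros(n_prom, np.int8)
        self.ppos = np.full(n_prom, -1, np.int32)
        self.prep = np.full(n_prom, -1, np.int32)
        self.pdegu = np.full(n_prom, -1, np.int32)
        self.pcomx = np.full(n_prom, -1, np.int32)
        self.pdim = np.full((n_prom, 2), -1, np.int32)
        self.occ = np.full(self.nsites, -1, np.int32)
        self._nbr, self._nnbr = neighbor_table(self.dims)
        self.freea = np.full(cap, -1, np.int32)
        self.freec = np.full(cap, -1, np.int32)
        self.meta = np.zeros(kn.N_META, np.int64)
        self.probs = self.rules.to_array()
        self._rebuild_state_tuple()

    def _rebuild_state_tuple(self) -> None:
        self._st = (
            self.sp, self.alive, self.apos, self.acomp, self.aprom, self.born,
            self.ckind, self.cmem, self.cpos, self.cprom,
            self.pgene, self.ppos, self.prep, self.pdegu, self.pcomx, self.pdim,
            self.occ, self._nbr, self._nnbr, self.freea, self.freec,
            self.meta, self.probs,
        )

    def _grow(self) -> None:
        cap = self.sp.shape[0] * 2
        for name in ("sp", "alive", "apos", "acomp", "aprom", "born",
                     "ckind", "cpos", "cprom", "freea", "freec"):
            old = getattr(self, name)
            fill = 0 if name in ("sp", "alive") else -1
            new = np.full(cap, fill, old.dtype)
            new[: old.shape[0]] = old
            setattr(self, name, new)
        old = self.cmem
        new = np.full((cap, 3), -1, np.int32)
        new[: old.shape[0]] = old
        self.cmem = new
        self._rebuild_state_tuple()

    @property
    def capacity(self) -> int:
        return int(self.sp.shape[0])

    # -- basic queries -------------------------------------------------
    @property
    def tick_count(self) -> int:
        return int(self.meta[kn.M_TICK])

    @property
    def competent(self) -> bool:
        return bool(self.meta[kn.M_COMPETENT])

    @property
    def competence_tick(self) -> Optional[int]:
        t = int(self.meta[kn.M_CTICK])
        return None if t < 0 else t

    def comk_count(self, recount: bool = False) -> int:
        """ComK monomer units present: free monomers, dimer members,
        promoter-bound dimers, and protease-bound ComK all count."""
        if recount:
            return int(np.sum((self.sp == COMK) & (self.alive == 1)))
        return int(self.meta[kn.M_KCOUNT])

    def coms_count(self, recount: bool = False) -> int:
        if recount:
            return int(np.sum((self.sp == COMS) & (self.alive == 1)))
        return int(self.meta[kn.M_SCOUNT])

    def species_counts(self) -> dict[str, int]:
        live = self.alive == 1
        return {
            name: int(np.sum(live & (self.sp == code)))
            for code, name in SPECIES_NAMES.items()
        }

    def complex_counts(self) -> dict[int, int]:
        kinds, counts = np.unique(self.ckind[self.ckind >= 0], return_counts=True)
        return {int(k): int(n) for k, n in zip(kinds, counts)}

    def agents_of(self, species: int) -> np.ndarray:
        return np.flatnonzero((self.sp == species) & (self.alive == 1))

    def complexes_of(self, kind: int) -> np.ndarray:
        return np.flatnonzero(self.ckind == kind)

    # -- construction helpers -----------------------------------------
    def place_agent(self, species: int, site: Optional[int] = None,
                    tick: Optional[int] = None) -> int:
        """Create one agent at ``site`` (or a uniformly random free site)."""
        if self.capacity - int(self.meta[kn.M_NAGENT]) + int(self.meta[kn.M_NFREEA]) < 8:
            self._grow()
        if site is None:
            site = int(kn.place_free(self._st, self.rng))
        elif self.occ[site] != -1:
            raise ValueError(f"site {site} occupied")
        born = self.tick_count if tick is None else tick
        return int(kn._new_agent(self._st, species, site, born - 1))

    def spawn_dimer(self, site: Optional[int] = None) -> int:
        """Create a pre-formed ComK homodimer (used by inheritance)."""
        if site is None:
            site = int(kn.place_free(self._st, self.rng))
        a = self.place_agent(COMK, site)
        b = int(kn._new_agent(self._st, COMK, site, self.tick_count - 1))
        # b shares the dimer site; _new_complex rewrites occ to the complex
        return int(kn._new_complex(self._st, COMK_DIMER, a, b, -1, site))

    def inject_comx(self) -> int:
        """Absorb one extracellular ComX pheromone molecule as a new agent.

        The new agent acts from the next tick (quiescent on its birth tick).
        """
        if self.capacity - int(self.meta[kn.M_NAGENT]) + int(self.meta[kn.M_NFREEA]) < 8:
            self._grow()
        site = int(kn.place_free(self._st, self.rng))
        return int(kn._new_agent(self._st, COMX, site, self.tick_count))

    def remove_random_repressor(self, rng: Optional[np.random.Generator] = None) -> bool:
        """Starvation response: delete one randomly selected repressor."""
        rng = rng if rng is not None else self.rng
        reps = self.agents_of(REPRESSOR)
        if reps.size == 0:
            return False
        a = int(reps[int(rng.integers(reps.size))])
        p = int(self.aprom[a])
        if p >= 0:
            self.prep[p] = -1  # vacate the promoter slot
        self.occ[self.apos[a]] = -1  # bound or free, it owns its site
        kn._kill_agent(self._st, a)
        return True

    # -- stepping ------------------------------------------------------
    _EMPTY_TRAJ = np.empty(0, np.int64)

    def tick(self, n: int = 1, traj_k: Optional[np.ndarray] = None,
             traj_s: Optional[np.ndarray] = None) -> None:
        """Advance ``n`` ticks, growing the state arrays as needed."""
        tk = traj_k if traj_k is not None else self._EMPTY_TRAJ
        ts = traj_s if traj_s is not None else self._EMPTY_TRAJ
        done = 0
        while done < n:
            step = int(kn.run_ticks(self._st, self.rng, n - done, tk, ts, done))
            done += step
            if done < n:
                self._grow()

    def run(self, n_ticks: int, record: bool = False):
        """Run ``n_ticks``; optionally return per-tick (ComK, ComS) counts."""
        if not record:
            self.tick(n_ticks)
            return None
        tk = np.zeros(n_ticks, np.int64)
        ts = np.zeros(n_ticks, np.int64)
        self.tick(n_ticks, tk, ts)
        return tk, ts

    # -- snapshot / restore (testing & provenance) ---------------------
    _SNAP_FIELDS = ("sp", "alive", "apos", "acomp", "aprom", "born", "ckind",
                    "cmem", "cpos", "cprom", "pgene", "ppos", "prep", "pdegu",
                    "pcomx", "pdim", "occ", "freea", "freec", "meta")

    def snapshot(self) -> dict[str, np.ndarray]:
        """Copy of the mutable state (excludes the RNG)."""
        return {f: getattr(self, f).copy() for f in self._SNAP_FIELDS}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for f in self._SNAP_FIELDS:
            arr = getattr(self, f)
            src = snap[f]
            if arr.shape != src.shape:  # capacity may have grown since
                setattr(self, f, src.copy())
            else:
                arr[...] = src
        self._rebuild_state_tuple()

    # -- single-operation surface (same jitted rules, one call each) ----
    def random_walk_step(self, agent: int) -> int:
        kn._move_agent(self._st, agent, self.rng)
        return int(self.apos[agent])

    def attempt_bind(self, a: int, b: int) -> bool:
        """One bind attempt between two adjacent free agents; no-op for
        pairs with no defined interaction."""
        sa, sb = int(self.sp[a]), int(self.sp[b])
        if sa == COMK and sb == COMK:
            return kn._bind_comk_pair(self._st, a, b, self.rng) >= 0
        if {sa, sb} == {CLPCP, MECA}:
            return kn._bind_clp_meca(self._st, a, b, self.rng) >= 0
        if sa == RIBOSOME and sb in (MRNA_COMK, MRNA_COMS) or (
            sb == RIBOSOME and sa in (MRNA_COMK, MRNA_COMS)
        ):
            return kn._bind_rib_mrna(self._st, a, b, self.rng) >= 0
        return False

    def attempt_join_protease(self, complex_id: int, substrate: int) -> bool:
        """Substrate capture by an adjacent ClpCP-MecA complex."""
        return bool(kn._join_protease(self._st, complex_id, substrate, self.rng))

    def displace_comk_for_coms(self, complex_id: int, coms_agent: int) -> int:
        """ComS displaces protease-bound ComK (unconditional); returns the
        freed ComK agent id."""
        if self.ckind[complex_id] != CLPCP_MECA_COMK:
            raise ValueError("complex holds no ComK substrate")
        return int(kn._displace_comk(self._st, complex_id, coms_agent))

    def promoter_bind(self, arrival: int, promoter: int, dimer: bool = False) -> bool:
        """One promoter-binding attempt by an adjacent agent or ComK dimer."""
        if dimer:
            return bool(kn._bind_dimer_to_promoter(self._st, arrival, promoter, self.rng))
        return bool(kn._bind_to_promoter(self._st, arrival, promoter, self.rng))

    def transcription_step(self, promoter: int) -> int:
        """One transcription attempt; returns the new mRNA id or -1."""
        return int(kn._transcription(self._st, promoter, self.rng, self.tick_count))

    def translation_step(self, complex_id: int) -> int:
        """One translation attempt by a ribosome-mRNA complex."""
        if self.ckind[complex_id] != RIBOSOME_MRNA:
            raise ValueError("not a ribosome-mRNA complex")
        return int(kn._translate(self._st, complex_id, self.rng, self.tick_count))

    def mrna_death_step(self, mrna: int) -> bool:
        if self.acomp[mrna] >= 0:
            return False  # bound transcripts never die
        return bool(kn._mrna_death(self._st, mrna, self.rng))

    def protease_degradation_step(self, complex_id: int) -> bool:
        return bool(kn._protease_degradation(self._st, complex_id, self.rng))

    def dissociation_step(self, promoter: int) -> None:
        kn._promoter_dissociation(self._st, promoter, self.rng)

    # -- consistency ---------------------------------------------------
    def check_consistency(self) -> None:
        """Exact occupancy/counter bookkeeping, assertable every tick."""
        live = np.flatnonzero(self.alive == 1)
        assert self.comk_count() == self.comk_count(recount=True)
        assert self.coms_count() == self.coms_count(recount=True)
        seen: dict[int, int] = {}
        for a in live:
            c = int(self.acomp[a])
            s = int(self.apos[a])
            if c >= 0:
                assert self.ckind[c] >= 0 and s == self.cpos[c]
            else:
                assert self.occ[s] == a, "free agent not at its recorded site"
                assert seen.setdefault(s, a) == a, "double occupancy"
        for c in np.flatnonzero(self.ckind >= 0):
            assert self.occ[self.cpos[c]] == kn.CBASE + c
        for p in range(self.pgene.shape[0]):
            assert self.occ[self.ppos[p]] == kn.PBASE + p
        occupied = set(np.flatnonzero(self.occ != -1))
        owners = (
            {int(self.apos[a]) for a in live if self.acomp[a] < 0}
            | {int(self.cpos[c]) for c in np.flatnonzero(self.ckind >= 0)}
            | {int(s) for s in self.ppos}
        )
        assert occupied == owners, "occupancy set mismatch"

    # -- division with molecular inheritance ----------------------------
    def divide(self, plane_rng: Optional[np.random.Generator] = None):
        """Split off a daughter cell through a random central plane.

        ComK, ComS, ComX and transcripts on the daughter side of a randomly
        oriented plane through the lattice center transfer to the daughter
        (ComK dimers move wholesale by their site; protease- and
        ribosome-bound substrates are released first and partition by the
        complex's site). The daughter receives a fresh machinery complement
        (ribosomes, MecA, ClpCP, repressors) and a full, identically composed
        promoter set: gene segregation is deterministic. Partitioned agents
        are re-placed uniformly at random in both cells.

        Returns ``(daughter, inheritance)`` where ``inheritance`` records the
        transferred ComK proteins/transcripts (and ComS/ComX) — the quantities
        the lineage analysis groups on.
        """
        rng = plane_rng if plane_rng is not None else self.rng
        axis = int(rng.integers(len(self.dims)))
        daughter_low = bool(rng.integers(2))
        half = self.dims[axis] // 2

        def side_is_daughter(site: int) -> bool:
            coord = np.unravel_index(site, self.dims)[axis]
            return (coord < half) == daughter_low

        units: list[tuple[str, int, int]] = []  # (kind, id, deciding site)
        # release promoter-bound ComX (a partitioned species) and dimers
        for p in range(self.pgene.shape[0]):
            x = int(self.pcomx[p])
            if x >= 0:
                self.pcomx[p] = -1
                self.aprom[x] = -1
        for c in np.flatnonzero(self.ckind >= 0):
            kind = int(self.ckind[c])
            if kind == COMK_DIMER:
                p = int(self.cprom[c])
                if p >= 0:
                    self.cprom[c] = -1
                    m = self.pdim[p]
                    m[m == c] = -1
                units.append(("dimer", int(c), int(self.cpos[c])))
            elif kind in (CLPCP_MECA_COMK, CLPCP_MECA_COMS):
                sub = int(self.cmem[c, 2])
                self.cmem[c, 2] = -1
                self.ckind[c] = CLPCP_MECA
                self.acomp[sub] = -1
                units.append(("loose", sub, int(self.cpos[c])))
            elif kind == RIBOSOME_MRNA:
                m = int(self.cmem[c, 1])
                rib = int(self.cmem[c, 0])
                site = int(self.cpos[c])
                self.acomp[m] = -1
                self.acomp[rib] = -1
                self.apos[rib] = site
                self.occ[site] = rib
                kn._free_complex(self._st, c)
                units.append(("loose", m, site))
        for a in np.flatnonzero(self.alive == 1):
            if int(self.sp[a]) in PARTITIONED and self.acomp[a] < 0 and self.aprom[a] < 0:
                if not any(u[1] == a and u[0] == "loose" for u in units):
                    units.append(("agent", int(a), int(self.apos[a])))

        inherit = {s: 0 for s in PARTITIONED}
        inherit_dimers = 0
        keep: list[tuple[str, int]] = []
        for kind, uid, site in units:
            if side_is_daughter(site):
                if kind == "dimer":
                    inherit_dimers += 1
                    inherit[COMK] += 2
                    self.occ[self.cpos[uid]] = -1
                    for j in (0, 1):
                        kn._kill_agent(self._st, int(self.cmem[uid, j]))
                    kn._free_complex(self._st, uid)
                else:
                    inherit[int(self.sp[uid])] += 1
                    if kind == "agent":
                        self.occ[self.apos[uid]] = -1
                    kn._kill_agent(self._st, uid)
            else:
                keep.append((kind, uid))

        # re-place what stays with the parent
        for kind, uid in keep:
            if kind == "dimer":
                self.occ[self.cpos[uid]] = -1
            elif kind == "agent":
                self.occ[self.apos[uid]] = -1
        for kind, uid in keep:
            s = int(kn.place_free(self._st, self.rng))
            if kind == "dimer":
                self.cpos[uid] = s
                for j in (0, 1):
                    self.apos[self.cmem[uid, j]] = s
                self.occ[s] = kn.CBASE + uid
            else:
                self.apos[uid] = s
                self.occ[s] = uid

        daughter = IntracellularModel(
            dims=self.dims,
            rules=self.rules,
            competence_threshold=self.competence_threshold,
            bind_scan=self.bind_scan,
            init_range=self.init_range,
            seedseq=self.seedseq.spawn(1)[0],
            _empty=True,
            **self.machinery,
        )
        daughter.meta[kn.M_TICK] = self.meta[kn.M_TICK]
        for spc, n in (
            (REPRESSOR, self.machinery["n_repressors"]),
            (RIBOSOME, self.machinery["n_ribosomes"]),
            (MECA, self.machinery["n_meca"]),
            (CLPCP, self.machinery["n_clpcp"]),
        ):
            for _ in range(n):
                daughter.place_agent(spc)
        for _ in range(inherit_dimers):
            daughter.spawn_dimer()
        for spc in PARTITIONED:
            n_free = inherit[spc] - (2 * inherit_dimers if spc == COMK else 0)
            for _ in range(n_free):
                daughter.place_agent(spc)

        record = {
            "comk_proteins": inherit[COMK],
            "comk_transcripts": inherit[MRNA_COMK],
            "coms_proteins": inherit[COMS],
            "coms_transcripts": inherit[MRNA_COMS],
            "comx": inherit[COMX],
            "comk_dimers": inherit_dimers,
        }
        return daughter, record
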