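"""Occupancy-tracked rectangular lattices.

The simulator runs on two grids: a 3-D lattice for the cell interior, where
molecular agents perform an excluded-volume random walk, and a 2-D lattice for
the culture plate. Both are closed boxes (reflecting boundaries): the Moore
neighborhood of a boundary site is simply clipped, so no agent can ever leave
the grid.

Positions are 0-based integer tuples; internally sites are flat C-order
indices. :func:`neighbor_table` builds (and caches) the per-site Moore
neighbor lists shared by the Python :class:`Grid` and the jitted intracellular
kernel.
"""

from __future__ import annotations

import itertools

import numpy as np

EMPTY = -1

_NEIGHBOR_CACHE: dict[tuple[int, ...], tuple[np.ndarray, np.ndarray]] = {}


def moore_offsets(ndim: int) -> list[tuple[int, ...]]:
    """All non-zero offsets with each coordinate in {-1, 0, 1}."""
    return [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]


def neighbor_table(dims: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Moore neighborhoods, clipped at the boundary.

    Returns ``(nbr, nnbr)`` where ``nbr[s, :nnbr[s]]`` are the flat indices of
    the neighbors of flat site ``s`` (padding is -1). Cached per ``dims``; the
    3-D table for the default 40x40x40 interior is ~6.6 MB and shared by every
    cell in a culture run.
    """
    dims = tuple(int(d) for d in dims)
    if dims in _NEIGHBOR_CACHE:
        return _NEIGHBOR_CACHE[dims]
    nd = len(dims)
    offsets = moore_offsets(nd)
    nsites = int(np.prod(dims))
    coords = np.indices(dims).reshape(nd, nsites)
    extents = np.asarray(dims)[:, None]
    nbr = np.full((nsites, len(offsets)), -1, dtype=np.int32)
    count = np.zeros(nsites, dtype=np.int64)
    for off in offsets:
        shifted = coords + np.asarray(off)[:, None]
        valid = np.all((shifted >= 0) & (shifted < extents), axis=0)
        rows = np.nonzero(valid)[0]
        flat = np.ravel_multi_index(tuple(shifted[:, valid]), dims)
        nbr[rows, count[rows]] = flat
        count[rows] += 1
    table = (nbr, count.astype(np.int8))
    _NEIGHBOR_CACHE[dims] = table
    return table


class GridFullError(RuntimeError):
    """Raised when more agents are placed than there are free sites."""


class Grid:
    """A rectangular occupancy grid with single occupancy per site.

    Tracks both ``occupant(site) -> id`` and ``position(id) -> site`` so the
    two views can never drift apart; `check_consistency` asserts it.
    """

    def __init__(self, dims: tuple[int, ...]):
        self.dims = tuple(int(d) for d in dims)
        if not self.dims or any(d < 1 for d in self.dims):
            raise ValueError(f"invalid grid dims {dims!r}")
        self.nsites = int(np.prod(self.dims))
        self.occ = np.full(self.nsites, EMPTY, dtype=np.int32)
        self.positions: dict[int, tuple[int, ...]] = {}
        self._nbr, self._nnbr = neighbor_table(self.dims)

    # -- coordinates ---------------------------------------------------
    def flat(self, pos: tuple[int, ...]) -> int:
        if len(pos) != len(self.dims) or any(
            not (0 <= c < d) for c, d in zip(pos, self.dims)
        ):
            raise ValueError(f"position {pos!r} outside grid {self.dims!r}")
        return int(np.ravel_multi_index(pos, self.dims))

    def unflat(self, site: int) -> tuple[int, ...]:
        return tuple(int(c) for c in np.unravel_index(site, self.dims))

    # -- queries -------------------------------------------------------
    def neighbors(self, pos: tuple[int, ...]) -> list[tuple[int, ...]]:
        """Moore neighborhood of ``pos``, clipped at the boundary."""
        s = self.flat(pos)
        n = int(self._nnbr[s])
        return [self.unflat(int(q)) for q in self._nbr[s, :n]]

    def is_free(self, pos: tuple[int, ...]) -> bool:
        return self.occ[self.flat(pos)] == EMPTY

    def occupant(self, pos: tuple[int, ...]) -> int | None:
        o = int(self.occ[self.flat(pos)])
        return None if o == EMPTY else o

    def n_free(self) -> int:
        return int(np.count_nonzero(self.occ == EMPTY))

    # -- mutation ------------------------------------------------------
    def place(self, occupant: int, pos: tuple[int, ...]) -> None:
        s = self.flat(pos)
        if self.occ[s] != EMPTY:
            raise ValueError(f"site {pos!r} already occupied")
        if occupant in self.positions:
            raise ValueError(f"occupant {occupant} already placed")
        self.occ[s] = occupant
        self.positions[occupant] = tuple(pos)

    def remove(self, occupant: int) -> None:
        pos = self.positions.pop(occupant)
        self.occ[self.flat(pos)] = EMPTY

    def move(self, occupant: int, pos: tuple[int, ...]) -> None:
        s = self.flat(pos)
        if self.occ[s] != EMPTY:
            raise ValueError(f"site {pos!r} already occupied")
        old = self.positions[occupant]
        self.occ[self.flat(old)] = EMPTY
        self.occ[s] = occupant
        self.positions[occupant] = tuple(pos)

    # -- random placement and movement ---------------------------------
    def draw_free_site(self, rng: np.random.Generator) -> tuple[int, ...]:
        """A uniformly random free site (rejection sampling)."""
        if self.n_free() == 0:
            raise GridFullError("no free sites")
        # occupancy is sparse in practice; rejection sampling stays cheap
        # and uses a deterministic number of draws per accept for a given rng
        for _ in range(100 * self.nsites):
            s = int(rng.integers(self.nsites))
            if self.occ[s] == EMPTY:
                return self.unflat(s)
        free = np.flatnonzero(self.occ == EMPTY)  # pragma: no cover
        return self.unflat(int(rng.choice(free)))  # pragma: no cover

    def place_randomly(
        self, occupants: list[int], rng: np.random.Generator
    ) -> dict[int, tuple[int, ...]]:
        """Place each occupant on a distinct uniformly-drawn free site."""
        if len(occupants) > self.n_free():
            raise GridFullError(
                f"cannot place {len(occupants)} agents on "
                f"{self.n_free()} free sites"
            )
        out = {}
        for o in occupants:
            pos = self.draw_free_site(rng)
            self.place(o, pos)
            out[o] = pos
        return out

    def random_walk_step(
        self, occupant: int, rng: np.random.Generator
    ) -> tuple[int, ...]:
        """One Moore step: draw a neighbor uniformly; move only if it is free.

        A blocked move is a legal no-op (the agent remains in place).
        """
        pos = self.positions[occupant]
        s = self.flat(pos)
        n = int(self._nnbr[s])
        q = int(self._nbr[s, int(rng.integers(n))])
        if self.occ[q] == EMPTY:
            target = self.unflat(q)
            self.move(occupant, target)
            return target
        return pos

    # -- invariants ----------------------------------------------------
    def check_consistency(self) -> None:
        """Occupancy bookkeeping is exact: occ and positions agree."""
        occupied = {int(s) for s in np.flatnonzero(self.occ != EMPTY)}
        tracked = {self.flat(p) for p in self.positions.values()}
        if occupied != tracked:
            raise AssertionError("grid occupancy and positions disagree")
        for o, p in self.positions.items():
            if int(self.occ[self.flat(p)]) != o:
                raise AssertionError(f"occupant {o} not at recorded site")
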