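"""Shared fixtures: bare lattice models and Monte-Carlo rule harnesses."""

from __future__ import annotations

import numpy as np
import pytest

from comswitch.intracellular import IntracellularModel
from comswitch.rules import COMK, COMS, MECA, CLPCP, CLPCP_MECA


def bare_model(seed: int = 123, dims=(10, 10, 10), n_promoters: int = 2,
               **kw) -> IntracellularModel:
    """A model with promoters but no molecular agents: a clean bench for
    exercising single rules in isolation."""
    defaults = dict(n_repressors=0, n_ribosomes=0, n_meca=0, n_clpcp=0,
                    comk=0, coms=0, comx=0, degu=0)
    defaults.update(kw)
    return IntracellularModel(dims=dims, n_promoters=n_promoters,
                              seed=seed, **defaults)


def adjacent_free_sites(model: IntracellularModel, n: int = 2) -> list[int]:
    """Flat indices of ``n`` mutually adjacent free sites (a line of sites)."""
    dims = model.dims
    for x in range(dims[0]):
        for y in range(dims[1]):
            base = [
                int(np.ravel_multi_index((x, y, z), dims)) for z in range(n)
            ]
            if all(model.occ[s] == -1 for s in base):
                return base
    raise RuntimeError("no free line of sites")


def place_pair(model: IntracellularModel, sa: int, sb: int) -> tuple[int, int]:
    s1, s2 = adjacent_free_sites(model, 2)
    return model.place_agent(sa, s1), model.place_agent(sb, s2)


def make_protease_complex(model: IntracellularModel) -> int:
    """Assemble one ClpCP-MecA complex (looping draws until the 0.5 bind
    fires)."""
    clp, meca = place_pair(model, CLPCP, MECA)
    for _ in range(1000):
        if model.attempt_bind(clp, meca):
            break
    (c,) = model.complexes_of(CLPCP_MECA)
    return int(c)


def free_neighbor(model: IntracellularModel, site: int) -> int:
    """First free Moore neighbor of a flat site."""
    for q in model._nbr[site, : int(model._nnbr[site])]:
        if model.occ[q] == -1:
            return int(q)
    raise RuntimeError("no free neighbor")


def monte_carlo(trial, n: int = 10_000) -> int:
    """Count successes of ``n`` independent trials."""
    return sum(1 for _ in range(n) if trial())


def within_3se(successes: int, n: int, p: float) -> bool:
    se = np.sqrt(n * p * (1.0 - p))
    return abs(successes - n * p) <= 3.0 * max(se, 1e-12)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
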