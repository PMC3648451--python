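"""Jitted rule engine for the 3-D intracellular lattice model.

All per-tick logic of the intracellular tier lives here as numba-compiled
free functions over a flat tuple of numpy arrays (the "state tuple"), so that
a 10,000-tick replicate is a single compiled call and a culture run can step
hundreds of embedded models per tick. The Python wrapper
(:class:`comswitch.intracellular.IntracellularModel`) owns the arrays and
calls the same jitted helpers for its single-operation methods, keeping one
source of truth for every rule.

State tuple layout (index: array):
  0 sp      int8[cap]     species code of each agent
  1 alive   uint8[cap]    liveness flag
  2 apos    int32[cap]    flat lattice site (complex members share the
                          complex's site)
  3 acomp   int32[cap]    complex id or -1
  4 aprom   int32[cap]    promoter the agent is bound to, or -1
  5 born    int32[cap]    creation tick (new agents act from the next tick)
  6 ckind   int8[ccap]    complex kind or -1
  7 cmem    int32[ccap,3] member agent ids (-1 padding); canonical order:
                          dimer (ComK, ComK, -), protease (ClpCP, MecA,
                          substrate|-), ribosome (Ribosome, mRNA, -)
  8 cpos    int32[ccap]   flat site of the (one-site) complex
  9 cprom   int32[ccap]   promoter a dimer is bound to, or -1
 10 pgene   int8[np]      promoter gene (0 comK, 1 comS)
 11 ppos    int32[np]     promoter site (immobile)
 12 prep    int32[np]     bound repressor agent id or -1
 13 pdegu   int32[np]     bound DegU agent id or -1 (comK promoters only)
 14 pcomx   int32[np]     bound ComX agent id or -1 (comS promoters only)
 15 pdim    int32[np,2]   bound ComK-dimer complex ids (-1 = free slot)
 16 occ     int32[nsites] site occupant: -1 empty, agent id, CBASE+complex,
                          PBASE+promoter
 17 nbr     int32[nsites,maxn]  clipped Moore neighbor table
 18 nnbr    int8[nsites]  neighbor count per site
 19 freea   int32[cap]    free-list of dead agent ids
 20 freec   int32[ccap]   free-list of dead complex ids
 21 meta    int64[N_META] counters/flags, see M_* below
 22 probs   float64[19]   RuleTable.to_array()
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .rules import (
    COMK, COMS, COMX, DEGU, MECA, CLPCP, RIBOSOME, REPRESSOR,
    MRNA_COMK, MRNA_COMS,
    GENE_COMK, GENE_COMS,
    COMK_DIMER, CLPCP_MECA, CLPCP_MECA_COMK, CLPCP_MECA_COMS, RIBOSOME_MRNA,
)

# occupancy encoding offsets
CBASE = 1 << 20
PBASE = 1 << 21

# probability indices == RuleTable field order
(PB_REP, PB_DEGU, PB_COMX, PB_DIMER, PB_DIMER_DEGU, PB_KK, PB_RIB, PB_CMK,
 PB_CMS, PB_CM, PT_BARE, PT_DIMER, PT_TETRA, PT_COMX, P_TL, P_MRNA_DEATH,
 P_PROT_DEATH, PD_REP, PD_DEGU) = range(19)

# meta indices
(M_NAGENT, M_NCOMP, M_NFREEA, M_NFREEC, M_KCOUNT, M_SCOUNT, M_COMPETENT,
 M_TICK, M_THRESH, M_CTICK, M_SCANALL) = range(11)
N_META = 11


@njit(cache=False)
def _new_agent(st, spc, pos, tick):
    sp, alive, apos, acomp, aprom, born = st[0], st[1], st[2], st[3], st[4], st[5]
    occ, freea, meta = st[16], st[19], st[21]
    if meta[M_NFREEA] > 0:
        meta[M_NFREEA] -= 1
        a = freea[meta[M_NFREEA]]
    else:
        a = meta[M_NAGENT]
        meta[M_NAGENT] += 1
    sp[a] = spc
    alive[a] = 1
    apos[a] = pos
    acomp[a] = -1
    aprom[a] = -1
    born[a] = tick
    occ[pos] = a
    if spc == COMK:
        meta[M_KCOUNT] += 1
    elif spc == COMS:
        meta[M_SCOUNT] += 1
    return a


@njit(cache=False)
def _kill_agent(st, a):
    # the caller clears occ when the agent owns its site
    sp, alive, acomp, aprom = st[0], st[1], st[3], st[4]
    freea, meta = st[19], st[21]
    alive[a] = 0
    acomp[a] = -1
    aprom[a] = -1
    freea[meta[M_NFREEA]] = a
    meta[M_NFREEA] += 1
    if sp[a] == COMK:
        meta[M_KCOUNT] -= 1
    elif sp[a] == COMS:
        meta[M_SCOUNT] -= 1


@njit(cache=False)
def _new_complex(st, kind, m0, m1, m2, pos):
    apos, acomp = st[2], st[3]
    ckind, cmem, cpos, cprom = st[6], st[7], st[8], st[9]
    occ, freec, meta = st[16], st[20], st[21]
    if meta[M_NFREEC] > 0:
        meta[M_NFREEC] -= 1
        c = freec[meta[M_NFREEC]]
    else:
        c = meta[M_NCOMP]
        meta[M_NCOMP] += 1
    ckind[c] = kind
    cmem[c, 0] = m0
    cmem[c, 1] = m1
    cmem[c, 2] = m2
    cpos[c] = pos
    cprom[c] = -1
    acomp[m0] = c
    apos[m0] = pos
    if m1 >= 0:
        acomp[m1] = c
        apos[m1] = pos
    if m2 >= 0:
        acomp[m2] = c
        apos[m2] = pos
    occ[pos] = CBASE + c
    return c


@njit(cache=False)
def _free_complex(st, c):
    ckind, freec, meta = st[6], st[20], st[21]
    ckind[c] = -1
    freec[meta[M_NFREEC]] = c
    meta[M_NFREEC] += 1


@njit(cache=False)
def _free_site_near(st, pos, rng):
    """A free Moore neighbor of ``pos`` scanned from a random offset, or -1."""
    occ, nbr, nnbr = st[16], st[17], st[18]
    nn = nnbr[pos]
    o = rng.integers(0, nn)
    for k in range(nn):
        q = nbr[pos, (o + k) % nn]
        if occ[q] == -1:
            return q
    return -1


@njit(cache=False)
def _move_entity(st, eid, pos, rng):
    """One random-walk step; a blocked move is a legal no-op."""
    occ, nbr, nnbr = st[16], st[17], st[18]
    q = nbr[pos, rng.integers(0, nnbr[pos])]
    if occ[q] != -1:
        return pos
    occ[pos] = -1
    occ[q] = eid
    return q


@njit(cache=False)
def _move_agent(st, a, rng):
    apos = st[2]
    apos[a] = _move_entity(st, a, apos[a], rng)


@njit(cache=False)
def _move_complex(st, c, rng):
    """A bound complex moves as a single unit; members are carried along."""
    apos, cmem, cpos = st[2], st[7], st[8]
    p = cpos[c]
    q = _move_entity(st, CBASE + c, p, rng)
    if q != p:
        cpos[c] = q
        for j in range(3):
            m = cmem[c, j]
            if m >= 0:
                apos[m] = q


# -- pairwise bind operations ------------------------------------------------

@njit(cache=False)
def _bind_comk_pair(st, a, b, rng):
    """ComK + ComK -> homodimer at a's site (b vacates its own site)."""
    if rng.random() >= st[22][PB_KK]:
        return -1
    apos, occ = st[2], st[16]
    occ[apos[b]] = -1
    return _new_complex(st, COMK_DIMER, a, b, -1, apos[a])


@njit(cache=False)
def _bind_clp_meca(st, actor, partner, rng):
    """Free ClpCP + free MecA -> substrate-free protease complex."""
    if rng.random() >= st[22][PB_CM]:
        return -1
    sp, apos, occ = st[0], st[2], st[16]
    clp = actor if sp[actor] == CLPCP else partner
    meca = partner if clp == actor else actor
    pos = apos[actor]
    occ[apos[partner]] = -1
    return _new_complex(st, CLPCP_MECA, clp, meca, -1, pos)


@njit(cache=False)
def _bind_rib_mrna(st, actor, partner, rng):
    if rng.random() >= st[22][PB_RIB]:
        return -1
    sp, apos, occ = st[0], st[2], st[16]
    rib = actor if sp[actor] == RIBOSOME else partner
    m = partner if rib == actor else actor
    pos = apos[actor]
    occ[apos[partner]] = -1
    return _new_complex(st, RIBOSOME_MRNA, rib, m, -1, pos)


@njit(cache=False)
def _join_protease(st, c, b, rng):
    """Free ComK/ComS b is captured by a substrate-free protease complex c."""
    sp = st[0]
    probs = st[22]
    pr = probs[PB_CMK] if sp[b] == COMK else probs[PB_CMS]
    if rng.random() >= pr:
        return False
    apos, acomp, occ = st[2], st[3], st[16]
    ckind, cmem, cpos = st[6], st[7], st[8]
    occ[apos[b]] = -1
    cmem[c, 2] = b
    acomp[b] = c
    apos[b] = cpos[c]
    ckind[c] = CLPCP_MECA_COMK if sp[b] == COMK else CLPCP_MECA_COMS
    return True


@njit(cache=False)
def _displace_comk(st, c, b):
    """ComS b displaces the bound ComK of protease complex c (unconditional).

    The freed ComK monomer takes over the site the ComS vacated, so the swap
    conserves molecule counts and occupancy exactly.
    """
    apos, acomp, occ = st[2], st[3], st[16]
    ckind, cmem, cpos = st[6], st[7], st[8]
    k = cmem[c, 2]
    site_b = apos[b]
    cmem[c, 2] = b
    acomp[b] = c
    apos[b] = cpos[c]
    ckind[c] = CLPCP_MECA_COMS
    acomp[k] = -1
    apos[k] = site_b
    occ[site_b] = k
    return k


@njit(cache=False)
def _capture_from_dimer(st, c_prot, c_dim, rng):
    """A substrate-free protease complex seizes one ComK from an adjacent
    free homodimer (same probability as monomer capture); the other member
    is released as a monomer on the dimer's site. Promoter-bound dimers are
    not touched."""
    if rng.random() >= st[22][PB_CMK]:
        return False
    apos, acomp = st[2], st[3]
    ckind, cmem, cpos = st[6], st[7], st[8]
    occ = st[16]
    j = rng.integers(0, 2)
    k_cap = cmem[c_dim, j]
    k_free = cmem[c_dim, 1 - j]
    site = cpos[c_dim]
    occ[site] = k_free
    apos[k_free] = site
    acomp[k_free] = -1
    _free_complex(st, c_dim)
    cmem[c_prot, 2] = k_cap
    acomp[k_cap] = c_prot
    apos[k_cap] = cpos[c_prot]
    ckind[c_prot] = CLPCP_MECA_COMK
    return True


@njit(cache=False)
def _bind_to_promoter(st, a, p, rng):
    """A repressor/DegU/ComX agent binds the promoter if its slot is open.

    Bound agents stay on their own lattice site but become immobile until
    released (dissociation, successful transcription, or division).
    """
    sp, aprom = st[0], st[4]
    pgene, prep, pdegu, pcomx = st[10], st[12], st[13], st[14]
    probs = st[22]
    s = sp[a]
    if s == REPRESSOR:
        if prep[p] >= 0:
            return False
        if rng.random() >= probs[PB_REP]:
            return False
        prep[p] = a
        aprom[a] = p
        return True
    if s == DEGU:
        if pgene[p] != GENE_COMK or pdegu[p] >= 0:
            return False
        if rng.random() >= probs[PB_DEGU]:
            return False
        pdegu[p] = a
        aprom[a] = p
        return True
    if s == COMX:
        if pgene[p] != GENE_COMS or pcomx[p] >= 0:
            return False
        if rng.random() >= probs[PB_COMX]:
            return False
        pcomx[p] = a
        aprom[a] = p
        return True
    return False


@njit(cache=False)
def _bind_dimer_to_promoter(st, c, p, rng):
    """A ComK dimer binds one of the two comK-promoter dimer slots.

    DegU at the promoter stimulates binding (higher probability); this is the
    route to the transcription-competent tetramer (two bound dimers).
    """
    cprom = st[9]
    pgene, pdegu, pdim = st[10], st[13], st[15]
    probs = st[22]
    if pgene[p] != GENE_COMK:
        return False
    slot = 0 if pdim[p, 0] < 0 else (1 if pdim[p, 1] < 0 else -1)
    if slot < 0:
        return False
    pr = probs[PB_DIMER_DEGU] if pdegu[p] >= 0 else probs[PB_DIMER]
    if rng.random() >= pr:
        return False
    pdim[p, slot] = c
    cprom[c] = p
    return True


# -- death / catalysis -------------------------------------------------------

@njit(cache=False)
def _mrna_death(st, a, rng):
    """Random degradation of an unbound transcript."""
    if rng.random() >= st[22][P_MRNA_DEATH]:
        return False
    apos, occ = st[2], st[16]
    occ[apos[a]] = -1
    _kill_agent(st, a)
    return True


@njit(cache=False)
def _protease_degradation(st, c, rng):
    """ClpCP destroys the substrate held by its MecA adapter."""
    ckind, cmem = st[6], st[7]
    if ckind[c] != CLPCP_MECA_COMK and ckind[c] != CLPCP_MECA_COMS:
        return False
    if rng.random() >= st[22][P_PROT_DEATH]:
        return False
    _kill_agent(st, cmem[c, 2])
    cmem[c, 2] = -1
    ckind[c] = CLPCP_MECA
    return True


@njit(cache=False)
def _translate(st, c, rng, tick):
    """One translation attempt by a ribosome-mRNA complex.

    On success a ComK/ComS protein appears at a free adjacent site and the
    ribosome releases the transcript (which steps off to a free neighbor, so
    single occupancy is preserved; if the neighborhood is packed the pair
    stays bound and may try again next tick).
    """
    if rng.random() >= st[22][P_TL]:
        return -1
    sp, apos, acomp = st[0], st[2], st[3]
    cmem, cpos = st[7], st[8]
    occ = st[16]
    pos = cpos[c]
    q1 = _free_site_near(st, pos, rng)
    if q1 < 0:
        return -1
    m = cmem[c, 1]
    prot = COMK if sp[m] == MRNA_COMK else COMS
    a = _new_agent(st, prot, q1, tick)
    q2 = _free_site_near(st, pos, rng)
    if q2 >= 0:
        rib = cmem[c, 0]
        acomp[m] = -1
        apos[m] = q2
        occ[q2] = m
        acomp[rib] = -1
        apos[rib] = pos
        occ[pos] = rib
        _free_complex(st, c)
    return a


# -- promoter turn -----------------------------------------------------------

@njit(cache=False)
def _transcription(st, p, rng, tick):
    """One transcription attempt; returns the new mRNA id or -1.

    A bound repressor blocks polymerase entirely. At the comK promoter the
    success probability climbs with the number of bound ComK dimers; at the
    comS promoter bound ComX activates transcription. All bound activators
    dissociate on success (become mobile again).
    """
    aprom, cprom = st[4], st[9]
    pgene, ppos, prep, pdegu, pcomx, pdim = (
        st[10], st[11], st[12], st[13], st[14], st[15],
    )
    probs = st[22]
    if prep[p] >= 0:
        return -1
    if pgene[p] == GENE_COMK:
        nd = (1 if pdim[p, 0] >= 0 else 0) + (1 if pdim[p, 1] >= 0 else 0)
        if nd == 2:
            pr = probs[PT_TETRA]
        elif nd == 1:
            pr = probs[PT_DIMER]
        else:
            pr = probs[PT_BARE]
    else:
        pr = probs[PT_COMX] if pcomx[p] >= 0 else probs[PT_BARE]
    if rng.random() >= pr:
        return -1
    q = _free_site_near(st, ppos[p], rng)
    if q < 0:
        return -1
    m = _new_agent(st, MRNA_COMK if pgene[p] == GENE_COMK else MRNA_COMS, q, tick)
    for j in range(2):
        c = pdim[p, j]
        if c >= 0:
            cprom[c] = -1
            pdim[p, j] = -1
    if pdegu[p] >= 0:
        aprom[pdegu[p]] = -1
        pdegu[p] = -1
    if pcomx[p] >= 0:
        aprom[pcomx[p]] = -1
        pcomx[p] = -1
    return m


@njit(cache=False)
def _promoter_dissociation(st, p, rng):
    """Slow spontaneous release of promoter-bound repressor and DegU."""
    aprom = st[4]
    prep, pdegu = st[12], st[13]
    probs = st[22]
    if prep[p] >= 0 and rng.random() < probs[PD_REP]:
        aprom[prep[p]] = -1
        prep[p] = -1
    if pdegu[p] >= 0 and rng.random() < probs[PD_DEGU]:
        aprom[pdegu[p]] = -1
        pdegu[p] = -1


# -- bind-rule dispatch ------------------------------------------------------

@njit(cache=False)
def _bind_rule(st, a, rng):
    """Bind rule of a free agent: search neighboring sites (from a random
    offset) for an occupant with a defined interaction and attempt it once.

    With meta[M_SCANALL] = 0 only a single uniformly random neighbor is
    inspected instead of the whole shell.
    """
    sp, apos, acomp, aprom = st[0], st[2], st[3], st[4]
    ckind = st[6]
    occ, nbr, nnbr = st[16], st[17], st[18]
    meta = st[21]
    s = sp[a]
    pos = apos[a]
    nn = nnbr[pos]
    o = rng.integers(0, nn)
    span = nn if meta[M_SCANALL] == 1 else 1
    for k in range(span):
        q = nbr[pos, (o + k) % nn]
        e = occ[q]
        if e == -1:
            continue
        if e >= PBASE:
            if s == REPRESSOR or s == DEGU or s == COMX:
                if _promoter_slot_open(st, s, e - PBASE):
                    _bind_to_promoter(st, a, e - PBASE, rng)
                    return
            continue
        if e >= CBASE:
            c = e - CBASE
            if s == COMK and ckind[c] == CLPCP_MECA:
                _join_protease(st, c, a, rng)
                return
            continue
        b = e
        if acomp[b] >= 0 or aprom[b] >= 0:
            continue
        sb = sp[b]
        if s == COMK:
            if sb == COMK:
                _bind_comk_pair(st, a, b, rng)
                return
        elif s == RIBOSOME:
            if sb == MRNA_COMK or sb == MRNA_COMS:
                _bind_rib_mrna(st, a, b, rng)
                return
        elif s == MECA:
            if sb == CLPCP:
                _bind_clp_meca(st, a, b, rng)
                return
        elif s == CLPCP:
            if sb == MECA:
                _bind_clp_meca(st, a, b, rng)
                return


@njit(cache=False)
def _promoter_slot_open(st, s, p):
    pgene, prep, pdegu, pcomx = st[10], st[12], st[13], st[14]
    if s == REPRESSOR:
        return prep[p] < 0
    if s == DEGU:
        return pgene[p] == GENE_COMK and pdegu[p] < 0
    if s == COMX:
        return pgene[p] == GENE_COMS and pcomx[p] < 0
    return False


@njit(cache=False)
def _complex_bind_rule(st, c, rng):
    """Bind rule executed on behalf of a mobile complex."""
    sp, acomp, aprom = st[0], st[3], st[4]
    ckind, cpos = st[6], st[8]
    pgene, pdim = st[10], st[15]
    occ, nbr, nnbr = st[16], st[17], st[18]
    meta = st[21]
    kind = ckind[c]
    pos = cpos[c]
    nn = nnbr[pos]
    o = rng.integers(0, nn)
    span = nn if meta[M_SCANALL] == 1 else 1
    for k in range(span):
        q = nbr[pos, (o + k) % nn]
        e = occ[q]
        if e == -1:
            continue
        if kind == COMK_DIMER:
            if e >= PBASE:
                p = e - PBASE
                if pgene[p] == GENE_COMK and (pdim[p, 0] < 0 or pdim[p, 1] < 0):
                    _bind_dimer_to_promoter(st, c, p, rng)
                    return
            continue
        if e >= CBASE or e >= PBASE:
            continue
        b = e
        if acomp[b] >= 0 or aprom[b] >= 0:
            continue
        if kind == CLPCP_MECA:
            if sp[b] == COMK or sp[b] == COMS:
                _join_protease(st, c, b, rng)
                return
        elif kind == CLPCP_MECA_COMK:
            if sp[b] == COMS:
                _displace_comk(st, c, b)
                return


# -- per-tick turns ----------------------------------------------------------

@njit(cache=False)
def _agent_turn(st, a, rng, tick):
    """One agent attempts each of its rules once (move, bind, then its
    species-specific rule). Complex members act through their representative:
    the first member listed (ComK of a dimer, ClpCP of a protease complex,
    the ribosome of a translating pair)."""
    sp, alive, acomp, aprom, born = st[0], st[1], st[3], st[4], st[5]
    ckind, cmem, cprom = st[6], st[7], st[9]
    if alive[a] == 0 or born[a] >= tick:
        return
    c = acomp[a]
    if c >= 0:
        kind = ckind[c]
        if kind == COMK_DIMER:
            if cmem[c, 0] != a:
                return
            if cprom[c] >= 0:
                return  # promoter-bound: immobile until released
            _move_complex(st, c, rng)
            _complex_bind_rule(st, c, rng)
        elif kind == RIBOSOME_MRNA:
            if sp[a] != RIBOSOME:
                return
            _move_complex(st, c, rng)
            _translate(st, c, rng, tick)
        else:
            if sp[a] != CLPCP:
                return
            _move_complex(st, c, rng)
            _complex_bind_rule(st, c, rng)
            _protease_degradation(st, c, rng)
        return
    if aprom[a] >= 0:
        return  # bound at a promoter: immobile until released
    s = sp[a]
    _move_agent(st, a, rng)
    if s == COMS:
        return  # ComS only moves; it is bound *by* MecA, never the binder
    if s == MRNA_COMK or s == MRNA_COMS:
        _mrna_death(st, a, rng)
        return
    _bind_rule(st, a, rng)
    if s == RIBOSOME and acomp[a] >= 0:
        _translate(st, acomp[a], rng, tick)


@njit(cache=False)
def _promoter_turn(st, p, rng, tick):
    _transcription(st, p, rng, tick)
    _promoter_dissociation(st, p, rng)


@njit(cache=False)
def run_ticks(st, rng, n_ticks, traj_k, traj_s, start):
    """Advance up to ``n_ticks`` ticks; returns the number completed.

    Stops early (before a tick) when array headroom runs low so the Python
    wrapper can grow the arrays and resume; a tick is never split.

    Each tick: every live agent present at tick start and every promoter is
    visited exactly once in a freshly shuffled order; agents created during
    the tick (proteins, transcripts, injected ComX) act from the next tick.
    The competence flag is evaluated at tick end and is monotone.
    """
    alive, born = st[1], st[5]
    meta = st[21]
    n_prom = st[10].shape[0]
    cap_a = st[0].shape[0]
    cap_c = st[6].shape[0]
    record = traj_k.shape[0] > 0
    done = 0
    for _ in range(n_ticks):
        need_a = 128 + n_prom
        need_c = 64 + (meta[M_NAGENT] - meta[M_NFREEA]) // 2
        if (cap_a - meta[M_NAGENT]) + meta[M_NFREEA] < need_a:
            break
        if (cap_c - meta[M_NCOMP]) + meta[M_NFREEC] < need_c:
            break
        tick = meta[M_TICK]
        na = meta[M_NAGENT]
        order = np.empty(na + n_prom, np.int64)
        n_act = 0
        for a in range(na):
            if alive[a] == 1 and born[a] < tick:
                order[n_act] = a
                n_act += 1
        for p in range(n_prom):
            order[n_act] = -(p + 1)
            n_act += 1
        for i in range(n_act - 1, 0, -1):
            j = rng.integers(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for i in range(n_act):
            e = order[i]
            if e >= 0:
                _agent_turn(st, e, rng, tick)
            else:
                _promoter_turn(st, -e - 1, rng, tick)
        meta[M_TICK] = tick + 1
        if meta[M_COMPETENT] == 0 and meta[M_KCOUNT] > meta[M_THRESH]:
            meta[M_COMPETENT] = 1
            meta[M_CTICK] = tick + 1
        if record:
            traj_k[start + done] = meta[M_KCOUNT]
            traj_s[start + done] = meta[M_SCOUNT]
        done += 1
    return done


@njit(cache=False)
def place_free(st, rng):
    """A uniformly random free site (rejection sampling on the occupancy)."""
    occ = st[16]
    n = occ.shape[0]
    while True:
        s = rng.integers(0, n)
        if occ[s] == -1:
            return s
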