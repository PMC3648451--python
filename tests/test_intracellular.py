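"""Intracellular model: initialization, rule mechanics, conservation, and
the competence criterion."""

import numpy as np
import pytest

from comswitch.intracellular import ConfigError, IntracellularModel
from comswitch.rules import (
    COMK, COMS, COMX, DEGU, MECA, CLPCP, RIBOSOME, REPRESSOR,
    MRNA_COMK, MRNA_COMS, GENE_COMK, GENE_COMS,
    COMK_DIMER, CLPCP_MECA, CLPCP_MECA_COMK, CLPCP_MECA_COMS, RIBOSOME_MRNA,
    RuleTable,
)

from conftest import bare_model, free_neighbor, make_protease_complex, place_pair


class TestInit:
    def test_default_machinery_counts(self):
        m = IntracellularModel(seed=0)
        c = m.species_counts()
        assert c["Ribosome"] == 80
        assert c["MecA"] == 20
        assert c["ClpCP"] == 20
        assert c["Repressor"] == 2
        assert c["mRNA_comK"] == 0 and c["mRNA_comS"] == 0
        for name in ("ComK", "ComS", "ComX", "DegU"):
            assert 0 <= c[name] <= 12

    def test_results_setting_overrides(self):
        m = IntracellularModel(comk=12, coms=12, comx=12, degu=12, seed=0)
        c = m.species_counts()
        assert (c["ComK"], c["ComS"], c["ComX"], c["DegU"]) == (12, 12, 12, 12)
        assert m.comk_count() == 12

    def test_promoter_regions_split_by_gene(self):
        m = IntracellularModel(seed=0, n_promoters=12)
        genes = list(m.pgene)
        assert genes.count(GENE_COMK) == 6 and genes.count(GENE_COMS) == 6

    def test_out_of_range_override_rejected(self):
        with pytest.raises(ConfigError):
            IntracellularModel(comk=13, seed=0)

    def test_same_seed_identical_placement(self):
        a = IntracellularModel(seed=9)
        b = IntracellularModel(seed=9)
        assert np.array_equal(a.apos, b.apos)
        assert np.array_equal(a.sp, b.sp)
        assert a.initial_counts == b.initial_counts


class TestComKCount:
    def test_counts_monomers_dimers_and_protease_bound(self):
        """3 free ComK + 1 dimer + 1 protease-bound ComK -> 6 units."""
        m = bare_model()
        for _ in range(3):
            m.place_agent(COMK)
        m.spawn_dimer()
        c = make_protease_complex(m)
        k = m.place_agent(COMK, free_neighbor(m, int(m.cpos[c])))
        # drive the capture through the same jitted rule the kernel uses
        captured = False
        for _ in range(2000):
            if m.attempt_join_protease(c, k):
                captured = True
                break
        assert captured
        assert m.comk_count() == 6
        assert m.comk_count(recount=True) == 6

    def test_threshold_crossing_sets_monotone_flag(self):
        m = bare_model(competence_threshold=20)
        for _ in range(21):
            m.place_agent(COMK)
        assert not m.competent
        m.tick(1)
        assert m.competent
        assert m.competence_tick == 1
        m.tick(50)
        assert m.competent  # flag never reverts


class TestBindMechanics:
    def test_dimer_formation_and_structure(self):
        m = bare_model(seed=5)
        a, b = place_pair(m, COMK, COMK)
        formed = False
        for _ in range(200):
            if m.attempt_bind(a, b):
                formed = True
                break
        assert formed
        (c,) = m.complexes_of(COMK_DIMER)
        assert set(m.cmem[c, :2]) == {a, b}
        assert m.apos[a] == m.apos[b] == m.cpos[c]  # one-site complex
        assert m.comk_count() == 2  # dimer members still count
        m.check_consistency()

    def test_undefined_pair_is_noop(self):
        m = bare_model(seed=6)
        a, b = place_pair(m, COMK, COMS)
        for _ in range(50):
            assert not m.attempt_bind(a, b)
        assert m.complex_counts() == {}

    def test_displacement_swaps_substrate_and_conserves_comk(self):
        m = bare_model(seed=7)
        c = make_protease_complex(m)
        k = m.place_agent(COMK, free_neighbor(m, int(m.cpos[c])))
        while not m.attempt_join_protease(c, k):
            pass
        assert m.ckind[c] == CLPCP_MECA_COMK
        before = m.comk_count()
        coms = m.place_agent(COMS, free_neighbor(m, int(m.cpos[c])))
        freed = m.displace_comk_for_coms(c, coms)
        assert m.ckind[c] == CLPCP_MECA_COMS
        assert freed == k and m.acomp[k] == -1
        assert m.comk_count() == before  # swap conserves ComK
        m.check_consistency()

    def test_substrate_free_complex_has_no_displacement(self):
        m = bare_model(seed=8)
        c = make_protease_complex(m)
        coms = m.place_agent(COMS, free_neighbor(m, int(m.cpos[c])))
        with pytest.raises(ValueError):
            m.displace_comk_for_coms(c, coms)


class TestExpression:
    def test_repressed_promoter_never_transcribes(self):
        """With a repressor permanently bound, no transcript is ever made."""
        rules = RuleTable(dissociation_repressor=0.0)
        m = bare_model(seed=9, rules=rules)
        p = 0  # a comK region
        assert m.pgene[p] == GENE_COMK
        rep = m.place_agent(REPRESSOR, free_neighbor(m, int(m.ppos[p])))
        while not m.promoter_bind(rep, p):
            pass
        for _ in range(20_000):
            assert m.transcription_step(p) < 0
        assert m.species_counts()["mRNA_comK"] == 0

    def test_transcription_releases_activators(self):
        rules = RuleTable(transcription_comx=1.0)
        m = bare_model(seed=10, rules=rules)
        p = int(np.flatnonzero(m.pgene == GENE_COMS)[0])
        x = m.place_agent(COMX, free_neighbor(m, int(m.ppos[p])))
        while not m.promoter_bind(x, p):
            pass
        assert m.pcomx[p] == x and m.aprom[x] == p
        mrna = m.transcription_step(p)
        assert mrna >= 0 and m.sp[mrna] == MRNA_COMS
        assert m.pcomx[p] == -1 and m.aprom[x] == -1  # activator released
        m.check_consistency()

    def test_translation_creates_matching_protein(self):
        rules = RuleTable(translation=1.0)
        m = bare_model(seed=11, rules=rules)
        rib, mr = place_pair(m, RIBOSOME, MRNA_COMK)
        while not m.attempt_bind(rib, mr):
            pass
        (c,) = m.complexes_of(RIBOSOME_MRNA)
        before = m.comk_count()
        prot = m.translation_step(int(c))
        assert prot >= 0 and m.sp[prot] == COMK
        assert m.comk_count() == before + 1
        # ribosome released its transcript afterwards
        assert m.acomp[rib] == -1 and m.acomp[mr] == -1
        m.check_consistency()

    def test_single_transcript_yields_several_proteins(self):
        """One comK transcript with a ribosome nearby and no proteases
        produces more than one ComK over its lifetime (ribosome rebinding
        at 0.9 vs slow transcript decay at 1e-4)."""
        yields = []
        for seed in range(8):
            m = bare_model(seed=100 + seed, dims=(12, 12, 12))
            mr = m.place_agent(MRNA_COMK)
            m.place_agent(RIBOSOME, free_neighbor(m, int(m.apos[mr])))
            for _ in range(40):
                m.tick(500)
                if not m.agents_of(MRNA_COMK).size and not m.complexes_of(
                        RIBOSOME_MRNA).size:
                    break  # transcript decayed
            yields.append(m.comk_count())
        assert np.mean(yields) > 1.0
        assert max(yields) >= 3  # "several" in the lucky runs

    def test_bound_mrna_never_dies(self):
        m = bare_model(seed=12, rules=RuleTable(mrna_death=1.0))
        rib, mr = place_pair(m, RIBOSOME, MRNA_COMS)
        while not m.attempt_bind(rib, mr):
            pass
        assert not m.mrna_death_step(mr)
        assert m.alive[mr] == 1

    def test_immortal_mrna_with_zero_death_rate(self):
        m = bare_model(seed=13, rules=RuleTable(mrna_death=0.0))
        mr = m.place_agent(MRNA_COMK)
        for _ in range(5000):
            assert not m.mrna_death_step(mr)

    def test_protease_degradation_removes_substrate_keeps_machinery(self):
        m = bare_model(seed=14, rules=RuleTable(protease_degradation=1.0))
        c = make_protease_complex(m)
        k = m.place_agent(COMK, free_neighbor(m, int(m.cpos[c])))
        while not m.attempt_join_protease(c, k):
            pass
        assert m.protease_degradation_step(c)
        assert m.ckind[c] == CLPCP_MECA  # machinery persists, may rebind
        assert m.alive[k] == 0
        assert m.comk_count() == 0
        m.check_consistency()


class TestMassAction:
    def test_comk_changes_only_by_translation_and_degradation(self):
        """Over a long free run the monomer ledger stays exact."""
        m = IntracellularModel(comk=12, coms=12, comx=12, degu=12, seed=21)
        for _ in range(10):
            m.tick(200)
            assert m.comk_count() == m.comk_count(recount=True)
            assert m.coms_count() == m.coms_count(recount=True)
            m.check_consistency()

    def test_determinism_same_seed_same_trajectory(self):
        a = IntracellularModel(comk=12, coms=12, comx=12, degu=12, seed=33)
        b = IntracellularModel(comk=12, coms=12, comx=12, degu=12, seed=33)
        ta = a.run(400, record=True)
        tb = b.run(400, record=True)
        assert np.array_equal(ta[0], tb[0]) and np.array_equal(ta[1], tb[1])
        assert np.array_equal(a.occ, b.occ)

    def test_snapshot_restore_roundtrip(self):
        m = IntracellularModel(comk=5, coms=5, comx=5, degu=5, seed=4)
        snap = m.snapshot()
        m.tick(100)
        changed = not np.array_equal(m.occ, snap["occ"])
        m.restore(snap)
        assert np.array_equal(m.occ, snap["occ"])
        assert m.tick_count == 0
        assert changed


class TestDivision:
    def test_counts_conserved_and_daughter_machinery_fresh(self):
        m = IntracellularModel(comk=10, coms=8, comx=6, degu=4, seed=40)
        m.tick(300)  # let complexes form
        before = {
            "ComK": m.comk_count(),
            "ComS": m.coms_count(),
            "ComX": m.species_counts()["ComX"],
            "mK": m.species_counts()["mRNA_comK"],
            "mS": m.species_counts()["mRNA_comS"],
        }
        d, rec = m.divide()
        after_p = m.species_counts()
        after_d = d.species_counts()
        assert after_p["ComK"] + after_d["ComK"] == before["ComK"]
        assert after_p["ComS"] + after_d["ComS"] == before["ComS"]
        assert after_p["ComX"] + after_d["ComX"] == before["ComX"]
        assert after_p["mRNA_comK"] + after_d["mRNA_comK"] == before["mK"]
        assert after_p["mRNA_comS"] + after_d["mRNA_comS"] == before["mS"]
        assert rec["comk_proteins"] == after_d["ComK"]
        # machinery is freshly drawn from the startup table, not partitioned
        assert after_d["Ribosome"] == 80 and after_d["MecA"] == 20
        assert after_d["ClpCP"] == 20 and after_d["Repressor"] == 2
        m.check_consistency()
        d.check_consistency()

    def test_promoter_complement_equal_and_gene_balanced(self):
        m = IntracellularModel(n_promoters=12, comk=6, coms=0, comx=0,
                               degu=0, seed=41)
        d, _ = m.divide()
        for model in (m, d):
            genes = list(model.pgene)
            assert genes.count(GENE_COMK) == 6
            assert genes.count(GENE_COMS) == 6

    def test_daughter_inherited_mean_is_half(self):
        """A uniformly random central plane passes half on average."""
        totals = []
        for i in range(300):
            m = IntracellularModel(comk=10, coms=0, comx=0, degu=0, seed=1000 + i)
            _, rec = m.divide()
            totals.append(rec["comk_proteins"])
        mean = np.mean(totals)
        assert abs(mean - 5.0) < 0.5  # 3 sigma ~ 0.27 at n=300


class TestCultureCoupling:
    def test_inject_comx_adds_quiescent_agent(self):
        """A newly absorbed ComX acts only from the next tick: on its birth
        tick it cannot move even on an otherwise empty lattice."""
        m = bare_model(seed=50)
        m.tick(3)
        a = m.inject_comx()
        assert m.sp[a] == COMX and m.born[a] == m.tick_count
        pos_birth = int(m.apos[a])
        m.tick(1)  # the tick it was born into: no action
        assert int(m.apos[a]) == pos_birth
        m.tick(1)  # all neighbors free, so an acting agent must move
        assert int(m.apos[a]) != pos_birth
        m.check_consistency()

    def test_remove_random_repressor_unbinds_first(self):
        m = bare_model(seed=51, n_repressors=2)
        rep = int(m.agents_of(REPRESSOR)[0])
        p = 0
        site = free_neighbor(m, int(m.ppos[p]))
        m.occ[m.apos[rep]] = -1
        m.apos[rep] = site
        m.occ[site] = rep
        while not m.promoter_bind(rep, p):
            pass
        rng = np.random.default_rng(0)
        n0 = m.species_counts()["Repressor"]
        assert m.remove_random_repressor(rng)
        assert m.remove_random_repressor(rng)
        assert not m.remove_random_repressor(rng)  # none left
        assert m.species_counts()["Repressor"] == n0 - 2
        assert (m.prep == -1).all()
        m.check_consistency()
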