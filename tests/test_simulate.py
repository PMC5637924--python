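"""Generator behaviour: divergence, ploidy structure, meiosis, observations."""

import numpy as np
import pytest

from lgphylo import simulate
from lgphylo.models import GTRModel


class TestProgenitorSequences:
    def test_zero_divergence_gives_identical_tips(self):
        seqs = simulate.simulate_progenitor_sequences(
            "((a:0.0,b:0.0):0.0,c:0.0);", 500, seed=3)
        assert np.array_equal(seqs["a"], seqs["b"])
        assert np.array_equal(seqs["a"], seqs["c"])

    def test_pairwise_divergence_matches_closed_form(self):
        # two tips at total distance 0.1 under the equal-rate model: expected
        # difference fraction 0.75 * (1 - exp(-4*0.1/3))
        L = 100_000
        seqs = simulate.simulate_progenitor_sequences("(a:0.06,b:0.04);", L, seed=4)
        p_exp = 0.75 * (1 - np.exp(-4 * 0.1 / 3))
        p_obs = (seqs["a"] != seqs["b"]).mean()
        sd = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * sd

    def test_single_tip_tree(self):
        seqs = simulate.simulate_progenitor_sequences("(solo:0.05);", 100, seed=5)
        assert set(seqs) >= {"solo"}
        assert len(seqs["solo"]) == 100

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError):
            simulate.simulate_progenitor_sequences("((a:0.1,b", 100)

    def test_negative_branch_raises(self):
        with pytest.raises(ValueError):
            simulate.simulate_progenitor_sequences("(a:-0.1,b:0.1);", 100)

    def test_seed_determinism(self):
        s1 = simulate.simulate_progenitor_sequences("(a:0.1,b:0.1);", 300, seed=9)
        s2 = simulate.simulate_progenitor_sequences("(a:0.1,b:0.1);", 300, seed=9)
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)


class TestAssemblePolyploid:
    def test_decaploid_pair_structure(self, small_world):
        mother, truth = small_world["mother"], small_world["truth"]
        assert mother.ploidy == 10
        pairs = mother.pairs()
        assert len(pairs) == 5
        assert all(len(v) == 2 for v in pairs.values())
        # scenario H2.C: four copies (two pairs) from the B2 lineage
        lineages = list(truth.pair_lineages.values())
        assert sorted(lineages) == ["Av", "B1", "B2", "B2", "Bi"]

    def test_degenerate_diploid(self):
        seqs = simulate.simulate_progenitor_sequences("(Av:0.02,Bi:0.02);", 800, seed=1)
        m, f, truth = simulate.assemble_polyploid({"Av": 2}, seqs, seed=2,
                                                  reference="Bi")
        assert m.ploidy == 2 and f.ploidy == 2

    def test_zero_heterozygosity_identical_pair_members(self):
        seqs = simulate.simulate_progenitor_sequences("(Av:0.02,Bi:0.02);", 2000, seed=1)
        m, _, _ = simulate.assemble_polyploid(
            {"Av": 4}, seqs, within_lineage_het=0.0, shared_het=0.0,
            seed=3, reference="Bi")
        for a, b in m.pairs().values():
            assert np.array_equal(a.seq, b.seq)

    @pytest.mark.parametrize("bad", [{"Av": 3}, {"nope": 2}])
    def test_invalid_spec_raises(self, bad):
        seqs = simulate.simulate_progenitor_sequences("(Av:0.02,Bi:0.02);", 500, seed=1)
        with pytest.raises(ValueError):
            simulate.assemble_polyploid(bad, seqs, seed=0, reference="Bi")

    def test_single_dose_markers_are_single_dose(self, small_world):
        mother, father, truth = (small_world["mother"], small_world["father"],
                                 small_world["truth"])
        mk = truth.markers
        for _, row in mk[mk.seg_class == "maternal"].head(20).iterrows():
            m_dose = sum(c.seq[row.pos - 1] == row.alt for c in mother.copies)
            p_dose = sum(c.seq[row.pos - 1] == row.alt for c in father.copies)
            assert (m_dose, p_dose) == (1, 0)


class TestF1Cross:
    def test_zero_progeny(self, small_world):
        pop = simulate.simulate_f1_cross(
            small_world["mother"], small_world["father"], small_world["truth"],
            0, 60.0, seed=1)
        assert pop.progeny == []

    @pytest.mark.parametrize("interference", ["haldane", "kosambi"])
    def test_recombination_fraction_10cM(self, small_world, interference):
        # two loci 10 cM apart: under the Kosambi-consistent generator the
        # recombinant fraction is 0.5*tanh(0.2) ~ 0.0987; the Poisson
        # (Haldane) generator gives 0.5*(1-exp(-0.2)) ~ 0.0906
        truth = small_world["truth"]
        n = 2000
        pop = simulate.simulate_f1_cross(
            small_world["mother"], small_world["father"], truth,
            n, 60.0, seed=7, interference=interference)
        L = truth.seq_length
        pos1 = 1
        pos2 = int(round(10.0 / 60.0 * (L - 1))) + 1
        pid = sorted(truth.pair_lineages)[0]
        rec = 0
        for prog in pop.progeny:
            g = prog.gametes[pid][0]
            rec += int(g.copy_at(pos1)) != int(g.copy_at(pos2))
        expected = (0.5 * np.tanh(0.2) if interference == "kosambi"
                    else 0.5 * (1 - np.exp(-0.2)))
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 3 * sd

    def test_independent_assortment_between_pairs(self, small_world):
        truth = small_world["truth"]
        n = 2000
        pop = simulate.simulate_f1_cross(
            small_world["mother"], small_world["father"], truth, n, 60.0, seed=8)
        pids = sorted(truth.pair_lineages)[:2]
        match = sum(
            int(p.gametes[pids[0]][0].copy_at(1)) == int(p.gametes[pids[1]][0].copy_at(1))
            for p in pop.progeny
        )
        assert abs(match / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_dominant_sterility_segregates_1_to_1(self, small_world):
        truth = small_world["truth"]
        pid = sorted(truth.pair_lineages)[0]
        trait = simulate.TraitLocus(pair_id=pid, pos=1000)
        pop = simulate.simulate_f1_cross(
            small_world["mother"], small_world["father"], truth,
            2000, 60.0, trait=trait, seed=9)
        frac = np.mean([p.phenotype == "sterile" for p in pop.progeny])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_trait_off_genome_raises(self, small_world):
        with pytest.raises(ValueError):
            simulate.simulate_f1_cross(
                small_world["mother"], small_world["father"], small_world["truth"],
                5, 60.0, trait=simulate.TraitLocus(pair_id="nope", pos=1), seed=1)


class TestObservations:
    def test_noiseless_high_depth_equals_truth(self, small_world):
        mother, father, truth, pop = (small_world[k] for k in
                                      ("mother", "father", "truth", "pop"))
        obs = simulate.emit_observations(mother, father, pop, truth,
                                         mean_depth=10_000, error_rate=0.0, seed=2)
        mk = truth.markers.set_index("pos")
        sub = obs[obs.individual == "F001"]
        for _, row in sub.head(40).iterrows():
            t = mk.loc[row.pos]
            prog = pop.progeny[0]
            gm, gp = prog.gametes[t.pair_id]
            m_has = (mother.pairs()[t.pair_id][gm.copy_at(row.pos)]
                     .seq[row.pos - 1] == t.alt)
            p_has = (father.pairs()[t.pair_id][gp.copy_at(row.pos)]
                     .seq[row.pos - 1] == t.alt)
            assert (row.alt_depth > 0) == bool(m_has or p_has)

    def test_parent_single_dose_fraction(self, small_world):
        mother, father, truth, pop = (small_world[k] for k in
                                      ("mother", "father", "truth", "pop"))
        obs = simulate.emit_observations(mother, father, pop, truth,
                                         mean_depth=500, error_rate=0.0,
                                         seed=3, parent_depth=1000)
        mk = truth.markers
        mat_pos = mk[mk.seg_class == "maternal"].pos
        sub = obs[(obs.individual == "M") & obs.pos.isin(mat_pos)]
        frac = sub.alt_depth.sum() / (sub.alt_depth + sub.ref_depth).sum()
        sd = np.sqrt(0.1 * 0.9 / (1000 * len(sub)))
        assert abs(frac - 0.1) < 3 * sd

    def test_zero_depth_all_missing(self, small_world):
        obs = simulate.emit_observations(
            small_world["mother"], small_world["father"], small_world["pop"],
            small_world["truth"], mean_depth=0, error_rate=0.0, seed=4,
            parent_depth=0)
        assert (obs.ref_depth + obs.alt_depth == 0).all()

    def test_seed_determinism(self, small_world):
        args = (small_world["mother"], small_world["father"], small_world["pop"],
                small_world["truth"])
        a = simulate.emit_observations(*args, mean_depth=40, error_rate=0.005, seed=5)
        b = simulate.emit_observations(*args, mean_depth=40, error_rate=0.005, seed=5)
        assert a.equals(b)
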