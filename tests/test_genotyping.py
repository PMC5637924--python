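"""Single-dose site classification and progeny genotype calling."""

import numpy as np
import pytest

from lgphylo import genotyping, simulate
from lgphylo.genotyping import (AA, AB, MISSING, DepthTable, MarkerCall,
                                call_markers, call_progeny,
                                classify_parental_site, segregation_filter)


class TestClassifyParentalSite:
    def test_below_min_depth_uninformative(self):
        assert classify_parental_site((35, 4), (100, 0)) == "uninformative"

    def test_maternal_single_dose(self):
        assert classify_parental_site((90, 10), (100, 0)) == "maternal"

    def test_paternal_single_dose(self):
        assert classify_parental_site((100, 0), (90, 10)) == "paternal"

    def test_biparental(self):
        assert classify_parental_site((180, 20), (180, 20)) == "biparental"

    def test_ambiguous_fraction_uninformative(self):
        # 40% alternate fraction is neither single-dose nor homozygous
        assert classify_parental_site((60, 40), (100, 0)) == "uninformative"

    def test_invalid_ploidy(self):
        with pytest.raises(ValueError):
            classify_parental_site((50, 5), (50, 0), ploidy=5)


class TestCallProgeny:
    def test_threshold_rules(self):
        ref = np.array([50, 10, 4, 30])
        alt = np.array([0, 3, 1, 0])
        geno = call_progeny(ref, alt, min_depth_progeny=10, min_alt_reads=2)
        assert list(geno) == [AA, AB, MISSING, AA]

    def test_low_depth_missing(self):
        geno = call_progeny(np.array([4]), np.array([1]))
        assert list(geno) == [MISSING]


class TestSegregationFilter:
    def test_balanced_counts_kept(self):
        m = MarkerCall("x", "I", 1, "maternal",
                       np.array([AA] * 22 + [AB] * 23, dtype=np.int8))
        flag = segregation_filter(m, alpha=0.01)
        assert flag.keep and flag.p_value > 0.01

    def test_fully_distorted_flagged(self):
        m = MarkerCall("x", "I", 1, "maternal", np.array([AA] * 45, dtype=np.int8))
        assert not segregation_filter(m).keep

    def test_insufficient_data_passthrough(self):
        m = MarkerCall("x", "I", 1, "maternal", np.full(45, MISSING, dtype=np.int8))
        flag = segregation_filter(m)
        assert flag.keep and flag.reason == "insufficient data"


class TestRoundTrip:
    def test_noiseless_calls_recover_truth(self, small_world):
        mother, father, truth, pop = (small_world[k] for k in
                                      ("mother", "father", "truth", "pop"))
        obs = simulate.emit_observations(mother, father, pop, truth,
                                         mean_depth=200, error_rate=0.0, seed=21)
        table = DepthTable.from_long(obs)
        markers, progeny_ids = call_markers(table)
        mk = truth.markers.set_index("pos")
        assert len(markers) >= 0.99 * len(mk)
        n_checked = n_correct = 0
        for m in markers:
            t = mk.loc[m.pos]
            assert m.seg_class == t.seg_class
            if t.seg_class != "maternal":
                continue
            pair = mother.pairs()[t.pair_id]
            for j, prog in enumerate(pop.progeny):
                gm = prog.gametes[t.pair_id][0]
                true_ab = pair[gm.copy_at(m.pos)].seq[m.pos - 1] == t.alt
                if m.genotypes[j] != MISSING:
                    n_checked += 1
                    n_correct += (m.genotypes[j] == AB) == bool(true_ab)
        assert n_checked > 1000
        assert n_correct / n_checked >= 0.999

    def test_min_depth_monotonicity(self, small_world):
        mother, father, truth, pop = (small_world[k] for k in
                                      ("mother", "father", "truth", "pop"))
        obs = simulate.emit_observations(mother, father, pop, truth,
                                         mean_depth=40, error_rate=0.005, seed=22)
        table = DepthTable.from_long(obs)
        counts = [len(call_markers(table, min_depth_parent=d)[0])
                  for d in (20, 40, 60, 80)]
        assert counts == sorted(counts, reverse=True)


class TestDepthTable:
    def test_tsv_round_trip(self, small_world, tmp_path):
        obs = simulate.emit_observations(
            small_world["mother"], small_world["father"], small_world["pop"],
            small_world["truth"], mean_depth=40, error_rate=0.005, seed=30)
        t1 = DepthTable.from_long(obs)
        path = tmp_path / "depth.tsv"
        t1.to_tsv(path)
        t2 = DepthTable.from_tsv(path)
        assert np.array_equal(t1.ref, t2.ref)
        assert np.array_equal(t1.alt, t2.alt)
        assert t1.individuals == t2.individuals

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            DepthTable(chrom=np.array(["I"]), pos=np.array([5]),
                       individuals=["a"], ref=np.array([[-1]]), alt=np.array([[0]]))
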