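"""Two-point statistics, grouping, ordering, refinement and homolog pairing."""

import numpy as np
import pytest

from lgphylo import linkmap
from lgphylo.genotyping import AA, AB, MISSING, MarkerCall
from lgphylo.linkmap import (group_markers, kosambi, kosambi_inverse,
                             merge_linked_groups, order_and_space,
                             pair_homologs, pairwise_rf_lod, refine_groups,
                             summarize_map, twopoint_rf_lod)


def _testcross_population(rng, n_markers, n_progeny, spacing_rf):
    """Markers along one chromosome with given adjacent rf (no errors)."""
    G = np.zeros((n_markers, n_progeny), dtype=np.int8)
    G[0] = rng.integers(0, 2, n_progeny)
    for k in range(1, n_markers):
        flip = rng.random(n_progeny) < spacing_rf
        G[k] = np.where(flip, 1 - G[k - 1], G[k - 1])
    return G


class TestTwoPoint:
    def test_zero_recombinants(self):
        g = np.array([AA, AB] * 23, dtype=np.int8)[:45]
        rf, lod, n = twopoint_rf_lod(g, g)
        assert rf == 0.0
        assert lod == pytest.approx(45 * np.log10(2), abs=1e-9)

    def test_half_recombinants_lod_zero(self):
        g1 = np.array([AA] * 20 + [AB] * 20, dtype=np.int8)
        g2 = np.array(([AA, AB] * 10) + ([AB, AA] * 10), dtype=np.int8)
        rf, lod, n = twopoint_rf_lod(g1, g2)
        assert rf == 0.5
        assert lod == pytest.approx(0.0, abs=1e-9)

    def test_ten_recombinants_of_45(self):
        g1 = np.array([AA] * 45, dtype=np.int8)
        g2 = g1.copy()
        g2[:10] = AB
        rf, lod, n = twopoint_rf_lod(g1, g2)
        # closed-form oracle
        r, N = 10, 45
        expected = (r * np.log10(r / N) + (N - r) * np.log10(1 - r / N)
                    + N * np.log10(2))
        assert rf == pytest.approx(10 / 45)
        assert lod == pytest.approx(expected, abs=1e-9)
        assert round(lod, 2) == 3.19

    def test_repulsion_phase_folded(self):
        g1 = np.array([AA, AB] * 20, dtype=np.int8)
        g2 = 1 - g1  # perfect repulsion
        rf, lod, _ = twopoint_rf_lod(g1, g2.astype(np.int8))
        assert rf == 0.0

    def test_no_shared_progeny_raises(self):
        g1 = np.array([AA, MISSING], dtype=np.int8)
        g2 = np.array([MISSING, AA], dtype=np.int8)
        with pytest.raises(ValueError):
            twopoint_rf_lod(g1, g2)

    def test_pairwise_matches_scalar(self, rng):
        G = _testcross_population(rng, 6, 50, 0.2)
        G[2, :5] = MISSING
        RF, LOD, N = pairwise_rf_lod(G)
        for i in range(6):
            for j in range(i + 1, 6):
                rf, lod, n = twopoint_rf_lod(G[i], G[j])
                assert RF[i, j] == pytest.approx(rf)
                assert LOD[i, j] == pytest.approx(lod, abs=1e-9)
                assert N[i, j] == n


class TestKosambi:
    def test_quarter_rf_distance(self):
        assert kosambi(0.25) == pytest.approx(25 * np.log(3), abs=1e-9)

    def test_zero(self):
        assert kosambi(0.0) == 0.0

    def test_monotone_and_inverse_round_trip(self):
        r = np.linspace(0.0, 0.49, 50)
        d = kosambi(r)
        assert (np.diff(d) > 0).all()
        assert np.allclose(kosambi_inverse(d), r, atol=1e-10)


class TestGrouping:
    def test_infinite_threshold_singletons(self, rng):
        G = _testcross_population(rng, 5, 40, 0.05)
        _, lod, _ = pairwise_rf_lod(G)
        groups = group_markers(lod, [str(i) for i in range(5)], np.inf)
        assert sorted(len(g) for g in groups) == [1] * 5

    def test_perfect_linkage_one_group(self):
        G = np.tile(np.array([AA, AB] * 20, dtype=np.int8), (4, 1))
        _, lod, _ = pairwise_rf_lod(G)
        groups = group_markers(lod, list("abcd"), 5.0)
        assert len(groups) == 1

    def test_two_unlinked_chromosomes_recovered(self, rng):
        G1 = _testcross_population(rng, 20, 45, 0.04)
        G2 = _testcross_population(rng, 20, 45, 0.04)
        G = np.vstack([G1, G2])
        _, lod, _ = pairwise_rf_lod(G)
        ids = [f"m{i:02d}" for i in range(40)]
        groups = [g for g in group_markers(lod, ids, 5.0) if len(g) > 1]
        assert len(groups) == 2
        assert sorted(len(g) for g in groups) == [20, 20]

    def test_merge_requires_multiple_links(self):
        lod = np.full((6, 6), -np.inf)
        lod[0, 3] = lod[3, 0] = 4.5  # isolated cross links: not enough
        lod[1, 4] = lod[4, 1] = 4.5
        merged = merge_linked_groups([[0, 1, 2], [3, 4, 5]], lod, 4.0)
        assert len(merged) == 2
        lod[2, 5] = lod[5, 2] = 4.5
        merged = merge_linked_groups([[0, 1, 2], [3, 4, 5]], lod, 4.0)
        assert len(merged) == 1


class TestOrdering:
    def _markers(self, G, positions):
        return [MarkerCall(f"I:{p}", "I", p, "maternal", G[k])
                for k, p in enumerate(positions)]

    def test_kosambi_spacing_quarter_rf(self, rng):
        G = _testcross_population(rng, 2, 100_000, 0.25)
        markers = self._markers(G, [100, 200])
        rf, lod, _ = pairwise_rf_lod(G)
        lg = order_and_space(markers, [0, 1], rf, lod, "lg", "m")
        sd_rf = np.sqrt(0.25 * 0.75 / 100_000)
        tol = kosambi(0.25 + 3 * sd_rf) - kosambi(0.25)
        assert lg.positions_cm[-1] == pytest.approx(25 * np.log(3), abs=tol)

    def test_zero_rf_zero_spacing(self):
        G = np.tile(np.array([AA, AB] * 20, dtype=np.int8), (2, 1))
        markers = self._markers(G, [1, 2])
        rf, lod, _ = pairwise_rf_lod(G)
        lg = order_and_space(markers, [0, 1], rf, lod, "lg", "m")
        assert lg.positions_cm[-1] == 0.0

    def test_order_recovery_large_population(self, rng):
        G = _testcross_population(rng, 10, 500, 0.08)
        markers = self._markers(G, list(range(10, 110, 10)))
        rf, lod, _ = pairwise_rf_lod(G)
        lg = order_and_space(markers, list(range(10)), rf, lod, "lg", "m")
        found = [m for m in lg.markers]
        truth = [m.marker_id for m in markers]
        assert found == truth or found == truth[::-1]


class TestRefine:
    def _lg(self, positions_cm, n=None):
        n = n or len(positions_cm)
        return linkmap.LinkageGroup(
            lg_id="x", parent="m",
            markers=[f"I:{i}" for i in range(n)],
            positions_cm=np.asarray(positions_cm, dtype=float),
            chroms=["I"] * n, ref_pos=list(range(1, n + 1)),
        )

    def test_large_gap_split(self):
        lg = self._lg([0, 2, 4, 6, 8, 44, 46, 48, 50, 52])
        refined, _, dropped = refine_groups([lg], max_gap=35.0, min_snps=5)
        assert len(refined) == 2

    def test_small_fragment_dropped(self):
        lg = self._lg([0, 1, 2, 3, 40, 41, 42, 43, 44])
        refined, _, dropped = refine_groups([lg], max_gap=35.0, min_snps=5)
        assert len(refined) == 1 and len(dropped) == 1
        assert dropped[0].n_markers == 4

    def test_no_gap_unchanged(self):
        lg = self._lg([0, 5, 10, 15, 20])
        refined, _, dropped = refine_groups([lg])
        assert len(refined) == 1 and refined[0].n_markers == 5


class TestPairing:
    def test_shared_biparental_markers_pair(self, rng):
        n = 45
        # one homolog pair observed in both parents plus an unrelated paternal LG
        anchor = rng.integers(0, 2, n).astype(np.int8)
        def linked(base, r):
            flip = rng.random(n) < r
            return np.where(flip, 1 - base, base).astype(np.int8)
        Gm = np.stack([linked(anchor, 0.02) for _ in range(6)])
        Gp = np.stack([linked(anchor, 0.02) for _ in range(6)])
        G_other = _testcross_population(rng, 6, n, 0.02)
        rf_m, lod_m, _ = pairwise_rf_lod(Gm)
        rf_p, lod_p, _ = pairwise_rf_lod(np.vstack([Gp, G_other]))
        m_markers = [MarkerCall(f"m{i}", "I", i + 1, "maternal", Gm[i]) for i in range(6)]
        p_markers = [MarkerCall(f"p{i}", "I", i + 1, "paternal", Gp[i]) for i in range(6)]
        o_markers = [MarkerCall(f"o{i}", "I", i + 50, "paternal", G_other[i]) for i in range(6)]
        lg_m = order_and_space(m_markers, list(range(6)), rf_m, lod_m, "LGm", "m")
        lg_p = order_and_space(p_markers, list(range(6)), rf_p[:6, :6], lod_p[:6, :6], "LGp", "p")
        lg_o = order_and_space(o_markers, list(range(6)), rf_p[6:, 6:], lod_p[6:, 6:], "LGo", "p")
        # biparental markers: present when either parent transmits the anchor allele
        father_transmit = rng.integers(0, 2, n)
        y = ((anchor == 1) | (father_transmit == 1)).astype(np.int8)
        bip = [MarkerCall("b0", "I", 500, "biparental", np.where(y == 1, AB, AA).astype(np.int8))
               for _ in range(4)]
        testcross = {m.marker_id: m for m in m_markers + p_markers + o_markers}
        pairing = pair_homologs([lg_m], [lg_p, lg_o], bip, testcross, lod_min=4.0)
        assert pairing["LGm"] == "LGp"

    def test_no_biparental_markers_unpaired(self, rng):
        G = _testcross_population(rng, 6, 45, 0.02)
        rf, lod, _ = pairwise_rf_lod(G)
        markers = [MarkerCall(f"m{i}", "I", i + 1, "maternal", G[i]) for i in range(6)]
        lg = order_and_space(markers, list(range(6)), rf, lod, "LGm", "m")
        pairing = pair_homologs([lg], [], [], {m.marker_id: m for m in markers})
        assert pairing == {"LGm": None}


class TestSummary:
    def test_cumulative_length_additive(self):
        lgs = [
            linkmap.LinkageGroup("a", "m", ["I:1", "I:2"], np.array([0.0, 10.0]),
                                 ["I", "I"], [1, 2], designation="I"),
            linkmap.LinkageGroup("b", "m", ["I:3", "I:4"], np.array([0.0, 20.0]),
                                 ["I", "I"], [3, 4], designation="I"),
        ]
        summary = summarize_map(lgs)
        assert summary.loc[0, "cumulative_cM"] == pytest.approx(30.0)
        assert summary.loc[0, "n_lgs"] == 2
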