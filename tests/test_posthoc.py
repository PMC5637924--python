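"""Segregation chi-square, trait placement, and introgression shares."""

import numpy as np
import pytest

from lgphylo import posthoc
from lgphylo.genotyping import AA, AB, MISSING, MarkerCall
from lgphylo.linkmap import LinkageGroup
from lgphylo.phylo.alignment import SupermatrixAlignment
from lgphylo.posthoc import (introgression_site_shares, map_trait,
                             segregation_chisq, trait_to_genotypes)


class TestSegregationChisq:
    def test_continuity_corrected_statistic(self):
        # oracle: E = 21.5, |20-21.5|-0.5 = 1.0 -> chi2 = 2/21.5
        stat, p, df = segregation_chisq(20, 23)
        assert stat == pytest.approx(2 * 1.0**2 / 21.5)
        assert df == 1

    def test_perfect_fit_zero(self):
        stat, p, _ = segregation_chisq(21, 21)
        assert stat == 0.0 and p == 1.0

    def test_symmetry(self):
        assert segregation_chisq(11, 17) == segregation_chisq(17, 11)

    def test_uncorrected_exact_zero_on_equal(self):
        stat, _, _ = segregation_chisq(8, 8, correction=False)
        assert stat == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            segregation_chisq(0, 0)


def _lg_with_markers(n=8, spacing=5.0):
    return LinkageGroup(
        lg_id="LG1", parent="m",
        markers=[f"I:{100 * (k + 1)}" for k in range(n)],
        positions_cm=np.arange(n) * spacing,
        chroms=["I"] * n,
        ref_pos=[100 * (k + 1) for k in range(n)],
    )


class TestMapTrait:
    def _markers(self, rng, lg, n_prog=45, rf=0.05):
        G = np.zeros((lg.n_markers, n_prog), dtype=np.int8)
        G[0] = rng.integers(0, 2, n_prog)
        for k in range(1, lg.n_markers):
            flip = rng.random(n_prog) < rf
            G[k] = np.where(flip, 1 - G[k - 1], G[k - 1])
        return {lg.markers[k]: MarkerCall(lg.markers[k], "I", lg.ref_pos[k],
                                          "maternal", G[k])
                for k in range(lg.n_markers)}

    def test_perfect_cosegregation_placed_at_marker(self, rng):
        lg = _lg_with_markers()
        markers = self._markers(rng, lg)
        target = lg.markers[3]
        phen = ["sterile" if g == AB else "fertile"
                for g in markers[target].genotypes]
        placement = map_trait(phen, markers, [lg])
        assert placement.status == "placed"
        assert placement.best_marker == target
        assert placement.lg_id == "LG1"
        assert placement.position_cm == pytest.approx(lg.positions_cm[3])
        lo, hi = placement.interval_bp
        # support interval must cover the co-segregating marker
        assert lo <= lg.ref_pos[3] <= hi

    def test_zero_tolerance_interval_collapses_to_flanking_pair(self, rng):
        lg = _lg_with_markers()
        markers = self._markers(rng, lg, rf=0.2)
        target = lg.markers[3]
        phen = ["sterile" if g == AB else "fertile"
                for g in markers[target].genotypes]
        placement = map_trait(phen, markers, [lg], count_tolerance=0)
        lo, hi = placement.interval_bp
        assert lo >= lg.ref_pos[2] and hi <= lg.ref_pos[4]

    def test_all_fertile_no_segregation(self, rng):
        lg = _lg_with_markers()
        markers = self._markers(rng, lg)
        placement = map_trait(["fertile"] * 45, markers, [lg])
        assert placement.status == "no-segregation"

    def test_unlinked_trait(self, rng):
        lg = _lg_with_markers()
        markers = self._markers(rng, lg)
        phen = ["sterile" if x else "fertile" for x in rng.integers(0, 2, 45)]
        placement = map_trait(phen, markers, [lg], lod_min=3.0)
        assert placement.status in ("unlinked", "placed")
        if placement.status == "placed":
            assert placement.best_lod >= 3.0

    def test_marker_order_invariance(self, rng):
        lg = _lg_with_markers()
        markers = self._markers(rng, lg)
        target = lg.markers[3]
        phen = ["sterile" if g == AB else "fertile"
                for g in markers[target].genotypes]
        p1 = map_trait(phen, markers, [lg])
        shuffled = dict(reversed(list(markers.items())))
        p2 = map_trait(phen, shuffled, [lg])
        assert (p1.lg_id, p1.best_marker, p1.interval_bp) == \
               (p2.lg_id, p2.best_marker, p2.interval_bp)

    def test_trait_coding(self):
        g = trait_to_genotypes(["sterile", "fertile", None, "missing"])
        assert list(g) == [AB, AA, MISSING, MISSING]


class TestIntrogressionShares:
    def _aln(self, rows):
        labels = list(rows)
        mat = np.stack([rows[l] for l in labels]).astype(np.uint8)
        return SupermatrixAlignment(labels, mat, np.arange(1, mat.shape[1] + 1))

    def test_identical_to_ingroup(self):
        L = 300
        rng = np.random.default_rng(1)
        ing = rng.integers(0, 4, L).astype(np.uint8)
        out = (ing + 1) % 4
        aln = self._aln({"focal": ing.copy(), "in1": ing.copy(),
                         "in2": ing.copy(), "out1": out})
        res = introgression_site_shares("focal", {"ingroup": ["in1", "in2"],
                                                  "outgroup": ["out1"]}, aln)
        assert res.shares["ingroup"] == 1.0
        assert res.n_discriminating == L

    def test_mosaic_half_and_half(self):
        L = 2000
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, L).astype(np.uint8)
        b = (a + rng.integers(1, 4, L)) % 4
        focal = np.where(np.arange(L) < L // 2, a, b).astype(np.uint8)
        aln = self._aln({"focal": focal, "ga": a, "gb": b})
        res = introgression_site_shares("focal", {"A": ["ga"], "B": ["gb"]}, aln)
        assert res.shares["A"] == pytest.approx(0.5, abs=0.01)
        assert res.shares["B"] == pytest.approx(0.5, abs=0.01)
        assert res.shares["A"] + res.shares["B"] + res.unassigned == \
               pytest.approx(1.0, abs=1e-9)

    def test_polymorphic_group_sites_excluded(self):
        a = np.array([0, 0, 1], dtype=np.uint8)
        aln = self._aln({
            "focal": a,
            "g1a": np.array([0, 0, 1], dtype=np.uint8),
            "g1b": np.array([0, 2, 1], dtype=np.uint8),  # group polymorphic at col 2
            "g2": np.array([1, 1, 2], dtype=np.uint8),
        })
        res = introgression_site_shares("focal", {"g1": ["g1a", "g1b"],
                                                  "g2": ["g2"]}, aln)
        assert res.n_discriminating == 2

    def test_overlapping_groups_rejected(self):
        aln = self._aln({"focal": np.zeros(5, dtype=np.uint8),
                         "x": np.zeros(5, dtype=np.uint8)})
        with pytest.raises(ValueError):
            introgression_site_shares("focal", {"a": ["x"], "b": ["x"]}, aln)
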