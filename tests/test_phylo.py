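"""Likelihood engine, consensus/supermatrix construction and tree search."""

import itertools

import numpy as np
import pytest

from lgphylo import simulate
from lgphylo.models import GTRModel, TransitionCalculator
from lgphylo.phylo.alignment import (SupermatrixAlignment, build_lg_consensus,
                                     build_supermatrix)
from lgphylo.phylo.likelihood import TreeLikelihood, gtr_gamma_loglik
from lgphylo.phylo.search import (bootstrap_support, exhaustive_search,
                                  root_with_outgroup, search_ml_tree)
from lgphylo.phylo.tree import Tree
from lgphylo.simulate import SegmentRead


def brute_force_loglik(tree, aln, model):
    """Exhaustive sum over internal-node states: the pruning oracle."""
    calc = TransitionCalculator(model)
    pi = np.asarray(model.freqs)
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    M = aln.matrix
    total = 0.0
    for col in range(M.shape[1]):
        site = 0.0
        for rate in calc.rates:
            Ps = {id(n): calc.probs_single(n.length, rate)
                  for n in nodes if n.parent is not None}
            acc = 0.0
            for states in itertools.product(range(4), repeat=len(internal)):
                st = {id(n): states[k] for k, n in enumerate(internal)}
                p = pi[st[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    ps = st[id(n.parent)]
                    if n.is_leaf:
                        obs = M[aln.labels.index(n.name), col]
                        p *= 1.0 if obs >= 4 else Ps[id(n)][ps, obs]
                    else:
                        p *= Ps[id(n)][ps, st[id(n)]]
                acc += p
            site += acc / len(calc.rates)
        total += np.log(site)
    return total


@pytest.fixture(scope="module")
def toy_model():
    return GTRModel(rates=(1.2, 2.0, 0.8, 1.1, 2.4, 1.0),
                    freqs=(0.3, 0.2, 0.25, 0.25), alpha=0.7, ncat=4)


@pytest.fixture(scope="module")
def toy_aln():
    rng = np.random.default_rng(17)
    mat = rng.integers(0, 4, (4, 20)).astype(np.uint8)
    mat[2, 5] = 4  # one ambiguous cell
    return SupermatrixAlignment(list("abcd"), mat, np.arange(1, 21))


class TestLikelihood:
    def test_identical_sequences_zero_branches(self):
        mat = np.array([[0, 1, 2, 3, 0, 1]] * 2, dtype=np.uint8)
        aln = SupermatrixAlignment(["a", "b"], mat, np.arange(1, 7))
        ll, site = gtr_gamma_loglik(Tree.from_newick("(a:0.0,b:0.0);"),
                                    aln, GTRModel())
        assert ll == pytest.approx(6 * np.log(0.25), abs=1e-9)
        assert site.sum() == pytest.approx(ll, abs=1e-9)

    def test_four_taxon_matches_brute_force(self, toy_model, toy_aln):
        tree = Tree.from_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.05);")
        ll, site = gtr_gamma_loglik(tree, toy_aln, toy_model)
        assert ll == pytest.approx(brute_force_loglik(tree, toy_aln, toy_model),
                                   abs=1e-8)
        assert site.sum() == pytest.approx(ll, abs=1e-6)

    def test_two_taxon_closed_form(self):
        d = 0.37
        rng = np.random.default_rng(23)
        model = GTRModel()
        calc = TransitionCalculator(model)
        a = rng.integers(0, 4, 1500).astype(np.uint8)
        P = calc.probs_single(d)
        b = np.array([rng.choice(4, p=P[x]) for x in a], dtype=np.uint8)
        aln = SupermatrixAlignment(["a", "b"], np.stack([a, b]), np.arange(1, 1501))
        ll, _ = gtr_gamma_loglik(Tree.from_newick(f"(a:{d},b:0.0);"), aln, model)
        n_match = int((a == b).sum())
        p_match = 0.25 + 0.75 * np.exp(-4 * d / 3)
        expected = (n_match * np.log(0.25 * p_match)
                    + (1500 - n_match) * np.log(0.25 * (1 - p_match) / 3))
        assert ll == pytest.approx(expected, abs=1e-7)

    def test_rerooting_invariance(self, toy_model, toy_aln):
        tree = Tree.from_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.05);")
        ll0, _ = gtr_gamma_loglik(tree, toy_aln, toy_model)
        for outgroup in "abcd":
            rerooted = tree.root_with_outgroup(outgroup)
            ll, _ = gtr_gamma_loglik(rerooted, toy_aln, toy_model)
            assert ll == pytest.approx(ll0, abs=1e-8)

    def test_large_alpha_equals_rate_homogeneous(self, toy_aln):
        tree = Tree.from_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.05);")
        base = GTRModel(freqs=(0.3, 0.2, 0.25, 0.25))
        hom, _ = gtr_gamma_loglik(tree, toy_aln, base)
        gam, _ = gtr_gamma_loglik(tree, toy_aln, base.with_alpha(1e7))
        assert gam == pytest.approx(hom, abs=1e-6)

    def test_branch_optimization_monotone(self, toy_model, toy_aln):
        tree = Tree.from_newick("((a:0.5,b:0.01):0.4,c:0.02,d:0.9);")
        tl = TreeLikelihood.from_alignment(tree, toy_aln, toy_model)
        before = tl.loglik()
        after = tl.optimize_branch_lengths(2)
        assert after >= before - 1e-9


class TestConsensus:
    def test_majority_tie_and_coverage(self):
        reads = [
            SegmentRead(1, np.array([0, 0, 0, 2], dtype=np.uint8)),
            SegmentRead(1, np.array([0, 0, 2, 3], dtype=np.uint8)),
            SegmentRead(1, np.array([0, 1, 0, 2], dtype=np.uint8)),
            SegmentRead(1, np.array([1, 1, 1, 1], dtype=np.uint8)),  # no marker allele
        ]
        # marker: position 1, alt base A (code 0)
        cons = build_lg_consensus([(1, 0)], reads, 6)
        assert cons[0] == 0          # majority A among assigned reads
        assert cons[1] == 0          # 2 A vs 1 C
        assert cons[2] == 0          # 2 A vs 1 G
        assert cons[3] == 2          # position 4: G, G, T -> G
        assert cons[4] == 4 and cons[5] == 4  # uncovered -> N

    def test_tie_gives_ambiguous(self):
        reads = [
            SegmentRead(1, np.array([0, 0], dtype=np.uint8)),
            SegmentRead(1, np.array([0, 2], dtype=np.uint8)),
        ]
        cons = build_lg_consensus([(1, 0)], reads, 2)
        assert cons[1] == 4  # 1 A vs 1 G

    def test_no_assigned_reads_all_missing(self):
        reads = [SegmentRead(1, np.array([1, 1], dtype=np.uint8))]
        cons = build_lg_consensus([(1, 0)], reads, 2)
        assert (cons == 4).all()


class TestSupermatrix:
    def test_identical_taxa_no_pis(self):
        row = np.zeros(100, dtype=np.uint8)
        aln = build_supermatrix({"lg1": row.copy()}, {"d1": row.copy(),
                                                      "d2": row.copy()})
        assert aln.n_columns == 100
        assert aln.pis_count() == 0

    def test_aatt_column_is_pis(self):
        mat = np.zeros((4, 10), dtype=np.uint8)
        mat[2:, 0] = 3
        aln = SupermatrixAlignment(list("abcd"), mat, np.arange(1, 11))
        assert aln.pis_count() == 1

    def test_column_union_matches_set_oracle(self, rng):
        L = 400
        lg = {}
        covered = {}
        for k in range(3):
            row = np.full(L, 4, dtype=np.uint8)
            idx = rng.choice(L, 150, replace=False)
            row[idx] = rng.integers(0, 4, 150)
            lg[f"lg{k}"] = row
            covered[f"lg{k}"] = set(np.nonzero(row < 4)[0])
        dip = {"d": rng.integers(0, 4, L).astype(np.uint8)}
        aln = build_supermatrix(lg, dip)
        assert aln.n_columns == len(set.union(*covered.values()))

    def test_fasta_round_trip(self, tmp_path, rng):
        mat = rng.integers(0, 5, (3, 50)).astype(np.uint8)
        aln = SupermatrixAlignment(["x", "y", "z"], mat, np.arange(1, 51))
        aln.to_fasta(tmp_path / "aln.fasta")
        back = SupermatrixAlignment.from_fasta(tmp_path / "aln.fasta")
        assert back.labels == aln.labels
        assert np.array_equal(back.matrix, aln.matrix)


@pytest.fixture(scope="module")
def six_taxon():
    nwk = "((a:0.05,b:0.05):0.03,(c:0.04,d:0.06):0.02,(e:0.07,f:0.03):0.01);"
    seqs = simulate.simulate_progenitor_sequences(nwk, 6000, GTRModel(), seed=5)
    labels = sorted(seqs)
    mat = np.stack([seqs[l] for l in labels])
    return SupermatrixAlignment(labels, mat, np.arange(1, 6001)), {
        frozenset("ab"), frozenset("cd"), frozenset("ef")}


class TestSearch:
    def test_three_taxa_single_topology(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 4, (3, 300)).astype(np.uint8)
        aln = SupermatrixAlignment(list("abc"), mat, np.arange(1, 301))
        res = search_ml_tree(aln, model=GTRModel(), estimate_model=False)
        assert sorted(res.tree.taxa()) == list("abc")
        assert np.isfinite(res.loglik)

    def test_true_topology_recovered(self, six_taxon):
        aln, truth = six_taxon
        res = search_ml_tree(aln, seed=1)
        assert res.tree.bipartitions() == truth

    def test_matches_exhaustive_oracle(self, six_taxon):
        aln, _ = six_taxon
        sub = aln.subset(["a", "b", "c", "d", "e"])
        model = GTRModel(alpha=1.0)
        nni = search_ml_tree(sub, model=model)
        exact = exhaustive_search(sub, model)
        assert nni.tree.bipartitions() == exact.tree.bipartitions()
        assert nni.loglik == pytest.approx(exact.loglik, abs=0.2)

    def test_constrained_search_respects_constraint(self, six_taxon):
        aln, _ = six_taxon
        constraint = [frozenset(["a", "c"]), frozenset(["b", "d"])]
        res = search_ml_tree(aln, model=GTRModel(alpha=1.0),
                             constraint=constraint)
        assert res.tree.is_compatible(constraint)
        free = search_ml_tree(aln, model=GTRModel(alpha=1.0))
        assert res.loglik <= free.loglik + 1e-6

    def test_bootstrap_saturated_signal(self, six_taxon):
        aln, truth = six_taxon
        res = search_ml_tree(aln, model=GTRModel(alpha=1.0))
        res = bootstrap_support(aln, n_reps=20, seed=3, result=res,
                                model=GTRModel(alpha=1.0))
        supports = [n.support for n in res.tree.postorder()
                    if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_bootstrap_zero_reps_unannotated(self, six_taxon):
        aln, _ = six_taxon
        res = search_ml_tree(aln, model=GTRModel(alpha=1.0))
        res = bootstrap_support(aln, n_reps=0, result=res)
        assert all(n.support is None for n in res.tree.postorder())


class TestRooting:
    def test_three_taxon_rooting(self):
        t = Tree.from_newick("(A:1,B:1,O:2);")
        rooted = root_with_outgroup(t, "O")
        kids = rooted.root.children
        names = sorted(c.name or "internal" for c in kids)
        assert "O" in names

    def test_round_trip_preserves_bipartitions(self):
        t = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1,(e:1,o:1):1);")
        before = t.bipartitions()
        rooted = root_with_outgroup(t, "o")
        rooted.unroot()
        assert rooted.bipartitions() == before

    def test_missing_outgroup_raises(self):
        t = Tree.from_newick("(a:1,b:1,c:1);")
        with pytest.raises(KeyError):
            root_with_outgroup(t, "zzz")
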