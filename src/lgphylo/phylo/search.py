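"""Maximum-likelihood tree search: NJ start, NNI hill-climbing, optional
monophyly constraints, nonparametric bootstrap, and an exhaustive-search
oracle for small taxon sets.

NNI rearrangements are scored locally from cached directional partials (all
three arrangements around an edge share the same outside terms, so their
score differences equal full log-likelihood differences at fixed branch
lengths, with the focal branch re-optimised per candidate).  The accepted
move therefore never decreases the likelihood.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from ..models import GTRModel
from .likelihood import (MAX_BRANCH, MIN_BRANCH, TreeLikelihood,
                         compress_patterns, empirical_frequencies, fit_model)
from .tree import Node, Tree

MAX_JC_P = 0.70


# --------------------------------------------------------------------------
# distances and starting trees
# --------------------------------------------------------------------------


def jc_distance_matrix(patterns: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Pairwise-deletion Jukes-Cantor distances from compressed patterns."""
    n = patterns.shape[0]
    D = np.zeros((n, n))
    known = patterns < 4
    for i in range(n):
        for j in range(i + 1, n):
            ok = known[i] & known[j]
            tot = counts[ok].sum()
            if tot == 0:
                p = MAX_JC_P
            else:
                p = counts[ok & (patterns[i] != patterns[j])].sum() / tot
            p = min(p, MAX_JC_P)
            D[i, j] = D[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return D


def nj_tree(D: np.ndarray, labels: list[str]) -> Tree:
    """Neighbor-joining start tree (scikit-bio), negative lengths clamped."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    sk = _nj(DistanceMatrix(D, ids=labels))
    buf = io.StringIO()
    sk.write(buf)
    t = Tree.from_newick(buf.getvalue())
    for n in t.postorder():
        if n.parent is not None:
            n.length = max(n.length, MIN_BRANCH)
    t.unroot()
    return t


def _upgma_join(items: list[tuple[Node, frozenset]], D: np.ndarray,
                index: dict[str, int]) -> Node:
    """Average-linkage join of already-built subtrees into one binary node."""
    if len(items) == 1:
        return items[0][0]
    k = len(items)
    M = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            ia = [index[t] for t in items[a][1]]
            ib = [index[t] for t in items[b][1]]
            M[a, b] = M[b, a] = D[np.ix_(ia, ib)].mean()
    Z = linkage(squareform(M, checks=False), method="average")
    nodes = [it[0] for it in items]
    heights = [0.0] * k
    for row in Z:
        a, b, h = int(row[0]), int(row[1]), row[2] / 2.0
        parent = Node(None, 0.0)
        for child_idx in (a, b):
            child = nodes[child_idx]
            child.length = max(h - heights[child_idx], MIN_BRANCH)
            parent.add(child)
        nodes.append(parent)
        heights.append(h)
    return nodes[-1]


def constrained_start_tree(D: np.ndarray, labels: list[str],
                           clades: list[frozenset]) -> Tree:
    """Binary starting tree compatible with nested monophyly constraints."""
    index = {l: i for i, l in enumerate(labels)}
    all_taxa = frozenset(labels)
    clades = [frozenset(c) for c in clades if 1 < len(frozenset(c))]

    def build(taxa: frozenset) -> Node:
        inside = [c for c in clades if c < taxa]
        top = [c for c in inside if not any(c < o for o in inside)]
        covered = frozenset().union(*top) if top else frozenset()
        items = [(build(c), c) for c in top]
        items += [(Node(t, 0.0), frozenset([t])) for t in sorted(taxa - covered)]
        return _upgma_join(items, D, index)

    for c in clades:
        if not c <= all_taxa:
            raise ValueError(f"constraint clade {sorted(c)} has unknown taxa")
    root = build(all_taxa)
    t = Tree(root)
    t.unroot()
    return t


# --------------------------------------------------------------------------
# NNI search
# --------------------------------------------------------------------------


def _opt_edge(tl: TreeLikelihood, A, upv, t0: float):
    """(best t, best score) for an edge given outside/inside partials."""
    def neg(t):
        return -tl._edge_loglik(-1, t, A=A, upv=upv)

    res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
                          options={"xatol": 1e-4, "maxiter": 14})
    return float(res.x), -float(res.fun)


def _nni_round(tl: TreeLikelihood, required: set[frozenset] | None,
               eps: float = 1e-4):
    """Best-improvement NNI pass; applies the best move in place.

    Returns the (local) log-likelihood gain, or None when no move improves.
    """
    tl._ensure(outside=True)
    nodes = tl.nodes
    idx = tl._node_index
    leafsets = tl.tree.leaf_sets() if required else None
    all_taxa = frozenset(tl.tree.taxa()) if required else None

    best = None  # (gain, v, b, c, new_t)
    for vi, v in enumerate(nodes):
        if v.parent is None or v.is_leaf or len(v.children) != 2:
            continue
        u = v.parent
        sibs = [c for c in u.children if c is not v]
        if not sibs:
            continue
        if required is not None:
            s = leafsets[vi]
            if s in required or (all_taxa - s) in required:
                continue  # this edge realises a required clade
        b = sibs[0]
        bi = idx[id(b)]
        A_minus = tl.O[idx[id(u)]].copy()
        for s in u.children:
            if s is not v and s is not b:
                A_minus *= tl.prop[idx[id(s)]]
        c1, c2 = v.children
        p_b, p_c1, p_c2 = (tl.prop[bi], tl.prop[idx[id(c1)]], tl.prop[idx[id(c2)]])
        base = tl._edge_loglik(-1, tl.lengths[vi], A=A_minus * p_b, upv=p_c1 * p_c2)
        for c_node, p_move, p_stay in ((c1, p_c1, p_c2), (c2, p_c2, p_c1)):
            t_new, score = _opt_edge(tl, A_minus * p_move, p_b * p_stay,
                                     tl.lengths[vi])
            gain = score - base
            if gain > eps and (best is None or gain > best[0]):
                best = (gain, v, b, c_node, t_new)
    if best is None:
        return None
    gain, v, b, c, t_new = best
    u = v.parent
    u.children[u.children.index(b)] = c
    c.parent = u
    v.children[v.children.index(c)] = b
    b.parent = v
    v.length = t_new
    tl._index_tree()
    return gain


@dataclass
class SearchResult:
    tree: Tree
    loglik: float
    model: GTRModel
    tl: TreeLikelihood


def search_ml_tree_core(
    patterns: np.ndarray,
    counts: np.ndarray,
    labels: list[str],
    model: GTRModel,
    constraint: list[frozenset] | None = None,
    start: Tree | None = None,
    max_rounds: int = 50,
    bl_sweeps: int = 2,
    inverse: np.ndarray | None = None,
) -> SearchResult:
    if len(labels) < 3:
        raise ValueError("tree search needs at least 3 taxa")
    required = None
    if constraint:
        required = {frozenset(c) for c in constraint if 1 < len(frozenset(c)) < len(labels)}
    if start is None or (required and not start.is_compatible(required)):
        D = jc_distance_matrix(patterns, counts)
        start = (constrained_start_tree(D, labels, list(required))
                 if required else nj_tree(D, labels))
    tree = start.copy()
    rows = {l: i for i, l in enumerate(labels)}
    tl = TreeLikelihood(tree, patterns, counts, rows, model, inverse=inverse)
    tl.optimize_branch_lengths(bl_sweeps)
    for _ in range(max_rounds):
        gain = _nni_round(tl, required)
        if gain is None:
            break
        tl.optimize_branch_lengths(1)
    tl.optimize_branch_lengths(1)
    return SearchResult(tl.tree, tl.loglik(), model, tl)


def search_ml_tree(
    aln,
    model: GTRModel | None = None,
    constraint: list[frozenset] | None = None,
    seed: int = 0,
    start: Tree | None = None,
    estimate_model: bool = True,
    optimize_rates: bool = True,
    **kwargs,
) -> SearchResult:
    """ML tree for a supermatrix under GTR+Gamma, optionally constrained.

    When ``model`` is None the base frequencies are taken from the alignment
    and the gamma shape (plus exchangeabilities) are estimated on the start
    tree before the topology search.
    """
    patterns, counts, inverse = compress_patterns(aln.matrix)
    if model is None:
        freqs = empirical_frequencies(aln.matrix)
        model = GTRModel(freqs=freqs, alpha=1.0)
        D = jc_distance_matrix(patterns, counts)
        start0 = start or nj_tree(D, list(aln.labels))
        rows = {l: i for i, l in enumerate(aln.labels)}
        tl0 = TreeLikelihood(start0.copy(), patterns, counts, rows, model)
        model = fit_model(start0, tl0, optimize_rates=optimize_rates)
    return search_ml_tree_core(patterns, counts, list(aln.labels), model,
                               constraint=constraint, start=start,
                               inverse=inverse, **kwargs)


# --------------------------------------------------------------------------
# exhaustive oracle (small taxon sets)
# --------------------------------------------------------------------------


def _all_topologies(taxa: list[str]):
    if len(taxa) > 8:
        raise ValueError("exhaustive search is limited to 8 taxa")
    base = Tree(Node(None))
    for t in taxa[:3]:
        base.root.add(Node(t, 0.05))

    def insert_all(tree: Tree, name: str):
        out = []
        n_edges = sum(1 for n in tree.postorder() if n.parent is not None)
        for k in range(n_edges):
            t2 = tree.copy()
            edges = [n for n in t2.postorder() if n.parent is not None]
            v = edges[k]
            u = v.parent
            mid = Node(None, v.length / 2)
            v.length = v.length / 2
            u.children[u.children.index(v)] = mid
            mid.parent = u
            mid.add(v)
            mid.add(Node(name, 0.05))
            out.append(t2)
        return out

    trees = [base]
    for name in taxa[3:]:
        trees = [t2 for t in trees for t2 in insert_all(t, name)]
    return trees


def exhaustive_search(aln, model: GTRModel, bl_sweeps: int = 2) -> SearchResult:
    """Optimise every unrooted topology; the reference oracle for <= 8 taxa."""
    patterns, counts, inverse = compress_patterns(aln.matrix)
    rows = {l: i for i, l in enumerate(aln.labels)}
    best = None
    for t in _all_topologies(list(aln.labels)):
        tl = TreeLikelihood(t, patterns, counts, rows, model, inverse=inverse)
        ll = tl.optimize_branch_lengths(bl_sweeps)
        if best is None or ll > best.loglik:
            best = SearchResult(tl.tree, ll, model, tl)
    return best


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------


def bootstrap_support(aln, model: GTRModel | None = None, n_reps: int = 100,
                      seed: int = 0, result: SearchResult | None = None,
                      **search_opts) -> SearchResult:
    """Column-resampling bootstrap; supports (%) annotated on the ML tree."""
    if result is None:
        result = search_ml_tree(aln, model=model, seed=seed, **search_opts)
    if n_reps == 0:
        return result
    model = result.model
    patterns, counts, _ = compress_patterns(aln.matrix)
    n = counts.sum()
    bipart_hits: dict[frozenset, int] = {}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        counts_b = rng.multinomial(int(n), counts / n).astype(float)
        keep = counts_b > 0
        res_b = search_ml_tree_core(patterns[:, keep], counts_b[keep],
                                    list(aln.labels), model, **search_opts)
        for bp in res_b.tree.bipartitions():
            bipart_hits[bp] = bipart_hits.get(bp, 0) + 1
    all_taxa = frozenset(aln.labels)
    tree = result.tree
    sets = tree.leaf_sets()
    nodes = tree.postorder()
    for i, node in enumerate(nodes):
        s = sets[i]
        if node.is_leaf or node.parent is None or not (1 < len(s) < len(all_taxa) - 1):
            continue
        key = min((s, all_taxa - s), key=lambda x: (len(x), sorted(x)))
        node.support = 100.0 * bipart_hits.get(key, 0) / n_reps
    return result


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root on the outgroup's pendant edge; raises if the taxon is absent."""
    return tree.root_with_outgroup(outgroup)
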