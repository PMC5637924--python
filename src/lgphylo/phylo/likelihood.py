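"""GTR+Gamma pruning likelihood with pattern compression and rescaling.

Likelihoods are computed by Felsenstein's pruning algorithm over site
patterns, with equal-weight discrete-gamma rate categories and per-pattern
numerical rescaling.  Ambiguous characters (N, gaps) are fully ambiguous.
Directional ("outside") partials support fast per-edge branch-length
optimisation and local rescoring of NNI rearrangements.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ..models import GTRModel, TransitionCalculator
from .tree import Tree

MIN_BRANCH = 1e-9
MAX_BRANCH = 10.0
_RESCALE_THRESHOLD = 1e-140


def compress_patterns(matrix: np.ndarray):
    """(n_taxa, n_cols) -> (patterns (n_taxa, n_pat), counts, inverse)."""
    cols = np.ascontiguousarray(matrix.T)
    uniq, inverse, counts = np.unique(cols, axis=0, return_inverse=True,
                                      return_counts=True)
    return uniq.T, counts.astype(np.float64), inverse


def empirical_frequencies(matrix: np.ndarray, pseudocount: float = 1.0) -> tuple:
    counts = np.array([(matrix == b).sum() for b in range(4)], dtype=float)
    counts += pseudocount
    return tuple(counts / counts.sum())


class TreeLikelihood:
    """Likelihood of one alignment under one tree and GTR(+gamma) model."""

    def __init__(self, tree: Tree, patterns: np.ndarray, counts: np.ndarray,
                 taxon_rows: dict[str, int], model: GTRModel,
                 inverse: np.ndarray | None = None):
        missing = [l for l in (n.name for n in tree.leaves()) if l not in taxon_rows]
        if missing:
            raise ValueError(f"tree taxa absent from alignment: {missing}")
        self.tree = tree
        self.patterns = patterns
        self.counts = counts
        self.inverse = inverse
        self.taxon_rows = taxon_rows
        self.set_model(model)
        self._index_tree()

    # -- setup -------------------------------------------------------------

    @classmethod
    def from_alignment(cls, tree: Tree, aln, model: GTRModel) -> "TreeLikelihood":
        patterns, counts, inverse = compress_patterns(aln.matrix)
        rows = {l: i for i, l in enumerate(aln.labels)}
        return cls(tree, patterns, counts, rows, model, inverse)

    def set_model(self, model: GTRModel):
        self.model = model
        self.calc = TransitionCalculator(model)
        self.pi = np.asarray(model.freqs)
        self._dirty = True
        self._outside_dirty = True

    def set_tree(self, tree: Tree):
        self.tree = tree
        self._index_tree()
        self._dirty = True

    def _index_tree(self):
        self.nodes = self.tree.postorder()
        self._node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self.lengths = np.array(
            [max(n.length, 0.0) if n.parent is not None else 0.0
             for n in self.nodes]
        )
        npat = self.patterns.shape[1]
        self._tips = {}
        for n in self.nodes:
            if n.is_leaf:
                row = self.patterns[self.taxon_rows[n.name]]
                tip = np.zeros((npat, 4))
                known = row < 4
                tip[known, row[known]] = 1.0
                tip[~known, :] = 1.0
                self._tips[id(n)] = tip
        self._dirty = True
        self._outside_dirty = True

    # -- core passes ---------------------------------------------------------

    def _compute(self):
        ncat = len(self.calc.rates)
        npat = self.patterns.shape[1]
        n = len(self.nodes)
        self.P = np.empty((n, ncat, 4, 4))
        for i, node in enumerate(self.nodes):
            if node.parent is not None:
                self.P[i] = self.calc.probs(self.lengths[i])
        up = np.empty((n, ncat, npat, 4))
        prop = np.empty((n, ncat, npat, 4))  # up propagated across own edge
        logscale = np.zeros((n, npat))
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                up[i] = self._tips[id(node)][None, :, :]
            else:
                acc = None
                ls = np.zeros(npat)
                for c in node.children:
                    ci = self._node_index[id(c)]
                    acc = prop[ci] if acc is None else acc * prop[ci]
                    ls += logscale[ci]
                m = acc.max(axis=(0, 2))
                if m.min() < _RESCALE_THRESHOLD:
                    factor = np.where(m > 0, m, 1.0)
                    acc = acc / factor[None, :, None]
                    ls = ls + np.log(factor)
                up[i] = acc
                logscale[i] = ls
            if node.parent is not None:
                prop[i] = np.matmul(up[i], self.P[i].swapaxes(1, 2))
        self.up, self.prop, self.logscale = up, prop, logscale
        self._dirty = False
        self._outside_dirty = True

    def _compute_outside(self):
        """Directional (outside) partials; needed for per-edge optimisation."""
        up, prop = self.up, self.prop
        O = np.empty_like(up)
        A = np.empty_like(up)
        ri = self._node_index[id(self.tree.root)]
        O[ri] = 1.0
        for node in self.tree.preorder():
            ui = self._node_index[id(node)]
            if node.is_leaf:
                continue
            kids = [self._node_index[id(c)] for c in node.children]
            for v in kids:
                acc = O[ui].copy()
                for s in kids:
                    if s != v:
                        acc *= prop[s]
                m = acc.max(axis=(0, 2))
                if m.min() < _RESCALE_THRESHOLD:
                    acc = acc / np.where(m > 0, m, 1.0)[None, :, None]
                A[v] = acc
                O[v] = np.matmul(acc, self.P[v].swapaxes(1, 2))
        self.O, self.A = O, A
        self._outside_dirty = False

    def _ensure(self, outside: bool = False):
        if self._dirty:
            self._compute()
        if outside and self._outside_dirty:
            self._compute_outside()

    # -- likelihood ----------------------------------------------------------

    def _pattern_loglik(self) -> np.ndarray:
        self._ensure()
        ri = self._node_index[id(self.tree.root)]
        per_cat = np.einsum("cpi,i->cp", self.up[ri], self.pi)
        Lp = self.calc.weights @ per_cat
        return np.log(np.clip(Lp, 1e-300, None)) + self.logscale[ri]

    def loglik(self) -> float:
        return float(self.counts @ self._pattern_loglik())

    def site_loglik(self) -> np.ndarray:
        """Per-column log-likelihood (expanded from patterns)."""
        pat = self._pattern_loglik()
        if self.inverse is None:
            return pat
        return pat[self.inverse]

    # -- branch-length optimisation -------------------------------------------

    def _edge_loglik(self, vi: int, t: float, A=None, upv=None) -> float:
        """Log-likelihood as a function of edge vi's length (scale-consistent
        with the cached pass; comparable across calls on the same cache)."""
        P = self.calc.probs(max(t, MIN_BRANCH))
        A = self.A[vi] if A is None else A
        upv = self.up[vi] if upv is None else upv
        propv = np.matmul(upv, P.swapaxes(1, 2))
        per_cat = np.einsum("cpi,cpi,i->cp", A, propv, self.pi)
        Lp = self.calc.weights @ per_cat
        return float(self.counts @ np.log(np.clip(Lp, 1e-300, None)))

    def optimize_branch_lengths(self, max_sweeps: int = 3, xatol: float = 1e-5):
        for _ in range(max_sweeps):
            self._ensure(outside=True)
            for vi, node in enumerate(self.nodes):
                if node.parent is None:
                    continue
                res = minimize_scalar(
                    lambda t: -self._edge_loglik(vi, t),
                    bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
                    options={"xatol": xatol, "maxiter": 24},
                )
                self.lengths[vi] = float(res.x)
                node.length = float(res.x)
            self._dirty = True
        return self.loglik()


def gtr_gamma_loglik(tree: Tree, aln, model: GTRModel):
    """Total and per-column log-likelihood of an alignment on a tree."""
    tl = TreeLikelihood.from_alignment(tree, aln, model)
    return tl.loglik(), tl.site_loglik()


def fit_model(
    tree: Tree,
    tl: TreeLikelihood,
    optimize_alpha: bool = True,
    optimize_rates: bool = True,
    alpha0: float = 1.0,
    maxiter: int = 80,
) -> GTRModel:
    """Estimate gamma shape and GTR exchangeabilities on a fixed tree.

    Branch lengths are optimised before and after; frequencies stay at their
    (empirical) values in the current model.  GT exchangeability is fixed at 1.
    """
    tl.optimize_branch_lengths(2)
    base = tl.model
    n_rate = 5 if optimize_rates else 0
    x0 = []
    if optimize_alpha:
        x0.append(np.log(base.alpha if base.alpha else alpha0))
    x0.extend([np.log(r / base.rates[5]) for r in base.rates[:5]] if optimize_rates else [])
    if not x0:
        return base

    def build(x):
        k = 0
        alpha = base.alpha
        if optimize_alpha:
            alpha = float(np.clip(np.exp(x[0]), 0.02, 100.0))
            k = 1
        rates = base.rates
        if optimize_rates:
            rr = np.clip(np.exp(x[k : k + 5]), 1e-4, 1e4)
            rates = tuple(rr) + (1.0,)
        return GTRModel(rates=rates, freqs=base.freqs, alpha=alpha, ncat=base.ncat)

    def neg(x):
        tl.set_model(build(x))
        return -tl.loglik()

    res = minimize(neg, np.array(x0), method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 0.02, "fatol": 0.2})
    best = build(res.x)
    tl.set_model(best)
    tl.optimize_branch_lengths(2)
    return best
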