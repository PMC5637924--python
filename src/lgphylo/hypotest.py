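"""Origin hypotheses as constraint topologies, with SH and AU tests.

An origin hypothesis states how many of the focal polyploid's linkage-group
taxa belong to each subgenome clade, e.g. the contemporary-origin hypothesis
H1 is (4,Av),((2,Bi),(2,B1),(2,B2)) for a decaploid: four LGs in the Av clade
and two in each B clade, with the B clades jointly monophyletic.  Homologous
maternal/paternal LGs move between clades together.  For every admissible
assignment of LG pairs to clades, the best constrained ML tree is found; the
hypothesis's test tree is the best over assignments.  Constrained trees are
compared to the unconstrained ML tree with the Shimodaira-Hasegawa test
(RELL resampling, centred replicates) and the approximately unbiased test
(multiscale RELL bootstrap with a signed-distance/curvature fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .phylo.likelihood import compress_patterns, empirical_frequencies, fit_model, TreeLikelihood
from .phylo.search import (jc_distance_matrix, nj_tree,
                           search_ml_tree_core, SearchResult)
from .phylo.tree import Tree
from .models import GTRModel

#: Hypothesis definitions in LG-count units for a decaploid (10 focal LGs).
#: ``free`` is the size of an extra clade of unassigned LGs (cryptic subgenome).
DEFAULT_HYPOTHESES = {
    "H1": {"Av": 4, "Bi": 2, "B1": 2, "B2": 2, "free": 0},
    "H2.A": {"Av": 2, "Bi": 4, "B1": 2, "B2": 2, "free": 0},
    "H2.B": {"Av": 2, "Bi": 2, "B1": 4, "B2": 2, "free": 0},
    "H2.C": {"Av": 2, "Bi": 2, "B1": 2, "B2": 4, "free": 0},
    "H3": {"Av": 2, "Bi": 2, "B1": 2, "B2": 2, "free": 2},
}

FREE_CLADE = "U"
B_CLADES = ("Bi", "B1", "B2")


@dataclass(frozen=True)
class HypothesisSpec:
    label: str
    counts: dict           # clade label -> required number of focal LG taxa
    free_clade_count: int = 0
    clade_anchors: dict = field(default_factory=dict)  # clade -> fixed taxa

    def total_lgs(self) -> int:
        return sum(self.counts.values()) + self.free_clade_count

    @classmethod
    def from_config(cls, label: str, cfg: dict, anchors: dict) -> "HypothesisSpec":
        counts = {k: v for k, v in cfg.items() if k != "free"}
        return cls(label, counts, int(cfg.get("free", 0)), dict(anchors))


@dataclass
class ConstraintBackbone:
    hypothesis: str
    assignment_id: int
    assignment: dict       # unit id (pair or single LG) -> clade label
    clades: dict           # clade label -> frozenset of taxa (anchors + LGs)

    def required_clades(self) -> list[frozenset]:
        named = {k: set(v) for k, v in self.clades.items()}
        out = [frozenset(v) for v in named.values() if len(v) > 1]
        b_super = set().union(*(named.get(b, set()) for b in B_CLADES))
        if len(b_super) > 1:
            out.append(frozenset(b_super))
        return out


def _units(lg_pairs: dict[str, str | None]) -> list[tuple[str, tuple[str, ...]]]:
    """Assignment units: homolog pairs move together, unpaired LGs singly."""
    units = []
    used = set()
    for m, p in sorted(lg_pairs.items()):
        if p is None:
            units.append((m, (m,)))
        else:
            units.append((f"{m}|{p}", (m, p)))
            used.add(p)
    return units


def _assignments(units, clade_lg_counts: dict[str, int]):
    """All distinct unit->clade assignments meeting the LG-count targets."""
    clades = sorted(clade_lg_counts)
    sizes = [len(t) for _, t in units]

    def rec(k, remaining):
        if k == len(units):
            if all(v == 0 for v in remaining.values()):
                yield ()
            return
        for c in clades:
            if remaining[c] >= sizes[k]:
                remaining[c] -= sizes[k]
                for rest in rec(k + 1, remaining):
                    yield (c,) + rest
                remaining[c] += sizes[k]

    return list(rec(0, dict(clade_lg_counts)))


def enumerate_constraints(
    hyp: HypothesisSpec,
    lg_pairs: dict[str, str | None],
    mode: str = "minimal",
    cap: int = 6,
    reference_tree: Tree | None = None,
) -> list[ConstraintBackbone]:
    """Enumerate pair->clade assignments satisfying a hypothesis.

    ``exhaustive`` yields every admissible assignment; ``minimal`` ranks them
    by disagreement with the focal LGs' placements in ``reference_tree``
    (fewest moved units first) and keeps at most ``cap``.
    """
    units = _units(lg_pairs)
    n_lgs = sum(len(t) for _, t in units)
    targets = dict(hyp.counts)
    if hyp.free_clade_count:
        targets[FREE_CLADE] = hyp.free_clade_count
    if sum(targets.values()) != n_lgs:
        raise ValueError(
            f"{hyp.label}: clade counts ({sum(targets.values())}) do not match "
            f"the {n_lgs} focal LG taxa"
        )
    assigns = _assignments(units, targets)
    if not assigns:
        raise ValueError(f"{hyp.label}: counts not satisfiable with the available "
                         f"homolog pairs (units of sizes {[len(t) for _, t in units]})")

    if mode == "minimal":
        cost = _assignment_cost_fn(units, hyp.clade_anchors, reference_tree)
        assigns = sorted(assigns, key=lambda a: (cost(a), a))[:cap]
    elif mode != "exhaustive":
        raise ValueError(f"unknown enumeration mode {mode!r}")

    backbones = []
    for k, a in enumerate(assigns):
        clades = {c: set(hyp.clade_anchors.get(c, ())) for c in targets}
        for (uid, taxa), c in zip(units, a):
            clades[c].update(taxa)
        backbones.append(
            ConstraintBackbone(
                hypothesis=hyp.label,
                assignment_id=k,
                assignment={uid: c for (uid, _), c in zip(units, a)},
                clades={c: frozenset(v) for c, v in clades.items()},
            )
        )
    return backbones


def _path_distances(tree: Tree) -> dict[tuple[str, str], int]:
    """Topological (edge-count) distances between all leaf pairs."""
    leaves = {n.name: n for n in tree.leaves()}

    def path_up(name):
        out, n = {}, leaves[name]
        d = 0
        while n is not None:
            out[id(n)] = d
            n = n.parent
            d += 1
        return out

    ups = {name: path_up(name) for name in leaves}
    dist = {}
    names = sorted(leaves)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            n, d = leaves[b], 0
            while id(n) not in ups[a]:
                n = n.parent
                d += 1
            dist[(a, b)] = dist[(b, a)] = d + ups[a][id(n)]
    return dist


def _assignment_cost_fn(units, anchors, tree: Tree | None):
    """Clustering cost of a unit->clade assignment under the reference tree.

    The cost sums, for each clade, the pairwise path distances among the LG
    taxa placed in it plus each member's distance to the clade anchors.
    Assignments agreeing with the reference tree's groupings are compact and
    rank first; with no reference tree all assignments tie.
    """
    if tree is None:
        return lambda a: 0
    dist = _path_distances(tree)
    leaf_set = {n.name for n in tree.leaves()}

    def d(a, b):
        return dist.get((a, b), 0)

    def cost(assignment):
        members: dict[str, list[str]] = {}
        for (uid, taxa), c in zip(units, assignment):
            members.setdefault(c, []).extend(t for t in taxa if t in leaf_set)
        total = 0.0
        for c, taxa in members.items():
            for i, a in enumerate(taxa):
                for b in taxa[i + 1:]:
                    total += d(a, b)
            for anc in anchors.get(c, ()):
                if anc in leaf_set:
                    total += sum(d(t, anc) for t in taxa)
        return total

    return cost


# --------------------------------------------------------------------------
# constrained search
# --------------------------------------------------------------------------


def best_constrained_tree(
    patterns, counts, labels, model: GTRModel,
    backbones: list[ConstraintBackbone],
    unconstrained: SearchResult | None = None,
    inverse=None,
    **search_opts,
):
    """Best constrained ML tree over backbones; ties break by assignment id."""
    if not backbones:
        raise ValueError("need at least one constraint backbone")
    best = None
    for bb in backbones:
        required = bb.required_clades()
        start = None
        if unconstrained is not None and unconstrained.tree.is_compatible(required):
            start = unconstrained.tree
        res = search_ml_tree_core(patterns, counts, labels, model,
                                  constraint=required, start=start,
                                  inverse=inverse, **search_opts)
        if best is None or res.loglik > best[0].loglik + 1e-9:
            best = (res, bb.assignment_id)
    return best


# --------------------------------------------------------------------------
# SH and AU tests
# --------------------------------------------------------------------------


def _resample_sums(site_lnl: np.ndarray, rng, n_resample: int, n_rell: int):
    """RELL replicate log-likelihood sums, shape (n_rell, n_trees).

    Sites are drawn uniformly with replacement (multinomial weights realised
    by bincounting uniform draws, which is much faster at genomic site
    counts).
    """
    n_sites = site_lnl.shape[1]
    lnl_T = np.ascontiguousarray(site_lnl.T)
    sums = np.empty((n_rell, site_lnl.shape[0]))
    for b in range(n_rell):
        idx = rng.integers(0, n_sites, n_resample)
        w = np.bincount(idx, minlength=n_sites)
        sums[b] = w @ lnl_T
    return sums


def sh_test(site_lnl: np.ndarray, n_rell: int = 1000, seed: int = 0) -> np.ndarray:
    """Shimodaira-Hasegawa p-value per candidate tree.

    ``site_lnl`` is (n_trees, n_sites).  Replicate sums are centred per tree;
    the null distribution of max-t'(centred) - centred_t is compared to the
    observed log-likelihood deficit of each tree (one-sided).
    """
    site_lnl = np.asarray(site_lnl, dtype=float)
    if site_lnl.ndim != 2 or site_lnl.shape[0] < 2:
        raise ValueError("SH test needs >= 2 candidate trees")
    rng = np.random.default_rng(seed)
    totals = site_lnl.sum(axis=1)
    delta_obs = totals.max() - totals
    sums = _resample_sums(site_lnl, rng, site_lnl.shape[1], n_rell)
    centred = sums - sums.mean(axis=0, keepdims=True)
    null = centred.max(axis=1, keepdims=True) - centred
    return (null >= delta_obs[None, :] - 1e-12).mean(axis=0)


def _bp_winners(sums: np.ndarray, rng) -> np.ndarray:
    """Winner per replicate, ties broken by fair randomisation.

    The tie tolerance is relative: identical candidate trees produce
    replicate sums that differ by BLAS rounding (order ~1e-16 of the sum's
    magnitude), far below any real log-likelihood difference.
    """
    n_rell, n_trees = sums.shape
    mx = sums.max(axis=1, keepdims=True)
    tol = 1e-9 * np.abs(mx) + 1e-9
    is_max = sums >= mx - tol
    winners = sums.argmax(axis=1)
    multi = is_max.sum(axis=1) > 1
    for i in np.nonzero(multi)[0]:
        winners[i] = rng.choice(np.nonzero(is_max[i])[0])
    return winners


@dataclass
class AUResult:
    p_values: np.ndarray
    flags: list[str]
    bp: np.ndarray          # (n_scales, n_trees)
    scales: np.ndarray


def au_test(
    site_lnl: np.ndarray,
    scales: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
    n_rell: int = 10000,
    seed: int = 0,
) -> AUResult:
    """Approximately unbiased test via the multiscale RELL bootstrap.

    For each scale r the bootstrap proportion BP_t(r) of replicates won by
    tree t (resample size ceil(r*n)) is computed; z = Phi^-1(1 - BP) is fitted
    to d*sqrt(r) + c/sqrt(r) by weighted least squares and p = 1 - Phi(d - c).
    Degenerate BP (clamped at every scale) short-circuits to 0 or 1.
    """
    site_lnl = np.asarray(site_lnl, dtype=float)
    if site_lnl.ndim != 2 or site_lnl.shape[0] < 2:
        raise ValueError("AU test needs >= 2 candidate trees")
    if len(scales) < 2:
        raise ValueError("AU test needs >= 2 bootstrap scales")
    rng = np.random.default_rng(seed)
    n_trees, n_sites = site_lnl.shape
    scales = np.asarray(scales, dtype=float)
    bp = np.zeros((len(scales), n_trees))
    for si, r in enumerate(scales):
        m = max(int(np.ceil(r * n_sites)), 1)
        sums = _resample_sums(site_lnl, rng, m, n_rell)
        winners = _bp_winners(sums, rng)
        bp[si] = np.bincount(winners, minlength=n_trees) / n_rell

    lo, hi = 1.0 / (2 * n_rell), 1.0 - 1.0 / (2 * n_rell)
    bp_c = np.clip(bp, lo, hi)
    p_out = np.zeros(n_trees)
    flags = []
    for t in range(n_trees):
        if np.all(bp[:, t] <= lo):
            p_out[t] = 0.0
            flags.append("degenerate-low")
            continue
        if np.all(bp[:, t] >= hi):
            p_out[t] = 1.0
            flags.append("degenerate-high")
            continue
        z = norm.isf(bp_c[:, t])
        X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
        phi = norm.pdf(z)
        w = n_rell * phi**2 / (bp_c[:, t] * (1 - bp_c[:, t]))
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        d_hat, c_hat = beta
        p_out[t] = float(norm.sf(d_hat - c_hat))
        flags.append("ok")
    return AUResult(p_out, flags, bp, scales)


# --------------------------------------------------------------------------
# suite
# --------------------------------------------------------------------------


@dataclass
class TopologyTestResult:
    chromosome: str
    hypothesis: str
    delta_lnl: float
    au_p: float
    sh_p: float
    best_assignment: int
    unconstrained_lnl: float

    @property
    def sh_stars(self) -> str:
        return "**" if self.sh_p < 0.01 else "*" if self.sh_p < 0.05 else ""

    @property
    def rejected(self) -> bool:
        return self.au_p < 0.05 or self.sh_p < 0.05


def run_hypothesis_suite(
    aln,
    lg_pairs: dict[str, str | None],
    hypotheses: dict[str, dict] | None = None,
    clade_anchors: dict | None = None,
    seed: int = 0,
    mode: str = "minimal",
    cap: int = 6,
    n_rell_sh: int = 1000,
    n_rell_au: int = 10000,
    au_scales: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
    model: GTRModel | None = None,
    estimate_rates: bool = True,
    **search_opts,
) -> tuple[pd.DataFrame, dict]:
    """Test every hypothesis on one chromosome's supermatrix.

    Returns a per-hypothesis table (delta logL, AU p, SH p with significance
    stars) and a detail dict with the trees.  The unconstrained candidate pool
    is augmented with every constrained result, so delta logL >= 0 throughout.
    """
    from .simulate import DEFAULT_CLADE_ANCHORS

    hypotheses = hypotheses or DEFAULT_HYPOTHESES
    clade_anchors = clade_anchors or {k: tuple(v) for k, v in DEFAULT_CLADE_ANCHORS.items()}
    patterns, counts, inverse = compress_patterns(aln.matrix)
    labels = list(aln.labels)
    rows = {l: i for i, l in enumerate(labels)}

    if model is None:
        freqs = empirical_frequencies(aln.matrix)
        D = jc_distance_matrix(patterns, counts)
        start0 = nj_tree(D, labels)
        tl0 = TreeLikelihood(start0, patterns, counts, rows,
                             GTRModel(freqs=freqs, alpha=1.0))
        model = fit_model(start0, tl0, optimize_rates=estimate_rates)

    unconstrained = search_ml_tree_core(patterns, counts, labels, model,
                                        inverse=inverse, **search_opts)
    pool = [("unconstrained", unconstrained)]
    per_hyp = {}
    for label in sorted(hypotheses):
        hyp = HypothesisSpec.from_config(label, hypotheses[label], clade_anchors)
        backbones = enumerate_constraints(hyp, lg_pairs, mode=mode, cap=cap,
                                          reference_tree=unconstrained.tree)
        res, assignment_id = best_constrained_tree(
            patterns, counts, labels, model, backbones,
            unconstrained=unconstrained, inverse=inverse, **search_opts)
        per_hyp[label] = (res, assignment_id)
        pool.append((label, res))

    best_lnl = max(r.loglik for _, r in pool)
    best_res = max(pool, key=lambda kv: kv[1].loglik)[1]

    # candidates sharing a topology share one per-site vector: re-optimised
    # branch lengths of the same tree would otherwise create hair-thin
    # dominance between duplicates and distort the resampling tests
    candidates = [("ML", best_res)] + [(h, per_hyp[h][0]) for h in sorted(per_hyp)]
    topo_cache: dict[frozenset, np.ndarray] = {}
    vectors = []
    for _, r in candidates:
        key = frozenset(r.tree.bipartitions())
        if key not in topo_cache:
            topo_cache[key] = r.tl.site_loglik()
        vectors.append(topo_cache[key])
    site_lnl = np.stack(vectors)
    sh_p = sh_test(site_lnl, n_rell=n_rell_sh, seed=seed + 1)
    au = au_test(site_lnl, scales=au_scales, n_rell=n_rell_au, seed=seed + 2)

    results = []
    for k, label in enumerate(sorted(per_hyp)):
        res, assignment_id = per_hyp[label]
        results.append(
            TopologyTestResult(
                chromosome=aln.chrom,
                hypothesis=label,
                delta_lnl=max(best_lnl - res.loglik, 0.0),
                au_p=float(au.p_values[k + 1]),
                sh_p=float(sh_p[k + 1]),
                best_assignment=assignment_id,
                unconstrained_lnl=best_lnl,
            )
        )
    table = pd.DataFrame(
        [
            {
                "chromosome": r.chromosome,
                "hypothesis": r.hypothesis,
                "delta_lnL": r.delta_lnl,
                "AU_p": r.au_p,
                "SH_p": r.sh_p,
                "SH_stars": r.sh_stars,
                "not_rejected": not r.rejected,
                "best_assignment": r.best_assignment,
                "unconstrained_lnL": r.unconstrained_lnl,
            }
            for r in results
        ]
    )
    details = {
        "unconstrained": unconstrained,
        "best": best_res,
        "per_hypothesis": per_hyp,
        "au_flags": au.flags,
        "candidates": [label for label, _ in candidates],
    }
    return table, details
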