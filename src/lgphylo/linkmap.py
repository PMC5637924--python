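"""Two-point testcross linkage mapping with Kosambi distances.

Maternal and paternal maps are built separately from single-dose testcross
markers: pairwise recombination fractions and LOD scores, single-linkage
grouping at a LOD threshold, greedy seriation ordering with local
improvement, Kosambi cM spacing, gap splitting / small-fragment removal, and
homolog pairing through biparental (ab x ab) markers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotyping import AA, AB, MISSING, MarkerCall

LOG10_2 = np.log10(2.0)


# --------------------------------------------------------------------------
# map functions
# --------------------------------------------------------------------------


def kosambi(r) -> np.ndarray:
    """Kosambi map distance in cM from a recombination fraction."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, 0.499999)
    return 100.0 * 0.25 * np.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d_cm) -> np.ndarray:
    """Recombination fraction from a Kosambi distance in cM."""
    d = np.asarray(d_cm, dtype=float) / 100.0
    return 0.5 * np.tanh(2.0 * d)


# --------------------------------------------------------------------------
# two-point statistics
# --------------------------------------------------------------------------


def twopoint_rf_lod(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, int]:
    """(rf, LOD, n) between two same-parent testcross genotype vectors.

    The recombination fraction is folded to <= 0.5 by phase choice; LOD is the
    log10 likelihood ratio of linkage at the estimated rf against rf = 0.5.
    Raises ValueError when no progeny is scored at both markers.
    """
    ok = (g1 != MISSING) & (g2 != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no jointly scored progeny for this marker pair")
    r_count = int((g1[ok] != g2[ok]).sum())
    r_count = min(r_count, n - r_count)
    rf = r_count / n
    lod = _lod_from_counts(r_count, n)
    return rf, lod, n


def _lod_from_counts(r, n):
    rf = r / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log10(np.maximum(rf, 1e-300)), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log10(np.maximum(1 - rf, 1e-300)), 0.0)
    return float(t1 + t2 + n * LOG10_2)


def pairwise_rf_lod(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs folded rf, LOD and joint-n for a (markers x progeny) matrix.

    Pairs with no jointly scored progeny get rf = NaN, LOD = -inf (treated as
    unlinked everywhere downstream).
    """
    V = np.zeros(G.shape, dtype=np.float64)
    V[G == AB] = 1.0
    V[G == AA] = -1.0
    nonmiss = (G != MISSING).astype(np.float64)
    N = nonmiss @ nonmiss.T
    S = V @ V.T  # matches - mismatches over jointly scored progeny
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (N - S) / 2.0
        R = np.minimum(R, N - R)
        RF = np.where(N > 0, R / np.maximum(N, 1), np.nan)
        logr = np.where(R > 0, np.log10(np.where(R > 0, RF, 1.0)), 0.0)
        logw = np.where(N - R > 0, np.log10(np.where(N - R > 0, 1 - RF, 1.0)), 0.0)
        LOD = np.where(N > 0, R * logr + (N - R) * logw + N * LOG10_2, -np.inf)
    np.fill_diagonal(LOD, -np.inf)
    np.fill_diagonal(RF, 0.0)
    return RF, LOD, N.astype(np.int64)


# --------------------------------------------------------------------------
# grouping and ordering
# --------------------------------------------------------------------------


def group_markers(lod: np.ndarray, marker_ids: list[str],
                  lod_threshold: float = 5.0,
                  triangle_support: bool = False) -> list[list[int]]:
    """Single-linkage partition over pairs with LOD >= threshold.

    With ``triangle_support``, an edge only counts when the two markers share
    at least one common above-threshold neighbour; this drops the isolated
    spurious links that single linkage is otherwise maximally sensitive to,
    while leaving densely linked chains intact.
    Groups are labelled deterministically by their smallest member id.
    """
    adj = np.isfinite(lod) & (lod >= lod_threshold)
    if triangle_support and adj.shape[0] > 2:
        A = adj.astype(np.int32)
        adj = adj & ((A @ A) > 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(i)
    groups.sort(key=lambda g: min(marker_ids[i] for i in g))
    return groups


def merge_linked_groups(groups: list[list[int]], lod: np.ndarray,
                        lod_attach: float = 4.0,
                        min_links: int = 3) -> list[list[int]]:
    """Touchdown merging of marker groups linked at the attachment LOD.

    Two groups are merged when at least ``min_links`` marker pairs between
    them reach LOD >= ``lod_attach``: one or two such pairs between maps of
    this size are as likely spurious long-range associations as a real
    junction.  Borderline real junctions that fail this bar are recovered by
    the consensus-similarity rejoin, which verifies the fragments against
    the other parent's homolog.  Merging repeats, strongest evidence first.
    """
    groups = [list(g) for g in groups]
    while len(groups) > 1:
        best = None
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                sub = lod[np.ix_(groups[a], groups[b])]
                links = np.isfinite(sub) & (sub >= lod_attach)
                n_links = int(links.sum())
                if n_links >= min_links:
                    score = (n_links, float(sub[links].sum()))
                    if best is None or score > best[0]:
                        best = (score, a, b)
        if best is None:
            break
        _, a, b = best
        groups[a] = groups[a] + groups[b]
        del groups[b]
    return groups


def _chain_order(rf, lod, members):
    """Greedy seriation: best-LOD seed pair, minimal-rf terminal extension."""
    if len(members) <= 2:
        return list(members)
    sub_lod = lod[np.ix_(members, members)]
    i, j = np.unravel_index(np.nanargmax(sub_lod), sub_lod.shape)
    order = [members[i], members[j]]
    remaining = [m for m in members if m not in order]
    while remaining:
        head, tail = order[0], order[-1]
        d_head = [rf[head, m] if np.isfinite(rf[head, m]) else 0.5 for m in remaining]
        d_tail = [rf[tail, m] if np.isfinite(rf[tail, m]) else 0.5 for m in remaining]
        bh, bt = int(np.argmin(d_head)), int(np.argmin(d_tail))
        if d_head[bh] < d_tail[bt]:
            order.insert(0, remaining.pop(bh))
        else:
            order.append(remaining.pop(bt))
    return order


#: lookahead weights for the seriation objective: adjacent rf plus damped
#: second/third/fourth-neighbour terms.  Pure adjacent-rf minimisation
#: overfits sampling noise at testcross sample sizes; near-neighbour terms
#: add information while preserving the optimum at the true order.
_LOOKAHEAD = (1.0, 0.5, 1.0 / 3.0, 0.25)


def _order_cost(rf, order, lam=_LOOKAHEAD):
    order = np.asarray(order)
    c = 0.0
    for k, l in enumerate(lam, start=1):
        if len(order) > k:
            r = rf[order[:-k], order[k:]]
            c += l * float(np.where(np.isfinite(r), r, 0.5).sum())
    return c


def _window_improve(rf, order, window=3, max_passes=30):
    order = list(order)
    n = len(order)
    improved = True
    passes = 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        for w in range(2, window + 1):
            for start in range(0, n - w + 1):
                best = _order_cost(rf, np.asarray(order))
                best_perm = None
                segment = order[start : start + w]
                for perm in itertools.permutations(segment):
                    if list(perm) == segment:
                        continue
                    cand = order[:start] + list(perm) + order[start + w :]
                    c = _order_cost(rf, np.asarray(cand))
                    if c < best - 1e-12:
                        best, best_perm = c, cand
                if best_perm is not None:
                    order = best_perm
                    improved = True
    return order


def _pcoa_order(rf, members):
    """Seriation by the first principal coordinate of the Kosambi distances."""
    D = kosambi(rf[np.ix_(members, members)])
    D = np.where(np.isfinite(D), D, kosambi(0.49))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    axis = V[:, -1]
    return [members[i] for i in np.argsort(axis, kind="stable")]


def _relocate_improve(rf, order, max_passes=20, max_rev=6):
    """Single-marker relocation and short segment-reversal moves."""
    order = list(order)
    n = len(order)
    for _ in range(max_passes):
        improved = False
        base = _order_cost(rf, order)
        for i in range(n):
            m = order[i]
            rest = order[:i] + order[i + 1 :]
            for slot in range(len(rest) + 1):
                if slot == i:
                    continue
                cand = rest[:slot] + [m] + rest[slot:]
                c = _order_cost(rf, cand)
                if c < base - 1e-12:
                    order, base, improved = cand, c, True
        for w in range(2, min(max_rev, n) + 1):
            for s in range(n - w + 1):
                cand = order[:s] + order[s : s + w][::-1] + order[s + w :]
                c = _order_cost(rf, cand)
                if c < base - 1e-12:
                    order, base, improved = cand, c, True
        # prefix/suffix reversals of any length (terminal blocks are the
        # weakly determined part of a seriation)
        for w in range(2, n):
            for cand in (order[:w][::-1] + order[w:], order[:-w] + order[-w:][::-1]):
                c = _order_cost(rf, cand)
                if c < base - 1e-12:
                    order, base, improved = cand, c, True
        # block relocation (or-opt)
        for w in (2, 3, 4):
            for s in range(n - w + 1):
                block = order[s : s + w]
                rest = order[:s] + order[s + w :]
                for slot in range(len(rest) + 1):
                    for b in (block, block[::-1]):
                        cand = rest[:slot] + b + rest[slot:]
                        if cand == order:
                            continue
                        c = _order_cost(rf, cand)
                        if c < base - 1e-12:
                            order, base, improved = cand, c, True
        if not improved:
            break
    return order


def _arrange_blocks(rf, blocks: list[list[int]],
                    ref_pos: np.ndarray | None = None,
                    min_signal_corr: float = 0.2) -> list[int]:
    """Best concatenation (order and orientation) of pre-ordered blocks.

    Junction-adjacent rf values are too noisy to orient blocks at testcross
    sample sizes, so every cross-block pair votes: a configuration is scored
    by sum over cross pairs of (0.45 - clipped rf) * rank distance, which is
    minimised when tightly linked markers across the junction end up close.
    In a crossover-poor family the cross-block rf can carry no distance
    signal at all; when the rf of cross pairs does not increase with the
    chosen arrangement's distances (correlation < ``min_signal_corr``) and
    reference coordinates are available, blocks are arranged by reference
    position instead — mirroring map curation against a reference assembly.
    """
    def clipped(a, b):
        r = rf[np.ix_(a, b)]
        return np.where(np.isfinite(r), np.minimum(r, 0.45), 0.45)

    best, best_score = None, np.inf
    for perm in itertools.permutations(range(len(blocks))):
        if perm[0] > perm[-1]:
            continue  # mirror configurations tie
        for flips in itertools.product((False, True), repeat=len(blocks)):
            order = []
            for k, f in zip(perm, flips):
                order.extend(blocks[k][::-1] if f else blocks[k])
            pos = {m: t for t, m in enumerate(order)}
            score = 0.0
            for a in range(len(blocks)):
                for b in range(a + 1, len(blocks)):
                    ia = np.array([pos[m] for m in blocks[a]])
                    ib = np.array([pos[m] for m in blocks[b]])
                    dist = np.abs(ia[:, None] - ib[None, :])
                    score += float(((0.45 - clipped(blocks[a], blocks[b])) * dist).sum())
            if score < best_score - 1e-12:
                best, best_score = order, score

    if ref_pos is not None:
        pos = {m: t for t, m in enumerate(best)}
        rs, ds = [], []
        for a in range(len(blocks)):
            for b in range(a + 1, len(blocks)):
                ia = np.array([pos[m] for m in blocks[a]])
                ib = np.array([pos[m] for m in blocks[b]])
                rs.append(clipped(blocks[a], blocks[b]).ravel())
                ds.append(np.abs(ia[:, None] - ib[None, :]).ravel())
        rs, ds = np.concatenate(rs), np.concatenate(ds)
        corr = np.corrcoef(rs, ds)[0, 1] if rs.std() > 0 and ds.std() > 0 else 0.0
        if not corr >= min_signal_corr:
            ranked = sorted(blocks, key=lambda b: float(np.median(ref_pos[b])))
            order = []
            for b in ranked:
                rho = np.corrcoef(np.arange(len(b)), ref_pos[b])[0, 1]
                order.extend(b[::-1] if rho < 0 else b)
            return order
    return best


def order_markers(rf: np.ndarray, lod: np.ndarray, members: list[int],
                  exhaustive_max: int = 8, polish: bool = True,
                  lod_block: float = 6.5,
                  ref_pos: np.ndarray | None = None) -> list[int]:
    """Order a group's markers; exact for small groups, seriation otherwise.

    Seriation combines a greedy chain and a principal-coordinate start (the
    better by the lookahead cost), followed by sliding-window permutation and
    single-marker relocation improvement.  Groups that contain several
    strongly linked blocks joined by weak evidence (touchdown merges) are
    ordered block by block and concatenated with the all-cross-pairs rule.
    """
    if len(members) <= 2:
        return list(members)
    if len(members) <= exhaustive_max:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(members):
            if perm[0] > perm[-1]:
                continue  # skip mirrors
            c = _order_cost(rf, np.asarray(perm))
            if c < best_cost - 1e-12:
                best, best_cost = list(perm), c
        return best

    sub_lod = lod[np.ix_(members, members)]
    comps = group_markers(sub_lod, [f"{m:06d}" for m in members], lod_block,
                          triangle_support=True)
    blocks = [[members[i] for i in g] for g in comps if len(g) >= 3]
    if polish and 2 <= len(blocks) <= 5:
        ordered_blocks = [
            _ordered_single_block(rf, lod, b, polish=True) for b in blocks
        ]
        order = _arrange_blocks(rf, ordered_blocks, ref_pos=ref_pos)
        placed = set(order)
        for extra in (m for m in members if m not in placed):
            costs = [_order_cost(rf, order[:s] + [extra] + order[s:])
                     for s in range(len(order) + 1)]
            order.insert(int(np.argmin(costs)), extra)
        return order
    return _ordered_single_block(rf, lod, members, polish=polish)


def _ordered_single_block(rf, lod, members, polish):
    cands = [_chain_order(rf, lod, members), _pcoa_order(rf, members)]
    order = min(cands, key=lambda o: _order_cost(rf, o))
    if not polish:
        return _window_improve(rf, order, window=3, max_passes=6)
    order = _window_improve(rf, order, window=4 if len(members) <= 40 else 3)
    return _relocate_improve(rf, order)


@dataclass
class LinkageGroup:
    lg_id: str
    parent: str
    markers: list[str]
    positions_cm: np.ndarray
    chroms: list[str]
    ref_pos: list[int]
    designation: str = ""
    designation_fraction: float = 0.0
    partner: str | None = None

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.positions_cm) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def _designate(lg: LinkageGroup):
    vals, counts = np.unique(np.asarray(lg.chroms), return_counts=True)
    k = int(np.argmax(counts))
    lg.designation = str(vals[k])
    lg.designation_fraction = float(counts[k] / len(lg.chroms))


def _space(rf, order):
    adj = np.array([rf[a, b] if np.isfinite(rf[a, b]) else 0.5
                    for a, b in zip(order[:-1], order[1:])])
    return np.concatenate([[0.0], np.cumsum(kosambi(adj))])


def order_and_space(
    markers: list[MarkerCall],
    members: list[int],
    rf: np.ndarray,
    lod: np.ndarray,
    lg_id: str,
    parent: str,
    attach: list[int] | None = None,
    lod_attach: float = 4.0,
    ref_pos: np.ndarray | None = None,
) -> LinkageGroup:
    """Order a group, insert touchdown markers, assign Kosambi cM positions.

    ``attach`` markers (linked below the grouping LOD but at LOD >=
    ``lod_attach`` to the group) are inserted at the position that minimises
    the added adjacent recombination.
    """
    order = order_markers(rf, lod, members, ref_pos=ref_pos)
    for extra in attach or []:
        best_lod = np.nanmax(lod[extra, order])
        if not np.isfinite(best_lod) or best_lod < lod_attach:
            continue
        costs = []
        for slot in range(len(order) + 1):
            cand = order[:slot] + [extra] + order[slot:]
            costs.append(_order_cost(rf, np.asarray(cand)))
        order.insert(int(np.argmin(costs)), extra)
    # canonical orientation: smaller marker id first
    if markers[order[0]].marker_id > markers[order[-1]].marker_id:
        order = order[::-1]
    return LinkageGroup(
        lg_id=lg_id,
        parent=parent,
        markers=[markers[i].marker_id for i in order],
        positions_cm=_space(rf, order),
        chroms=[markers[i].chrom for i in order],
        ref_pos=[markers[i].pos for i in order],
    )


def refine_groups(
    lgs: list[LinkageGroup],
    max_gap: float = 35.0,
    min_snps: int = 5,
) -> tuple[list[LinkageGroup], list[tuple[str, str]], list[LinkageGroup]]:
    """Split at gaps >= ``max_gap`` cM, drop fragments with < ``min_snps``.

    Returns (refined groups, rejoin suggestions among same-designation
    fragments, dropped fragments).  Rejoining is advisory only: in the source
    protocol oversplit fragments are re-merged by hand from their reference
    positions and a preliminary phylogeny.
    """
    refined, dropped = [], []
    for lg in lgs:
        gaps = np.diff(lg.positions_cm)
        cut = np.nonzero(gaps >= max_gap)[0]
        pieces = np.split(np.arange(lg.n_markers), cut + 1)
        for k, idx in enumerate(pieces):
            frag = LinkageGroup(
                lg_id=lg.lg_id if len(pieces) == 1 else f"{lg.lg_id}.{k + 1}",
                parent=lg.parent,
                markers=[lg.markers[i] for i in idx],
                positions_cm=lg.positions_cm[idx] - lg.positions_cm[idx[0]],
                chroms=[lg.chroms[i] for i in idx],
                ref_pos=[lg.ref_pos[i] for i in idx],
            )
            _designate(frag)
            (refined if frag.n_markers >= min_snps else dropped).append(frag)
    suggestions = [
        (a.lg_id, b.lg_id)
        for i, a in enumerate(refined)
        for b in refined[i + 1 :]
        if a.parent == b.parent and a.designation == b.designation
        and (a.lg_id.split(".")[0] == b.lg_id.split(".")[0])
        and a.lg_id != b.lg_id
    ]
    return refined, suggestions, dropped


def _phase_flips(G, order, rf_raw_mismatch):
    """Per-marker phase flips so consecutive markers share coupling phase."""
    flips = np.zeros(len(order), dtype=bool)
    flip = False
    for t in range(1, len(order)):
        if rf_raw_mismatch[order[t - 1], order[t]] > 0.5:
            flip = not flip
        flips[t] = flip
    return flips


def clean_double_recombinants(G: np.ndarray, order: list[int],
                              max_flank: int = 2) -> np.ndarray:
    """Correct or fill genotype calls using flanking-marker consensus.

    A single-dose dropout (a heterozygote read as aa at moderate depth) shows
    up as an apparent double recombinant between tightly linked neighbours; at
    testcross marker spacing these are overwhelmingly genotyping errors.  A
    call contradicted by agreeing flanking markers is replaced by the flank
    value, and a missing call bracketed by agreeing flanks is imputed.
    Phases are aligned along the given marker order first.
    """
    if len(order) < 3:
        return G
    V = np.zeros(G.shape); V[G == AB] = 1.0; V[G == AA] = -1.0
    nm = (G != MISSING).astype(float)
    with np.errstate(invalid="ignore"):
        N = nm @ nm.T
        mismatch = np.where(N > 0, (N - V @ V.T) / 2.0 / np.maximum(N, 1), 0.5)
    flips = _phase_flips(G, order, mismatch)
    A = G[order].astype(np.int8).copy()
    for t in np.nonzero(flips)[0]:
        known = A[t] != MISSING
        A[t, known] = 1 - A[t, known]
    k, n = A.shape
    out = A.copy()
    for t in range(k):
        left = np.full(n, MISSING, dtype=np.int8)
        for s in range(t - 1, max(t - 1 - max_flank, -1), -1):
            take = (left == MISSING) & (A[s] != MISSING)
            left[take] = A[s, take]
        right = np.full(n, MISSING, dtype=np.int8)
        for s in range(t + 1, min(t + 1 + max_flank, k)):
            take = (right == MISSING) & (A[s] != MISSING)
            right[take] = A[s, take]
        flank_ok = (left != MISSING) & (right != MISSING) & (left == right)
        conflict = flank_ok & (A[t] != MISSING) & (A[t] != left)
        fill = flank_ok & (A[t] == MISSING)
        out[t, conflict | fill] = left[conflict | fill]
    G = G.copy()
    for t in range(k):
        row = out[t].copy()
        if flips[t]:
            known = row != MISSING
            row[known] = 1 - row[known]
        G[order[t]] = row
    return G


def build_parent_map(
    markers: list[MarkerCall],
    parent: str,
    lod_group: float = 5.0,
    lod_attach: float = 4.0,
    max_gap: float = 35.0,
    min_snps: int = 5,
    lg_prefix: str = "Fcas",
    clean_errors: bool = True,
):
    """Group, order (touchdown 5 -> 4), space and refine one parent's map.

    With ``clean_errors`` (default), a provisional pass orders each LOD-5
    group, blanks apparent double recombinants, and regroups on the cleaned
    genotypes before the final ordering: two-point rf estimates are otherwise
    uniformly inflated by single-dose dropout errors.
    Returns (refined LGs, rejoin suggestions, dropped fragments, diagnostics).
    """
    if not markers:
        return [], [], [], {}
    G = np.stack([m.genotypes for m in markers])
    ids = [m.marker_id for m in markers]
    if clean_errors:
        for _ in range(2):
            rf0, lod0, _ = pairwise_rf_lod(G)
            for g in group_markers(lod0, ids, lod_group, triangle_support=True):
                if len(g) >= 3:
                    G = clean_double_recombinants(
                        G, order_markers(rf0, lod0, g, polish=False))
    rf, lod, _ = pairwise_rf_lod(G)
    markers = [
        MarkerCall(m.marker_id, m.chrom, m.pos, m.seg_class, G[i], m.alt_base)
        for i, m in enumerate(markers)
    ]
    groups = group_markers(lod, ids, lod_group, triangle_support=True)
    singles = [g[0] for g in groups if len(g) == 1]
    cores = merge_linked_groups([g for g in groups if len(g) > 1], lod, lod_attach)

    # touchdown: markers not grouped at lod_group attach to the best group
    # they reach at lod_attach
    attach_map: dict[int, list[int]] = {k: [] for k in range(len(cores))}
    leftovers = []
    for s in singles:
        best_k, best_lod = None, lod_attach
        for k, g in enumerate(cores):
            top = np.nanmax(lod[s, g]) if g else -np.inf
            if np.isfinite(top) and top >= best_lod:
                best_k, best_lod = k, top
        if best_k is None:
            leftovers.append(s)
        else:
            attach_map[best_k].append(s)

    pos_arr = np.array([m.pos for m in markers])
    lgs = []
    for k, g in enumerate(cores):
        chrom_mode = pd.Series([markers[i].chrom for i in g]).mode().iloc[0]
        lg_id = f"{lg_prefix}-{chrom_mode}-{parent}-{k + 1}"
        lgs.append(
            order_and_space(markers, g, rf, lod, lg_id, parent,
                            attach=attach_map[k], lod_attach=lod_attach,
                            ref_pos=pos_arr)
        )
    refined, suggestions, dropped_frag = refine_groups(lgs, max_gap, min_snps)
    # renumber within each chromosome designation for stable, readable ids
    counter: dict[str, int] = {}
    for lg in refined:
        key = f"{lg_prefix}-{lg.designation}-{parent}"
        counter[key] = counter.get(key, 0) + 1
        lg.lg_id = f"{key}-{counter[key]}"
    diag = {
        "n_initial_groups": len(cores),
        "n_unplaced": len(leftovers),
        "markers": markers,       # cleaned genotypes
        "ids": ids,
        "rf": rf,
        "lod": lod,
    }
    return refined, suggestions, dropped_frag, diag


def rejoin_to_expected_count(lgs: list[LinkageGroup], expected: int,
                             diag: dict) -> list[LinkageGroup]:
    """Ploidy-guided final curation: merge surplus span-disjoint fragments.

    A homolog pair can split in both parents at a shared marker desert
    (regions polymorphic among the homolog copies carry no usable markers in
    either parent), leaving no consensus overlap and no cross-parent
    yardstick.  A disomic polyploid has exactly ploidy/2 linkage groups per
    parent per homeologous group, so while the map carries more, the
    same-designation, span-disjoint pair with the strongest residual genetic
    affinity (lowest mean cross rf) is rejoined — the count-based curation
    step used when finalising real polyploid maps.
    """
    lgs = list(lgs)
    if len(lgs) <= expected or "markers" not in diag:
        return lgs
    markers, ids = diag["markers"], diag["ids"]
    rf = diag["rf"]
    index = {mid: k for k, mid in enumerate(ids)}
    ref_arr = np.array([m.pos for m in markers])

    def affinity(a, b):
        ia = [index[m] for m in a.markers if m in index]
        ib = [index[m] for m in b.markers if m in index]
        r = rf[np.ix_(ia, ib)]
        r = np.where(np.isfinite(r), np.minimum(r, 0.5), 0.5)
        return float(r.mean())

    while len(lgs) > expected:
        best = None
        for i in range(len(lgs)):
            for j in range(i + 1, len(lgs)):
                a, b = lgs[i], lgs[j]
                if a.designation != b.designation:
                    continue
                lo_a, hi_a = min(a.ref_pos), max(a.ref_pos)
                lo_b, hi_b = min(b.ref_pos), max(b.ref_pos)
                overlap = max(0, min(hi_a, hi_b) - max(lo_a, lo_b))
                if overlap >= 0.25 * max(min(hi_a - lo_a, hi_b - lo_b), 1):
                    continue
                score = affinity(a, b)
                if best is None or score < best[0]:
                    best = (score, i, j)
        if best is None:
            break
        _, i, j = best
        oa = [index[m] for m in lgs[i].markers if m in index]
        ob = [index[m] for m in lgs[j].markers if m in index]
        order = _arrange_blocks(rf, [oa, ob], ref_pos=ref_arr)
        joined = LinkageGroup(
            lg_id=lgs[i].lg_id,
            parent=lgs[i].parent,
            markers=[markers[k].marker_id for k in order],
            positions_cm=_space(rf, order),
            chroms=[markers[k].chrom for k in order],
            ref_pos=[markers[k].pos for k in order],
        )
        _designate(joined)
        lgs = [lg for k, lg in enumerate(lgs) if k not in (i, j)] + [joined]
    return lgs


def consensus_distance(a: np.ndarray, b: np.ndarray,
                       min_overlap: int = 200) -> float:
    """p-distance between two consensus rows over jointly covered positions."""
    ok = (a < 4) & (b < 4)
    if int(ok.sum()) < min_overlap:
        return np.nan
    return float((a[ok] != b[ok]).mean())


def consensus_noise_floor(maternal_lgs, paternal_lgs, similarity) -> float:
    """Typical consensus distance between the two maps' homologous LGs.

    Each maternal LG's nearest paternal LG is almost always its homolog
    (same pair founder), so the median nearest-neighbour distance across
    parents estimates the consensus noise floor without any truth labels.
    """
    mins = []
    for m in maternal_lgs:
        ds = [consensus_distance(similarity[m.lg_id], similarity[p.lg_id])
              for p in paternal_lgs]
        ds = [d for d in ds if np.isfinite(d)]
        if ds:
            mins.append(min(ds))
    return float(np.median(mins)) if mins else np.nan


def rejoin_similar_groups(
    lgs: list[LinkageGroup],
    similarity: dict[str, np.ndarray],
    diag: dict,
    noise_floor: float,
    factor: float = 1.5,
    partner_lgs: list[LinkageGroup] | None = None,
) -> list[LinkageGroup]:
    """Rejoin oversplit fragments whose consensus sequences nearly coincide.

    Fragments of one homolog pair share the pair's haplotypes, so their
    consensus distance sits at the consensus noise floor, while even the most
    similar distinct pairs differ additionally at their pair-private sites.
    Two same-parent, same-designation LGs are rejoined when their marker
    spans are essentially disjoint (fragments arise from a split at a map
    gap; two complete homolog pairs overlap along the whole chromosome) and
    either their direct consensus distance is within ``factor`` times the
    noise floor, or both have the same nearest opposite-parent homolog at a
    distance within twice that bound (small fragments carry noisier
    consensus) — the sequence counterpart of rejoining by placement in a
    preliminary phylogeny.
    """
    if not np.isfinite(noise_floor):
        return list(lgs)
    lgs = list(lgs)
    markers, ids = diag["markers"], diag["ids"]
    rf, lod = diag["rf"], diag["lod"]
    index = {mid: k for k, mid in enumerate(ids)}
    partner_lgs = partner_lgs or []

    def nearest_partner(lg):
        best = (np.nan, None)
        for p in partner_lgs:
            d = consensus_distance(similarity[lg.lg_id], similarity[p.lg_id])
            if np.isfinite(d) and (best[1] is None or d < best[0]):
                best = (d, p.lg_id)
        return best

    def spans_disjoint(a, b, max_frac=0.25):
        lo_a, hi_a = min(a.ref_pos), max(a.ref_pos)
        lo_b, hi_b = min(b.ref_pos), max(b.ref_pos)
        overlap = max(0, min(hi_a, hi_b) - max(lo_a, lo_b))
        shorter = max(min(hi_a - lo_a, hi_b - lo_b), 1)
        return overlap < max_frac * shorter

    merged = True
    while merged and len(lgs) > 1:
        merged = False
        best = None
        near = {lg.lg_id: nearest_partner(lg) for lg in lgs}
        for i in range(len(lgs)):
            for j in range(i + 1, len(lgs)):
                if lgs[i].designation != lgs[j].designation:
                    continue
                if not spans_disjoint(lgs[i], lgs[j]):
                    continue
                d = consensus_distance(similarity[lgs[i].lg_id],
                                       similarity[lgs[j].lg_id])
                if not (np.isfinite(d) and d < factor * noise_floor):
                    # fragments of one pair can cover disjoint reference
                    # spans; fall back on the other parent's full-length
                    # homolog as the common yardstick
                    di, pi_ = near[lgs[i].lg_id]
                    dj, pj = near[lgs[j].lg_id]
                    if (pi_ is not None and pi_ == pj
                            and di < 2 * factor * noise_floor
                            and dj < 2 * factor * noise_floor):
                        d = max(di, dj)
                    else:
                        continue
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        # keep each fragment's internal order: across the junction there is
        # little or no linkage signal, so free reordering would interleave
        # the blocks; only the block orientations and order are chosen
        oa = [index[m] for m in lgs[i].markers if m in index]
        ob = [index[m] for m in lgs[j].markers if m in index]
        ref_arr = np.array([m.pos for m in markers])
        order = _arrange_blocks(rf, [oa, ob], ref_pos=ref_arr)
        joined = LinkageGroup(
            lg_id=lgs[i].lg_id,
            parent=lgs[i].parent,
            markers=[markers[k].marker_id for k in order],
            positions_cm=_space(rf, order),
            chroms=[markers[k].chrom for k in order],
            ref_pos=[markers[k].pos for k in order],
        )
        _designate(joined)
        similarity[joined.lg_id] = similarity[lgs[i].lg_id]
        lgs = [lg for k, lg in enumerate(lgs) if k not in (i, j)] + [joined]
        merged = True
    return lgs


# --------------------------------------------------------------------------
# homolog pairing via biparental markers
# --------------------------------------------------------------------------


_R_GRID = np.linspace(0.0, 0.5, 26)


def _biparental_lod_profile(y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """LOD linking a dominant presence/absence marker to testcross markers.

    ``y`` is alternate-allele presence (1/0, -1 missing) of an ab x ab marker;
    ``G`` a (markers x progeny) testcross genotype matrix of the parent under
    test.  The other parent transmits its alternate allele independently with
    probability 1/2.  Maximised over a grid of rf in [0, 0.5] and over
    coupling phase; returns one LOD per testcross marker.
    """
    lods = np.full(G.shape[0], -np.inf)
    for k in range(G.shape[0]):
        ok = (y != MISSING) & (G[k] != MISSING)
        if not ok.any():
            continue
        yv, gv = y[ok], G[k][ok]
        best = np.inf
        null = None
        for phase in (AB, AA):
            pm = np.where(gv[None, :] == phase, 1.0 - _R_GRID[:, None], _R_GRID[:, None])
            p1 = 1.0 - (1.0 - pm) * 0.5
            p = np.where(yv[None, :] == 1, p1, 1.0 - p1)
            ll = np.log(np.clip(p, 1e-300, None)).sum(axis=1)
            best = min(best, -ll.max())
            if null is None:
                null = -ll[-1]  # r = 0.5
        lods[k] = (null - best) / np.log(10.0)
    return lods


def pair_homologs(
    maternal_lgs: list[LinkageGroup],
    paternal_lgs: list[LinkageGroup],
    biparental: list[MarkerCall],
    testcross: dict[str, MarkerCall],
    lod_min: float = 4.0,
    lod_floor: float = 2.0,
) -> dict[str, str | None]:
    """Pair each maternal LG with the paternal LG sharing most biparental links.

    A biparental marker is fully 'shared' by a (maternal LG, paternal LG)
    combination when it reaches LOD >= ``lod_min`` against a member of both;
    combinations are ranked by that count, then by total LOD over markers
    clearing a floor of ``lod_floor`` on both sides (small mapping populations
    rarely push a dominant marker past the strict threshold, but the summed
    evidence still identifies the partner unambiguously).  Unpaired LGs map
    to None.
    """
    def top_lods(lgs):
        out = []
        for b in biparental:
            y = np.where(b.genotypes == MISSING, MISSING,
                         (b.genotypes == AB).astype(np.int8))
            per_lg = {}
            for lg in lgs:
                G = np.stack([testcross[mid].genotypes for mid in lg.markers
                              if mid in testcross])
                per_lg[lg.lg_id] = float(np.max(_biparental_lod_profile(y, G)))
            out.append(per_lg)
        return out

    if not biparental or not maternal_lgs or not paternal_lgs:
        return {lg.lg_id: None for lg in maternal_lgs}
    m_links = top_lods(maternal_lgs)
    p_links = top_lods(paternal_lgs)
    scores: dict[tuple[str, str], list] = {}
    for lm, lp in zip(m_links, p_links):
        for mid, ml in lm.items():
            for pid, pl in lp.items():
                cnt, s = scores.get((mid, pid), (0, 0.0))
                if ml >= lod_min and pl >= lod_min:
                    cnt += 1
                if ml >= lod_floor and pl >= lod_floor:
                    s += ml + pl
                scores[(mid, pid)] = (cnt, s)

    pairing: dict[str, str | None] = {lg.lg_id: None for lg in maternal_lgs}
    used_p: set[str] = set()
    for (mid, pid), (cnt, s) in sorted(
        scores.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0])
    ):
        if s <= 0.0 and cnt == 0:
            continue
        if pairing.get(mid) is None and pid not in used_p:
            pairing[mid] = pid
            used_p.add(pid)
    return pairing


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def summarize_map(lgs: list[LinkageGroup],
                  ref_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-parent map summary: LG count, cumulative cM, physical span, etc."""
    rows = []
    for parent in sorted({lg.parent for lg in lgs}):
        sub = [lg for lg in lgs if lg.parent == parent]
        n_snps = [lg.n_markers for lg in sub]
        consistent = sum(
            sum(c == lg.designation for c in lg.chroms) for lg in sub
        )
        span_mb = 0.0
        for lg in sub:
            ps = [p for p, c in zip(lg.ref_pos, lg.chroms) if c == lg.designation]
            if ps:
                span_mb += (max(ps) - min(ps)) / 1e6
        rows.append(
            {
                "parent": parent,
                "n_lgs": len(sub),
                "cumulative_cM": float(sum(lg.length_cm for lg in sub)),
                "physical_span_Mb": span_mb,
                "mean_snps_per_lg": float(np.mean(n_snps)) if n_snps else 0.0,
                "median_snps_per_lg": float(np.median(n_snps)) if n_snps else 0.0,
                "pct_designation_consistent": 100.0 * consistent / max(sum(n_snps), 1),
            }
        )
    return pd.DataFrame(rows)


def map_to_table(lgs: list[LinkageGroup]) -> pd.DataFrame:
    rows = []
    for lg in lgs:
        for mid, cm, chrom, rp in zip(lg.markers, lg.positions_cm, lg.chroms, lg.ref_pos):
            rows.append({"lg_id": lg.lg_id, "marker": mid, "chrom": chrom,
                         "pos": rp, "cM": float(cm), "parent": lg.parent})
    return pd.DataFrame(rows)
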