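"""Synthetic decaploid F1-cross data with full truth labelling.

The generator emulates the observational structure of a targeted-capture
study of a decaploid mapping population:

* diploid progenitor lineages diverge on a user-supplied species tree
  (branch lengths in expected substitutions per site);
* a decaploid carries 10 homologous copies per homeologous chromosome group,
  organised as 5 strictly disomic homolog pairs drawn from up to 4 subgenome
  lineages in configurable counts;
* two decaploid parents share the same pair structure; each pair carries
  parent-private heterozygous sites (single-dose testcross markers), shared
  heterozygous sites (biparental markers), and pair-private divergence;
* an F1 cross of configurable size with Poisson (no-interference) or
  gamma-renewal (interference, Kosambi-like) crossovers;
* allele-depth observations at marker sites with Poisson total depth and a
  symmetric per-read error rate;
* short reference-aligned read segments from each homolog copy, from which
  linkage-group consensus sequences can be assembled downstream;
* an optional dominant male-sterility locus on one maternal homolog.

Every sampling step is driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .models import BASES, GTRModel, TransitionCalculator, decode_sequence

# --------------------------------------------------------------------------
# species tree + progenitor sequences
# --------------------------------------------------------------------------

#: Default synthetic species tree.  The study system provides no divergence
#: times among the Av/Bi/B1/B2 subgenome lineages, so these branch lengths are
#: configuration, not biological claims: the Av lineage (with its diploid
#: relatives) sits well apart from the B lineages; Bi is anchored by a diploid;
#: B1/B2 are anchorless sister lineages; U is a cryptic lineage sister to the
#: B group; three distant taxa act as outgroup-side references.
DEFAULT_SPECIES_TREE = (
    "((Rubus:0.12,(Fvir:0.03,Fman:0.03):0.03):0.04,"
    "(((Fves_vesca:0.008,Fves_brac1:0.008,Fves_brac2:0.009,Fves_brac3:0.009,Av:0.010):0.030,"
    "(((Fiin:0.010,Bi:0.010):0.014,(B1:0.016,B2:0.016):0.008):0.006,U:0.026):0.014):0.005));"
)

#: Diploid reference taxa present in the default tree (full-coverage rows of
#: the supermatrix); ``Rubus`` is the rooting outgroup.
DEFAULT_DIPLOIDS = (
    "Rubus", "Fvir", "Fman",
    "Fves_vesca", "Fves_brac1", "Fves_brac2", "Fves_brac3", "Fiin",
)
DEFAULT_OUTGROUP = "Rubus"
#: Anchor taxa defining the named subgenome clades in constraint topologies.
DEFAULT_CLADE_ANCHORS = {
    "Av": ("Fves_vesca", "Fves_brac1", "Fves_brac2", "Fves_brac3"),
    "Bi": ("Fiin",),
    "B1": (),
    "B2": (),
}

#: Homolog-copy counts per origin scenario (10 copies = 5 disomic pairs).
SCENARIOS = {
    "H1": {"Av": 4, "Bi": 2, "B1": 2, "B2": 2},
    "H2.A": {"Av": 2, "Bi": 4, "B1": 2, "B2": 2},
    "H2.B": {"Av": 2, "Bi": 2, "B1": 4, "B2": 2},
    "H2.C": {"Av": 2, "Bi": 2, "B1": 2, "B2": 4},
    "H3": {"Av": 2, "Bi": 2, "B1": 2, "B2": 2, "U": 2},
}


def parse_species_tree(newick: str) -> dendropy.Tree:
    """Parse and validate a newick species tree."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick species tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("species tree tip labels must be unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("species tree branch lengths must be non-negative")
    return tree


def simulate_progenitor_sequences(
    tree,
    length: int,
    model: GTRModel | None = None,
    seed: int = 0,
    rate_categories: int = 16,
) -> dict[str, np.ndarray]:
    """Evolve one sequence per tip of ``tree``; returns label -> uint8 codes.

    Gamma rate heterogeneity (``model.alpha``) is discretised into
    ``rate_categories`` per-site rate classes.
    """
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    if isinstance(tree, str):
        tree = parse_species_tree(tree)
    model = model or GTRModel()
    rng = np.random.default_rng(seed)
    calc = TransitionCalculator(model)
    pi = np.asarray(model.freqs)

    if model.alpha is None:
        site_rate_class = np.zeros(length, dtype=np.int64)
        class_rates = np.ones(1)
    else:
        from .models import discrete_gamma_rates

        class_rates = discrete_gamma_rates(model.alpha, rate_categories)
        site_rate_class = rng.integers(0, rate_categories, size=length)

    root_seq = rng.choice(4, size=length, p=pi).astype(np.uint8)
    seqs: dict[str, np.ndarray] = {}
    root = tree.seed_node
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf():
            seqs[node.taxon.label] = seq
            continue
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            stack.append((child, _evolve(seq, t, calc, class_rates, site_rate_class, rng)))
    return seqs


def _evolve(parent_seq, t, calc, class_rates, site_rate_class, rng):
    if t == 0.0:
        return parent_seq.copy()
    child = np.empty_like(parent_seq)
    u = rng.random(parent_seq.shape[0])
    for c, rate in enumerate(class_rates):
        mask = site_rate_class == c
        if not mask.any():
            continue
        P = calc.probs_single(t, rate)
        cum = P.cumsum(axis=1)
        child[mask] = (u[mask, None] > cum[parent_seq[mask]]).sum(axis=1).astype(np.uint8)
    return child


# --------------------------------------------------------------------------
# polyploid assembly
# --------------------------------------------------------------------------


@dataclass
class HomologCopy:
    copy_id: str
    parent: str          # 'm' | 'p'
    lineage: str
    pair_id: str
    seq: np.ndarray      # uint8 codes, 0-based indexing


@dataclass
class ParentGenome:
    parent: str
    copies: list[HomologCopy]

    @property
    def ploidy(self) -> int:
        return len(self.copies)

    def pairs(self) -> dict[str, tuple[HomologCopy, HomologCopy]]:
        out: dict[str, list[HomologCopy]] = {}
        for c in self.copies:
            out.setdefault(c.pair_id, []).append(c)
        return {k: tuple(v) for k, v in out.items()}


@dataclass
class TraitLocus:
    pair_id: str
    pos: int             # 1-based reference coordinate
    parent: str = "m"
    copy: int = 0        # index of the sterility-allele-bearing copy in the pair


@dataclass
class SimTruth:
    """Ground-truth side table for one simulated homeologous group."""

    chrom: str
    seq_length: int
    pair_lineages: dict[str, str]
    markers: pd.DataFrame      # pos, alt, seg_class, pair_id, m_copy, p_copy
    reference: np.ndarray
    map_length_cM: float | None = None
    trait: TraitLocus | None = None
    seed: int | None = None

    def marker_id(self, pos: int) -> str:
        return f"{self.chrom}:{pos}"

    def cm_of(self, pos) -> np.ndarray:
        """Linear bp -> cM genetic map (first base at 0 cM)."""
        if self.map_length_cM is None:
            raise ValueError("no genetic map defined yet (run the F1 cross)")
        pos = np.asarray(pos, dtype=float)
        return (pos - 1.0) / max(self.seq_length - 1, 1) * self.map_length_cM


def _stratified_positions(n, length, rng, taken):
    """n distinct 1-based positions, jittered-grid spaced, avoiding ``taken``."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    out = []
    edges = np.linspace(0, length, n + 1)
    for k in range(n):
        lo, hi = int(edges[k]), max(int(edges[k + 1]), int(edges[k]) + 1)
        for _ in range(200):
            p = int(rng.integers(lo, hi)) + 1
            if p not in taken:
                taken.add(p)
                out.append(p)
                break
        else:  # stratum saturated; fall back to anywhere
            while True:
                p = int(rng.integers(0, length)) + 1
                if p not in taken:
                    taken.add(p)
                    out.append(p)
                    break
    return np.array(sorted(out), dtype=np.int64)


def _mutate(seq, pos0, rng):
    """Flip seq[pos0] to a uniformly chosen different base."""
    old = seq[pos0]
    seq[pos0] = (old + rng.integers(1, 4, size=np.shape(pos0))) % 4


def assemble_polyploid(
    spec: dict[str, int],
    progenitor_seqs: dict[str, np.ndarray],
    within_lineage_het: float = 1.5e-3,
    seed: int = 0,
    *,
    shared_het: float = 4.0e-4,
    pair_divergence: float = 3.0e-3,
    reference: str | np.ndarray = "Fves_vesca",
    chrom: str = "I",
) -> tuple[ParentGenome, ParentGenome, SimTruth]:
    """Build two parental multi-homolog genomes plus the truth table.

    ``spec`` maps lineage label -> copy count (even).  Copies are grouped into
    disomic pairs; both parents share each pair's founder haplotype.  Parent-
    private heterozygous sites become testcross markers (expected count per
    pair per parent = ``within_lineage_het * length``), shared heterozygous
    sites become biparental markers (rate ``shared_het``).  Marker sites are
    placed where all copies carry the reference base, so the alternate-allele
    read fraction in a parent is dose/ploidy.
    """
    for lineage, count in spec.items():
        if lineage not in progenitor_seqs:
            raise ValueError(f"unknown lineage label {lineage!r}")
        if count < 0 or count % 2 != 0:
            raise ValueError(f"copy count for {lineage!r} must be even and >= 0")
    ploidy = sum(spec.values())
    if ploidy == 0:
        raise ValueError("polyploid must have at least one homolog pair")

    rng = np.random.default_rng(seed)
    length = len(next(iter(progenitor_seqs.values())))
    ref_seq = (
        progenitor_seqs[reference].copy()
        if isinstance(reference, str)
        else np.asarray(reference, dtype=np.uint8)
    )

    # pair founders
    pair_ids, founders, lineages = [], [], {}
    for lineage in sorted(spec):
        for k in range(spec[lineage] // 2):
            pid = f"{lineage}-{k + 1}"
            founder = progenitor_seqs[lineage].copy()
            n_div = rng.binomial(length, pair_divergence)
            if n_div:
                _mutate(founder, rng.choice(length, size=n_div, replace=False), rng)
            pair_ids.append(pid)
            founders.append(founder)
            lineages[pid] = lineage

    mother = ParentGenome("m", [])
    father = ParentGenome("p", [])
    for pid, founder in zip(pair_ids, founders):
        for parent, genome in (("m", mother), ("p", father)):
            for k in range(2):
                genome.copies.append(
                    HomologCopy(f"{parent}-{pid}-{k}", parent, lineages[pid], pid, founder.copy())
                )

    # marker placement: only at sites where every copy carries the ref base
    copy_stack = np.stack([c.seq for c in mother.copies + father.copies])
    monomorphic_ref = (copy_stack == ref_seq[None, :]).all(axis=0)
    taken = set((np.nonzero(~monomorphic_ref)[0] + 1).tolist())

    rows = []
    pairs_m, pairs_p = mother.pairs(), father.pairs()
    for pid in pair_ids:
        for seg_class, rate in (("maternal", within_lineage_het),
                                ("paternal", within_lineage_het),
                                ("biparental", shared_het)):
            n = rng.binomial(length, rate)
            positions = _stratified_positions(n, length, rng, taken)
            for pos in positions:
                m_copy = p_copy = -1
                if seg_class in ("maternal", "biparental"):
                    m_copy = int(rng.integers(0, 2))
                if seg_class in ("paternal", "biparental"):
                    p_copy = int(rng.integers(0, 2))
                alt = int((ref_seq[pos - 1] + rng.integers(1, 4)) % 4)
                if m_copy >= 0:
                    pairs_m[pid][m_copy].seq[pos - 1] = alt
                if p_copy >= 0:
                    pairs_p[pid][p_copy].seq[pos - 1] = alt
                rows.append((int(pos), alt, seg_class, pid, m_copy, p_copy))

    markers = pd.DataFrame(
        rows, columns=["pos", "alt", "seg_class", "pair_id", "m_copy", "p_copy"]
    ).sort_values("pos").reset_index(drop=True)
    truth = SimTruth(
        chrom=chrom,
        seq_length=length,
        pair_lineages=lineages,
        markers=markers,
        reference=ref_seq,
        seed=seed,
    )
    return mother, father, truth


# --------------------------------------------------------------------------
# F1 cross
# --------------------------------------------------------------------------


@dataclass
class Gamete:
    start_copy: int
    breakpoints: np.ndarray  # sorted 1-based bp positions of crossovers

    def copy_at(self, pos) -> np.ndarray:
        """Which pair copy (0/1) this gamete carries at 1-based position(s)."""
        k = np.searchsorted(self.breakpoints, np.asarray(pos), side="right")
        return (self.start_copy + k) % 2


@dataclass
class Progeny:
    progeny_id: str
    gametes: dict[str, tuple[Gamete, Gamete]]  # pair_id -> (maternal, paternal)
    phenotype: str | None = None               # 'sterile' | 'fertile' | None


@dataclass
class F1Population:
    progeny: list[Progeny]
    map_length_cM: float
    trait: TraitLocus | None = None


def _crossovers(rng, map_length_cm, interference):
    if interference == "haldane":
        n = rng.poisson(map_length_cm / 100.0)
        return np.sort(rng.uniform(0.0, map_length_cm, size=n))
    if interference == "kosambi":
        # gamma-renewal chiasma process (shape ~2.63 approximates the Kosambi
        # map function) thinned by 1/2 into crossovers; burn-in gives an
        # approximately stationary process at the chromosome start.
        shape = 2.63
        scale = 50.0 / shape  # mean chiasma spacing 50 cM -> 1 crossover/100 cM
        t = -500.0 + rng.gamma(shape, scale) * rng.uniform()
        pts = []
        while t < map_length_cm:
            if t >= 0 and rng.random() < 0.5:
                pts.append(t)
            t += rng.gamma(shape, scale)
        return np.asarray(pts)
    raise ValueError(f"unknown interference model {interference!r}")


def simulate_f1_cross(
    mother: ParentGenome,
    father: ParentGenome,
    truth: SimTruth,
    n_progeny: int,
    map_length_cM: float = 100.0,
    trait: TraitLocus | None = None,
    seed: int = 0,
    interference: str = "haldane",
) -> F1Population:
    """Disomic F1 cross: one recombinant copy per pair per parent per progeny."""
    if n_progeny < 0:
        raise ValueError("n_progeny must be >= 0")
    if map_length_cM <= 0:
        raise ValueError("map length must be positive")
    if trait is not None and trait.pair_id not in truth.pair_lineages:
        raise ValueError(f"trait locus pair {trait.pair_id!r} not in the genome")
    rng = np.random.default_rng(seed)
    truth.map_length_cM = map_length_cM
    truth.trait = trait
    length = truth.seq_length
    cm_per_bp = map_length_cM / max(length - 1, 1)

    progeny = []
    pair_ids = sorted(truth.pair_lineages)
    for i in range(n_progeny):
        gametes = {}
        for pid in pair_ids:
            gs = []
            for _parent in ("m", "p"):
                bx_cm = _crossovers(rng, map_length_cM, interference)
                bx_bp = np.floor(bx_cm / cm_per_bp).astype(np.int64) + 1
                gs.append(Gamete(int(rng.integers(0, 2)), np.sort(bx_bp)))
            gametes[pid] = (gs[0], gs[1])
        pheno = None
        if trait is not None:
            g = gametes[trait.pair_id][0 if trait.parent == "m" else 1]
            pheno = "sterile" if int(g.copy_at(trait.pos)) == trait.copy else "fertile"
        progeny.append(Progeny(f"F{i + 1:03d}", gametes, pheno))
    return F1Population(progeny, map_length_cM, trait)


# --------------------------------------------------------------------------
# observations
# --------------------------------------------------------------------------


def _progeny_doses(mother, father, population, truth) -> np.ndarray:
    """(n_markers, n_progeny) alternate-allele dose (0/1/2) in each progeny."""
    mk = truth.markers
    pairs_m, pairs_p = mother.pairs(), father.pairs()
    doses = np.zeros((len(mk), len(population.progeny)), dtype=np.int8)
    for pid in truth.pair_lineages:
        rows = np.nonzero(mk.pair_id.values == pid)[0]
        if rows.size == 0:
            continue
        pos = mk.pos.values[rows]
        alt = mk.alt.values[rows]
        m_has = np.stack([pairs_m[pid][k].seq[pos - 1] == alt for k in range(2)])
        p_has = np.stack([pairs_p[pid][k].seq[pos - 1] == alt for k in range(2)])
        for j, prog in enumerate(population.progeny):
            gm, gp = prog.gametes[pid]
            doses[rows, j] = (
                m_has[gm.copy_at(pos), np.arange(rows.size)]
                + p_has[gp.copy_at(pos), np.arange(rows.size)]
            )
    return doses


def emit_observations(
    mother: ParentGenome,
    father: ParentGenome,
    population: F1Population,
    truth: SimTruth,
    mean_depth: float = 40.0,
    error_rate: float = 0.005,
    seed: int = 0,
    parent_depth: float | None = None,
) -> pd.DataFrame:
    """Per-site, per-individual ref/alt read depths at the marker sites.

    Total depth is Poisson(``mean_depth``) per individual-site (parents use
    ``parent_depth``, default 2x the progeny depth); a read from a copy reports
    the wrong base with probability ``error_rate`` (uniform over the three
    other bases).  Reads showing neither ref nor alt are dropped, as a
    biallelic caller would.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    if parent_depth is None:
        parent_depth = 2.0 * mean_depth
    mk = truth.markers
    n_mk = len(mk)
    pos = mk.pos.values
    alt = mk.alt.values
    ploidy = mother.ploidy

    m_dose = np.stack([c.seq[pos - 1] == alt for c in mother.copies]).sum(axis=0)
    p_dose = np.stack([c.seq[pos - 1] == alt for c in father.copies]).sum(axis=0)
    prog_dose = _progeny_doses(mother, father, population, truth)

    individuals = ["M", "P"] + [p.progeny_id for p in population.progeny]
    doses = np.column_stack([m_dose, p_dose, prog_dose]) if population.progeny else \
        np.column_stack([m_dose, p_dose])
    depth_means = np.array([parent_depth, parent_depth] + [mean_depth] * len(population.progeny))

    e = error_rate
    f = doses / ploidy
    p_alt = f * (1 - e) + (1 - f) * (e / 3.0)
    p_ref = (1 - f) * (1 - e) + f * (e / 3.0)

    total = rng.poisson(np.broadcast_to(depth_means, (n_mk, len(individuals))))
    alt_reads = rng.binomial(total, p_alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = np.where(p_alt < 1.0, p_ref / (1.0 - p_alt), 0.0)
    ref_reads = rng.binomial(total - alt_reads, np.clip(p_cond, 0.0, 1.0))

    ref_base = truth.reference[pos - 1]
    out = pd.DataFrame(
        {
            "chrom": np.repeat(truth.chrom, n_mk * len(individuals)),
            "pos": np.tile(pos, len(individuals)),
            "individual": np.repeat(individuals, n_mk),
            "ref_depth": ref_reads.T.ravel(),
            "alt_depth": alt_reads.T.ravel(),
            "ref_base": np.tile([BASES[b] for b in ref_base], len(individuals)),
            "alt_base": np.tile([BASES[b] for b in alt], len(individuals)),
        }
    )
    return out.sort_values(["pos", "individual"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# read segments (consensus input)
# --------------------------------------------------------------------------


@dataclass
class SegmentRead:
    start: int           # 1-based inclusive
    bases: np.ndarray    # uint8 codes

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.start + len(self.bases) - 1


def emit_segment_reads(
    mother: ParentGenome,
    father: ParentGenome,
    segment_length: int = 800,
    passes: int = 3,
    error_rate: float = 0.005,
    seed: int = 0,
) -> list[SegmentRead]:
    """Reference-aligned read segments tiling every homolog copy.

    Each pass tiles a copy with randomly offset windows; per-base errors are
    symmetric.  Segments carry no source label: downstream consensus building
    must assign them to linkage groups via the marker alleles they contain.
    """
    rng = np.random.default_rng(seed)
    reads = []
    for copy in mother.copies + father.copies:
        L = len(copy.seq)
        for _ in range(passes):
            offset = int(rng.integers(0, segment_length))
            starts = list(range(offset, L, segment_length))
            if offset > 0:
                starts = [0] + starts
            for s in starts:
                bases = copy.seq[s : s + segment_length].copy()
                n_err = rng.binomial(len(bases), error_rate)
                if n_err:
                    _mutate(bases, rng.choice(len(bases), size=n_err, replace=False), rng)
                reads.append(SegmentRead(s + 1, bases))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


# --------------------------------------------------------------------------
# convenience writers
# --------------------------------------------------------------------------


def sequences_to_fasta(seqs: dict[str, np.ndarray], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(decode_sequence(arr)), id=name, description="")
        for name, arr in seqs.items()
    ]
    seqio_write(records, str(path), "fasta")
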