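"""End-to-end pipeline on synthetic data: simulate -> genotype -> map ->
phylogeny -> hypothesis tests -> trait mapping.

`RunConfig` carries the study-design defaults (decaploid, seven homeologous
groups, 45 progeny, 40x depth threshold, LOD 5 grouping with touchdown to 4,
35 cM gap splitting, five-SNP minimum, 100 bootstrap replicates).  Reduced
problem sizes for desk-scale experiments are explicit arguments of the
experiment helpers, not changes to the defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import genotyping, linkmap, posthoc, simulate
from .hypotest import DEFAULT_HYPOTHESES, run_hypothesis_suite
from .models import BASE_INDEX, GTRModel
from .phylo.alignment import build_lg_consensus, build_supermatrix

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class RunConfig:
    seed: int = 1
    ploidy: int = 10
    n_chromosomes: int = 7
    n_progeny: int = 45
    scenario: str = "H2.C"
    seq_length: int = 20_000
    map_length_cM: float = 90.0
    mean_depth: float = 40.0
    error_rate: float = 0.005
    min_depth_parent: int = 40
    min_depth_progeny: int = 10
    min_alt_reads: int = 2
    lod_group: float = 5.0
    lod_attach: float = 4.0
    max_gap_cM: float = 35.0
    min_snps: int = 5
    bootstrap_reps: int = 100
    hypotheses: tuple = tuple(sorted(DEFAULT_HYPOTHESES))
    within_lineage_het: float = 1.5e-3
    shared_het: float = 4.0e-4
    pair_divergence: float = 3.0e-3
    segment_length: int = 800
    segment_passes: int = 3
    species_tree: str = simulate.DEFAULT_SPECIES_TREE
    n_rell_sh: int = 1000
    n_rell_au: int = 10000
    au_scales: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)
    trait_chromosome: int = 6          # homeologous group VI, 1-based
    trait_map_fraction: float = 0.7    # distal placement along the group

    def __post_init__(self):
        for name in ("n_progeny",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ploidy", "n_chromosomes", "min_depth_parent", "min_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lod_group <= 0 or self.lod_attach <= 0 or self.max_gap_cM <= 0:
            raise ValueError("thresholds must be positive")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=list)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("hypotheses", "au_scales"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# --------------------------------------------------------------------------
# per-chromosome simulation + analysis bundles
# --------------------------------------------------------------------------


@dataclass
class ChromosomeData:
    chrom: str
    progenitors: dict
    mother: simulate.ParentGenome
    father: simulate.ParentGenome
    truth: simulate.SimTruth
    population: simulate.F1Population
    depth: pd.DataFrame
    reads: list


def simulate_chromosome(config: RunConfig, chrom_index: int,
                        seed: int, with_trait: bool = False) -> ChromosomeData:
    """Generate one homeologous group's data under the configured scenario."""
    chrom = ROMAN[chrom_index]
    ss = np.random.SeedSequence([seed, chrom_index])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    seqs = simulate.simulate_progenitor_sequences(
        config.species_tree, config.seq_length, GTRModel(), seed=seeds[0])
    spec = dict(simulate.SCENARIOS[config.scenario])
    mother, father, truth = simulate.assemble_polyploid(
        spec, seqs,
        within_lineage_het=config.within_lineage_het,
        shared_het=config.shared_het,
        pair_divergence=config.pair_divergence,
        seed=seeds[1], chrom=chrom,
    )
    trait = None
    if with_trait:
        pair_ids = sorted(truth.pair_lineages)
        b1 = [p for p in pair_ids if truth.pair_lineages[p] == "B1"]
        trait = simulate.TraitLocus(
            pair_id=(b1 or pair_ids)[0],
            pos=int(config.trait_map_fraction * config.seq_length),
            parent="m", copy=0,
        )
    population = simulate.simulate_f1_cross(
        mother, father, truth, config.n_progeny, config.map_length_cM,
        trait=trait, seed=seeds[2])
    depth = simulate.emit_observations(
        mother, father, population, truth,
        mean_depth=config.mean_depth, error_rate=config.error_rate, seed=seeds[3])
    reads = simulate.emit_segment_reads(
        mother, father, segment_length=config.segment_length,
        passes=config.segment_passes, error_rate=config.error_rate, seed=seeds[4])
    return ChromosomeData(chrom, seqs, mother, father, truth, population, depth, reads)


@dataclass
class ChromosomeAnalysis:
    chrom: str
    markers: list
    progeny_ids: list
    maternal_lgs: list
    paternal_lgs: list
    pairing: dict
    aln: object | None = None
    lg_truth_pairs: dict = field(default_factory=dict)
    lg_units: dict = field(default_factory=dict)


def analyze_chromosome(data: ChromosomeData, config: RunConfig,
                       diploids=simulate.DEFAULT_DIPLOIDS,
                       build_alignment: bool = True) -> ChromosomeAnalysis:
    """Genotype, map, pair homologs and (optionally) build the supermatrix."""
    table = genotyping.DepthTable.from_long(data.depth)
    markers, progeny_ids = genotyping.call_markers(
        table, ploidy=config.ploidy,
        min_depth_parent=config.min_depth_parent,
        min_depth_progeny=config.min_depth_progeny,
        min_alt_reads=config.min_alt_reads,
    )
# the 1:1 guard applies to testcross markers only (biparental segregate 3:1)
    maternal = [m for m in markers if m.seg_class == genotyping.MATERNAL
                and genotyping.segregation_filter(m).keep]
    paternal = [m for m in markers if m.seg_class == genotyping.PATERNAL
                and genotyping.segregation_filter(m).keep]
    biparental = [m for m in markers if m.seg_class == genotyping.BIPARENTAL]

    lgs_m, _, _, diag_m = linkmap.build_parent_map(
        maternal, "m", lod_group=config.lod_group, lod_attach=config.lod_attach,
        max_gap=config.max_gap_cM, min_snps=config.min_snps)
    lgs_p, _, _, diag_p = linkmap.build_parent_map(
        paternal, "p", lod_group=config.lod_group, lod_attach=config.lod_attach,
        max_gap=config.max_gap_cM, min_snps=config.min_snps)

    if not lgs_m and not lgs_p:
        raise RuntimeError(
            f"linkage stage failed on chromosome {data.chrom}: no linkage "
            "groups could be formed (no informative markers; is n_progeny 0?)"
        )

    testcross = {m.marker_id: m for m in maternal + paternal}

    def make_consensus(lgs):
        out = {}
        for lg in lgs:
            sites = [(m.pos, BASE_INDEX[m.alt_base])
                     for m in (testcross[mid] for mid in lg.markers
                               if mid in testcross)]
            out[lg.lg_id] = build_lg_consensus(sites, data.reads,
                                               data.truth.seq_length)
        return out

    consensus = make_consensus(lgs_m + lgs_p)
    # oversplit fragments rejoin by consensus similarity (the sequence
    # analogue of placement in a preliminary phylogeny)
    floor = linkmap.consensus_noise_floor(lgs_m, lgs_p, consensus)
    n_before = len(lgs_m) + len(lgs_p)
    lgs_m = linkmap.rejoin_similar_groups(lgs_m, consensus, diag_m, floor,
                                          partner_lgs=lgs_p)
    lgs_p = linkmap.rejoin_similar_groups(lgs_p, consensus, diag_p, floor,
                                          partner_lgs=lgs_m)
    # a pair can split in both parents at a shared marker desert; the final
    # curation enforces the disomic expectation of ploidy/2 LGs per parent
    expected = config.ploidy // 2
    lgs_m = linkmap.rejoin_to_expected_count(lgs_m, expected, diag_m)
    lgs_p = linkmap.rejoin_to_expected_count(lgs_p, expected, diag_p)
    if len(lgs_m) + len(lgs_p) != n_before:
        consensus = make_consensus(lgs_m + lgs_p)

    pairing = linkmap.pair_homologs(lgs_m, lgs_p, biparental, testcross,
                                    lod_min=config.lod_attach)
    # homologous LGs not resolved by shared biparental markers are paired
    # by consensus-sequence similarity (their phylogenetic placement)
    pairing = _consensus_pair_fallback(pairing, lgs_p, consensus)

    analysis = ChromosomeAnalysis(data.chrom, markers, progeny_ids,
                                  lgs_m, lgs_p, pairing)
    analysis.lg_truth_pairs = {
        lg.lg_id: _modal_truth_pair(lg, data.truth) for lg in lgs_m + lgs_p
    }
    if build_alignment:
        dip_seqs = {d: data.progenitors[d] for d in diploids}
        analysis.aln = build_supermatrix(consensus, dip_seqs, chrom=data.chrom)

    # assignment units for constraint enumeration: homolog pairs move
    # together, unpaired LGs (either parent) are assigned singly
    lg_units = dict(pairing)
    used_p = {p for p in pairing.values() if p is not None}
    for lg in lgs_p:
        if lg.lg_id not in used_p:
            lg_units[lg.lg_id] = None
    analysis.lg_units = lg_units
    return analysis


def _consensus_pair_fallback(pairing, lgs_p, consensus):
    """Greedy pairing of leftover LGs by smallest consensus p-distance.

    A homolog pair's maternal and paternal LGs share the pair founder
    haplotype, so their consensus sequences are nearly identical; a match is
    accepted only when clearly closer than the alternatives (< 0.5x the
    median distance to other candidates).
    """
    pairing = dict(pairing)
    used = {p for p in pairing.values() if p is not None}
    free_p = [lg.lg_id for lg in lgs_p if lg.lg_id not in used]
    free_m = [m for m, p in pairing.items() if p is None]
    cand = []
    for m in free_m:
        row_m = consensus[m]
        ds = {}
        for p in free_p:
            row_p = consensus[p]
            ok = (row_m < 4) & (row_p < 4)
            ds[p] = (row_m[ok] != row_p[ok]).mean() if ok.sum() >= 200 else np.nan
        vals = [v for v in ds.values() if np.isfinite(v)]
        if not vals:
            continue
        med = float(np.median(vals))
        for p, d in ds.items():
            if np.isfinite(d) and (len(vals) == 1 or d < 0.5 * med):
                cand.append((d, m, p))
    for d, m, p in sorted(cand):
        if pairing[m] is None and p in free_p and p not in used:
            pairing[m] = p
            used.add(p)
    return pairing


def _modal_truth_pair(lg, truth) -> str:
    mk = truth.markers.set_index(truth.markers.pos.map(truth.marker_id))
    pairs = [mk.loc[mid, "pair_id"] for mid in lg.markers if mid in mk.index]
    return pd.Series(pairs).mode().iloc[0] if pairs else ""


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------


def run_linkage_experiment(seed: int, config: RunConfig | None = None) -> dict:
    """Map one simulated homeologous group; report truth-recovery metrics."""
    config = config or RunConfig(seed=seed, n_chromosomes=1)
    data = simulate_chromosome(config, 0, seed)
    analysis = analyze_chromosome(data, config, build_alignment=False)
    n_pairs = len(data.truth.pair_lineages)

    taus = []
    for lg in analysis.maternal_lgs + analysis.paternal_lgs:
        true_pos = [int(mid.split(":")[1]) for mid in lg.markers]
        if len(true_pos) >= 3:
            tau, _ = kendalltau(np.arange(len(true_pos)), true_pos)
            taus.append(abs(tau))
    correct_pairs = sum(
        1 for m, p in analysis.pairing.items()
        if p is not None
        and analysis.lg_truth_pairs.get(m) == analysis.lg_truth_pairs.get(p)
    )
    return {
        "true_lgs_per_parent": n_pairs,
        "n_maternal_lgs": len(analysis.maternal_lgs),
        "n_paternal_lgs": len(analysis.paternal_lgs),
        "mean_kendall": float(np.mean(taus)) if taus else 0.0,
        "n_paired": sum(p is not None for p in analysis.pairing.values()),
        "n_correctly_paired": correct_pairs,
        "analysis": analysis,
        "data": data,
    }


def run_origin_experiment(
    seed: int,
    config: RunConfig | None = None,
    hypotheses: tuple = ("H1", "H2.C"),
    mode: str = "minimal",
    cap: int = 6,
) -> dict:
    """One replicate of the origin test on a single homeologous group.

    Simulates under ``config.scenario``, recovers linkage groups, builds the
    LG + diploid supermatrix and runs the constrained/unconstrained tests.
    """
    config = config or RunConfig(seed=seed, n_chromosomes=1)
    data = simulate_chromosome(config, 0, seed)
    analysis = analyze_chromosome(data, config)
    hyp_cfg = {h: DEFAULT_HYPOTHESES[h] for h in hypotheses}
    table, details = run_hypothesis_suite(
        analysis.aln, analysis.lg_units, hypotheses=hyp_cfg,
        seed=seed, mode=mode, cap=cap,
        n_rell_sh=config.n_rell_sh, n_rell_au=config.n_rell_au,
        au_scales=config.au_scales,
    )
    return {
        "table": table,
        "details": details,
        "analysis": analysis,
        "data": data,
        "n_lg_taxa": len(analysis.maternal_lgs) + len(analysis.paternal_lgs),
    }


def run_trait_experiment(seed: int, config: RunConfig | None = None) -> dict:
    """Simulate a dominant sterility locus and map it as a pseudo-marker."""
    config = config or RunConfig(seed=seed, n_chromosomes=1)
    data = simulate_chromosome(config, 0, seed, with_trait=True)
    analysis = analyze_chromosome(data, config, build_alignment=False)
    phenotypes = [p.phenotype for p in data.population.progeny]
    testcross = {
        m.marker_id: m for m in analysis.markers
        if m.seg_class in (genotyping.MATERNAL,)
    }
    placement = posthoc.map_trait(phenotypes, testcross, analysis.maternal_lgs)
    trait = data.truth.trait
    true_lg = None
    for lg in analysis.maternal_lgs:
        if analysis.lg_truth_pairs.get(lg.lg_id) == trait.pair_id:
            true_lg = lg.lg_id
            break
    on_true_lg = placement.status == "placed" and placement.lg_id == true_lg
    covered = (
        placement.status == "placed"
        and placement.interval_bp[0] <= trait.pos <= placement.interval_bp[1]
    )
    n_sterile = phenotypes.count("sterile")
    n_fertile = phenotypes.count("fertile")
    return {
        "placement": placement,
        "true_pair": trait.pair_id,
        "true_pos": trait.pos,
        "true_lg": true_lg,
        "on_true_lg": bool(on_true_lg),
        "interval_covers_truth": bool(covered),
        "segregation": posthoc.segregation_chisq(n_sterile, n_fertile),
        "counts": (n_sterile, n_fertile),
    }


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Run every stage over all configured homeologous groups.

    Returns a report dict; when ``outdir`` is given, writes the genetic maps,
    supermatrices, trees and the hypothesis-test table there along with a
    config echo for provenance.
    """
    from pathlib import Path

    report = {"config": asdict(config), "chromosomes": {}}
    tables = []
    trait_result = None
    for k in range(config.n_chromosomes):
        with_trait = (k + 1) == config.trait_chromosome
        data = simulate_chromosome(config, k, config.seed, with_trait=with_trait)
        analysis = analyze_chromosome(data, config)
        if config.n_progeny == 0 or not analysis.maternal_lgs:
            raise RuntimeError(
                f"linkage stage failed on chromosome {data.chrom}: "
                "no linkage groups could be formed (is n_progeny 0?)"
            )
        hyp_cfg = {h: DEFAULT_HYPOTHESES[h] for h in config.hypotheses}
        table, details = run_hypothesis_suite(
            analysis.aln, analysis.lg_units, hypotheses=hyp_cfg, seed=config.seed,
            n_rell_sh=config.n_rell_sh, n_rell_au=config.n_rell_au,
            au_scales=config.au_scales,
        )
        tables.append(table)
        report["chromosomes"][data.chrom] = {
            "n_maternal_lgs": len(analysis.maternal_lgs),
            "n_paternal_lgs": len(analysis.paternal_lgs),
            "n_columns": analysis.aln.n_columns,
            "n_pis": analysis.aln.pis_count(),
            "unconstrained_lnL": float(details["best"].loglik),
        }
        if with_trait:
            phenotypes = [p.phenotype for p in data.population.progeny]
            testcross = {m.marker_id: m for m in analysis.markers
                         if m.seg_class == genotyping.MATERNAL}
            trait_result = posthoc.map_trait(phenotypes, testcross,
                                             analysis.maternal_lgs)
        if outdir:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            linkmap.map_to_table(
                analysis.maternal_lgs + analysis.paternal_lgs
            ).to_csv(out / f"map_{data.chrom}.tsv", sep="\t", index=False)
            analysis.aln.to_fasta(out / f"supermatrix_{data.chrom}.fasta")
            with open(out / f"ml_tree_{data.chrom}.nwk", "w") as fh:
                fh.write(details["best"].tree.to_newick(supports=True))
    full_table = pd.concat(tables, ignore_index=True)
    report["hypothesis_table"] = full_table
    report["trait"] = trait_result
    if outdir:
        out = Path(outdir)
        full_table.to_csv(out / "hypothesis_tests.tsv", sep="\t", index=False)
        config.to_json(out / "config.json")
    return report
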