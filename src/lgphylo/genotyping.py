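"""Single-dose genotype calling from per-site allele depths.

A testcross marker in a decaploid is a SNP heterozygous on exactly one homolog
copy of one parent, so its alternate-allele read fraction in that parent is
close to 1/ploidy.  Sites are classified from the two parents' depths into
segregation classes (maternal ab x aa, paternal aa x ab, biparental ab x ab)
and progeny are scored aa / ab / missing by simple depth thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

MATERNAL = "maternal"
PATERNAL = "paternal"
BIPARENTAL = "biparental"
UNINFORMATIVE = "uninformative"

AA, AB, MISSING = 0, 1, -1


@dataclass
class DepthTable:
    """Wide view of a per-site, per-individual allele-depth table."""

    chrom: np.ndarray
    pos: np.ndarray
    individuals: list[str]
    ref: np.ndarray  # (n_sites, n_individuals)
    alt: np.ndarray
    ref_base: np.ndarray | None = None
    alt_base: np.ndarray | None = None

    def __post_init__(self):
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read depths must be non-negative")
        if (np.asarray(self.pos) < 1).any():
            raise ValueError("positions are 1-based (>= 1)")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids must be unique")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "DepthTable":
        individuals = list(pd.unique(df["individual"]))
        piv_r = df.pivot_table(index=["chrom", "pos"], columns="individual",
                               values="ref_depth", fill_value=0, sort=False)
        piv_a = df.pivot_table(index=["chrom", "pos"], columns="individual",
                               values="alt_depth", fill_value=0, sort=False)
        piv_r, piv_a = piv_r[individuals], piv_a[individuals]
        idx = piv_r.index.to_frame(index=False)
        bases = None
        if "ref_base" in df.columns and "alt_base" in df.columns:
            bases = df.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])
            bases = bases.loc[list(piv_r.index)]
        return cls(
            chrom=idx["chrom"].to_numpy(),
            pos=idx["pos"].to_numpy(),
            individuals=individuals,
            ref=piv_r.to_numpy(),
            alt=piv_a.to_numpy(),
            ref_base=None if bases is None else bases["ref_base"].to_numpy(),
            alt_base=None if bases is None else bases["alt_base"].to_numpy(),
        )

    @classmethod
    def from_tsv(cls, path) -> "DepthTable":
        return cls.from_long(pd.read_csv(path, sep="\t"))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for j, ind in enumerate(self.individuals):
            df = pd.DataFrame(
                {"chrom": self.chrom, "pos": self.pos, "individual": ind,
                 "ref_depth": self.ref[:, j], "alt_depth": self.alt[:, j]}
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


@dataclass
class MarkerCall:
    marker_id: str
    chrom: str
    pos: int
    seg_class: str
    genotypes: np.ndarray  # int8 over progeny: 0=aa, 1=ab, -1=missing
    alt_base: str | None = None

    @property
    def n_informative(self) -> int:
        return int((self.genotypes != MISSING).sum())


def _parent_state(ref_d, alt_d, ploidy, min_depth, dose_band, hom_max_frac):
    total = ref_d + alt_d
    if total < min_depth:
        return "lowdepth"
    frac = alt_d / total
    lo, hi = dose_band[0] / ploidy, dose_band[1] / ploidy
    if lo <= frac <= hi:
        return "het"
    if frac <= hom_max_frac:
        return "hom"
    return "ambiguous"


def classify_parental_site(
    maternal_depths: tuple[int, int],
    paternal_depths: tuple[int, int],
    ploidy: int = 10,
    min_depth: int = 40,
    dose_band: tuple[float, float] = (0.5, 2.0),
    hom_max_frac: float = 0.02,
) -> str:
    """Segregation class from (ref, alt) depths of the two parents.

    A parent is single-dose heterozygous when its alternate fraction falls in
    ``dose_band`` expressed in dose units (default 0.5/ploidy .. 2/ploidy) at
    depth >= ``min_depth``; homozygous when the fraction is <= ``hom_max_frac``.
    """
    if ploidy < 2 or ploidy % 2:
        raise ValueError("ploidy must be even and >= 2")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    m = _parent_state(*maternal_depths, ploidy, min_depth, dose_band, hom_max_frac)
    p = _parent_state(*paternal_depths, ploidy, min_depth, dose_band, hom_max_frac)
    if m == "het" and p == "hom":
        return MATERNAL
    if m == "hom" and p == "het":
        return PATERNAL
    if m == "het" and p == "het":
        return BIPARENTAL
    return UNINFORMATIVE


def call_progeny(
    ref_d: np.ndarray,
    alt_d: np.ndarray,
    min_depth_progeny: int = 10,
    min_alt_reads: int = 2,
) -> np.ndarray:
    """Score progeny ab / aa / missing from their (ref, alt) depth vectors."""
    total = ref_d + alt_d
    geno = np.full(ref_d.shape, MISSING, dtype=np.int8)
    geno[alt_d >= min_alt_reads] = AB
    geno[(alt_d == 0) & (total >= min_depth_progeny)] = AA
    return geno


def call_markers(
    table: DepthTable,
    mother: str = "M",
    father: str = "P",
    ploidy: int = 10,
    min_depth_parent: int = 40,
    min_depth_progeny: int = 10,
    min_alt_reads: int = 2,
    dose_band: tuple[float, float] = (0.5, 2.0),
    hom_max_frac: float = 0.02,
) -> tuple[list[MarkerCall], list[str]]:
    """Classify every site and call progeny; returns (markers, progeny ids)."""
    mi, pi_ = table.individuals.index(mother), table.individuals.index(father)
    progeny_idx = [j for j, ind in enumerate(table.individuals) if ind not in (mother, father)]
    progeny_ids = [table.individuals[j] for j in progeny_idx]
    markers = []
    for i in range(len(table.pos)):
        seg = classify_parental_site(
            (table.ref[i, mi], table.alt[i, mi]),
            (table.ref[i, pi_], table.alt[i, pi_]),
            ploidy=ploidy, min_depth=min_depth_parent,
            dose_band=dose_band, hom_max_frac=hom_max_frac,
        )
        if seg == UNINFORMATIVE:
            continue
        geno = call_progeny(
            table.ref[i, progeny_idx], table.alt[i, progeny_idx],
            min_depth_progeny=min_depth_progeny, min_alt_reads=min_alt_reads,
        )
        if (geno != MISSING).sum() == 0:
            continue
        markers.append(
            MarkerCall(
                marker_id=f"{table.chrom[i]}:{table.pos[i]}",
                chrom=str(table.chrom[i]),
                pos=int(table.pos[i]),
                seg_class=seg,
                genotypes=geno,
                alt_base=None if table.alt_base is None else str(table.alt_base[i]),
            )
        )
    return markers, progeny_ids


@dataclass
class SegregationFlag:
    keep: bool
    p_value: float | None
    reason: str


def segregation_filter(marker: MarkerCall, alpha: float = 0.01,
                       min_informative: int = 10) -> SegregationFlag:
    """Chi-square 1:1 guard for distorted testcross markers (advisory flag).

    Markers with fewer than ``min_informative`` scored progeny are passed
    through with an 'insufficient data' flag rather than tested.
    """
    n_aa = int((marker.genotypes == AA).sum())
    n_ab = int((marker.genotypes == AB).sum())
    n = n_aa + n_ab
    if n == 0:
        return SegregationFlag(True, None, "insufficient data")
    if n < min_informative:
        return SegregationFlag(True, None, "insufficient data")
    expected = n / 2.0
    stat = (n_aa - expected) ** 2 / expected + (n_ab - expected) ** 2 / expected
    p = float(chi2.sf(stat, df=1))
    if p < alpha:
        return SegregationFlag(False, p, "distorted")
    return SegregationFlag(True, p, "ok")
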