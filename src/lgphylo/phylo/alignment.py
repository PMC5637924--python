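"""Linkage-group consensus sequences and reference-projected supermatrices.

Linkage groups become phylogenetic taxa: reads carrying a group's diagnostic
(single-dose) alleles are collected, and a per-position majority consensus is
taken over them.  Because all sequences are indexed by the same reference
coordinates, the supermatrix is assembled positionally with no de novo
alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..models import AMBIGUOUS, decode_sequence, encode_sequence


def build_lg_consensus(
    marker_sites: list[tuple[int, int]],
    reads,
    seq_length: int,
) -> np.ndarray:
    """Majority consensus over reads carrying a linkage group's alleles.

    ``marker_sites`` are (1-based position, alt base code) pairs diagnostic for
    the group; a read is assigned to the group when it shows the alternate
    base at one or more of these sites.  Ties and uncovered positions are N.
    """
    if not marker_sites:
        return np.full(seq_length, AMBIGUOUS, dtype=np.uint8)
    pos = np.array([p for p, _ in marker_sites], dtype=np.int64)
    alt = np.array([a for _, a in marker_sites], dtype=np.uint8)
    order = np.argsort(pos)
    pos, alt = pos[order], alt[order]

    counts = np.zeros((seq_length, 4), dtype=np.int32)
    n_assigned = 0
    for read in reads:
        lo = np.searchsorted(pos, read.start)
        hi = np.searchsorted(pos, read.end, side="right")
        if lo == hi:
            continue
        covered = pos[lo:hi] - read.start
        if not (read.bases[covered] == alt[lo:hi]).any():
            continue
        n_assigned += 1
        sl = slice(read.start - 1, read.start - 1 + len(read.bases))
        valid = read.bases < 4
        idx = np.arange(sl.start, sl.stop)[valid]
        np.add.at(counts, (idx, read.bases[valid].astype(np.int64)), 1)

    consensus = np.full(seq_length, AMBIGUOUS, dtype=np.uint8)
    top = counts.max(axis=1)
    argtop = counts.argmax(axis=1)
    ties = (counts == top[:, None]).sum(axis=1) > 1
    covered = top > 0
    consensus[covered & ~ties] = argtop[covered & ~ties].astype(np.uint8)
    return consensus


@dataclass
class SupermatrixAlignment:
    """Reference-coordinate supermatrix over LG-consensus and diploid taxa."""

    labels: list[str]
    matrix: np.ndarray           # (n_taxa, n_cols) uint8; 4 = missing
    positions: np.ndarray        # (n_cols,) 1-based reference coordinates
    chrom: str = "I"

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("one row per taxon required")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("one reference position per column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxon labels must be unique")
        if len(np.unique(self.positions)) != len(self.positions):
            raise ValueError("columns must map to unique reference positions")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.labels.index(label)]

    def pis_count(self) -> int:
        """Parsimony-informative sites: >= 2 states each in >= 2 taxa."""
        n_pis = 0
        M = self.matrix
        for j in range(M.shape[1]):
            col = M[:, j]
            col = col[col < 4]
            if col.size < 4:
                continue
            _, counts = np.unique(col, return_counts=True)
            if (counts >= 2).sum() >= 2:
                n_pis += 1
        return int(n_pis)

    def subset(self, labels: list[str]) -> "SupermatrixAlignment":
        idx = [self.labels.index(l) for l in labels]
        return SupermatrixAlignment(list(labels), self.matrix[idx].copy(),
                                    self.positions.copy(), self.chrom)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.matrix):
                fh.write(f">{label}\n{decode_sequence(row)}\n")

    @classmethod
    def from_fasta(cls, path, chrom: str = "I") -> "SupermatrixAlignment":
        from Bio import SeqIO

        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(encode_sequence(str(rec.seq)))
        matrix = np.stack(rows)
        return cls(labels, matrix, np.arange(1, matrix.shape[1] + 1), chrom)


def build_supermatrix(
    lg_consensus: dict[str, np.ndarray],
    diploid_seqs: dict[str, np.ndarray],
    chrom: str = "I",
) -> SupermatrixAlignment:
    """Stack LG consensus and diploid rows; keep columns covered in >= 1 LG
    taxon and in every diploid."""
    if not lg_consensus or not diploid_seqs:
        raise ValueError("need at least one LG consensus and one diploid sequence")
    lg_labels = sorted(lg_consensus)
    dip_labels = sorted(diploid_seqs)
    lg_stack = np.stack([lg_consensus[l] for l in lg_labels])
    dip_stack = np.stack([diploid_seqs[l] for l in dip_labels])
    if lg_stack.shape[1] != dip_stack.shape[1]:
        raise ValueError("all sequences must share the reference coordinate system")
    keep = (lg_stack < 4).any(axis=0) & (dip_stack < 4).all(axis=0)
    if not keep.any():
        raise ValueError("no shared covered reference positions")
    cols = np.nonzero(keep)[0]
    matrix = np.vstack([lg_stack[:, cols], dip_stack[:, cols]])
    return SupermatrixAlignment(lg_labels + dip_labels, matrix, cols + 1, chrom)
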