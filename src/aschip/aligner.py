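"""A deterministic seed-and-extend aligner for desk-scale genomes.

The allele-swap remap filter only needs an aligner that (a) is deterministic,
(b) reports the leftmost reference coordinate, strand, and a uniqueness/MAPQ
signal, and (c) tolerates the short indels that allele substitution introduces.
This module provides such an aligner for the small synthetic genomes used in
tests and calibration runs: exact k-mer seeds anchor candidate loci and a
banded edit-distance alignment (edlib) extends them.  Production data should
go through the FASTQ adapter in :mod:`aschip.biasfilter` and an external
mapper instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol

import edlib

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Alignment:
    """One read placement: leftmost 0-based coordinate, strand, MAPQ, uniqueness."""

    chrom: str
    pos: int  # leftmost 0-based reference coordinate
    strand: str  # '+' or '-'
    mapq: int
    is_unique: bool
    edit_distance: int
    cigar: str  # extended CIGAR (=/X/I/D) of the placement


class AlignerInterface(Protocol):
    """Contract for pluggable aligners; no engine is mandated."""

    def align(self, seq: str) -> Alignment | None:  # pragma: no cover - protocol
        """Best placement of ``seq`` on the reference, or None if unmapped."""
        ...


class KmerAligner:
    """Exact-seed + banded-extend aligner over an in-memory genome.

    Parameters
    ----------
    genome : mapping of chromosome name to sequence string.
    k : seed length; seeds are taken at the start, middle, and end of the read.
    max_edit_distance : maximum edit distance for a valid placement.  The
        default (5, roughly what production mappers tolerate on 75 bp reads)
        means reads carrying longer indels fail to place — exactly the
        reference-bias failure mode the allele-swap filter exists to
        neutralise.  A stricter cap makes the bias correspondingly harsher.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 16, max_edit_distance: int = 5):
        self.k = k
        self.max_edit_distance = max_edit_distance
        self.genome = {c: str(genome[c]).upper() for c in genome}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(self.genome):
            seq = self.genome[chrom]
            for i in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def align(self, seq: str) -> Alignment | None:
        seq = seq.upper()
        hits: dict[tuple[str, str, int], tuple[int, str]] = {}
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for chrom, anchor in self._candidates(s):
                placed = self._extend(s, chrom, anchor)
                if placed is None:
                    continue
                pos, dist, cigar = placed
                key = (chrom, strand, pos)
                if key not in hits or dist < hits[key][0]:
                    hits[key] = (dist, cigar)
        if not hits:
            return None
        # Merge placements within max_edit_distance of each other on the same
        # chrom/strand: they are the same locus reached from different seeds.
        loci: list[tuple[str, str, int, int, str]] = []
        for (chrom, strand, pos), (dist, cigar) in sorted(hits.items()):
            merged = False
            for i, (c2, s2, p2, d2, cg2) in enumerate(loci):
                if c2 == chrom and s2 == strand and abs(pos - p2) <= self.max_edit_distance:
                    if dist < d2:
                        loci[i] = (chrom, strand, pos, dist, cigar)
                    merged = True
                    break
            if not merged:
                loci.append((chrom, strand, pos, dist, cigar))
        best = min(d for *_x, d, _c in loci)
        top = [l for l in loci if l[3] == best]
        chrom, strand, pos, dist, cigar = top[0]
        unique = len(top) == 1
        return Alignment(chrom, pos, strand, 60 if unique else 0, unique, dist, cigar)

    def _candidates(self, s: str) -> set[tuple[str, int]]:
        n, k = len(s), self.k
        if n < k:
            return set()
        cands: set[tuple[str, int]] = set()
        for off in {0, (n - k) // 2, n - k}:
            for chrom, pos in self._index.get(s[off : off + k], ()):
                cands.add((chrom, pos - off))
        return cands

    def _extend(self, s: str, chrom: str, anchor: int) -> tuple[int, int, str] | None:
        ref = self.genome[chrom]
        pad = self.max_edit_distance + 2
        w0 = max(0, anchor - pad)
        w1 = min(len(ref), anchor + len(s) + pad)
        res = edlib.align(s, ref[w0:w1], mode="HW", task="path", k=self.max_edit_distance)
        if res["editDistance"] < 0:
            return None
        loc = res["locations"][0]
        return w0 + loc[0], res["editDistance"], res["cigar"]


@dataclass(frozen=True)
class PairAlignment:
    mate1: Alignment
    mate2: Alignment
    proper: bool


def align_pair(
    aligner: AlignerInterface, seq1: str, seq2: str, max_insert: int = 2000
) -> PairAlignment | None:
    """Align two mates independently and flag FR proper pairing."""
    a1 = aligner.align(seq1)
    a2 = aligner.align(seq2)
    if a1 is None or a2 is None:
        return None
    proper = (
        a1.chrom == a2.chrom
        and a1.strand != a2.strand
        and abs(a1.pos - a2.pos) <= max_insert
    )
    return PairAlignment(a1, a2, proper)
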