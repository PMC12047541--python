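"""Indel-aware removal of reference-mapping bias from aligned ChIP-seq reads.

Reads carrying non-reference alleles — indels above all — map worse against
the reference genome, so naive allele counting inflates the REF allele.  The
filter implemented here removes that bias symmetrically: every read pair that
overlaps a panel variant is rewritten into all allele combinations of the
variants it touches, each version is remapped, and the pair survives only if
*every* version maps uniquely (MAPQ > 10) back to the original locus.  Loci
where any allele maps poorly therefore lose reads from *both* haplotypes,
leaving the surviving allelic ratio unbiased.  A final random de-duplication
avoids the reference bias of best-quality-read dedup.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pysam

from .aligner import AlignerInterface
from .variants import PhasedGenotypePanel, Variant, haplotype_sequence

logger = logging.getLogger(__name__)

DEFAULT_MAX_COMBINATIONS = 64


class UnsortedBamError(ValueError):
    """Input BAM is not coordinate-sorted; sort it first."""


class AlignerFailure(RuntimeError):
    """The remap aligner failed; reads are never silently kept."""


@dataclass
class MateInfo:
    """Original placement of one mate (leftmost coordinate, forward-strand SEQ)."""

    chrom: str
    ref_start: int  # 0-based leftmost
    length: int
    is_reverse: bool
    seq: str


@dataclass
class ReadVersionSet:
    """A read pair plus its allele-swapped versions and filter status."""

    read_id: str
    mates: tuple[MateInfo, MateInfo]
    overlapped_variants: list[Variant] = field(default_factory=list)
    versions: list[tuple[tuple[str, str], tuple[int, ...]]] = field(default_factory=list)
    status: str = "pending"  # pending | kept | dropped
    reason: str | None = None
    _reads: tuple = ()  # original pysam records, for output writing

    def drop(self, reason: str) -> "ReadVersionSet":
        self.status, self.reason = "dropped", reason
        return self

    def keep(self) -> "ReadVersionSet":
        self.status, self.reason = "kept", None
        return self


# ---------------------------------------------------------------------------
# Pair iteration and variant intersection
# ---------------------------------------------------------------------------

def _check_sorted(bam: pysam.AlignmentFile) -> None:
    so = bam.header.get("HD", {}).get("SO")
    if so != "coordinate":
        raise UnsortedBamError(
            f"{bam.filename.decode()}: BAM must be coordinate-sorted (SO={so}); "
            "run samtools sort / pysam.sort first"
        )


def iter_pairs(bam: pysam.AlignmentFile) -> Iterator[tuple[pysam.AlignedSegment, pysam.AlignedSegment]]:
    """Yield primary proper read pairs; mate-unmapped reads are dropped."""
    pending: dict[str, pysam.AlignedSegment] = {}
    for read in bam.fetch(until_eof=True):
        if read.is_secondary or read.is_supplementary or read.is_unmapped:
            continue
        if read.mate_is_unmapped or not read.is_paired:
            continue
        other = pending.pop(read.query_name, None)
        if other is None:
            pending[read.query_name] = read
        else:
            yield (other, read) if other.reference_start <= read.reference_start else (read, other)


def find_intersecting_reads(
    bam_path: str,
    panel: PhasedGenotypePanel,
    passthrough=None,
) -> Iterator[ReadVersionSet]:
    """Stream read pairs whose aligned span intersects a panel variant.

    A pair is emitted iff at least one mate's aligned reference span
    intersects a variant's reference span.  Non-intersecting pairs are passed
    to the ``passthrough`` callback (if given) untouched.
    """
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        _check_sorted(bam)
        for r1, r2 in iter_pairs(bam):
            idxs: set[int] = set()
            for r in (r1, r2):
                idxs.update(panel.overlapping(r.reference_name, r.reference_start, r.reference_end))
            if not idxs:
                if passthrough is not None:
                    passthrough(r1, r2)
                continue
            variants = sorted((panel.variants[i] for i in idxs), key=lambda v: v.start0)
            mates = tuple(
                MateInfo(r.reference_name, r.reference_start, r.query_length, r.is_reverse,
                         r.query_sequence.upper())
                for r in (r1, r2)
            )
            yield ReadVersionSet(r1.query_name, mates, overlapped_variants=variants,
                                 _reads=(r1, r2))


# ---------------------------------------------------------------------------
# Allele-version enumeration
# ---------------------------------------------------------------------------

def _rebuild_mate(
    mate: MateInfo,
    variants: Sequence[Variant],
    assignment: Sequence[int],
    genome: Mapping[str, str],
) -> str:
    """Mate sequence under one allele assignment, anchored at the leftmost coordinate.

    The sequence is rebuilt from the corresponding haplotype starting at the
    mate's leftmost reference coordinate and trimmed/extended with haplotype
    flanking sequence to preserve read length (indel-aware).  Anchoring at the
    leftmost end keeps the leftmost mapping coordinate invariant across
    versions, which is what the remap comparison requires.
    """
    slack = sum(len(v.ref) for v in variants) + mate.length + 30
    w_start0 = min([mate.ref_start] + [v.start0 for v in variants])
    w_end0 = mate.ref_start + mate.length + slack
    chrom_len = len(genome[mate.chrom])
    w_end0 = min(w_end0, chrom_len)
    alleles = {
        v: a
        for v, a in zip(variants, assignment)
        if v.start0 >= w_start0 and v.end0 <= w_end0
    }
    seq, cmap = haplotype_sequence(genome, mate.chrom, w_start0 + 1, w_end0, alleles)
    h0 = cmap.to_hap(mate.ref_start - w_start0, snap="right")
    return seq[h0 : h0 + mate.length]


def enumerate_allele_versions(
    rvs: ReadVersionSet,
    genome: Mapping[str, str],
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
) -> ReadVersionSet:
    """Populate ``rvs.versions`` with all 2^h allele assignments.

    ``h`` is the number of biallelic variants overlapped by either mate; the
    original allele assignment is among the enumerated versions, so unstable
    loci are caught even when no swap is involved.  Pairs exceeding
    ``max_combinations`` versions are dropped with reason
    ``"too_many_combinations"``.
    """
    h = len(rvs.overlapped_variants)
    if 2**h > max_combinations:
        return rvs.drop("too_many_combinations")
    versions = []
    for assignment in itertools.product((0, 1), repeat=h):
        seqs = tuple(
            _rebuild_mate(m, rvs.overlapped_variants, assignment, genome) for m in rvs.mates
        )
        versions.append((seqs, assignment))
    rvs.versions = versions
    return rvs


# ---------------------------------------------------------------------------
# Remap filter
# ---------------------------------------------------------------------------

def remap_filter(rvs: ReadVersionSet, aligner: AlignerInterface) -> ReadVersionSet:
    """Keep the pair iff every version of both mates remaps to the original locus.

    Required per mate: unique placement, MAPQ > 10, same chromosome, same
    leftmost coordinate, forward orientation of the rebuilt (forward-strand)
    sequence.  Otherwise the pair is dropped with the first failing reason
    among unmapped / multimapped / low_mapq / moved.
    """
    if not rvs.versions:
        raise ValueError(f"{rvs.read_id}: versions not enumerated")
    for (seq1, seq2), _assignment in rvs.versions:
        for mate, seq in zip(rvs.mates, (seq1, seq2)):
            try:
                aln = aligner.align(seq)
            except Exception as exc:  # noqa: BLE001 - deliberate re-raise as hard error
                raise AlignerFailure(f"aligner failed on {rvs.read_id}") from exc
            if aln is None:
                return rvs.drop("unmapped")
            if not aln.is_unique:
                return rvs.drop("multimapped")
            if aln.mapq <= 10:
                return rvs.drop("low_mapq")
            if aln.chrom != mate.chrom or aln.pos != mate.ref_start or aln.strand != "+":
                return rvs.drop("moved")
    return rvs.keep()


# ---------------------------------------------------------------------------
# Random de-duplication
# ---------------------------------------------------------------------------

def dedup_random(bam_in: str, bam_out: str, seed: int) -> dict[str, int]:
    """Keep one pair per duplicate group, chosen uniformly at random.

    Duplicate groups share both mates' (chrom, leftmost coordinate,
    orientation).  The survivor is drawn with a generator seeded by ``seed``
    over the group's name-sorted members, so the output is identical across
    runs and independent of input order.
    """
    groups: dict[tuple, list[str]] = {}
    with pysam.AlignmentFile(bam_in, "rb") as bam:
        _check_sorted(bam)
        for r1, r2 in iter_pairs(bam):
            key = tuple(sorted(
                (r.reference_name, r.reference_start, r.is_reverse) for r in (r1, r2)
            ))
            groups.setdefault(key, []).append(r1.query_name)
    rng = np.random.default_rng(seed)
    survivors: set[str] = set()
    for key in sorted(groups):
        names = sorted(groups[key])
        survivors.add(names[rng.integers(len(names))])
    with pysam.AlignmentFile(bam_in, "rb") as bam, pysam.AlignmentFile(
        bam_out, "wb", template=bam
    ) as out:
        for read in bam.fetch(until_eof=True):
            if read.query_name in survivors:
                out.write(read)
    pysam.index(bam_out)
    n_dup = sum(len(v) - 1 for v in groups.values())
    logger.info("dedup_random: %d groups, removed %d duplicate pairs", len(groups), n_dup)
    return {"groups": len(groups), "removed_pairs": n_dup}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def filter_bam(
    bam_in: str,
    bam_out: str,
    panel: PhasedGenotypePanel,
    genome: Mapping[str, str],
    aligner: AlignerInterface,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
) -> dict[str, int]:
    """Run intersect → enumerate → remap over a BAM; write surviving reads.

    Non-intersecting pairs pass through untouched.  Returns drop-reason
    counts.  Output is coordinate-sorted and indexed.
    """
    stats = {"passthrough": 0, "kept": 0, "too_many_combinations": 0, "unmapped": 0,
             "multimapped": 0, "low_mapq": 0, "moved": 0}
    tmp = bam_out + ".unsorted.bam"
    with pysam.AlignmentFile(bam_in, "rb") as src:
        header = src.header.to_dict()
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        def passthrough(r1, r2):
            stats["passthrough"] += 1
            out.write(r1)
            out.write(r2)

        for rvs in find_intersecting_reads(bam_in, panel, passthrough=passthrough):
            enumerate_allele_versions(rvs, genome, max_combinations)
            if rvs.status != "dropped":
                remap_filter(rvs, aligner)
            if rvs.status == "kept":
                stats["kept"] += 1
                for r in rvs._reads:
                    out.write(r)
            else:
                stats[rvs.reason] += 1
    pysam.sort("-o", bam_out, tmp)
    pysam.index(bam_out)
    import os

    os.remove(tmp)
    logger.info("filter_bam(%s): %s", bam_in, stats)
    return stats


def run_bias_filter(
    bam_in: str,
    bam_out: str,
    panel: PhasedGenotypePanel,
    genome: Mapping[str, str],
    aligner: AlignerInterface,
    seed: int,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
) -> dict[str, int]:
    """Full bias removal: remap filter followed by random de-duplication."""
    mid = bam_out + ".filtered.bam"
    stats = filter_bam(bam_in, mid, panel, genome, aligner, max_combinations)
    stats.update(dedup_random(mid, bam_out, seed))
    import os

    os.remove(mid)
    if os.path.exists(mid + ".bai"):
        os.remove(mid + ".bai")
    return stats


def write_versions_fastq(
    versions: Iterator[ReadVersionSet], fq1_path: str, fq2_path: str
) -> int:
    """Adapter for external mappers: emit every allele version as paired FASTQ.

    Read names encode the pair id, version index, and expected locus so an
    external remapping run can be checked with :func:`remap_filter` semantics.
    """
    n = 0
    with open(fq1_path, "w") as f1, open(fq2_path, "w") as f2:
        for rvs in versions:
            for vi, ((s1, s2), _a) in enumerate(rvs.versions):
                name = f"{rvs.read_id}|v{vi}|{rvs.mates[0].chrom}:{rvs.mates[0].ref_start}:{rvs.mates[1].ref_start}"
                f1.write(f"@{name}\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@{name}\n{s2}\n+\n{'I' * len(s2)}\n")
                n += 1
    return n
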