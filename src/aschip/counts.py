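"""Consensus peaks, target regions, and total / allele-specific read counts.

A *target region* is a ±radius window around a consensus-peak summit; every
panel variant inside it becomes a *test variant* paired with that region.
Per sample the region carries a total fragment count ``T``, an adjusted
expected count ``E`` (library size, GC, fraction-of-reads-in-peaks), the test
variant genotype, and — through the phase — fragment-level allele-specific
counts assigned to the maternal or paternal haplotype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .variants import PhasedGenotypePanel, Variant, _max_ref_len, haplotype_sequence

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    chrom: str
    start: int  # 0-based half-open
    end: int
    summit: int  # absolute position, start <= summit < end
    n_lines: int = 0

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start}, {self.end})")


def read_peaks_bed(path: str) -> list[Peak]:
    """Read BED or narrowPeak; narrowPeak column 10 supplies the summit offset."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            summit = start + int(f[9]) if len(f) >= 10 and f[9] != "-1" else (start + end) // 2
            peaks.append(Peak(chrom, start, end, summit))
    return peaks


def consensus_peaks(
    per_line_peaks: Sequence[Sequence[Peak] | Sequence[tuple]],
    pooled_coverage: Mapping[str, np.ndarray],
    min_lines: int = 3,
) -> list[Peak]:
    """Merge per-line peak sets into consensus peaks supported by >= min_lines.

    Intervals sharing at least 1 bp are transitively merged; a line supports a
    merged interval if any of its peaks overlaps it.  The summit is the argmax
    of pooled per-base coverage inside the merged interval (leftmost on ties).
    """
    if not per_line_peaks or all(len(p) == 0 for p in per_line_peaks):
        warnings.warn("consensus_peaks: no input peaks", stacklevel=2)
        return []
    if len(per_line_peaks) < min_lines:
        raise ValueError(f"need >= {min_lines} peak sets, got {len(per_line_peaks)}")
    intervals: list[tuple[str, int, int, int]] = []
    for line_i, peak_set in enumerate(per_line_peaks):
        for p in peak_set:
            chrom, start, end = (p.chrom, p.start, p.end) if isinstance(p, Peak) else p[:3]
            intervals.append((chrom, start, end, line_i))
    out: list[Peak] = []
    intervals.sort()
    i = 0
    while i < len(intervals):
        chrom, start, end, line_i = intervals[i]
        lines = {line_i}
        j = i + 1
        while j < len(intervals) and intervals[j][0] == chrom and intervals[j][1] < end:
            end = max(end, intervals[j][2])
            lines.add(intervals[j][3])
            j += 1
        if len(lines) >= min_lines:
            cov = np.asarray(pooled_coverage[chrom][start:end])
            summit = start + int(np.argmax(cov))
            out.append(Peak(chrom, start, end, summit, n_lines=len(lines)))
        i = j
    return out


# ---------------------------------------------------------------------------
# Allele calling on aligned fragments
# ---------------------------------------------------------------------------

def _variant_contexts(
    genome: Mapping[str, str],
    panel: PhasedGenotypePanel,
    sample_idx: int,
    variant_idx: int,
    flank: int = 10,
) -> tuple[str, str]:
    """Expected read context of a het variant on each phased haplotype.

    The context is the variant's allele plus ``flank`` bases of *haplotype*
    sequence on each side — neighbouring variants carry the sample's own
    phased alleles, so clustered variants sharpen rather than break the
    match.  Returns (maternal context, paternal context).
    """
    v = panel.variants[variant_idx]
    chrom_len = len(genome[v.chrom])
    pad = flank + 3 * _max_ref_len(panel.variants, [variant_idx]) + 25
    w0 = max(0, v.start0 - pad)
    w1 = min(chrom_len, v.end0 + pad)
    out = []
    for hap_side in (0, 1):
        alleles = {
            panel.variants[i]: int(panel.gt[i, sample_idx, hap_side])
            for i in panel.overlapping(v.chrom, w0, w1)
            if panel.variants[i].start0 >= w0 and panel.variants[i].end0 <= w1
        }
        seq, cmap = haplotype_sequence(genome, v.chrom, w0 + 1, w1, alleles)
        vs = cmap.to_hap(v.start0 - w0, snap="right")
        allele = v.allele(int(panel.gt[variant_idx, sample_idx, hap_side]))
        out.append(seq[max(0, vs - flank) : vs + len(allele) + flank])
    return out[0], out[1]


def _call_haplotype(
    reads: Sequence[pysam.AlignedSegment],
    v: Variant,
    m_ctx: str,
    p_ctx: str,
) -> tuple[str | None, int]:
    """Assign a fragment to the maternal or paternal haplotype at one variant.

    A mate votes for the haplotype whose expected context it contains as an
    exact substring.  Context matching is position-free, so it is robust both
    to gap-placement ambiguity in alignments and to slightly misplaced reads.
    Returns ('M' | 'P' | 'other' | None, quality): "other" when a mate spans
    the site but matches neither context (sequencing error or non-panel
    allele); None when no mate fully spans the variant.
    """
    best: tuple[str, int] | None = None
    spans = False
    for read in reads:
        if read.reference_start <= v.start0 - 2 and read.reference_end >= v.end0 + 2:
            spans = True
        seq = read.query_sequence
        quals = read.query_qualities
        hits = []
        for code, ctx in (("M", m_ctx), ("P", p_ctx)):
            off = seq.find(ctx)
            if off >= 0:
                hits.append((code, min(int(q) for q in quals[off : off + len(ctx)])))
        if len(hits) != 1:  # no match, or ambiguous repeat matching both
            continue
        if best is None or hits[0][1] > best[1]:
            best = hits[0]
    if best is not None:
        return best
    return ("other", 0) if spans else (None, 0)


@dataclass
class RegionCounts:
    """Per-sample counting result for one target region."""

    n_fragments: int
    as_m: int  # fragments assigned to the maternal haplotype
    as_p: int  # fragments assigned to the paternal haplotype
    per_variant: dict[str, np.ndarray]  # id -> [ref, alt, other] fragment counts


def count_alleles(
    bam_path: str,
    panel: PhasedGenotypePanel,
    sample: str,
    chrom: str,
    start0: int,
    end0: int,
    min_base_quality: int = 10,
    genome: Mapping[str, str] | None = None,
    context_flank: int = 10,
) -> RegionCounts:
    """Count total and haplotype-assigned fragments for one sample and region.

    Fragments are assigned at each covered heterozygous site by exact match
    against the two phased haplotype contexts (:func:`_variant_contexts`).
    Each fragment contributes at most one allele-specific observation: among
    its confidently called sites, the one with the highest base quality
    (leftmost on ties) decides the haplotype.  Per-variant counts tally every
    covered heterozygous site once per fragment; calls below
    ``min_base_quality`` are ignored and spanning fragments matching neither
    haplotype are counted as "other".
    """
    if genome is None:
        raise ValueError("count_alleles requires the reference genome for "
                         "haplotype context matching")
    si = panel.sample_index(sample)
    het_idx = [i for i in panel.overlapping(chrom, start0, end0) if panel.is_het(i, si)]
    het_variants = [
        (i, panel.variants[i], *_variant_contexts(genome, panel, si, i, context_flank))
        for i in het_idx
    ]
    per_variant = {panel.variants[i].id: np.zeros(3, dtype=int) for i in het_idx}
    n_fragments = as_m = as_p = 0
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for r1, r2 in _pairs_in_region(bam, chrom, start0, end0):
            n_fragments += 1
            calls: list[tuple[int, int, int, str]] = []  # (-qual, pos, vidx, hap)
            for vidx, v, m_ctx, p_ctx in het_variants:
                hap, qual = _call_haplotype((r1, r2), v, m_ctx, p_ctx)
                if hap is None:
                    continue
                if hap == "other":
                    per_variant[v.id][2] += 1
                    continue
                if qual < min_base_quality:
                    continue
                allele = panel.gt[vidx, si, 0 if hap == "M" else 1]
                per_variant[v.id][int(allele)] += 1
                calls.append((-qual, v.start0, vidx, hap))
            if not calls:
                continue
            _, _, vidx, hap = min(calls)
            if hap == "M":
                as_m += 1
            else:
                as_p += 1
    return RegionCounts(n_fragments, as_m, as_p, per_variant)


def _pairs_in_region(bam: pysam.AlignmentFile, chrom: str, start0: int, end0: int):
    """Primary pairs with either mate overlapping the region, each pair once."""
    seen: dict[str, pysam.AlignedSegment] = {}
    done: set[str] = set()
    for read in bam.fetch(chrom, start0, end0):
        if read.is_secondary or read.is_supplementary or read.is_unmapped:
            continue
        if read.query_name in done:
            continue
        other = seen.pop(read.query_name, None)
        if other is not None:
            done.add(read.query_name)
            yield (other, read)
        else:
            seen[read.query_name] = read
    # mates whose partner lies outside the fetch window
    for name, read in sorted(seen.items()):
        try:
            mate = bam.mate(read)
        except ValueError:
            continue
        done.add(name)
        yield (read, mate) if read.reference_start <= mate.reference_start else (mate, read)


# ---------------------------------------------------------------------------
# Region tests
# ---------------------------------------------------------------------------

@dataclass
class RegionTest:
    """One (target region, test variant) unit: the combined haplotype test's input."""

    region_id: str
    chrom: str
    start: int
    end: int
    variant: Variant
    samples: list[str]
    T: np.ndarray  # total fragment counts per sample
    E: np.ndarray  # adjusted expected counts per sample
    g: np.ndarray  # ALT copies (0/1/2) of the test variant per sample
    phase: np.ndarray  # (n_samples, 2) maternal/paternal allele of the test variant
    as_m: np.ndarray  # region allele-specific counts on the maternal haplotype
    as_p: np.ndarray
    summit: int = -1

    def __post_init__(self) -> None:
        for name in ("T", "E", "g", "as_m", "as_p"):
            setattr(self, name, np.asarray(getattr(self, name)))
        self.phase = np.asarray(self.phase, dtype=np.int8)

    @property
    def het(self) -> np.ndarray:
        return self.phase[:, 0] != self.phase[:, 1]

    @property
    def as_ref(self) -> np.ndarray:
        """AS counts on the haplotype carrying the test variant's REF allele (het only)."""
        ref_on_maternal = self.phase[:, 0] == 0
        return np.where(ref_on_maternal, self.as_m, self.as_p)

    @property
    def as_alt(self) -> np.ndarray:
        ref_on_maternal = self.phase[:, 0] == 0
        return np.where(ref_on_maternal, self.as_p, self.as_m)

    def relative_counts(self) -> np.ndarray:
        """100 x total / expected region read counts per sample."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return 100.0 * self.T / self.E


def define_region_tests(
    peaks: Sequence[Peak],
    panel: PhasedGenotypePanel,
    bam_paths: Mapping[str, str],
    genome: Mapping[str, str] | None = None,
    radius: int = 2500,
    min_read_count: int = 400,
    min_as_count: int = 50,
    min_het_count: int = 1,
    min_minor_allele_count: int = 1,
    min_base_quality: int = 10,
    frip: Mapping[str, float] | None = None,
) -> tuple[list[RegionTest], dict[str, int]]:
    """Build all (region, variant) tests passing the four count filters.

    ``min_read_count`` applies to the region total across all samples,
    ``min_as_count`` to allele-specific reads summed over samples heterozygous
    at the test variant; thresholds are inclusive.  Returns the tests plus
    filter-attrition counts.
    """
    samples = list(bam_paths)
    chrom_len = {c: len(genome[c]) for c in genome} if genome is not None else {}
    region_counts: dict[int, dict[str, RegionCounts]] = {}
    regions: list[tuple[int, Peak, int, int]] = []
    for pi, peak in enumerate(peaks):
        r0 = max(0, peak.summit - radius)
        r1 = peak.summit + radius
        if peak.chrom in chrom_len:
            r1 = min(r1, chrom_len[peak.chrom])
        regions.append((pi, peak, r0, r1))
        region_counts[pi] = {
            s: count_alleles(bam_paths[s], panel, s, peak.chrom, r0, r1,
                             min_base_quality, genome=genome)
            for s in samples
        }
    totals = pd.DataFrame(
        {s: [region_counts[pi][s].n_fragments for pi, *_ in regions] for s in samples},
        index=[pi for pi, *_ in regions],
    )
    gc = None
    if genome is not None:
        gc = pd.Series(
            [_gc_fraction(genome, p.chrom, r0, r1) for _, p, r0, r1 in regions],
            index=totals.index,
        )
    E = adjust_expected_counts(totals, gc=gc, frip=frip).E

    attrition = {"candidates": 0, "fail_read_count": 0, "fail_as_count": 0,
                 "fail_het_count": 0, "fail_minor_allele": 0, "no_genotyped": 0, "passed": 0}
    tests: list[RegionTest] = []
    for pi, peak, r0, r1 in regions:
        counts = region_counts[pi]
        T = totals.loc[pi].to_numpy()
        Ei = E.loc[pi].to_numpy()
        if T.sum() < min_read_count:
            n_var = len(panel.overlapping(peak.chrom, r0, r1))
            attrition["candidates"] += n_var
            attrition["fail_read_count"] += n_var
            continue
        for vidx in panel.overlapping(peak.chrom, r0, r1):
            attrition["candidates"] += 1
            v = panel.variants[vidx]
            phase = panel.gt[vidx]
            g = phase.sum(axis=1)
            het = phase[:, 0] != phase[:, 1]
            if het.sum() < min_het_count:
                attrition["fail_het_count"] += 1
                continue
            alt_chroms = int(g.sum())
            minor = min(alt_chroms, 2 * len(samples) - alt_chroms)
            if minor < min_minor_allele_count:
                attrition["fail_minor_allele"] += 1
                continue
            as_m = np.array([counts[s].as_m for s in samples])
            as_p = np.array([counts[s].as_p for s in samples])
            if (as_m + as_p)[het].sum() < min_as_count:
                attrition["fail_as_count"] += 1
                continue
            attrition["passed"] += 1
            tests.append(RegionTest(
                region_id=f"region_{pi}", chrom=peak.chrom, start=r0, end=r1,
                variant=v, samples=samples, T=T, E=Ei, g=g, phase=phase,
                as_m=as_m, as_p=as_p, summit=peak.summit,
            ))
    logger.info("define_region_tests: %s", attrition)
    return tests, attrition


def _gc_fraction(genome: Mapping[str, str], chrom: str, start0: int, end0: int) -> float:
    seq = str(genome[chrom][start0:end0]).upper()
    return (seq.count("G") + seq.count("C")) / max(1, len(seq))


# ---------------------------------------------------------------------------
# Expected-count adjustment
# ---------------------------------------------------------------------------

@dataclass
class ExpectedCounts:
    E: pd.DataFrame
    gc_factors: pd.DataFrame | None  # per (sample, GC bin) median ratio


def adjust_expected_counts(
    totals: pd.DataFrame,
    gc: pd.Series | None = None,
    frip: Mapping[str, float] | None = None,
    n_gc_bins: int = 4,
) -> ExpectedCounts:
    """Expected per-sample region counts from library size, GC, and FRiP.

    ``totals`` is regions x samples.  The baseline expectation splits each
    region's pooled total by the samples' effective library shares (library
    size scaled by fraction-of-reads-in-peaks when given).  A quartile-binned
    median-ratio GC factor per sample then corrects sample-specific GC trends.
    Rows are rescaled at the end so that sum_i E_i = sum_i T_i per region.
    """
    if len(totals) < 20:
        warnings.warn(
            f"adjust_expected_counts: only {len(totals)} regions; "
            "GC/FRiP fitting may be unstable", stacklevel=2,
        )
    frip_w = pd.Series(1.0, index=totals.columns)
    if frip is not None:
        frip_w = pd.Series(frip)[totals.columns]
    lib = totals.sum(axis=0).astype(float) * frip_w
    share = lib / lib.sum()

    # Only *relative* factors across samples within a GC bin are identifiable
    # (region effects absorb any trend shared by all samples), so the factor
    # fit works on per-region library-normalized compositions.
    gc_factors = None
    if gc is not None:
        try:
            bins = pd.qcut(gc, n_gc_bins, labels=False, duplicates="drop")
        except ValueError:
            bins = pd.Series(0, index=gc.index)
        if bins.nunique() < 2:
            warnings.warn("adjust_expected_counts: degenerate GC bins; factor fixed at 1",
                          stacklevel=2)
        else:
            normed = totals.div(lib, axis=1)
            comp = normed.div(normed.sum(axis=1), axis=0)  # library-free composition
            med = comp.groupby(bins.values).median()
            med = med.where(np.isfinite(med) & (med > 0), np.nan)
            factors = med.div(med.mean(axis=1), axis=0)  # per-bin mean 1 across samples
            gc_factors = factors.fillna(1.0)

    if gc_factors is not None:
        corr = gc_factors.reindex(np.asarray(bins.values)).to_numpy()
        weights = share.to_numpy()[None, :] * corr
    else:
        weights = np.broadcast_to(share.to_numpy()[None, :], totals.shape)
    weights = weights / weights.sum(axis=1, keepdims=True)
    E = pd.DataFrame(totals.sum(axis=1).to_numpy()[:, None] * weights,
                     index=totals.index, columns=totals.columns)
    return ExpectedCounts(E=E, gc_factors=gc_factors)


def region_tests_to_frame(tests: Sequence[RegionTest]) -> pd.DataFrame:
    """Tidy TSV-ready table: one row per (region, variant, sample)."""
    rows = []
    for rt in tests:
        for j, s in enumerate(rt.samples):
            rows.append({
                "region_id": rt.region_id, "variant_id": rt.variant.id, "sample": s,
                "g": int(rt.g[j]), "T": int(rt.T[j]), "E": float(rt.E[j]),
                "as_ref": int(rt.as_ref[j]) if rt.het[j] else 0,
                "as_alt": int(rt.as_alt[j]) if rt.het[j] else 0,
                "het": bool(rt.het[j]),
            })
    return pd.DataFrame(rows)
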