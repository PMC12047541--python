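"""Variant panels, F1 phasing, and haplotype sequence construction.

The experimental design this package targets is a set of F1 hybrid crosses:
every variant at which the two inbred parents differ is heterozygous in the
offspring with known phase, so allele-specific read counts can be assigned to
the maternal or paternal haplotype without statistical phasing.

Conventions
-----------
VCF coordinates are 1-based; everything internal is 0-based half-open.
Conversion happens only at the I/O boundary (``load_variants``,
``write_panel_vcf``).  A variant occupies the reference interval
``[pos0, pos0 + len(ref))``.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Malformed VCF record; message names the offending line."""


class UnphasedGenotypeError(ValueError):
    """Heterozygous genotype without a phase separator."""


class OverlappingVariantsError(ValueError):
    """Two chosen variants occupy overlapping reference intervals."""


@dataclass(frozen=True)
class Variant:
    """One biallelic SNP or indel.

    ``pos`` is the 1-based coordinate of the first REF base (VCF style, with
    indels left-anchored on a shared first base).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele in {self.chrom}:{self.pos}")
        if set(self.ref) - _BASES or set(self.alt) - _BASES:
            raise ValueError(f"non-ACGT allele in {self.chrom}:{self.pos}:{self.ref}:{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snp"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def start0(self) -> int:
        """0-based start of the reference span."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based half-open end of the reference span."""
        return self.pos - 1 + len(self.ref)

    def allele(self, code: int) -> str:
        return self.ref if code == 0 else self.alt


@dataclass
class PhasedGenotypePanel:
    """Ordered variant list with fully phased genotypes per sample.

    ``gt[i, j]`` is the ordered (maternal, paternal) allele pair of sample
    ``j`` at variant ``i``; alleles are 0 (REF) or 1 (ALT).
    """

    variants: list[Variant]
    samples: list[str]
    gt: np.ndarray  # (n_variants, n_samples, 2) int8
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        n, s = len(self.variants), len(self.samples)
        if self.gt.shape != (n, s, 2):
            raise ValueError(f"gt shape {self.gt.shape} != ({n}, {s}, 2)")
        self._index: dict[str, tuple[list[int], list[int]]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, v in enumerate(self.variants):
            by_chrom.setdefault(v.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            idx.sort(key=lambda i: self.variants[i].start0)
            self._index[chrom] = (idx, [self.variants[i].start0 for i in idx])
        self._by_id = {v.id: i for i, v in enumerate(self.variants)}

    def __len__(self) -> int:
        return len(self.variants)

    def index_of(self, variant_id: str) -> int:
        return self._by_id[variant_id]

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def is_het(self, variant_idx: int, sample_idx: int) -> bool:
        m, p = self.gt[variant_idx, sample_idx]
        return m != p

    def alt_copies(self, variant_idx: int, sample_idx: int) -> int:
        return int(self.gt[variant_idx, sample_idx].sum())

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[int]:
        """Indices of variants whose reference span intersects [start0, end0)."""
        if chrom not in self._index:
            return []
        idx, starts = self._index[chrom]
        # Reference spans are short (<= longest indel); scan a padded window.
        lo = bisect_left(starts, start0 - _max_ref_len(self.variants, idx))
        hi = bisect_right(starts, end0)
        out = []
        for k in range(lo, hi):
            v = self.variants[idx[k]]
            if v.start0 < end0 and v.end0 > start0:
                out.append(idx[k])
        return out

    def subset_samples(self, keep: Sequence[str]) -> "PhasedGenotypePanel":
        cols = [self.samples.index(s) for s in keep]
        return PhasedGenotypePanel(self.variants, list(keep), self.gt[:, cols, :])


def _max_ref_len(variants: Sequence[Variant], idx: Sequence[int]) -> int:
    return max((len(variants[i].ref) for i in idx), default=1)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def load_variants(
    vcf_path: str,
    require_biallelic: bool = True,
    assume_parental_phase: bool = False,
) -> PhasedGenotypePanel:
    """Read a VCF with phased GT fields into a :class:`PhasedGenotypePanel`.

    Multiallelic records and records with missing genotypes are dropped when
    ``require_biallelic`` is set (counts retained in ``panel.dropped`` and
    logged).  A heterozygous genotype written with ``/`` raises
    :class:`UnphasedGenotypeError` unless ``assume_parental_phase`` is set, in
    which case the written allele order is taken as (maternal, paternal).
    """
    variants: list[Variant] = []
    samples: list[str] = []
    rows: list[np.ndarray] = []
    dropped = {"multiallelic": 0, "missing_gt": 0, "non_acgt": 0}
    with open(vcf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise VcfParseError(f"{vcf_path}:{lineno}: no sample columns")
                samples = cols[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10 or not samples:
                raise VcfParseError(f"{vcf_path}:{lineno}: truncated record")
            chrom, pos_s, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise VcfParseError(f"{vcf_path}:{lineno}: bad POS {pos_s!r}") from exc
            if "," in alt:
                if require_biallelic:
                    dropped["multiallelic"] += 1
                    continue
                raise VcfParseError(f"{vcf_path}:{lineno}: multiallelic record")
            fmt = fields[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError as exc:
                raise VcfParseError(f"{vcf_path}:{lineno}: no GT in FORMAT") from exc
            row = np.empty((len(samples), 2), dtype=np.int8)
            missing = False
            for j, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_i]
                sep = "|" if "|" in gt else "/"
                parts = gt.split(sep)
                if len(parts) != 2 or "." in parts:
                    missing = True
                    break
                a, b = int(parts[0]), int(parts[1])
                if sep == "/" and a != b and not assume_parental_phase:
                    raise UnphasedGenotypeError(
                        f"{vcf_path}:{lineno}: unphased het GT {gt!r} for sample "
                        f"{samples[j]} (pass assume_parental_phase to accept)"
                    )
                row[j] = (a, b)
            if missing:
                if require_biallelic:
                    dropped["missing_gt"] += 1
                    continue
                raise VcfParseError(f"{vcf_path}:{lineno}: missing genotype")
            if set(ref) - _BASES or set(alt) - _BASES:
                dropped["non_acgt"] += 1
                continue
            variants.append(Variant(chrom, pos, ref, alt))
            rows.append(row)
    gt = np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int8)
    n_drop = sum(dropped.values())
    if n_drop:
        logger.info("load_variants(%s): dropped %s records (%s)", vcf_path, n_drop, dropped)
    return PhasedGenotypePanel(variants, samples, gt, dropped=dropped)


def write_panel_vcf(panel: PhasedGenotypePanel, path: str) -> None:
    """Write the panel as a minimal phased VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples) + "\n")
        for i, v in enumerate(panel.variants):
            gts = "\t".join(f"{m}|{p}" for m, p in panel.gt[i])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def panel_to_frame(panel: PhasedGenotypePanel):
    """Panel as a tidy DataFrame (one row per variant, GT columns per sample)."""
    import pandas as pd

    data = {
        "chrom": [v.chrom for v in panel.variants],
        "pos": [v.pos for v in panel.variants],
        "ref": [v.ref for v in panel.variants],
        "alt": [v.alt for v in panel.variants],
        "kind": [v.kind for v in panel.variants],
    }
    for j, s in enumerate(panel.samples):
        data[s] = [f"{m}|{p}" for m, p in panel.gt[:, j, :]]
    return pd.DataFrame(data, index=[v.id for v in panel.variants])


# ---------------------------------------------------------------------------
# F1 phasing from homozygous parents
# ---------------------------------------------------------------------------

def phase_f1(
    variants: Sequence[Variant],
    maternal_gts: Mapping[str, tuple[int, int]],
    paternal_gts: Mapping[str, tuple[int, int]],
    sample_name: str = "F1",
) -> PhasedGenotypePanel:
    """Construct the phased F1 genotype of one cross from homozygous parents.

    The F1 genotype at each variant is (maternal allele | paternal allele).
    Variants at which either parent is heterozygous or missing are excluded
    (never guessed); the exclusion count is recorded under
    ``panel.dropped['parent_het_or_missing']``.
    """
    kept: list[Variant] = []
    rows: list[tuple[int, int]] = []
    excluded = 0
    for v in variants:
        m = maternal_gts.get(v.id)
        p = paternal_gts.get(v.id)
        if m is None or p is None or m[0] != m[1] or p[0] != p[1]:
            excluded += 1
            continue
        kept.append(v)
        rows.append((m[0], p[0]))
    if excluded:
        logger.info("phase_f1(%s): excluded %d variants (parent het/missing)", sample_name, excluded)
    gt = np.array(rows, dtype=np.int8).reshape(len(kept), 1, 2)
    return PhasedGenotypePanel(
        kept, [sample_name], gt, dropped={"parent_het_or_missing": excluded}
    )


def phase_crosses(
    parent_panel: PhasedGenotypePanel,
    mother: str,
    fathers: Sequence[str],
    f1_names: Sequence[str] | None = None,
) -> PhasedGenotypePanel:
    """Phase several F1 crosses sharing one maternal line.

    Only variants at which the mother and *every* father are homozygous are
    retained, mirroring a design in which all parental lines are inbred.
    """
    if f1_names is None:
        f1_names = [f"{mother}x{f}" for f in fathers]
    mi = parent_panel.sample_index(mother)
    fis = [parent_panel.sample_index(f) for f in fathers]
    keep_rows = []
    kept: list[Variant] = []
    excluded = 0
    for i, v in enumerate(parent_panel.variants):
        cells = [parent_panel.gt[i, mi]] + [parent_panel.gt[i, fi] for fi in fis]
        if any(c[0] != c[1] for c in cells):
            excluded += 1
            continue
        kept.append(v)
        keep_rows.append([(parent_panel.gt[i, mi, 0], parent_panel.gt[i, fi, 0]) for fi in fis])
    gt = np.array(keep_rows, dtype=np.int8).reshape(len(kept), len(fis), 2)
    return PhasedGenotypePanel(kept, list(f1_names), gt, dropped={"parent_het_or_missing": excluded})


# ---------------------------------------------------------------------------
# Haplotype sequence construction
# ---------------------------------------------------------------------------

class CoordinateMap:
    """Bidirectional map between reference and haplotype coordinates.

    Offsets are 0-based within the construction window.  ``ref_to_hap`` is -1
    at deleted reference bases; ``hap_to_ref`` is -1 at inserted haplotype
    bases; everywhere else the two arrays are mutually inverse.
    """

    def __init__(self, ref_to_hap: np.ndarray, hap_to_ref: np.ndarray, ref_start0: int):
        self.ref_to_hap = ref_to_hap
        self.hap_to_ref = hap_to_ref
        self.ref_start0 = ref_start0  # absolute 0-based start of the window

    def to_hap(self, ref_off: int, snap: str | None = None) -> int:
        """Haplotype offset of a window-relative reference offset.

        ``snap='right'`` returns the next mappable position for deleted bases
        (useful for anchoring reads whose start falls inside a deletion).
        """
        h = int(self.ref_to_hap[ref_off])
        if h >= 0 or snap is None:
            return h
        if snap == "right":
            nxt = np.nonzero(self.ref_to_hap[ref_off:] >= 0)[0]
            return int(self.ref_to_hap[ref_off + nxt[0]]) if nxt.size else -1
        raise ValueError(f"unknown snap mode {snap!r}")

    def to_ref(self, hap_off: int) -> int:
        return int(self.hap_to_ref[hap_off])


def haplotype_sequence(
    genome: Mapping[str, str],
    chrom: str,
    start: int,
    end: int,
    alleles: Mapping[Variant, int] | Iterable[tuple[Variant, int]],
) -> tuple[str, CoordinateMap]:
    """Build the sequence of a chosen haplotype over [start, end] (1-based, inclusive).

    ``alleles`` assigns 0 (REF) or 1 (ALT) to each variant; variants must lie
    inside the window and must not overlap each other on the reference.
    Choosing all-0 (or passing no variants) returns the reference substring
    verbatim.  Returns the haplotype sequence and a :class:`CoordinateMap`
    accounting for indel length shifts.
    """
    if not isinstance(alleles, Mapping):
        alleles = dict(alleles)
    start0, end0 = start - 1, end  # half-open
    ref_seq = _fetch(genome, chrom, start0, end0)
    chosen = sorted((v for v, a in alleles.items() if a == 1), key=lambda v: v.start0)
    for v in alleles:
        if v.chrom != chrom or v.start0 < start0 or v.end0 > end0:
            raise ValueError(f"variant {v.id} outside window {chrom}:{start}-{end}")
    for a, b in zip(chosen, chosen[1:]):
        if b.start0 < a.end0:
            raise OverlappingVariantsError(f"overlapping variants: {a.id}, {b.id}")

    n_ref = end0 - start0
    ref_to_hap = np.empty(n_ref, dtype=np.int64)
    hap_to_ref: list[int] = []
    pieces: list[str] = []
    cursor = start0  # absolute ref coordinate
    hap_pos = 0
    for v in chosen:
        expected = _fetch(genome, chrom, v.start0, v.end0)
        if expected != v.ref:
            raise ValueError(
                f"REF mismatch for {v.id}: genome has {expected!r} (genome/VCF mismatch)"
            )
        # untouched reference run before the variant
        run = v.start0 - cursor
        pieces.append(ref_seq[cursor - start0 : v.start0 - start0])
        ref_to_hap[cursor - start0 : v.start0 - start0] = np.arange(hap_pos, hap_pos + run)
        hap_to_ref.extend(range(cursor - start0, v.start0 - start0))
        hap_pos += run
        # the variant itself: align the shared prefix, then insert/delete
        shared = min(len(v.ref), len(v.alt))
        pieces.append(v.alt)
        for k in range(shared):
            ref_to_hap[v.start0 - start0 + k] = hap_pos + k
            hap_to_ref.append(v.start0 - start0 + k)
        for k in range(shared, len(v.ref)):  # deleted reference bases
            ref_to_hap[v.start0 - start0 + k] = -1
        hap_to_ref.extend([-1] * (len(v.alt) - shared))  # inserted bases
        hap_pos += len(v.alt)
        cursor = v.end0
    run = end0 - cursor
    pieces.append(ref_seq[cursor - start0 :])
    ref_to_hap[cursor - start0 :] = np.arange(hap_pos, hap_pos + run)
    hap_to_ref.extend(range(cursor - start0, end0 - start0))
    seq = "".join(pieces)
    cmap = CoordinateMap(ref_to_hap, np.asarray(hap_to_ref, dtype=np.int64), start0)
    return seq, cmap


def _fetch(genome: Mapping[str, str], chrom: str, start0: int, end0: int) -> str:
    seq = genome[chrom]
    out = str(seq[start0:end0])
    return out.upper()
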