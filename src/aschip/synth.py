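"""Synthetic diploid ChIP-seq data with known allelic ground truth.

The generator emulates the genetic structure of an F1-hybrid binding study:
a small random genome, a dense biallelic SNP+indel panel homozygous in the
parental lines, several F1 crosses sharing one maternal line, and paired-end
fragments drawn from the two haplotypes of each cross with a configurable
per-region allelic imbalance.  Every simulated read records its haplotype of
origin, so mapping-bias removal, allelic-ratio calibration, test power, and
causal-variant recovery can all be measured against exact truth.

Defaults mirror the density of natural variation in inbred fly crosses
(roughly one variant per 230 bp, 18% indels with short geometric lengths)
and a desk-scale study design of 8 F1 lines and 20 peak regions at 1,000
fragments per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .aligner import KmerAligner, revcomp
from .counts import RegionTest, count_alleles
from .variants import PhasedGenotypePanel, Variant, haplotype_sequence, write_panel_vcf

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic F1 ChIP-seq experiment."""

    seed: int = 0
    n_regions: int = 20
    region_length: int = 1000
    region_spacing: int = 1000
    margin: int = 2000
    n_f1_lines: int = 8
    variant_density: float = 1.0 / 230.0  # variants per bp
    indel_fraction: float = 0.18
    indel_max: int = 20
    indel_geom_p: float = 0.35
    mother_alt_prob: float = 0.3
    father_alt_prob: float = 0.5
    fragment_min: int = 200
    fragment_max: int = 300
    read_length: int = 75
    depth: int = 1000  # expected fragments per region per sample
    error_rate: float = 0.001
    imbalance_mode: str = "null"  # null | fixed | motif
    imbalance_p: float = 0.5  # ALT-haplotype fragment probability (fixed mode)
    pwm: object = None  # PWM driving occupancy in motif mode
    predictor_lam: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise ValueError("indel_fraction out of range")
        if not (0.0 < self.imbalance_p < 1.0):
            raise ValueError("imbalance_p out of range")
        if self.imbalance_mode not in ("null", "fixed", "motif"):
            raise ValueError(f"unknown imbalance_mode {self.imbalance_mode!r}")
        if self.imbalance_mode == "motif" and self.pwm is None:
            raise ValueError("motif mode requires a pwm")

    @property
    def genome_length(self) -> int:
        return (self.n_regions * (self.region_length + self.region_spacing)
                + 2 * self.margin)

    def rng(self, stream: str) -> np.random.Generator:
        """Named child stream so modules are independently reproducible."""
        streams = {"genome": 1, "panel": 2, "reads": 3, "errors": 4, "perm": 5}
        return np.random.default_rng([self.seed, streams[stream]])


@dataclass
class GroundTruth:
    """Exact truth for every simulated region (and, via read names, read)."""

    region_p: np.ndarray  # true ALT-haplotype fragment probability per region
    causal: list  # causal variant id per region (None under the null)
    motif_positions: list  # planted motif start per region (None if none)


@dataclass
class SimData:
    config: SimulationConfig
    genome: dict[str, str]
    panel: PhasedGenotypePanel
    regions: list[tuple[str, int, int]]  # chrom, start0, end0
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(cfg: SimulationConfig) -> SimData:
    """Genome + phased F1 variant panel + ground truth, deterministic per seed.

    Parents are homozygous everywhere; an F1 line is heterozygous at a variant
    iff its two parents carry different alleles.  Indel counts are fixed at
    ``round(indel_fraction * n_variants)`` so realized proportions match the
    configuration exactly.
    """
    g_rng = cfg.rng("genome")
    p_rng = cfg.rng("panel")
    L = cfg.genome_length
    seq = g_rng.choice(_BASES, size=L)
    chrom = "chr1"
    regions = []
    for i in range(cfg.n_regions):
        start = cfg.margin + i * (cfg.region_length + cfg.region_spacing)
        regions.append((chrom, start, start + cfg.region_length))

    motif_positions: list = [None] * cfg.n_regions
    if cfg.imbalance_mode == "motif":
        for ri, (_, start, end) in enumerate(regions):
            mstart = (start + end) // 2 - cfg.pwm.width // 2
            seq[mstart : mstart + cfg.pwm.width] = list(cfg.pwm.consensus)
            motif_positions[ri] = mstart

    # variant sites on a coarse grid with jitter: guarantees non-overlap even
    # for the longest deletion (grid step > indel_max + jitter)
    step = cfg.indel_max + 5
    grid = np.arange(50, L - 50 - cfg.indel_max, step)
    n_var = min(len(grid), int(round(L * cfg.variant_density)))
    sites = np.sort(p_rng.choice(grid, size=n_var, replace=False))
    sites = sites + p_rng.integers(0, 4, size=n_var)

    n_indel = int(round(cfg.indel_fraction * n_var))
    is_indel = np.zeros(n_var, dtype=bool)
    is_indel[p_rng.choice(n_var, size=n_indel, replace=False)] = True

    genome = {chrom: "".join(seq)}
    variants: list[Variant] = []
    causal: list = [None] * cfg.n_regions
    for i, pos0 in enumerate(sites):
        ref_base = genome[chrom][pos0]
        if is_indel[i]:
            size = int(min(p_rng.geometric(cfg.indel_geom_p), cfg.indel_max))
            if p_rng.random() < 0.5:  # deletion
                ref = genome[chrom][pos0 : pos0 + size + 1]
                alt = ref[0]
            else:  # insertion
                ref = ref_base
                alt = ref + "".join(p_rng.choice(_BASES, size=size))
        else:
            ref = ref_base
            alt = str(p_rng.choice([b for b in "ACGT" if b != ref_base]))
        variants.append(Variant(chrom, int(pos0) + 1, ref, alt))

    if cfg.imbalance_mode == "motif":
        variants, causal = _plant_motif_variants(cfg, genome, variants, regions,
                                                 motif_positions, p_rng)

    # parental alleles: one shared maternal line, one paternal line per cross
    n = len(variants)
    mother = (p_rng.random(n) < cfg.mother_alt_prob).astype(np.int8)
    fathers = (p_rng.random((n, cfg.n_f1_lines)) < cfg.father_alt_prob).astype(np.int8)
    if cfg.imbalance_mode == "motif":
        # a causal motif variant is informative in every cross: the shared
        # maternal line carries REF, all paternal lines carry ALT
        by_id = {v.id: i for i, v in enumerate(variants)}
        for cid in causal:
            if cid is not None:
                mother[by_id[cid]] = 0
                fathers[by_id[cid], :] = 1
    gt = np.stack([np.repeat(mother[:, None], cfg.n_f1_lines, axis=1), fathers], axis=2)
    samples = [f"F1_{i}" for i in range(cfg.n_f1_lines)]
    panel = PhasedGenotypePanel(variants, samples, gt)

    region_p = np.full(cfg.n_regions, 0.5)
    if cfg.imbalance_mode == "fixed":
        region_p[:] = cfg.imbalance_p
        for ri, (c, s, e) in enumerate(regions):
            mid = (s + e) // 2
            idxs = panel.overlapping(c, s, e)
            het_any = [i for i in idxs
                       if (panel.gt[i, :, 0] != panel.gt[i, :, 1]).any()]
            pool = het_any or idxs
            if pool:
                causal[ri] = panel.variants[
                    min(pool, key=lambda i: abs(panel.variants[i].start0 - mid))
                ].id
    elif cfg.imbalance_mode == "motif":
        from .pai import PWMEnergyPredictor, predict_pai

        predictor = PWMEnergyPredictor(cfg.pwm, lam=cfg.predictor_lam,
                                       window=min(256, cfg.region_length))
        for ri in range(cfg.n_regions):
            if causal[ri] is None:
                continue
            v = panel.variants[panel.index_of(causal[ri])]
            pai = predict_pai(predictor, genome, v)
            region_p[ri] = 1.0 - pai  # ALT-haplotype share of predicted occupancy
    truth = GroundTruth(region_p=region_p, causal=causal, motif_positions=motif_positions)
    return SimData(config=cfg, genome=genome, panel=panel, regions=regions, truth=truth)


def _plant_motif_variants(cfg, genome, variants, regions, motif_positions, rng):
    """Replace the grid variant nearest each planted motif with a SNP that
    destroys the motif's maximum-information position."""
    causal: list = [None] * cfg.n_regions
    pwm = cfg.pwm
    info = (pwm.probs * np.log2(np.clip(pwm.probs, 1e-9, None) / 0.25)).sum(axis=1)
    key_pos = int(np.argmax(info))
    out = list(variants)
    for ri, mstart in enumerate(motif_positions):
        if mstart is None:
            continue
        vpos0 = mstart + key_pos
        ref_base = genome["chr1"][vpos0]
        worst = "ACGT"[int(np.argmin(pwm.probs[key_pos]))]
        if worst == ref_base:
            worst = "ACGT"[int(np.argsort(pwm.probs[key_pos])[1])]
        causal_v = Variant("chr1", vpos0 + 1, ref_base, worst)
        # drop grid variants colliding with the planted one
        out = [v for v in out if abs(v.start0 - vpos0) > cfg.indel_max + 2]
        out.append(causal_v)
        causal[ri] = causal_v.id
    out.sort(key=lambda v: v.start0)
    return out, causal


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = str(genome[chrom])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Read simulation and mapping
# ---------------------------------------------------------------------------

def _hap_weights(panel, causal_idx: int, si: int, p_alt: float) -> tuple[float, float]:
    """Per-haplotype fragment weights given the causal variant's alleles."""
    if causal_idx is None or p_alt == 0.5:
        return 0.5, 0.5
    am, ap = panel.gt[causal_idx, si]
    wm = p_alt if am == 1 else 1.0 - p_alt
    wp = p_alt if ap == 1 else 1.0 - p_alt
    return wm, wp


def simulate_fragments(sim: SimData, sample: str):
    """Yield (qname, r1_seq, r2_seq) paired-end fragments for one sample.

    Fragments are drawn per region with the haplotype chosen according to the
    region's true ALT-haplotype probability; sequences come from the chosen
    haplotype (indel-aware).  The haplotype of origin is encoded in the read
    name (``...:M`` / ``...:P``), which is the per-read ground truth.
    """
    cfg = sim.config
    rng = np.random.default_rng([cfg.seed, 3, sim.panel.sample_index(sample)])
    err_rng = np.random.default_rng([cfg.seed, 4, sim.panel.sample_index(sample)])
    si = sim.panel.sample_index(sample)
    for ri, (chrom, start, end) in enumerate(sim.regions):
        pad = cfg.fragment_max + cfg.indel_max + 10
        w0, w1 = max(0, start - pad), min(len(sim.genome[chrom]), end + pad)
        idxs = sim.panel.overlapping(chrom, w0, w1)
        haps = []
        for hap_side in (0, 1):
            alleles = {sim.panel.variants[i]: int(sim.panel.gt[i, si, hap_side])
                       for i in idxs
                       if sim.panel.variants[i].start0 >= w0
                       and sim.panel.variants[i].end0 <= w1}
            hap_seq, cmap = haplotype_sequence(sim.genome, chrom, w0 + 1, w1, alleles)
            haps.append((hap_seq, cmap))
        causal_idx = (sim.panel.index_of(sim.truth.causal[ri])
                      if sim.truth.causal[ri] else None)
        wm, wp = _hap_weights(sim.panel, causal_idx, si, float(sim.truth.region_p[ri]))
        n_frag = rng.poisson(cfg.depth * (wm + wp))
        prob_m = wm / (wm + wp)
        for fi in range(n_frag):
            side = 0 if rng.random() < prob_m else 1
            hap_seq, cmap = haps[side]
            h_start = cmap.to_hap(start - w0, snap="right")
            h_end = cmap.to_hap(end - 1 - w0, snap="right")
            flen = int(rng.integers(cfg.fragment_min, cfg.fragment_max + 1))
            if h_end - h_start <= flen:
                continue
            fs = int(rng.integers(h_start, h_end - flen))
            frag = hap_seq[fs : fs + flen]
            r1 = frag[: cfg.read_length]
            r2 = revcomp(frag[-cfg.read_length :])
            if cfg.error_rate > 0:
                r1 = _add_errors(r1, cfg.error_rate, err_rng)
                r2 = _add_errors(r2, cfg.error_rate, err_rng)
            hap_label = "M" if side == 0 else "P"
            yield f"sim:{sample}:r{ri}:f{fi}:{hap_label}", r1, r2


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for pos in rng.integers(0, len(seq), size=n_err):
        out[pos] = str(rng.choice([b for b in "ACGT" if b != out[pos]]))
    return "".join(out)


def write_fastq(fragments, fq1_path: str, fq2_path: str) -> int:
    n = 0
    with open(fq1_path, "w") as f1, open(fq2_path, "w") as f2:
        for qname, r1, r2 in fragments:
            f1.write(f"@{qname}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{qname}\n{r2}\n+\n{'I' * len(r2)}\n")
            n += 1
    return n


_CIGAR_OPS = {"=": 7, "X": 8, "I": 1, "D": 2, "M": 0}


def _cigar_tuples(cigar: str):
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((_CIGAR_OPS[ch], int(num)))
            num = ""
    return out


def map_fragments(
    fragments,
    genome: Mapping[str, str],
    aligner: KmerAligner,
    bam_path: str,
) -> dict[str, int]:
    """Naively map simulated pairs to the reference and write a sorted BAM.

    This reproduces the biased step the filter corrects: each mate is placed
    independently; pairs with an unmapped, multimapped, or improperly paired
    mate are discarded, exactly the fate that befalls indel-carrying reads.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in genome],
    }
    refs = {c: i for i, c in enumerate(genome)}
    stats = {"pairs": 0, "mapped": 0, "lost": 0}
    tmp = bam_path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for qname, r1, r2 in fragments:
            stats["pairs"] += 1
            a1 = aligner.align(r1)
            a2 = aligner.align(r2)
            ok = (
                a1 is not None and a2 is not None
                and a1.is_unique and a2.is_unique
                and a1.chrom == a2.chrom and a1.strand != a2.strand
            )
            if not ok:
                stats["lost"] += 1
                continue
            stats["mapped"] += 1
            for seq, aln, other, first in ((r1, a1, a2, True), (r2, a2, a1, False)):
                rec = pysam.AlignedSegment()
                rec.query_name = qname
                stored = revcomp(seq) if aln.strand == "-" else seq
                rec.query_sequence = stored
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(stored))
                rec.reference_id = refs[aln.chrom]
                rec.reference_start = aln.pos
                rec.cigartuples = _cigar_tuples(aln.cigar)
                rec.mapping_quality = aln.mapq
                rec.is_paired = True
                rec.is_proper_pair = True
                rec.is_read1 = first
                rec.is_read2 = not first
                rec.is_reverse = aln.strand == "-"
                rec.mate_is_reverse = other.strand == "-"
                rec.next_reference_id = refs[other.chrom]
                rec.next_reference_start = other.pos
                out.write(rec)
    pysam.sort("-o", bam_path, tmp)
    pysam.index(bam_path)
    import os

    os.remove(tmp)
    return stats


# ---------------------------------------------------------------------------
# End-to-end pipeline on simulated data
# ---------------------------------------------------------------------------

def run_read_pipeline(sim: SimData, workdir: str, aligner: KmerAligner | None = None):
    """Simulate, map, and bias-filter reads for every sample.

    Returns {sample: filtered BAM path} plus per-sample filter statistics.
    """
    import os

    from .biasfilter import run_bias_filter

    os.makedirs(workdir, exist_ok=True)
    if aligner is None:
        aligner = KmerAligner(sim.genome)
    cfg = sim.config
    bams: dict[str, str] = {}
    stats: dict[str, dict] = {}
    for si, sample in enumerate(sim.panel.samples):
        raw = os.path.join(workdir, f"{sample}.raw.bam")
        filtered = os.path.join(workdir, f"{sample}.filtered.bam")
        map_stats = map_fragments(simulate_fragments(sim, sample), sim.genome, aligner, raw)
        f_stats = run_bias_filter(raw, filtered, sim.panel, sim.genome, aligner,
                                  seed=cfg.seed * 1000 + si)
        bams[sample] = filtered
        stats[sample] = {**map_stats, **f_stats}
    return bams, stats


def mean_allelic_ratio(sim: SimData, bams: Mapping[str, str],
                       min_variant_reads: int = 50) -> dict:
    """Mean share of reads assigned to the REF-carrying haplotype across het variants.

    Per heterozygous (variant, region) the fragment-level REF/ALT counts are
    pooled across samples heterozygous there; variants with fewer than
    ``min_variant_reads`` informative fragments are skipped.  Unbiased data
    with no true imbalance centers at 0.5.
    """
    totals: dict[str, np.ndarray] = {}
    for chrom, start, end in sim.regions:
        for sample in sim.panel.samples:
            rc = count_alleles(bams[sample], sim.panel, sample, chrom, start, end,
                               genome=sim.genome)
            for vid, arr in rc.per_variant.items():
                totals.setdefault(vid, np.zeros(3, dtype=int))
                totals[vid] += arr
    ratios = []
    for vid, (ref, alt, _other) in totals.items():
        if ref + alt >= min_variant_reads:
            ratios.append(ref / (ref + alt))
    ratios = np.asarray(ratios)
    return {
        "mean_ratio": float(ratios.mean()) if ratios.size else float("nan"),
        "n_variants": int(ratios.size),
        "ratios": ratios,
    }


# ---------------------------------------------------------------------------
# Counts-level simulation (direct RegionTest generation)
# ---------------------------------------------------------------------------

def simulate_region_tests(
    n_regions: int = 100,
    n_samples: int = 8,
    depth: float = 1000.0,
    as_depth: float = 200.0,
    p_true=0.5,
    rho_as: float = 0.01,
    phi: float = 100.0,
    seed: int = 0,
    mother_alt_prob: float = 0.3,
    father_alt_prob: float = 0.5,
) -> tuple[list[RegionTest], np.ndarray]:
    """Draw RegionTests directly from the test's own generative model.

    Totals are gamma-Poisson with mean ``depth`` scaled by the genotype and
    the true ALT-haplotype probability; allele-specific counts are
    beta-binomial with probability ``p_true`` in heterozygous samples.  Used
    for calibration, power, and parameter-recovery studies where read-level
    simulation adds nothing.
    """
    rng = np.random.default_rng(seed)
    p_true = np.broadcast_to(np.asarray(p_true, dtype=float), (n_regions,))
    samples = [f"S{j}" for j in range(n_samples)]
    tests: list[RegionTest] = []
    for ri in range(n_regions):
        p = float(p_true[ri])
        while True:
            m = (rng.random() < mother_alt_prob) * np.ones(n_samples, dtype=np.int8)
            f = (rng.random(n_samples) < father_alt_prob).astype(np.int8)
            phase = np.stack([m, f], axis=1)
            if (m != f).any():
                break
        g = phase.sum(axis=1)
        c_alt = g.astype(float)
        mu = depth * ((2.0 - c_alt) * (1.0 - p) + c_alt * p)
        lam = rng.gamma(shape=phi, scale=mu / phi)
        T = rng.poisson(lam)
        het = phase[:, 0] != phase[:, 1]
        n_as = np.where(het, rng.poisson(as_depth, n_samples), 0)
        if rho_as > 0:
            a = p * (1 - rho_as) / rho_as
            b = (1 - p) * (1 - rho_as) / rho_as
            pp = rng.beta(a, b, n_samples)
        else:
            pp = np.full(n_samples, p)
        k_alt = rng.binomial(n_as, pp)
        as_alt, as_ref = k_alt, n_as - k_alt
        ref_on_m = phase[:, 0] == 0
        as_m = np.where(ref_on_m, as_ref, as_alt)
        as_p = np.where(ref_on_m, as_alt, as_ref)
        v = Variant("chr1", 1000 * (ri + 1), "A", "T")
        tests.append(RegionTest(
            region_id=f"region_{ri}", chrom="chr1", start=1000 * ri, end=1000 * (ri + 1),
            variant=v, samples=samples, T=T, E=np.full(n_samples, depth, dtype=float),
            g=g, phase=phase, as_m=as_m, as_p=as_p,
        ))
    return tests, np.asarray(p_true).copy()


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------

def truth_eval(
    results: pd.DataFrame,
    true_p: Mapping[str, float],
    fdr_threshold: float = 0.01,
    min_ai: float = 0.1,
    component: str = "full",
) -> dict:
    """Type-I error, power, and AI estimation RMSE against simulation truth.

    ``true_p`` maps region_id to the true ALT-haplotype probability.  Raises
    on region ids missing from the truth table.
    """
    sub = results[results["component"] == component].copy()
    missing = set(sub["region_id"]) - set(true_p)
    if missing:
        raise ValueError(f"regions missing from truth: {sorted(missing)[:5]}")
    sub["true_p"] = sub["region_id"].map(true_p)
    sub["true_ai"] = (sub["true_p"] - 0.5).abs()
    sub["sig"] = (sub["fdr"] < fdr_threshold) & (sub["ai"] > min_ai)
    null = sub[sub["true_ai"] == 0]
    effect = sub[sub["true_ai"] > 0]
    out: dict = {"n_tests": int(len(sub))}
    out["type_i"] = float(null["sig"].mean()) if len(null) else float("nan")
    if len(effect):
        by_region = effect.groupby("region_id")["sig"].any()
        out["power"] = float(by_region.mean())
    else:
        out["power"] = float("nan")
    top = sub.sort_values("p_value").groupby("region_id").first()
    out["ai_rmse"] = float(np.sqrt(((top["ai"] - top["true_ai"]) ** 2).mean()))
    return out


def save_panel(sim: SimData, fasta_path: str, vcf_path: str) -> None:
    """Emit the simulated genome and phased panel as standard FASTA/VCF."""
    write_fasta(sim.genome, fasta_path)
    write_panel_vcf(sim.panel, vcf_path)
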