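"""Variant-centered PWM scanning and allelic-imbalance-based motif reconstruction.

Two complementary readouts connect sequence motifs to allele-specific binding:

* *disruption*: score a TF's PWM on the reference and alternative alleles of
  a short window centered on each variant; the signed score change should
  agree with the direction of measured allelic imbalance;
* *reconstruction*: at each motif position, tally which base the
  higher-occupancy haplotype carries across significant variants — a count
  matrix of in vivo base preferences that can be rendered as an information
  content logo and compared with the affinity-based PWM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import revcomp
from .variants import Variant, haplotype_sequence

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = dict(zip(BASES, "TGCA"))


class PWM:
    """Position weight matrix over {A, C, G, T} with a log-odds scorer.

    ``probs`` is width x 4 (columns A, C, G, T, each row summing to 1).  The
    default calling threshold is the log-odds score whose p-value under the
    background model is ``threshold_pvalue`` (dynamic-programming score
    distribution, no sampling).
    """

    def __init__(
        self,
        name: str,
        probs: np.ndarray,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        threshold_pvalue: float = 1e-4,
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be width x 4")
        if probs.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probabilities per position must sum to 1")
        self.name = name
        self.probs = probs
        self.background = np.asarray(background, dtype=float)
        self.log_odds = np.log2(np.clip(probs, 1e-9, None) / self.background)
        self._threshold: float | None = None
        self.threshold_pvalue = threshold_pvalue

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @property
    def threshold(self) -> float:
        if self._threshold is None:
            self._threshold = self.threshold_for_pvalue(self.threshold_pvalue)
        return self._threshold

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.5,
                    **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, counts / counts.sum(axis=1, keepdims=True), **kw)

    @classmethod
    def from_jaspar(cls, path: str, pseudocount: float = 0.5) -> list["PWM"]:
        from Bio import motifs as bio_motifs

        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "jaspar")
        return [cls._from_bio(m, pseudocount) for m in parsed]

    @classmethod
    def from_meme(cls, path: str, pseudocount: float = 0.0) -> list["PWM"]:
        from Bio import motifs as bio_motifs

        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
        return [cls._from_bio(m, pseudocount) for m in parsed]

    @classmethod
    def _from_bio(cls, m, pseudocount: float) -> "PWM":
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        counts = counts + pseudocount
        return cls(m.name or m.base_id or "motif",
                   counts / counts.sum(axis=1, keepdims=True))

    def score_positions(self, seq: str) -> np.ndarray:
        """Log-odds score at every offset of ``seq`` (forward strand only).

        Non-ACGT bases contribute 0 (background odds)."""
        w = self.width
        n = len(seq) - w + 1
        if n <= 0:
            return np.empty(0)
        enc = np.fromiter((_BASE_IDX.get(c, 4) for c in seq.upper()), dtype=np.int8,
                          count=len(seq))
        lo = np.hstack([self.log_odds, np.zeros((w, 1))])  # column 4: N scores 0
        scores = np.zeros(n)
        for j in range(w):
            scores += lo[j, enc[j : j + n]]
        return scores

    def best_hit(self, seq: str) -> tuple[float, int, str]:
        """Best (score, forward-strand offset of the motif start, strand)."""
        fwd = self.score_positions(seq)
        rev = self.score_positions(revcomp(seq))
        best = (-math.inf, 0, "+")
        if fwd.size:
            i = int(np.argmax(fwd))
            best = (float(fwd[i]), i, "+")
        if rev.size:
            i = int(np.argmax(rev))
            if float(rev[i]) > best[0]:
                best = (float(rev[i]), len(seq) - self.width - i, "-")
        return best

    def threshold_for_pvalue(self, pvalue: float, step: float = 0.01) -> float:
        """Smallest score whose background exceedance probability <= pvalue."""
        grid: dict[int, float] = {0: 1.0}
        for j in range(self.width):
            nxt: dict[int, float] = {}
            for s, pr in grid.items():
                for b in range(4):
                    key = s + int(round(self.log_odds[j, b] / step))
                    nxt[key] = nxt.get(key, 0.0) + pr * self.background[b]
            grid = nxt
        keys = sorted(grid, reverse=True)
        tail = 0.0
        for key in keys:
            tail += grid[key]
            if tail > pvalue:
                return (key + 1) * step
        return keys[-1] * step


@dataclass
class MotifHit:
    """Best PWM match in one allele's variant-centered window."""

    variant_id: str
    allele: str  # 'ref' | 'alt'
    strand: str
    offset: int  # motif start relative to the variant position (window coords)
    score: float
    called: bool
    position_in_motif: int | None  # variant position in PWM coordinates, if inside
    motif_start0: int  # absolute reference coordinate of the motif start (ref frame)
    truncated: bool = False


def scan_variant(
    pwm: PWM,
    genome: Mapping[str, str],
    variant: Variant,
    window: int = 30,
    threshold: float | None = None,
) -> tuple[MotifHit, MotifHit]:
    """Score a PWM on both alleles of a window centered on a variant.

    The alternative window is rebuilt through the haplotype machinery
    (indel-aware) and re-centered on the variant.  Returns the per-allele best
    hits; ``score_ref - score_alt`` is the motif score change.
    """
    if window < pwm.width:
        raise ValueError(f"window {window} < motif width {pwm.width}")
    if threshold is None:
        threshold = pwm.threshold
    chrom_seq = genome[variant.chrom]
    chrom_len = len(chrom_seq)
    half = window // 2
    c0 = variant.start0
    truncated = c0 - half < 0 or c0 - half + window > chrom_len

    r_start = max(0, c0 - half)
    r_end = min(chrom_len, c0 - half + window)
    ref_seq = str(chrom_seq[r_start:r_end]).upper()

    pad = half + len(variant.ref) + len(variant.alt)
    w_start = max(0, c0 - pad)
    w_end = min(chrom_len, c0 + pad + len(variant.ref))
    hap, cmap = haplotype_sequence(genome, variant.chrom, w_start + 1, w_end,
                                   {variant: 1})
    hc = cmap.to_hap(c0 - w_start, snap="right")
    a_start = max(0, hc - half)
    alt_seq = hap[a_start : a_start + window]
    truncated = truncated or len(alt_seq) < window

    hits = []
    for allele, seq, center in (("ref", ref_seq, c0 - r_start), ("alt", alt_seq, hc - a_start)):
        score, off, strand = pwm.best_hit(seq)
        inside = off <= center < off + pwm.width
        pos = None
        if inside:
            pos = center - off if strand == "+" else pwm.width - 1 - (center - off)
        hits.append(MotifHit(
            variant_id=variant.id, allele=allele, strand=strand,
            offset=off - center, score=score, called=score >= threshold,
            position_in_motif=pos,
            motif_start0=(r_start + off) if allele == "ref" else (w_start + off),
            truncated=truncated,
        ))
    return hits[0], hits[1]


def scan_variants(
    pwm: PWM,
    genome: Mapping[str, str],
    variants: Iterable[Variant],
    window: int = 30,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Tabulate :func:`scan_variant` over many variants (one row per variant)."""
    rows = []
    for v in variants:
        h_ref, h_alt = scan_variant(pwm, genome, v, window, threshold)
        rows.append({
            "variant_id": v.id, "pwm": pwm.name,
            "score_ref": h_ref.score, "score_alt": h_alt.score,
            "score_change": h_ref.score - h_alt.score,
            "called_ref": h_ref.called, "called_alt": h_alt.called,
            "strand_ref": h_ref.strand,
            "position_in_motif": h_ref.position_in_motif,
            "motif_start0": h_ref.motif_start0,
            "motif_end0": h_ref.motif_start0 + pwm.width,
        })
    return pd.DataFrame(rows)


def disruption_concordance(
    hits: pd.DataFrame,
    cht_results: pd.DataFrame,
    min_abs_score_change: float = 1.0,
    component: str = "full",
) -> dict:
    """Fraction of variants whose motif score change agrees with the AI direction.

    Considers variants with the motif called in both alleles and
    ``|score_change| >= min_abs_score_change``; concordant means
    ``sign(score_ref - score_alt) == sign(ref_bias - 0.5)``.
    """
    res = cht_results[cht_results["component"] == component]
    merged = hits.merge(res[["variant_id", "ref_bias"]], on="variant_id")
    both = merged[merged["called_ref"] & merged["called_alt"]]
    both = both[both["score_change"].abs() >= min_abs_score_change]
    both = both[both["ref_bias"] != 0.5]
    if both.empty:
        return {"n": 0, "concordance": float("nan")}
    same = np.sign(both["score_change"]) == np.sign(both["ref_bias"] - 0.5)
    return {"n": int(len(both)), "concordance": float(same.mean())}


# ---------------------------------------------------------------------------
# Allelic-imbalance-based motif reconstruction
# ---------------------------------------------------------------------------

def preferred_allele_records(
    hits: pd.DataFrame,
    cht_results: pd.DataFrame,
    variants: Mapping[str, Variant],
    fdr_threshold: float = 0.01,
    min_ai: float = 0.1,
    component: str = "full",
) -> list[tuple[int, str]]:
    """(motif position, preferred base) for significant SNPs inside the motif.

    The preferred base is the allele carried by the higher-occupancy haplotype
    (REF if ref_bias > 0.5, ALT otherwise); orientation is normalized to the
    PWM strand (complemented when the best hit is on the minus strand).
    Indels have no single preferred base and are skipped.
    """
    res = cht_results[cht_results["component"] == component]
    sig = res[(res["fdr"] < fdr_threshold) & (res["ai"] > min_ai)]
    merged = hits.merge(sig[["variant_id", "ref_bias"]], on="variant_id")
    merged = merged[merged["position_in_motif"].notna()]
    records = []
    for row in merged.itertuples():
        v = variants[row.variant_id]
        if v.kind != "snp" or row.ref_bias == 0.5:
            continue
        base = v.ref if row.ref_bias > 0.5 else v.alt
        if row.strand_ref == "-":
            base = _COMPLEMENT[base]
        records.append((int(row.position_in_motif), base))
    return records


def build_ai_pwm(
    records: Iterable[tuple[int, str]],
    width: int,
    pseudocount: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allelic-imbalance count matrix and its information-content transform.

    ``counts[pos, base]`` is the number of significant variants whose
    preferred base at that motif position is ``base``.  The ICM adds the
    pseudocount per base, normalizes each column, and scales letter heights
    by the column information content ``2 + sum_b f_b log2 f_b`` (so an
    empty position is a flat, ~0-bit column, never imputed).
    """
    counts = np.zeros((width, 4))
    for pos, base in records:
        if not 0 <= pos < width:
            raise ValueError(f"motif position {pos} outside width {width}")
        counts[pos, _BASE_IDX[base]] += 1
    f = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    ic = 2.0 + (f * np.log2(f)).sum(axis=1)
    icm = f * ic[:, None]
    cols = list(BASES)
    return (pd.DataFrame(counts, columns=cols, dtype=int),
            pd.DataFrame(icm, columns=cols))


def motif_distance_annotation(hits: pd.DataFrame, peaks: Sequence) -> pd.DataFrame:
    """Distance of each ref-allele motif to the nearest peak summit, plus
    an inside-peak flag (motif interval fully contained in the peak)."""
    out = hits.copy()
    dists, inside = [], []
    for row in out.itertuples():
        mid = (row.motif_start0 + row.motif_end0) / 2.0
        chrom = row.variant_id.split(":")[0]
        best, is_in = float("inf"), False
        for p in peaks:
            if p.chrom != chrom:
                continue
            d = abs(mid - p.summit)
            if d < best:
                best = d
                is_in = p.start <= row.motif_start0 and row.motif_end0 <= p.end
        dists.append(best)
        inside.append(is_in)
    out["summit_distance"] = dists
    out["inside_peak"] = inside
    return out
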