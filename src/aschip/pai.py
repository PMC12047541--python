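"""Predictor-based variant prioritization: pAI and in silico saturation mutagenesis.

Any model that maps a DNA window to a non-negative predicted coverage can
drive these analyses; the interface is a single ``predict(seq)`` call plus a
window length.  The predicted allelic imbalance of a variant is

    pAI = pred(ref window) / (pred(ref window) + pred(alt window)),

so 0.5 means no predicted effect and ``|pAI - 0.5|`` ranks candidate causal
variants within a peak.  Saturation mutagenesis substitutes every base at
every position of a window, normalizes the scores by the mean absolute score,
subtracts the reference-base score per position (deltas), and sums absolute
deltas into a per-position importance track.

A PWM-energy predictor ships as the reference implementation: deterministic,
motif-driven, and computable in closed form, so every downstream statistic
has exact ground truth.  Adapters for trained sequence-to-coverage networks
only need to export per-window summed predictions through the same protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .motifs import BASES, PWM
from .variants import Variant, haplotype_sequence


class CoveragePredictor(Protocol):
    """Deterministic map from a sequence window to predicted summed coverage."""

    window: int

    def predict(self, seq: str) -> float:  # pragma: no cover - protocol
        ...


class PWMEnergyPredictor:
    """Toy occupancy model: summed Boltzmann weights of PWM matches.

    ``predict(seq) = sum over offsets and strands of exp(lam * log-odds)``.
    Smooth in the sequence, strictly positive, and maximal when the window
    contains strong motif matches; ``lam`` sharpens the motif dependence.
    """

    def __init__(self, pwm: PWM, lam: float = 1.0, window: int = 256):
        self.pwm = pwm
        self.lam = lam
        self.window = window

    def predict(self, seq: str) -> float:
        from .aligner import revcomp

        total = 0.0
        for s in (seq, revcomp(seq)):
            scores = self.pwm.score_positions(s)
            if scores.size:
                total += float(np.exp(self.lam * scores).sum())
        return total


class ConstantPredictor:
    """Sequence-independent predictor; useful as a null control."""

    def __init__(self, value: float = 1.0, window: int = 256):
        self.value = value
        self.window = window

    def predict(self, seq: str) -> float:
        return self.value


# ---------------------------------------------------------------------------
# pAI
# ---------------------------------------------------------------------------

def _allele_windows(
    genome: Mapping[str, str], variant: Variant, length: int
) -> tuple[str, str]:
    """Fixed-length ref and alt windows re-centered on the variant."""
    chrom_seq = genome[variant.chrom]
    chrom_len = len(chrom_seq)
    half = length // 2
    c0 = variant.start0
    r0 = max(0, min(c0 - half, chrom_len - length))
    ref_seq = str(chrom_seq[r0 : r0 + length]).upper()
    pad = half + len(variant.ref) + len(variant.alt) + 1
    w0 = max(0, c0 - pad)
    w1 = min(chrom_len, c0 + pad + len(variant.ref))
    hap, cmap = haplotype_sequence(genome, variant.chrom, w0 + 1, w1, {variant: 1})
    hc = cmap.to_hap(c0 - w0, snap="right")
    a0 = max(0, min(hc - half, len(hap) - length))
    alt_seq = hap[a0 : a0 + length]
    return ref_seq, alt_seq


def predict_pai(
    predictor: CoveragePredictor,
    genome: Mapping[str, str],
    variant: Variant,
) -> float:
    """Predicted allelic imbalance of one variant; NaN if total prediction is 0."""
    ref_seq, alt_seq = _allele_windows(genome, variant, predictor.window)
    pr = predictor.predict(ref_seq)
    pa = predictor.predict(alt_seq)
    if pr < 0 or pa < 0:
        raise ValueError("predictor returned a negative coverage")
    total = pr + pa
    if total == 0:
        return float("nan")
    return pr / total


def pai_table(
    predictor: CoveragePredictor,
    genome: Mapping[str, str],
    variants: Sequence[Variant],
) -> pd.DataFrame:
    rows = [{
        "variant_id": v.id, "chrom": v.chrom, "pos": v.pos,
        "pai": predict_pai(predictor, genome, v),
    } for v in variants]
    df = pd.DataFrame(rows)
    if not df.empty:
        df["abs_pai"] = (df["pai"] - 0.5).abs()
    return df


def rank_variants(
    pai: pd.DataFrame,
    summit_by_region: Mapping[str, int] | None = None,
    region_col: str = "region_id",
) -> pd.DataFrame:
    """Rank variants per peak by descending ``|pAI - 0.5|``.

    Ties break by distance to the peak summit, then by coordinate; rank 1 is
    the top-predicted (candidate causal) variant.
    """
    df = pai.copy()
    df["abs_pai"] = (df["pai"] - 0.5).abs()
    if summit_by_region is not None:
        df["_summit_dist"] = [
            abs(row.pos - 1 - summit_by_region.get(getattr(row, region_col), 0))
            for row in df.itertuples()
        ]
    else:
        df["_summit_dist"] = 0
    df = df.sort_values(
        ["abs_pai", "_summit_dist", "pos"], ascending=[False, True, True]
    )
    df["rank"] = df.groupby(region_col).cumcount() + 1 if region_col in df else (
        np.arange(len(df)) + 1
    )
    return df.drop(columns="_summit_dist").sort_values([region_col, "rank"]
                                                       if region_col in df else ["rank"])


def direction_agreement(
    pai: pd.DataFrame,
    cht_results: pd.DataFrame,
    strong_threshold: float = 0.1,
    component: str = "full",
) -> tuple[dict, pd.DataFrame]:
    """Agreement between predicted and measured imbalance direction.

    A prediction is correct iff ``pAI - 0.5`` and ``ref_bias - 0.5`` share
    sign.  The *strong* set requires both deviations to exceed
    ``strong_threshold``.  Returns summary stats and the annotated table.
    """
    res = cht_results[cht_results["component"] == component]
    merged = pai.merge(res[["variant_id", "ref_bias", "ai", "fdr"]], on="variant_id")
    merged = merged.dropna(subset=["pai"])
    merged = merged[(merged["pai"] != 0.5) & (merged["ref_bias"] != 0.5)]
    merged["correct"] = np.sign(merged["pai"] - 0.5) == np.sign(merged["ref_bias"] - 0.5)
    merged["strong"] = ((merged["pai"] - 0.5).abs() > strong_threshold) & (
        merged["ai"] > strong_threshold
    )
    strong = merged[merged["strong"]]
    summary = {
        "n": int(len(merged)),
        "agreement": float(merged["correct"].mean()) if len(merged) else float("nan"),
        "n_strong": int(len(strong)),
        "agreement_strong": float(strong["correct"].mean()) if len(strong) else float("nan"),
    }
    return summary, merged


# ---------------------------------------------------------------------------
# In silico saturation mutagenesis
# ---------------------------------------------------------------------------

@dataclass
class SatMutResult:
    """Per-position, per-base predictor scores around a center position.

    ``raw[pos, base]`` is the prediction with that base substituted;
    ``normalized`` divides by the mean absolute raw score; ``deltas``
    subtracts the reference-base score per position (so the reference base is
    exactly 0 everywhere); ``importance[pos] = sum_base |delta|``.
    """

    chrom: str
    center: int  # 0-based
    flank: int
    positions: np.ndarray  # absolute 0-based coordinates
    ref_bases: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    deltas: np.ndarray
    importance: np.ndarray
    skipped: list[int] = field(default_factory=list)  # positions with N reference

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.deltas, columns=list(BASES))
        df.insert(0, "pos0", self.positions)
        df.insert(1, "ref_base", self.ref_bases)
        df["importance"] = self.importance
        return df


def saturation_mutagenesis(
    predictor: CoveragePredictor,
    genome: Mapping[str, str],
    chrom: str,
    center: int,
    flank: int = 75,
) -> SatMutResult:
    """Score every single-base substitution in ``center ± flank``.

    Predictions are made on the predictor's own window centered on ``center``;
    scores are normalized by the mean of their absolute values before deltas
    are taken.  Positions whose reference base is not A/C/G/T are skipped and
    reported.
    """
    chrom_seq = genome[chrom]
    chrom_len = len(chrom_seq)
    length = predictor.window
    w0 = max(0, min(center - length // 2, chrom_len - length))
    window_seq = list(str(chrom_seq[w0 : w0 + length]).upper())
    start = center - flank
    n_pos = 2 * flank + 1
    if start < w0 or start + n_pos > w0 + length:
        raise ValueError("mutagenesis span exceeds the predictor window")
    raw = np.zeros((n_pos, 4))
    ref_bases: list[str] = []
    skipped: list[int] = []
    for i in range(n_pos):
        pos = start + i
        ref_base = window_seq[pos - w0]
        ref_bases.append(ref_base)
        if ref_base not in BASES:
            skipped.append(pos)
            continue
        for bi, base in enumerate(BASES):
            if base == ref_base:
                mutated = window_seq
            else:
                mutated = window_seq.copy()
                mutated[pos - w0] = base
            raw[i, bi] = predictor.predict("".join(mutated))
    mean_abs = np.abs(raw).mean() if np.abs(raw).sum() > 0 else 1.0
    normalized = raw / mean_abs
    deltas = np.zeros_like(normalized)
    for i, ref_base in enumerate(ref_bases):
        if ref_base in BASES:
            deltas[i] = normalized[i] - normalized[i, BASES.index(ref_base)]
    importance = np.abs(deltas).sum(axis=1)
    return SatMutResult(
        chrom=chrom, center=center, flank=flank,
        positions=np.arange(start, start + n_pos), ref_bases=ref_bases,
        raw=raw, normalized=normalized, deltas=deltas, importance=importance,
        skipped=skipped,
    )
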