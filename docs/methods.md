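# Methods

This note documents the models, procedures, parameter choices, and known
limitations of `aschip`.

## Study design and data model

The package targets F1-hybrid ChIP-seq designs: several crosses share one
inbred maternal line, each with a different inbred paternal line.  Because
all parents are homozygous, the F1 genotype at every retained variant is the
ordered pair (maternal allele | paternal allele), and a sample is
heterozygous exactly where its parents differ.  Phasing is therefore
deterministic (`variants.phase_f1`); variants at which any parent is
heterozygous or missing are excluded, never imputed.  Only biallelic
SNPs and short indels are handled; multiallelic records are dropped at VCF
load with counts reported.

All internal interval arithmetic is 0-based half-open; VCF coordinates
(1-based, indels left-anchored on a shared first base) are converted only at
the I/O boundary.  Overlapping variants are rejected rather than resolved —
a stringently filtered panel is non-overlapping by construction, and silent
resolution would hide genotyping problems.

`variants.haplotype_sequence` is the package's single substitution engine:
it builds the sequence of any chosen haplotype over a window together with a
bidirectional reference↔haplotype coordinate map (deleted bases map to −1 on
the haplotype side, inserted bases to −1 on the reference side).  The bias
filter, the allele-specific counter, the motif scanner, the predictors, and
the read simulator all rebuild sequence through it, so indel length
shifts are handled identically everywhere.

## Mapping-bias removal

Reads carrying non-reference alleles map worse against the reference genome;
for indels the effect is strong enough that naive counting can lose the ALT
allele entirely at a locus.  The filter removes this asymmetry
symmetrically:

1. every read pair whose aligned span intersects a panel variant is
   identified (`find_intersecting_reads`); clean pairs pass through
   untouched;
2. each such pair is rewritten into all `2^h` allele assignments of the `h`
   biallelic variants it overlaps (`enumerate_allele_versions`), capped at
   64 versions (pairs over more than 6 variants are dropped as
   `too_many_combinations`); the original assignment is among the versions,
   so unstable loci are caught even without a swap;
3. each version of each mate is remapped; the pair is kept only if every
   version maps uniquely, with MAPQ > 10, to the original (chromosome,
   leftmost coordinate) in forward orientation (`remap_filter`);
4. duplicates (pairs sharing both mates' coordinates and orientations) are
   reduced to one survivor chosen uniformly at random under a fixed seed
   (`dedup_random`) — choosing "best" duplicates would favour
   reference-matching reads.

Version rebuilds are anchored at each mate's *leftmost* reference
coordinate and trimmed/extended with haplotype flanking sequence to preserve
read length.  Anchoring left (rather than at the biological 5′ end of
reverse-strand mates) is deliberate: it keeps the leftmost mapping
coordinate invariant under indel substitution, which is exactly the quantity
the "same position" comparison uses, and makes the comparison well defined
for both mates.

The remap step is pluggable (`aligner.AlignerInterface`).  The built-in
`KmerAligner` — exact 16-mer seeds at three read offsets, banded
edit-distance extension via edlib, uniqueness by counting best-distance
loci — is deterministic and sufficient for the desk-scale genomes of the
test suite; production data should be remapped with the same external
mapper used for the original alignment (adapter: `write_versions_fastq`).
Its `max_edit_distance` default of 5 mirrors what production mappers
tolerate on 75 bp reads; stricter caps make the simulated reference bias
correspondingly harsher (the bias-removal property test uses a cap of 3 so
that a 4 bp deletion defeats naive mapping).

Known limitation: reads whose end *clips* an indel junction pay only part of
the indel's edit cost at mapping, so their fate under capped-edit-distance
mapping is not exactly invariant under exchanging the REF/ALT labels of the
panel — the label-swap symmetry test exempts such junction-clipping
fragments (about 1% at the tested depth) and bounds their number.  Real
mappers share this behaviour.

## Target regions and counts

Consensus peaks merge per-line peak sets transitively at ≥ 1 bp overlap and
keep intervals supported by at least 3 lines; the summit is recomputed as
the argmax of pooled per-base coverage (leftmost on ties).  A *target
region* is the ±2,500 bp window around a summit; every panel variant inside
it becomes a *test variant*.  A (region, variant) pair enters the analysis
only if (inclusive thresholds): ≥ 400 total reads across samples in the
region, ≥ 50 allele-specific reads summed over samples heterozygous at the
test variant, ≥ 1 heterozygous sample, and ≥ 1 chromosome carrying the
minor allele.

Allele-specific counting is fully haplotype-aware.  For each heterozygous
site and sample, the expected *maternal* and *paternal* read contexts are
built from the sample's two phased haplotypes (the site's allele plus 10 bp
of haplotype sequence on each side, neighbouring variants included with
their phased alleles).  A fragment is assigned at a site iff exactly one of
the two contexts occurs in one of its mates; the minimum base quality over
the matched span must reach 10 (configurable).  Context matching is
position-free, which makes it robust to the two failure modes of
alignment-based calling: gap-placement ambiguity in repeats (a left-shifted
deletion looks like the reference allele to a CIGAR walk) and slightly
misplaced reads.  Each fragment contributes at most one allele-specific
observation per region — among its confidently called sites, the highest
base quality (leftmost on ties) decides — and overlapping mates are counted
once.  Spanning fragments matching neither context are tallied as "other"
and excluded from allele-specific counts.

Expected counts `E_i` split each region's pooled total by the samples'
effective library shares (library size × fraction-of-reads-in-peaks when
provided), corrected by a per-sample GC factor and rescaled so that
`Σ E_i = Σ T_i` per region.  Because a GC trend shared by all samples is
absorbed by region effects, only *relative* factors across samples within a
GC bin are identifiable; the fit therefore works on per-region
library-normalized compositions, taking the median composition per GC
quartile and sample.  On data with exactly planted factors this recovers
the biased sample's relative profile exactly.  With a single distinct GC
bin the factor degenerates to 1 with a warning.

## The combined haplotype test

Each (region, variant) test couples two likelihood components through one
effect parameter `p ∈ (0,1)`, the probability that a fragment originates
from the haplotype carrying the test variant's ALT allele:

- allele-specific: for heterozygous samples, `k = as_alt` out of
  `n = as_ref + as_alt` follows a beta-binomial with mean `p` and
  intraclass-correlation overdispersion `ρ_AS ∈ [0,1)` (ρ→0 is binomial);
- read depth: each sample's total `T_i` follows a gamma-mixed Poisson
  (negative binomial) with dispersion `φ` (variance `μ + μ²/φ`; φ→∞ is
  Poisson), optionally deepened by a mean-preserving beta layer on the NB
  success probability, with mean
  `μ_i = E_i (c_ref (1−p) + c_alt p)`, `(c_ref, c_alt)` = (2,0), (1,1),
  (0,2) by ALT dosage.

The null fixes `p = 0.5` (equal haplotype output, dosage-independent
depth); the alternative maximizes over `p` by bounded scalar optimization
(`p ∈ [10⁻⁶, 1−10⁻⁶]`, tolerance 10⁻⁸ — the shared-effect structure makes
`p` the single free effect parameter).  Significance is a χ²(1) LRT;
non-convergence is flagged and reported conservatively as p = 1.  Tests
with no heterozygous sample *and* no genotype contrast in depth are
skipped, not assigned p = 1.  Reported effects: `α = s(1−p̂)`,
`β = s·p̂` (s the summed AS count scale), reference-allele bias
`α/(α+β)`, `AI = |0.5 − α/(α+β)|`, and relative region counts
`100·T_i/E_i`.

Overdispersions are estimated genome-wide by maximum likelihood under the
null (α = β per region); with fewer than 50 regions the configurable
defaults (ρ_AS = 0.01, φ = 100) are used with a warning.  Numerical note:
ρ < 10⁻⁸ and φ > 10⁸ are routed to the exact binomial/Poisson limit
branches, which are more accurate there than the beta/gamma forms.

`run_cht` evaluates the full test plus the AS-only and depth-only
components, and applies Benjamini–Hochberg FDR across all tested variants
within each component.  Significant variants require FDR < 0.01 *and*
AI > 0.1; a peak is imbalanced if it has ≥ 1 significant variant, with the
top variant chosen by minimum p (ties: larger AI, then leftmost).

Permutation mode shuffles each test's per-sample genotype-and-phase blocks
(seeded) while counts stay with their samples; a sample that becomes
heterozygous under the permutation contributes its own maternal/paternal
counts polarized by the permuted phase.  This is exchangeable under the
null and reproduces uniform p-values in the calibration tests.  Biological
replicates are treated as independent samples.

## Motif analyses

PWM scanning is variant-centered: 30 bp windows on the reference and the
(indel-aware, re-centered) alternative allele, all offsets, both strands.
Indels inside motifs are handled by whole-window re-scan rather than
per-position alignment.  A motif is "called" when its best log-odds score
reaches the score whose exceedance probability under the background model
is 10⁻⁴ by default (exact dynamic-programming score distribution at 0.01
resolution).  The threshold p-value is configurable per PWM: for very
low-information motifs a 10⁻⁴ threshold can exceed even the consensus
score, in which case nothing is callable by construction.

Concordance compares `sign(score_ref − score_alt)` with
`sign(ref_bias − 0.5)` for variants with the motif called in both alleles,
excluding |Δscore| < 1.  The allelic-imbalance count matrix records, per
motif position, the base carried by the higher-occupancy haplotype of each
significant motif-overlapping SNP (orientation normalized to the PWM
strand; indels skipped, having no single preferred base).  The
information-content transform adds a 0.25 pseudocount per base, normalizes
columns, and scales letter heights by `2 + Σ_b f_b log₂ f_b`; positions
without variants render as flat ~0-bit columns, never imputed.

## Predictor-based prioritization

`CoveragePredictor` is a one-method contract (`predict(seq) → ≥ 0` with a
fixed window length); nothing in the core requires a deep-learning
framework.  The reference `PWMEnergyPredictor` scores
`Σ exp(λ·log-odds)` over all offsets and strands (λ default 1, window
default 256 bp) — deterministic, strictly positive, and computable in
closed form, so every downstream statistic has exact ground truth.

`pAI = pred(ref window)/(pred(ref) + pred(alt))`, both windows fixed-length
and re-centered on the variant; equal predictions give exactly 0.5, a zero
total is reported NA.  The prediction statistic is the sum over the
predictor's full window.  Candidate causal variants are ranked per peak by
descending `|pAI − 0.5|` (ties: distance to summit, then coordinate).
Direction agreement counts a prediction correct when `pAI − 0.5` and
`ref_bias − 0.5` share sign; the *strong* set requires both deviations to
exceed 0.1.  Saturation mutagenesis substitutes all four bases at every
position of center ± 75 bp, normalizes scores by the mean absolute score,
subtracts the reference-base score per position (the reference delta is
identically zero), and sums absolute deltas into per-position importance;
non-ACGT reference positions are skipped and flagged.

## Synthetic data

The generator's defaults are the package's standard study conditions: a
random uniform A/C/G/T genome of 20 regions × 1 kb (plus spacing), 8 F1
lines sharing one maternal line, variant density 1/230 bp with 18% indels
(geometric lengths, capped at 20 bp, placed on a jittered grid that
guarantees non-overlap), paired-end 75 bp reads from 200–300 bp fragments
at 1,000 fragments per region per sample, and per-base error rate 10⁻³.
Density and indel share mirror the natural variation of inbred fly crosses;
depth and design size are chosen so that calibration statistics resolve at
desk scale in about a minute.  Maternal/paternal ALT frequencies (0.3/0.5)
make most variants informative in at least one cross.

Imbalance modes: `null` (p = 0.5 everywhere), `fixed` (a chosen
ALT-haplotype probability, causal variant = the heterozygous variant
nearest each region center), and `motif` (a PWM consensus planted at the
region center, a SNP destroying its maximum-information position, and the
true p derived from the energy predictor's own ref/alt ratio, so sequence,
occupancy, and truth are mutually consistent).  Haplotype weights scale
both fragment allocation and total depth (an ALT-homozygous sample has
2p× the baseline depth), giving the depth component of the CHT a real
signal.  Every read name encodes its haplotype of origin — the per-read
ground truth used by the calibration analyses.  All randomness derives
from one seed through named child streams, so panel, reads, and
permutations are independently reproducible.

A counts-level generator (`simulate_region_tests`) draws RegionTests
directly from the test's own generative model (gamma-Poisson totals,
beta-binomial allele counts) for calibration, power, and recovery studies
where read-level simulation adds nothing; the FDR-calibration and
effect-recovery checks use it at 400 and 40 regions respectively.

What the generator does *not* emulate: chromatin structure and
fragment-level biases, repeat-driven mappability pathologies (tests plant
exact duplicated segments when needed), linkage disequilibrium between
distant variants, and multiallelic sites.  Passing tests therefore
demonstrate correctness of the statistical machinery and the bias
correction under the stated genetic structure, not robustness to every
artefact of real chromatin data.

## Verification summary

The suite checks, among others: exact worked examples for haplotype
substitution and version enumeration (2^h versions, 64-cap); recovery of
a 0.5 allelic ratio after filtering when the ALT haplotype carries a 4 bp
deletion, against a naive mapping that demonstrably under-counts ALT;
closed-form binomial/Poisson limits of the likelihoods (oracle:
scipy's beta-binomial and an exhaustive pmf sum); uniform permuted-null
p-values (KS test) and ≤ 1% of permuted-null variants passing the
significance definition; recovery of p = 0.7 within ±0.05 at depth 2,000;
AI-PWM modal-base recovery; exact pAI antisymmetry and zero reference
deltas; and rank-1 causal-variant recovery above a 10,000-permutation
baseline (empirical p < 0.001).  The full-pipeline null calibration (the
number `scripts/acceptance.py` recomputes) runs the standard conditions
end-to-end and lands at 0.50 ± 0.01 across seeds.
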