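# aschip — allele-specific ChIP-seq analysis in F1 hybrids

`aschip` quantifies the cis-regulatory effect of genetic variants on
transcription-factor (TF) binding using ChIP-seq from F1 hybrid crosses.
In an F1 of two inbred lines every variant at which the parents differ is
heterozygous with known phase, so the two parental alleles compete inside
the same nuclei: any reproducible skew in the reads assigned to one
haplotype (allelic imbalance) is direct evidence of a cis effect.  The
package is aimed at groups analysing such designs (fly, mouse, or hybrid
cell lines) who need the full path from aligned reads to prioritized
causal variants without adopting a lab-specific pipeline.

It implements:

- **Indel-aware mapping-bias filtering.**  Reads carrying non-reference
  alleles — indels above all — map worse against the reference, inflating
  apparent REF counts.  Every read pair overlapping a panel variant is
  rewritten into all allele combinations of the variants it touches (up to
  64 versions per pair by default), each version is remapped, and the pair
  survives only if *every* version maps uniquely (MAPQ > 10) to the
  original locus.  Duplicates are then removed at random, never by
  quality, to avoid re-introducing reference bias.
- **The combined haplotype test (CHT).**  Per (target region, test
  variant), a beta-binomial likelihood over allele-specific counts at
  phased heterozygous sites and a beta-negative-binomial likelihood over
  total region counts share a single effect parameter
  `p = β/(α+β)`, the probability that a fragment originates from the
  ALT-carrying haplotype.  A 1-df likelihood-ratio test gives p-values;
  effects are summarized as the reference-allele bias `α/(α+β)` and the
  allelic imbalance `AI = |0.5 − α/(α+β)|`; significance is BH-FDR < 0.01
  with AI > 0.1.
- **Motif-disruption analysis.**  PWMs are scanned in 30 bp windows
  centered on each variant on both alleles; the signed motif score change
  is compared with the direction of measured imbalance, and the preferred
  alleles of significant motif variants are assembled into an
  allelic-imbalance count matrix / information-content logo — an in vivo
  readout of per-base importance.
- **Predictor-based prioritization.**  Any sequence-to-coverage model
  exposes `predict(seq)`; the predicted allelic imbalance
  `pAI = pred(ref)/(pred(ref)+pred(alt))` ranks candidate causal variants
  per peak, and in silico saturation mutagenesis (± 75 bp, all four bases
  per position, deltas versus the reference base) localizes the sequence
  features behind a prediction.  A deterministic PWM-energy predictor
  ships as the reference implementation.
- **A synthetic-data generator** producing a genome, a phased SNP+indel
  panel homozygous in the parents, F1 crosses sharing one maternal line,
  and paired-end reads with configurable per-region imbalance — exact
  ground truth for every calibration and recovery test.

## Worked example

Simulate a null experiment (8 F1 lines, 20 regions, 1,000 fragments per
region, no true imbalance), run the bias filter, and check the allelic
ratio; then test one region with the CHT:

```python
from aschip.synth import (SimulationConfig, simulate_panel,
                          run_read_pipeline, mean_allelic_ratio,
                          simulate_region_tests)
from aschip.cht import Dispersions, fit_cht

sim = simulate_panel(SimulationConfig(seed=1))
bams, stats = run_read_pipeline(sim, "scratch/null_run")
ratio = mean_allelic_ratio(sim, bams)
print(f"mean allelic ratio {ratio['mean_ratio']:.4f} "
      f"over {ratio['n_variants']} het variants")

tests, _ = simulate_region_tests(n_regions=1, depth=2000, as_depth=2000,
                                 p_true=0.7, seed=9)
res = fit_cht(tests[0], Dispersions(rho_as=0.01, phi_bnb=200.0))
print(f"ref_bias {res.ref_bias:.3f}  AI {res.ai:.3f}  p {res.p_value:.2e}")
```

prints

```
mean allelic ratio 0.5041 over 85 het variants
ref_bias 0.333  AI 0.167  p 3.39e-42
```

The first line is the post-filter calibration: with no true imbalance the
share of reads on the REF-carrying haplotype is 0.5 up to simulation
noise, i.e. the mapping bias introduced by indels has been removed.  The
second line recovers a planted ALT-haplotype probability of 0.7 in one
region (`ref_bias` estimated 0.33 against a truth of 0.30, `AI` 0.17)
with overwhelming evidence against the balanced null.

A `aschip` command-line tool wraps the same steps
(`aschip phase`, `aschip filter-remapped`, `aschip regions`, `aschip cht`,
`aschip make-synthetic`); `aschip --help` lists the subcommands.

## Not in scope

Peak calling (MACS2/IDR), genotype calling and production read alignment
(GATK/BWA — the remap step accepts any aligner through
`aschip.aligner.AlignerInterface`, and a built-in seed-and-extend aligner
covers desk-scale genomes), deep-learning model training, and GO/landscape
enrichment analyses.
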