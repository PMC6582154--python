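# Methods

## Problem setting

`skimgt` evaluates whether skim-coverage (sub-1× to a few ×) long-read
sequencing can genotype *pre-validated* biallelic SNP loci accurately enough
to replace short-read genotyping, using doubled-haploid (DH) panels as the
testbed. DH individuals are expected to be homozygous at every locus, which
turns heterozygous calls into a diagnostic: in long-read (LRS) data they are
mostly products of random base error at low depth, while in short-read (SRS)
data they are dominated by *hemi-SNPs* — reads from homoeologous or
paralogous regions co-aligning to one reference position, a chronic problem
in highly duplicated genomes such as allopolyploid *Brassica napus*.

The package has two modes. In real-data mode it consumes per-platform
multi-sample VCFs plus a SNP panel TSV. In synthetic mode a generator
produces truth sets and pileups with the statistical structure above, so
every downstream stage is testable without external sequencing data.

## Genotype model

At a biallelic locus with alleles {ref, alt}, each retained pileup
observation *b<sub>i</sub>* with phred quality *q<sub>i</sub>* has error
probability *e<sub>i</sub>* = 10^(−q<sub>i</sub>/10) and

  P(b<sub>i</sub> | hom X) = 1 − e<sub>i</sub> if b<sub>i</sub> = X, else e<sub>i</sub>/3
  P(b<sub>i</sub> | het)  = ½ P(b<sub>i</sub> | hom ref) + ½ P(b<sub>i</sub> | hom alt)

Observations with quality below `min_bq` (default 13, the conventional
pileup-caller default; 1 and 20 are supported sweep values) are excluded
before anything else, so DP, AD and the likelihoods all see the same reads.
Observations matching neither allele still contribute through the error
terms. Genotype log-likelihoods are sums of per-observation logs; PL values
are `round(−10·log10 L)` shifted so the minimum is 0.

**Genotype prior.** By default the call is the argmin-PL genotype (uniform
prior). The caller also exposes `het_prior` *h*: the call then maximises
likelihood × prior with prior masses ((1−h)/2, h, (1−h)/2), while PL stays
pure likelihood — the same division of labour production callers use (PL
excludes priors; the emitted GT does not). The hook matters quantitatively:
with a uniform prior, a single error read among up to ~7 high-quality
concordant reads always wins the het call (the per-read evidence ratio
against het is only ≈ log((1−e)/0.5) per concordant read), so apparent
heterozygosity would *grow* with depth. A modest het-suppressing prior
restores the behaviour seen in real skim data, where added depth drowns
error-driven heterozygotes. The study pipeline uses *h* = 0.01, the
residual heterozygosity a breeder would expect of DH material; at reported
q20 this makes a 1-ref-1-alt pair still call het while a 2-ref-1-alt triple
calls hom-ref.

**Tie handling.** A tie between a homozygote and the het resolves toward
the genotype supported by the larger AD component; residual ties (e.g. a
single other-base read, where all three likelihoods are equal) yield a
missing genotype that keeps its DP and PL. On the prior path, posterior
comparisons tolerate 1e−9 of float summation noise when detecting ties.

## Synthetic data generator

The generator works at the pileup level: read alignment is out of scope, so
misalignment is modelled as a read-origin mixture at duplicated loci.

* **Truth sets.** Each locus draws distinct ref/alt bases uniformly, a
  duplication flag (probability `dup_fraction`, default 0.1), and per-sample
  genotypes: hom-alt with probability `allele_freq` (default 0.5), else
  hom-ref, then flipped to het with probability `residual_het_rate`
  (default 0 — the DH expectation). At a duplicated locus the paralog
  carries the non-reference allele with probability `paralog_divergence`
  (default 1; only divergent paralogs can manufacture hemi-SNPs).
* **Pileups.** Observation counts are Poisson(`mean_depth`), per sample.
  Each observation draws its origin (truth haplotype, or the paralog with
  probability `misalignment_rate` at duplicated loci), is substituted
  uniformly to one of the three other bases with probability
  `base_error_rate`, and carries a read length and a within-read position.
  Optional nucleotide bias scales the substitution rate at G/C truth bases
  and drops A/T observations with a deletion probability (deletions are
  modelled only as dropout; indel genotyping is out of scope).
* **Read lengths** are log-normal with the platform mean and CV ≈ 25%,
  floored at 100 bp. A unimodal model is deliberate: libraries prepared
  without shearing have a length mode near the fragment mean, and an
  exponential-tailed model would over-represent near-minimum reads so badly
  that end-trimming 100 bp would discard ~10% of observations instead of
  the ≈ 200/mean ≈ 2.7% that holds when lengths concentrate near the mean.
  Positions within reads are uniform; the recorded offset is the distance
  to the nearer end, which is what end-trim filters consume.
* **Base quality** is a per-platform constant (optionally jittered).
  Reported quality is deliberately decoupled from realised error:
  long-read basecallers are overconfident at error sites, so the realised
  substitution rate is set by `base_error_rate` while `base_qual` sets what
  the caller is told. The constants must sit above the caller's `min_bq`,
  otherwise every observation is excluded. The study configuration uses
  q30 for the SRS-role platform and q20 for the LRS-role platform.

**Study configuration** (`pipeline.study_config`): 9 DH samples; the
SRS-role platform has base error 0.1%, misalignment 0.5 at duplicated loci,
150 bp reads, and per-sample mean depths 4.4–14.4× (deep but variable); the
LRS-role platform has base error 10%, no misalignment, 7525 bp mean reads,
and per-sample depths spanning sub-1× to a few × to emulate uneven pooling.
Simulation "coverage" for a sample is its mean pileup depth — the
panel-level analogue of genome coverage; `coverage_from_reads` provides the
total-bases/genome-size definition for real data.

What the generator does **not** emulate: alignment artefacts beyond the
origin mixture (soft-clipping, mapping-quality structure), error
clustering along reads, locus-to-locus error-rate variation, collapsed
reference regions that inflate depth, and organellar insertions. Passing
tests therefore demonstrate the pipeline's statistical machinery under the
stated error model, not performance on any particular real dataset.

## Concordance analysis

"Accuracy" is concordance of the genotype class between the query platform
and the reference platform over comparable cells (both non-missing), the
operational definition low-coverage genotyping studies use when no
independent truth exists. The reference side is always filtered to a
minimum depth of 2 (no maximum); the query side follows the active
`FilterSpec`. Depth windows are inclusive at both ends, percentages are
reported to one decimal, and non-comparable cells never enter denominators.

Classified discrepancies split into het-in-reference/hom-in-query (in DH
material, likelier a reference-side hemi-SNP), hom-in-reference/het-in-query
(likelier query sequencing error), and opposite-homozygote calls (not
attributable from two platforms alone). *DH-adjusted accuracy* counts the
first class as correct:

  adjusted = %concordant + %discrepant × het-in-reference share / 100.

Per-SNP accuracy keeps SNPs comparable in ≥ `min_samples` samples (default
7 of 9) and reports the cumulative percentage of SNPs whose correct-call
proportion meets each threshold on a 0.1 grid (which contains the
conventional reporting points 0.5/0.8/0.9/1.0). The optimal supporting-read
analysis computes accuracy within exact-DP strata per sample (strata with
fewer than `min_cells` = 20 comparable cells are excluded from the argmax;
ties resolve to the smaller depth) and reports the Pearson correlation of
the per-sample optimum with coverage.

## Heterozygote reassignment

Two rules convert het calls for use outside fully homozygous panels:
PL-based (reassign to the lower-PL homozygote when PL_het ≠ 0; hom/hom PL
tie leaves the call) and AD-based (majority allele by allelic depth; exact
ties left as het — a deliberately conservative choice since the evidence
favours neither class; other-base reads are not part of AD). Both are
idempotent and never touch hom or missing calls. With a likelihood-
consistent caller every called het has PL_het = 0, so the PL rule only
fires on calls produced by callers whose genotype assignment uses
information beyond the likelihood (e.g. allele-frequency priors); the
AD rule fires on any depth imbalance and therefore converts a larger share.
Evaluation windows (dp 2–5, and dp 4–6 for the deeper-support variant) are
expressed as `FilterSpec`s rather than separate code paths.

## Statistics

Coverage–heterozygosity association uses Pearson correlation with the
two-sided t-distribution p-value and significance flags at 0.01 and 0.02;
zero variance in either vector is reported as undefined rather than raised.
%het denominators are all non-missing query calls (after any active depth
window). The nucleotide-bias table conditions query discrepancy rates on
the reference's homozygous class, where the class is the doubled allele
actually called (AA/CC/GG/TT), and tests homogeneity with a chi-square on
the classes × (concordant, discrepant) count table, no continuity
correction; empty classes are reported with zero counts and excluded from
the test. The test's type-I error is verified by simulation to sit at the
nominal rate.

## Numerical and scale choices

PLs round to the nearest integer. All randomness flows from a single
integer seed through `numpy.random.SeedSequence` spawning (per-platform and
per-sample child seeds stay below 2³¹); identical seeds give byte-identical
outputs. Simulation-backed checks use 1,200–12,000 loci and 9 samples;
repeated-seed checks use seeds 0–9. VCF output is a minimal 4.2 dialect
(FORMAT `GT:DP:AD:PL`, missing "./."), parsed back via htslib/pysam so the
writer stays honest against an external grammar.

## Known limitations

* No indel or triallelic genotyping; no BAQ or mapping-quality weighting
  (no alignment exists at pileup level).
* Exact numeric parity with any particular samtools/bcftools version is
  not claimed; those callers add quality recalibration and version-specific
  priors on top of the independent-error model.
* Under the read-replacement misalignment model, the probability a
  duplicated locus shows a het rises with depth inside a 2–5 window
  (sampling both copies becomes more likely), so the misalignment regime
  shows a mild positive coverage–heterozygosity trend rather than the flat
  profile deep real data exhibits; the regime contrast with random error
  (strongly negative vs non-negative) is preserved.
* In the pure random-error regime, accuracy by depth saturates rather than
  peaking, so the "optimal depth" estimator has wide sampling variability
  between near-tied strata; its positive association with coverage is
  robust in sign, less so in small-sample significance.
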