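# Methods

This note records the models, conventions and design decisions behind
svmosaic, in the order the pipeline runs them. It states no numbers that
the test suite or `scripts/acceptance.py` do not themselves compute.

## The synthetic cohort

All stages are exercised on a generated cohort (`svmosaic.synth`) rather
than real reads, because every computation in the package consumes
genotypes, call sets and depth tracks — never alignments. The generator
emulates an elite inbred crop panel:

**Samples and structure.** 102 samples (default) assigned round-robin to
five subpopulations. Genotypes are unphased diploid codes {0/0, 0/1, 1/1,
./.}; samples are inbred, so genotypes are drawn as homozygous haplotype
copies and heterozygosity enters only through the explicit noise channels
below.

**Haplotype blocks.** Each chromosome is partitioned into blocks of
`block_size` consecutive sites (default 150 sites at ~1 site/kb, i.e.
~150-kb blocks). Every block has five common haplotypes (Dirichlet
frequencies) plus one low-frequency haplotype (frequency U(0.01, 0.05)).
Sites in the lowest MAF bin are *private* to the rare haplotype; other
sites take their ALT allele on one of a small per-bin dictionary of
common-haplotype subsets whose frequency sums sit near the bin centres
(0.15/0.25/0.35/0.45). Consequences, both deliberate:

* sites sharing a subset are in perfect LD — tag-SNP pruning has real work
  to do, and the number of LD classes per block is small and dominated by
  common haplotypes, so the tag-SNP saturation curve plateaus early;
* a newly sampled rare haplotype contributes many new variants (all its
  private sites) but only one new tag SNP — which is why the variant
  saturation curve keeps climbing after the tag curve has flattened, the
  qualitative behaviour the saturation analysis is designed to show.

Subpopulation structure perturbs block haplotype frequencies with a
mean-preserving Dirichlet (concentration 30); blocks are independent
(no between-block linkage — a stated non-goal).

**MAF spectrum.** Bin weights default to 35/20/17/14/14% over
[0, 0.1) ... [0.4, 0.5]. The realized histogram matches the weights to
within ~0.05 per bin at 10^4 sites; the residual smearing comes from
finite-sample drift of haplotype frequencies (sd ≈ 0.03 at n = 102) and
from rare haplotypes occasionally drifting to fixation (such monomorphic
sites are excluded). Duplication-artefact heterozygosity also drags
affected sites toward 0.5, so the spectrum property is checked on a cohort
without planted duplications.

**Noise channels.** Background heterozygosity: each genotype flips to 0/1
with probability 0.005 (<1%, matching a fully inbred panel). Missingness:
9%. Planted duplicated segments (default twenty 30-kb segments, 8–20
carriers each) flip carrier genotypes inside the segment to heterozygous at
rate 0.35 and multiply carrier window depth by 2.0; two segments carry no
heterozygosity artefact, so the duplication/heterozygosity concordance has
a known expected value below 1. Artefact heterozygosity is planted at the
genotype level, not via read simulation — the downstream analyses consume
genotypes and depth, not reads.

**Variant classes and QC fields.** Sites are SNP/MNP/indel in proportions
0.815/0.057/0.128 with alleles derived from the generated reference. QUAL,
MQ, depth and per-allele strand-support counts are drawn so that clean
sites pass the filters; violations are planted explicitly by the tests.

**Genes.** Non-overlapping 2–4-exon genes whose CDS is written into the
reference as a real ORF (ATG, no internal stops, terminal stop), so
codon-level impact classification is exact, on both strands.

**SV truth and mock callers.** Per-type truth events with log-uniform
sizes; same-type events are kept >= 2 kb apart so that zero-noise mock
calls can never cross-merge. DUP/CNV truth events are the duplication
segments themselves, keeping the heterozygosity analysis and the SV
catalogue consistent. Three mock callers emulate split-read, paired-end
and read-depth tools: per-caller false-negative rates (0.05/0.12/0.15),
breakpoint jitter (N(0, sd), sd 3/8/15 bp — the scale of real breakpoint
precision), false positives, and type blind spots (the paired-end caller
cannot see tandem duplications or small inversions; the read-depth caller
sees only copy-number types; only the paired-end caller reports
interchromosomal translocations).

**Array subset.** 300 WGS loci (5% indels) re-coded with planted per-class
platform-discordance rates — homozygous 0.3%, heterozygous 1.4%, indel
3.9% — plus 1% missingness and 2% ref/alt-swapped sites to exercise
allele reconciliation. These rates are the study conditions the
concordance machinery is expected to recover.

## Conventions and numerical choices

* **Coordinates.** Genotype matrices and gene models are 1-based inclusive
  (VCF/GFF3 convention); SV intervals, depth bins and window profiles are
  0-based half-open internally, converted at every I/O boundary (a VCF SV
  with POS 1001 / END 2000 becomes [1000, 2000), length 1000).
* **Filter thresholds are inclusive on retention** (removal conditions are
  strict inequalities): QUAL exactly 32, MQ exactly 20, depth exactly 2 and
  MAF exactly 0.02 are all kept. A record failing several rules is tallied
  once, at the first rule in the order: allele count, strand support, QUAL,
  MQ, depth, MAF.
* **Depth rule interpretation.** The depth filter is applied to the
  site-level mean by default; a per-sample mode (mask under-covered
  genotypes, drop the site only if nothing callable remains) is available
  via `FilterConfig(depth_mode="sample")` — the per-site reading is an
  interpretation, so both are implemented.
* **MAF bins** are left-closed right-open with the final bin closed at 0.5,
  so the five bins partition [0, 0.5] with 0.1 falling in the second bin.
* **Splice sites** are the canonical 2-bp intron termini (donor at the
  intron's 5' end in transcript orientation). Introns shorter than 4 bp
  are not given splice termini.
* **Impact precedence** within a coding substitution: stop gained > start
  lost > stop lost > missense > synonymous; a variant touching several
  genes reports every per-gene effect and summarizes with the most severe.
  MNPs are kept as block substitutions and classified codon-by-codon.
* **LD estimation** treats homozygous inbred genotypes as haplotypes and
  excludes heterozygous/missing calls pairwise — no EM phasing, defensible
  because the cohort is inbred and residual heterozygosity is largely
  artefactual. Perfect LD means r² within 1e-9 of 1.
* **Pruning** slides a 50-SNP window by one site, so any pair within 49
  index positions is co-windowed; perfect-LD groups are transitive closures
  of such pairs, and the left-most member of each group is the tag
  (deterministic tie-break). A pruned site is connected to its tag by a
  chain of perfect-LD edges; the *direct* pruned–tag r² can be below 1
  because each edge is estimated on its own pairwise-complete sample set.
* **LD decay** is the midpoint of the first distance bin whose mean r²
  falls below the threshold with all later occupied bins also below it;
  if that never happens the result is flagged open-ended rather than
  extrapolated.
* **The imputer** is a deliberately simple k-nearest-neighbour haplotype
  matcher (defaults k = 5, w = 50 typed flanking sites; both are this
  package's parameters, not study-derived): Hamming distance over the
  window, majority vote, ties toward the panel-major genotype. Panel
  samples at distance zero (exact local haplotype match) take precedence
  over the fixed-k vote, so a target identical to a panel sample is
  reproduced exactly. It is a protocol stand-in for model-based imputation
  engines — the *evaluation protocol* (leave-one-out at untyped loci, five
  seeded permutations without replacement, accuracy = fraction of imputed
  genotypes identical to the withheld truth, het/hom classed by the truth
  genotype) is the object under test, not the imputer.
* **SV merge criteria** (80% reciprocal overlap AND both breakpoint offsets
  <= 250 bp for intervallic types; offsets only for insertions and
  translocations) are conjunctive, and components are single-linkage —
  standard in SV site-list construction and deterministic. Representative
  breakpoints are lower medians of member coordinates; breakpoint
  precision is the largest member offset from the representative. DUP
  (dispersed) and CNV (tandem) are distinct types and never cross-merge.
* **Read-depth ratio direction.** The ratio is carrier depth over
  non-carrier depth, so the single published bound (< 0.75) is physically
  meaningful for losses only; deletions must fall below it and
  duplications/CNVs must exceed its reciprocal (> 1.33); balanced and
  point events are exempt. Copy-number calls without a ratio are
  unevaluable and tallied separately rather than silently passed.
* **Inversion support ratio.** "Genotyped to ungenotyped > 0.4" is read
  literally (genotyped/ungenotyped); the alternative genotyped/total
  reading is available via `inv_ratio_mode`.
* **Cross-tool concordance** is reported at two levels: per *call*
  (fraction of individual calls in >= 2-tool components — the literal
  ConcordanceStats contract) and per *site* (fraction of consensus sites
  with >= 2 tools — the quantity meant by "X% of SVs were called by at
  least two tools", and the one that equals a planted agreement rate).
  The weighted mean is over DEL/INS/INV/DUP, weighted by their counts.
* **SV-gene scenarios** are positional, not strand-aware (they describe SV
  geometry, not regulation). Boundary convention: an SV containing every
  gene base is `whole_gene`; an SV whose bases all lie inside the gene is
  `in_gene` (the degenerate equal case counts as `in_gene`). Insertions
  are points by default (only `in_gene` is realizable); interval semantics
  using the reported insertion length are behind `ins_as_interval`.
  Inversions and translocations count a gene only on breakpoint contact.
  A multi-gene hit contributes each scenario to the counts but once to the
  site-level "affects genes" percentage, keeping percentages <= 100.
* **Heterozygosity clusters.** Windows default to 100 kb / 50 kb steps on
  real-genome scales (the toy cohort uses 5–10 kb); the cluster threshold
  is 10x the per-sample background with an absolute floor of 0.05, and a
  zero background without an absolute threshold is an error. With few
  sites per window the rate is quantized at 1/n_sites, so window size
  should give >= ~10 informative sites per window for the threshold to
  separate artefact (0.35) from background (0.005) cleanly — the planted
  recovery analyses use windows of one tenth the duplication length at 10
  sites per window. "Coincided" is any overlap between a call interval and
  a cluster of a *carrier* sample, at the call level; region-level scoring
  (calls merged across samples) is behind `mode="region"`.

## What passing on synthetic data does and does not show

The generator plants exactly the structures the analyses look for: block
LD, known per-class platform discordances, duplication-driven
heterozygosity with elevated depth, caller error models with known rates.
Passing therefore shows the machinery is correct — filters remove exactly
the planted violations, clustering equals an independent union-find
oracle, planted rates and intervals are recovered within sampling error.
It does not show robustness to what the generator omits: alignment
artefacts, reference errors, segmental-duplication mimicry beyond the
planted model, LD decay within blocks, genotyping-error correlation
between platforms, or SV breakpoint microhomology. Absolute headline
numbers from the real study (millions of variants, array-scale
concordance counts) are scale-dependent and are not reproduced at desk
scale; the acceptance script reports the toy-scale analogues its own runs
produce.

## Problem sizes

Defaults were chosen so the whole test suite runs in well under a minute
and the acceptance script in seconds on one CPU: 2 chromosomes x 2 Mb,
4 000 sites x 102 samples for the default cohort; 8 000 sites x 60 samples
for the duplication-recovery experiment; 50 replicates for agreement-rate
recovery; 10 replicates per subset size for saturation curves.
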