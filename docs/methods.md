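# Methods

## LOH calling and typing

Input is a per-SNP allele-specific copy-number track (sample, chrom,
pos, major_cn, minor_cn), the kind of output an array or sequencing
pipeline produces after comparing tumour genotypes to the matched
normal at germline-heterozygous sites.  A position is called LOH when
the minor allele carries fewer than 0.5 copies; positions with
minor_cn ≥ 0.5 are allelic imbalance, never LOH.  Runs of same-state
adjacent positions are merged into maximal half-open segments whose
boundary is the first probe of the next run; the last run on a
chromosome is closed one modal probe-spacing after its final probe, so
segments tile an evenly spaced grid exactly.  Merging is by LOH state
only, so a segment can span a CNL→CNN transition; its type is then
decided by the mean total copy number, which can misassign a small
minority of loci (< 0.1 % of (sample, locus) pairs at default noise).

Typing uses mean total copy number with the CNL/CNN boundary at 1.5
copies — the midpoint between one and two copies — with the boundary
value itself assigned CNN.  The underlying data only define the two
types conceptually (deletion versus duplication/conversion of the
retained allele); the numeric split is this package's choice, and a
continuous rather than integer-state rule is used because
allele-specific copy-number estimates are continuous.  Homozygous
deletion is total copy number below 0.5.

Locus summaries: LOH frequency is LOH samples over informative
(covered) samples.  A locus is CNL-enriched when strictly more than 2/3
of its LOH samples are CNL (matching a ">66 %" rule), CNN-enriched
symmetrically, "insufficient" below 20 % LOH frequency, else
"neither".  Candidate regions are loci above 35 % LOH frequency overall
or within any histological subtype, or loci overlapping a homozygous
deletion recurrent in ≥ 2 samples ("recurrent" is not numerically
defined in the source material; two is the weakest reading).

## Statistical kernel

All tests are deliberately minimal and verified against brute-force
oracles in the test suite:

- `chisq_gof_2(a, b)`: 1-df Pearson goodness of fit against an equal
  split, no continuity correction.  The uncorrected statistic is a
  deliberate choice: the published benchmark split 22 vs 6 yields
  p = 0.0025 uncorrected (statistic 9.143) whereas the Yates-corrected
  value would be ≈ 0.0046.
- `chisq_2x2`: uncorrected Pearson χ² on a 2×2 table; degenerate
  (zero-margin) tables raise rather than returning NaN.
- `binom_two_sided`: exact two-sided binomial under the "minlike"
  convention (sum of outcome probabilities no larger than the observed
  outcome's, with the conventional 1e-7 relative tie tolerance), the
  same convention as R's `binom.test`.  Published bound-level claims
  (p < 0.0001 and similar) are insensitive to the convention; minlike
  is fixed here and documented.
- `welch_t`: two-sided unequal-variance t-test; groups with fewer than
  two values or zero variance are rejected so callers skip-and-count
  instead of propagating NaNs.
- `bonferroni_threshold(m, α) = α/m` over the m features actually
  tested, not the number annotated — at 22 374 methylation probes and
  α = 0.05 this is 2.2×10⁻⁶.  At 10 925 expression genes the computed
  threshold is 4.58×10⁻⁶; the slightly different figure sometimes
  quoted for that analysis (4.56×10⁻⁶) implies a marginally different
  denominator that cannot be reconstructed, so the exact α/m definition
  is used.

## The five models

**Classic two-hit (screen).**  Raw tumour/normal calls are accepted as
somatic only if (i) not called in the matched normal, (ii) supported by
fewer than 2 reads in the normal, (iii) seen on both strands in the
tumour.  Consequences map to three classes: synonymous; other
non-synonymous (missense, in-frame indel); overtly deleterious
(nonsense, frameshift, essential splice site — plus gene deletions at
the gene level).  A (gene, sample) pair is biallelic via mutation
inside an LOH segment, gene-footprint mean total copy number below the
homozygous-deletion threshold, or two mutations at distinct positions;
phase consistency between mutation and LOH is not assessable from
array-plus-exome data and is not attempted.  Three discovery filters:
(1) recurrence — an upper-tail exact binomial test of the gene's
mutation count against the cohort background rate × gene length ×
samples, flagged at Bonferroni α across genes tested (a deliberately
simple, verifiable stand-in for full background-rate modelling
frameworks, whose convolution/likelihood-ratio machinery is out of
scope here); (2) biallelic proportion bands — > 80 %, 60–80 % (a
proportion of exactly 0.8 falls in the lower band), or 2/2 mutated
samples; (3) deleterious majority — strictly more than half of the
gene's inactivating events.  "Exactly half" fails, by construction.

**Epigenetic two-hit (methylation).**  Beta values are categorised high
(> 0.75), low (< 0.25) or intermediate — both cut-offs open, so the
boundary values are intermediate — and contrasted per probe between
samples with and without LOH at the probe's locus.  The per-feature
test is Welch's t; the data carry no named test for this contrast, so
the test function is injectable (a rank-based alternative can be
swapped in) and Welch is the documented default.  Significant probes
get a fold-change class (LOH/no-LOH mean ratio > 1.5 up, < 0.75 down)
and are stratified by their locus's CNL/CNN enrichment class, compared
by 2×2 χ².  The X chromosome is analysed as its own stratum: with one
copy inactivated (intermediate beta), LOH that retains the active copy
lowers methylation — the opposite direction from the autosomal
hypermethylation model — so the model verdict is based on autosomal
probes only.

**Mutation load (enrichment).**  For each class × stratum cell, the
observed fraction of mutations inside the stratum is tested against the
fraction expected under uniform placement on each sample's gene
territory.  The expectation weights samples by the number of mutations
they contribute (each mutation is one binomial trial with its own
sample's territory fraction as success probability); the unweighted
per-sample mean is reported alongside, because a cohort-level summary
of territory is usually quoted that way.  A single aggregated exact
binomial test is used rather than a per-sample meta-analysis.  Known
driver genes (e.g. a TP53-like outlier) can be excluded via a toggle
that removes their mutations from both numerator and denominator.

**Haploinsufficiency (expression).**  Identical contrast machinery on
the expression matrix (log-scale values expected): genes under-expressed
in LOH carriers, concentrated at CNL-enriched loci.

**Risk retention.**  For each predisposition SNP (or an LD proxy with
r² > 0.7 inheriting the lead SNP's risk-allele orientation), germline
heterozygotes are tabulated by tumour genotype into het / aa / bb / nc,
with germline homozygotes uninformative (hom).  Tumour homozygosity is
taken from genotype calls, not segment overlap, so extreme allelic
imbalance can be included — the table carries everything needed to
cross-check against called segments.  The direction test is
`chisq_gof_2(aa, bb)`; direction is `risk_retained` when the
tumour-homozygous class carrying the risk allele is larger, and is
always computed from the counts (significance is reported separately).
%LOH is (aa+bb)/(het+aa+bb).  Loci with several SNPs are summarised as
concordant / partially supported / discordant by the directions of
their significant SNPs.

The package bundles the published genotype counts at 18 ovarian-cancer
GWAS SNPs in a 364-case cohort (`lohsel/data/ovarian_gwas_snp_loh.tsv`)
— real printed data, margin-checked on read — as both a regression
benchmark and a worked input for the `table2` command.

## Synthetic cohort

The generator emulates the data structure the analyses consume, with
ground truth retained, on a toy genome of fixed-size 10-kb gene bins
(default 1000 loci: four autosome-like chromosomes plus one X-like).

- **Segments.** LOH is segmental: within each chromosome arm a
  stationary two-state Markov chain over loci produces contiguous
  segments with geometric lengths (mean 25 loci).  The chain enters
  each arm at its stationary frequency, so realized territory hits the
  target in expectation exactly.  Arm-level frequency weights
  (1 ± 0.45, alternating hot/cold arms) give the genome both
  candidate-region territory (> 35 % LOH) and insufficient territory
  (< 20 %).  Defaults place 26.8 % of the exome in CNL-LOH and 8.7 % in
  CNN-LOH per sample — the headline territory figures of the motivating
  ovarian-carcinoma analysis — via chromosome-level CNL shares (0.95,
  0.90, 0.85, 0.20, 0.875): chromosome 4 is CNN-dominant so both locus
  classes exist.  Homozygous deletions are planted at configurable loci
  in 3 samples each; an optional two-hit driver forces CNN-LOH plus a
  deleterious mutation in a configurable fraction of samples.
- **Copy number.** One probe per locus; Gaussian noise (sd 0.05) around
  (1,1), (1,0), (2,0) or (0.12, 0.05)-like states; minor ≤ major
  enforced.  At this noise the caller recovers > 99.9 % of
  (sample, locus) states.
- **Mutations.** Poisson per sample (default 0.01 per gene bin — bins
  are several-fold larger than typical coding genes); class mix
  (0.25, 0.62, 0.13) for synonymous / other non-synonymous /
  deleterious, taken from the observed 139/561 synonymous and 72/561
  truncating proportions in the motivating screen.  Deleterious
  mutations sample genes with weight k (default 1.2, ≈ the observed
  10.3 %/8.7 % CNN excess) where the sample has CNN-LOH.  A 5 % admix
  of artifact calls (germline evidence, ≥ 2 normal reads, or
  unidirectional support) exists purely to exercise the somatic filter;
  artifacts fail it by construction.
- **Methylation.** Two-component Beta mixture — Beta(2,8) unmethylated
  (70 % of probes), Beta(8,2) methylated — so the 0.25/0.75 categories
  are meaningful.  A planted 10 % of unmethylated autosomal probes gain
  +0.3 beta in LOH carriers.  X-like probes are Beta(5,5)
  (one-methylated-copy pattern) and lose 0.3 in LOH carriers,
  emulating retention of the active copy.
- **Expression.** Gene means N(8, 1), noise sd 1.0; CNL-LOH carriers
  shifted by −1.0 (one noise sd).
- **Risk SNPs.** Six SNPs at high-LOH loci in three 2-SNP loci; one
  locus carries retention odds 4 (an LOH event keeps the risk allele
  with probability 4/5), the others are unbiased; Hardy–Weinberg
  germline genotypes, 3 % no-call rate per compartment.

All randomness flows through one seeded generator in a fixed draw
order (segments → deletions → two-hit → copy-number noise → mutations →
methylation → expression → genotypes); identical seeds give
byte-identical files.  The run manifest records SHA-256 digests per
output and no wall-clock information, so the whole run directory is
reproducible bit-for-bit.

What the simulator does **not** model: tumour purity and subclonality,
read-level sequencing error, probe-level measurement correlation,
cell-type heterogeneity in methylation, LD structure beyond a fixed r²
annotation, and real genome annotation.  Passing recovery tests
therefore show that the analyses detect their targets when the data
match the stated generative assumptions — not that those assumptions
hold in any real cohort; the published consortium-scale fractions
(29.7 % of mutations in LOH, 34.6 % of genes differentially expressed,
and similar) depend on external data and are out of reproduction scope.

## Calibration and power

`lohsel.calibration` runs all five models in memory.  Null calibration
disables every planted effect (enrichment 1, shifts 0, expression
effect 0, odds 1) and pools each model's significant calls — under its
own decision rule: Bonferroni for the screen and the per-feature
contrasts, raw α for the mutation-load panel and the retention tests —
over replicates; each rate must sit at or below α up to three binomial
standard errors, and raw per-feature p-values must be uniform (rejection
rate within [0.03, 0.07] at α = 0.05).  Power uses strong effects
(deleterious CNN enrichment 3, methylation shift 0.3, expression effect
−1 sd, retention odds 4, a planted two-hit driver in 30 % of samples) at
100 samples and requires each model to recover the planted direction in
more than 80 % of replicates.  The shipped configurations use 100 null
replicates of 40 samples × 120 loci and 15 strong replicates of
100 × 500 — sizes chosen to estimate the rates adequately at desk
scale; all observed powers are 1.0 and null rates ≤ 0.05.

## Numerical conventions and edge cases

Coordinates are 0-based half-open everywhere; BED on disk for
intervals, MAF-style tables for mutations (standard
`Variant_Classification` vocabulary, mapped to the three-class scheme
on read).  p-values are kept at full double precision and rounded only
for display.  Degenerate inputs fail loudly and specifically: both
counts zero, zero-margin 2×2 tables, undersized or constant t-test
groups, unsorted copy-number tracks, counts tables whose margins do not
reconcile.  Features skipped in a contrast (fewer than two samples per
arm) are excluded from the Bonferroni denominator and reported with a
reason.  A retention table with no allele-loss events yields no test
and direction `none`.
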