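# Methods

snapcall performs short-read secondary analysis — paired-end alignment,
duplicate marking, base quality score recalibration (BQSR), indel
realignment, per-base SNAPSHOT construction and Bayesian variant calling —
entirely in memory, plus tumor–normal somatic SNV/indel and CNV calling
that operate on stored snapshots. This note documents the models, the
numerical choices, and what the bundled simulator does and does not emulate.

## Alignment

Reads are seeded with non-overlapping k-mers (default k=16) against a hash
table of reference k-mers; k-mers occurring more than `max_occ` (64) times
are treated as repetitive and yield no seeds. Seed hits clustered on a
common diagonal nominate candidate loci. Candidates are scored with an
affine-gap local alignment (match +1, mismatch −4, gap open −6, gap extend
−1, so a length-L gap costs 6+L; read ends may be soft-clipped whenever
clipping improves the score). Reads whose seeds agree on one diagonal and
differ from the reference by at most two interior substitutions take a
gapless fast path whose result is provably identical to the DP optimum.
The DP kernels are numba-compiled; their scores are verified against an
independent plain-Python Smith–Waterman in the test suite.

Mates are paired by maximizing `score1 + score2 + pair_bonus`, the bonus
applying to opposite-strand placements with insert within mean ± 4 sd
(default 500 ± 25). A seedless mate is rescued by DP inside the window its
partner and the insert model imply. Mapping quality is 60 when the best
candidate beats the runner-up by ≥10 score points, otherwise
`6·(best − second)` clamped to [0, 60], and 0 for exact ties — a simple
monotone measure of placement ambiguity.

## Duplicate marking

One hash pass over pairs keyed by the unclipped 5′ coordinates and strands
of both mates (canonically ordered, so mate order does not matter). Within
a key, the pair with the highest summed base quality survives; ties keep
the first seen in input order. No coordinate sort is required, and the
kept-set size is invariant under permutation of the input.

## BQSR

Covariates are (reported quality, machine cycle in sequencing orientation,
preceding+current dinucleotide in sequencing orientation). Candidate
variant sites — positions whose first-pass pileup shows a non-reference
allele fraction ≥ 0.2 — are masked, replacing the usual known-sites
database and keeping the tool self-contained; this slightly over-masks in
noisy regions, which only costs observations. Empirical quality per cell
is `phred((mismatches+1)/(observations+2))` (add-one smoothing avoids
infinite qualities in clean cells), capped at Q60. Bases in cells never
observed during training fall back to the reported-quality marginal.
On simulated reads with a uniform true error rate the recalibrated
qualities converge to the true phred value within ±1 (tested).

## Indel realignment

Every gapped alignment op, left-normalized, nominates an indel hypothesis;
identical hypotheses merge with summed support and those below
`min_support` (2) are dropped. Soft-clip clusters of ≥4 reads sharing a
boundary seed an insertion hypothesis from the majority consensus of the
clipped bases. Hypotheses are grouped into windows (anchor ± 100 bp,
merged when closer than 200 bp, split above 400 bp, at most the 8
best-supported hypotheses per window).

Each window haplotype is the reference edited by a single hypothesis.
All overlapping reads are scored against all haplotypes with the aligner's
DP kernel. Because haplotypes carry one event each, selection is greedy and
iterative: the haplotype maximizing the achievable summed read score is
applied, its strict improvers are rewritten into reference-space alignments
through the event, and the remaining hypotheses are reconsidered until none
helps — so a window containing several nearby true indels resolves all of
them. Two guards matter in practice:

* a read only counts toward (and is only rewritten onto) a haplotype when
  it gains at least the gap-open cost (5). Gains of 1–3 come from restoring
  soft-clipped read ends, which cannot distinguish a real event from a
  clipped mismatch; without this rule, clip-consensus hypotheses adjacent
  to homozygous SNPs acquire false support.
* leading/trailing insertion ops produced by remapping fold back into soft
  clips: a read tail reaching only part-way into an insertion would
  otherwise mint a spurious partial-payload event.

Total DP score over a window never decreases, and realigning an
already-realigned window is a no-op (both asserted).

## SNAPSHOT

The snapshot stores, per reference position: stranded counts, recalibrated
quality sums and mapping-quality sums per base; an N/other count; a
deletion-span count (reads whose deletion covers the position); and indel
event tables (inserted sequence → stranded counts + quality sum; deletion
length → stranded counts). Insertions anchor on the reference base to
their left, matching VCF anchoring. A read carrying an indel anchored at p
contributes the event observation there instead of its aligned base, so
depth = bases + N/other + deletion spans + events counts each overlapping
read exactly once.

The outermost 3 aligned bases of every read are tallied in the N/other
bucket rather than as base evidence. A read that ends at or just past an
indel anchor is consistent with both the indel and the reference; letting
it vote for the reference base biases homozygous indels toward
heterozygous calls (switching this rule on took indel genotype concordance
from 96.3% to 100% at 1 Mb/40× in development-scale runs of the bundled
simulator).

On disk, columns are chunked into blocks of 65,536 positions,
deflate-compressed, CRC-checked, and indexed by (region, block start) so a
point query decompresses exactly one block. The header records the
reference checksum; calling from a stale snapshot against the wrong
reference fails loudly. In exome mode only the BED-declared regions are
stored and off-target queries raise an out-of-coverage error rather than
returning empty columns. Serialization is lossless: calling from a loaded
snapshot reproduces the original VCF byte for byte.

Known fidelity gaps versus a BAM: per-read identity is not recoverable,
and only the mapping-quality *sum* per base cell is kept (enough for mean
MQ annotations, not full MQ histograms).

## The 16-genotype model

At each site the caller enumerates 16 diploid genotypes: the 10 unordered
base pairs, four base/indel heterozygotes {A/I, C/I, G/I, T/I}, the
homozygous indel I/I, and the compound heterozygote I₁/I₂, where I and
I₁/I₂ bind to the best- and second-best-supported indel events at the
column (ties break deterministically). Genotypes referencing an indel
allele with no backing event have likelihood −∞ and posterior 0.

Each read is one observation: a base, or an indel event. An observation o
with error probability ε has P(o|a) = 1−ε if o matches allele a and ε/3
otherwise; a genotype {a1,a2} sees the even mixture. Because the column
stores quality sums rather than per-read qualities, ε derives from the
cell's mean quality (clamped to [1e−6, 0.75]); deletion events, which
carry no quality of their own, use the column's mean base quality
(fallback Q30). Deletion-span reads count toward depth but cast no allele
vote: spans are shadows of deletions anchored at an upstream column, and
letting them support this column's deletion alleles allows one stray
mis-anchored event to inherit the full support of its neighbour
(measured as the dominant false-indel mode in development).

Priors: θ_snp = 1e−3 split over the three alternative bases with
transitions twice as likely as either transversion, hom-alt at θ_snp/2,
θ_indel = 1e−4 for ref/indel heterozygotes, θ_indel/2 for I/I, θ_indel²
for I₁/I₂, θ_snp·θ_indel·w for base-alt/indel pairs, and the homozygous
reference genotype absorbing the remainder (priors sum to one). QUAL is
the phred-scaled posterior of the homozygous-reference genotype, capped at
10,000; a site is emitted only when the posterior argmax is not hom-ref.

Sites without indel events are evaluated with a vectorized 10-genotype
computation that is exactly the 16-genotype model restricted to its finite
entries; event sites run the full per-column model. Both agree with an
independent brute-force implementation to 1e−9 (tested on 1,000 random
columns).

## Filtration

A random forest (200 trees, seeded) classifies calls using QUAL, depth,
alt fraction, strand bias (phred-scaled Fisher exact), mean mapping
quality, mean alt base quality, homopolymer run length, distance to the
nearest other call, an indel flag and indel length. Training data comes
from a fresh labeled simulation (truth matches = positives; the rest plus
a degraded no-realignment companion run = negatives). Decision rule:
probability ≥ 0.95 and QUAL ≥ 30 → PASS; probability ≥ 0.95 with QUAL <
30 → LowQual; otherwise RF_FAIL. Without a model calls pass through as
UNFILTERED.

## Somatic calling

The joint posterior over all 16×16 genotype pairs is
prior(G_n)·P(D_n|G_n)·T(G_t|G_n)·P(D_t|G_t), with T holding the genotype
with probability 1−μ and spreading μ = 1e−6 uniformly over the other 15.
Indel alleles bind to the pooled tumor+normal event ranking so I means the
same event in both samples. The somatic score is the phred of one minus
the posterior mass of pairs with hom-ref normal and a novel tumor allele;
calls need score ≥ 30, depth ≥ 8 in both samples, normal alt fraction
< 0.03 and (for SNVs) at least one alt read per strand. Tumor purity is
not modeled; alt fractions are reported for post-filtering.

## CNV calling

Per 1,000 bp window, the depth ratio r = log2((t/med_t)/(n/med_n)) is
computed over windows with normal depth ≥ 10, GC-corrected by subtracting
per-GC-bin (2% bins) medians estimated from apparently copy-neutral
windows only — a bin dominated by a real event would otherwise subtract
the event out of its own windows. Segmentation is recursive binary
splitting: the split maximizing a two-sample t statistic with a *global*
noise sigma (MAD of first differences — a within-segment variance estimate
would absorb short embedded events) is accepted while its
Bonferroni-adjusted p stays below 1e−4; adjacent segments with
|Δmean| < 0.2 are merged back, and each boundary is refined within ±5
windows by minimizing the within-segment sum of squares. States: GAIN at
mean ≥ +0.3, LOSS at ≤ −0.3, else NEUTRAL. Fewer than 50 usable windows
is an error, not a silent empty result.

## Simulator

The generator emulates Illumina-style WGS data: 100 bp paired-end reads,
FR orientation, Gaussian insert (500 ± 25), substitution errors rising
linearly from 0.1% at the first cycle to 0.5% at the last, reported
qualities equal to the cycle's true phred value jittered by ±3, and rare
(1e−5/base) 1 bp read indels. Variants are Poisson-placed (SNPs with a
2:1 ts:tv ratio; indel lengths geometric p=0.4 capped at 20; het fraction
2/3 with the carrier haplotype chosen at random), left-normalized, and
overlaps dropped. Tumor genomes add het somatic edits disjoint from
germline events and scale fragment sampling inside CNV regions by
copy-number/2; trios transmit one whole haplotype per parent (no
recombination at megabase scale) with optional forced de novo SNVs.
Every read records its true origin, so aligner accuracy and truth
coverage are exactly measurable.

What the simulator does not emulate — and hence what passing tests cannot
certify on real data: base-composition and GC-coverage bias (beyond CNV
scaling), PCR and optical duplicate structure, sequencer-specific error
motifs, mapping ambiguity from genome-scale repeat families, and
contamination/sub-clonal tumor fractions.

## Evaluation

Calls and truth are decomposed into (pos, ref, alt) alleles and
left-normalized through one shared routine; SNPs match on site + alt,
indels on the full normalized triple. Truth is restricted to variants
covered by ≥1 simulated read. Sensitivity, FDR, genotype concordance and
depth/alt-fraction strata are reported; the report is invariant under
permutation of the call list.

## Problem sizes

Development and acceptance runs use a 1 Mb genome at 40× (≈400,000
reads), which the full pipeline processes in a few minutes on one core;
unit and property tests use 20–120 kb genomes at 20–40×. SNP and indel
planting rates in the headline experiment are both 1e−3 so that FDR
estimates for the two classes rest on comparable call counts (~1,000
each).

## Known limitations

Single-sample germline calling only (no joint/population calling); one
read group (no lane/flow-cell covariates in BQSR); single-event realignment
haplotypes (two planted indels closer than ~10 bp can shadow each other);
no split/chimeric alignment; somatic calling assumes purity 1.0; CNV
segmentation assumes roughly uniform window noise after GC correction.
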