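# Methods

## The collapsed four-copy model

The pipeline models a gene whose internal exon block is duplicated into a
pseudogene at high identity. When the pseudogene interval of the reference
is hard-masked, reads from all four haplotype copies (two gene, two
pseudogene) align to the gene. Every downstream statistic follows from
counting copies:

* **Allele balance.** At a homology position, a variant on `a` of the four
  copies is expected in a/4 of reads. The genotyper scores
  `Binom(alt | depth, p_θ)` with `p_θ = θ(1−ε) + (1−θ)ε/3` over
  θ ∈ {0, ¼, ½, ¾, 1} (unique regions: {0, ½, 1}). ε is a symmetric
  per-base substitution error (default 0.01); the ε/3 term routes errors
  uniformly to the three non-template bases. The ¾ and 1 states (hom in one
  locus plus het/hom in the other) are genuinely rare and carry prior mass
  0.01 each; the other states share a flat prior. A site whose top two
  log-likelihoods are within 2 nats is flagged ambiguous and is exactly the
  material the long-read stage exists for. Depth 0 is an explicit no-call.
* **Read depth.** A heterozygous deletion in either locus removes one of
  four copies: the combined depth ratio is 0.75 and the combined copy
  number grid is cn ∈ {0..6} with expected level cn/4 of the homology
  baseline (cn/2 in unique regions). The deliberately conventional
  "diploid-grid" mode treats the observed collapsed level as diploid and
  tests {0, ½, 1}: 0.75 is closer to 1 than to ½ under any Poisson-like
  likelihood, so the event is missed — the mechanism that loses these
  calls in practice, kept as a reproducible control.
* **PSV evidence.** Positions where the two loci differ (paralogous
  sequence variants) are recovered by aligning the pseudogene into the gene
  (edlib, banded edit distance; for substitution-only divergence the
  aligned span equals the pseudogene length and PSVs are read off
  column-wise, which avoids the optimal-path ambiguity where a mismatch
  pair ties with an indel pair). Under a combined cn=3 call, the
  pseudogene-base fraction at PSVs inside the event shifts from 2/4 to 2/3
  (gene copy lost) or 1/3 (pseudogene copy lost); a pooled binomial
  log-likelihood ratio `(2·n_pseudo − n)·ln 2` with a 3-nat threshold
  decides the attribution. Relatedness of a candidate pair is gated on
  normalised edit distance (> 0.45 refuses), because an edit-optimised
  alignment of unrelated random DNA still attains ~0.54 column identity.

## Synthetic data: what it emulates and what it does not

The generator builds uniform-random DNA with an exon/intron ladder,
duplicates exons `dup_first..dup_last` (plus intervening introns) into a
pseudogene, and plants PSVs uniformly at density 1 − identity (default
0.98), forcing at least one PSV per duplicated exon so every exon is
locus-resolvable. Default geometry: 12 exons, exons 4–10 duplicated,
exon length 1250 bp, intron length 1200 bp — five unique exons serve as
depth controls. The exons are wider than typical human exons; this is a
deliberate desk-scale choice (see "operating points" below), and the
86-exon mimic of the real geometry is exercised separately in the tests.

Short reads are 150-bp pairs from uniform fragments of 150–300 bp, the
published library's range; `coverage` means collapsed depth over the
homology block (each haplotype sequenced at coverage/4). Long reads have
log-normal lengths (mean 6 kb, sd 2 kb), 3% substitution and 2% 1-bp indel
errors, and `coverage` means per-locus diploid depth, matching how a
targeted long-read run is quoted. Fragments are drawn from the four
haplotypes in proportion to their length, i.e. with equal per-base weight —
equal *fragment* counts per haplotype would skew PSV fractions away from ½
and break the a/4 arithmetic. Quality strings are constant (Q30/Q12);
callers take explicit error-rate parameters instead. Not modelled: GC and
strand bias, PCR duplicates, quality-profile errors, reverse-complement
orientation (the built-in mapper is forward-strand and both mates are
written in reference orientation — the collapse phenomenon is
orientation-independent), capture bias, or multi-copy (>2 paralog)
families. Passing tests therefore demonstrate the copy-counting logic, not
robustness to real-library artefacts.

## The built-in mapper

Seed-and-extend at toy scale: exact k-mers (k = 15, k ≥ 11 enforced) of the
masked reference are indexed — k-mers containing N are never indexed, so
placement on masked sequence is impossible and the four-allele collapse is
structural. Anchors group into exact-diagonal runs (split at gaps > 50 bp);
a chaining DP maximises anchored read coverage with a penalty of
4 + 0.02·|Δdiagonal| per junction, scoring only the marginal coverage of
overlapping segments. Between chained segments, equal short gaps are taken
as substitutions, small unbalanced gaps are closed with edlib, and gaps
whose net indel exceeds 30 bp get an exact mismatch-minimising breakpoint
split (leftmost optimum), so a multi-kilobase deletion becomes a single `D`
op with reproducible breakpoints. Flank extension stops at masked bases,
contig ends, or when running mismatches exceed 0.3·length + 2 (junk guard);
clipped bases never enter pileups. Ties in chain score break to the
leftmost position. Externally produced SAM is accepted (pysam) and
alignments are emitted as minimal SAM.

Allele extraction for long reads uses local realignment: the read slice
over a ±25 bp window is compared by edit distance against the reference
context and the alternate-haplotype context. CIGAR-walk extraction is
brittle when a 1-bp sequencing indel sits next to the site (the aligner may
phase it either side), which costs ~10% of reads at a site; realignment
reduces the miscall rate to roughly the substitution error.

## Operating points and why

These were fixed by design-time power analysis on the generative model
(Poisson fragment counts), before the test expectations were frozen:

* **Depth statistic**: fragments overlapping a probe-padded exon target
  (pad 600 bp), because mates of a pair are correlated and fragment counts
  are the independent unit. Effective capture spans are computed per copy —
  gene copies clamp at contig ends, pseudogene copies at homology-block
  edges — otherwise edge exons sit ~10–15% low at baseline and fail as
  false deletions.
* **Exon/target size**: at 100x collapsed depth a 0.75-vs-1.0 ratio on a
  ~200-bp target is statistically undetectable at the required operating
  point (~1σ separation); the default geometry's ~2.4-kb targets give
  per-exon fragment counts near 900 so the het-deletion log-likelihood
  gain is ~30 nats.
* **CNV call margin 6 nats** (MAP cn must beat baseline by this much):
  chosen so a full 12-exon null profile produces a call in < 1% of samples
  while het-deletion sensitivity stays ≥ 95% and the diploid-grid baseline
  stays ≤ 20%. Dispersion φ defaults to 1.3 (mild overdispersion typical
  of capture data; Poisson at φ = 1); simulation studies in the tests run
  the caller at φ matching the Poisson generative model where stated.
* **Candidate scan** min_alt_frac = 0.12: catches θ = 0.25 sites with
  ≥ 99% sensitivity at 100x by the binomial tail, while PSV columns are
  suppressed as reference-state unless their pseudo-base fraction departs
  from ½ by more than 0.2 (such departures are copy-number signal).
* **Long-read binning threshold 3 nats** at q = 0.05: a read spanning five
  PSVs needs four of them flipped by error to be misassigned, an exact
  binomial tail of ~3×10⁻⁵ (< 10⁻³).
* **Deletion clustering tolerance 60 bp**: a 1-bp read indel adjacent to
  the junction shifts a single read's apparent breakpoints by tens of
  bases; clustering is generous and the reported breakpoints are cluster
  medians, which land within ±2 bp of truth in the tests. Split alignments
  (two pieces of one read flanking a reference gap, contiguous on the read
  within the tolerance) are merged into the same deletion signal.
* **Phasing**: greedy read-backed majority voting between consecutive het
  sites, breaking blocks when the vote margin falls below 0.8 or fewer
  than 3 co-spanning reads exist; conflicting reads are counted and
  reported. This is a from-scratch method exercising the capability, not a
  reimplementation of any published phasing model.

## Replicate studies

Repeated-replicate statements (CNV sensitivity over 200 replicates, null
false-positive rate, homozygosity re-genotyping over 200 replicates) draw
per-exon fragment counts or per-site read counts directly from the same
Poisson/binomial model the read simulator induces; the equivalence of the
count-level and read-level paths is checked once per stage by a full
simulate–map–call round in the tests. Study sizes in the suite: 200
replicates for the CNV and re-genotyping operating points, 100 null
samples for the false-positive rate, 20 full long-read rounds for 3-site
phase recovery.

## Coordinates and formats

Variants and exon tables are 1-based inclusive (VCF convention); BED
output is 0-based half-open. The single-contig layout (gene, 500-bp N
spacer, pseudogene on `chrT`, with a JSON offset sidecar) is the default so
BED masking is meaningful; masking is byte-identical to
`bedtools maskfasta` (checked in the tests). Published interval notation is
ambiguous between BED and 1-based conventions, so the CLI accepts
`--coords {bed,one-based}` rather than guessing. Calls are emitted as
VCF-like TSV (optionally minimal VCF 4.2), CNVs as BED+TSV, deletions as
BEDPE-like TSV and phase blocks as pipe-separated genotypes.

## Limitations

The cohort fixture replays published variant-level evidence through the
tier rules; it cannot re-discover which patients carry which variants.
Clinical classification (ACMG), external splice/missense predictors,
methylation, insertions/inversions as SV classes, adaptive-sampling
behaviour (emulated only as higher on-target coverage) and real-genome
alignment at scale are out of scope. Near the 50%-identity floor the
paralog/unrelated boundary is intrinsically fuzzy; the model is intended
for the ≥ 90% identity regime it was built for.
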