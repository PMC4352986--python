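# Methods

This note documents the models, conventions and numerical choices behind
`pancrna`, and what the synthetic-data generator does and does not emulate.

## Coordinates and windows

All internal coordinates are 0-based half-open `[start, end)`; GTF input is
read as 1-based inclusive and BED output written 0-based half-open. The TSS
is the 5′-most transcribed base of the gene span (`start` on +, `end−1` on −;
with multiple transcripts the span edge is automatically the 5′-most TSS).
Windows anchored on the TSS:

| window | + strand gene | − strand gene | used for |
|---|---|---|---|
| promoter −1000..−1 | `[t−1000, t)` | `[t+1, t+1001)` | pancRNA counting, CpGi classification |
| promoter −500..−1 | `[t−500, t)` | `[t+1, t+501)` | motif asymmetry, CpGi×motif association |
| gene body +1..+500 | `[t, t+500)` | `[t−499, t+1)` | motif asymmetry |
| search −200..−1 | `[t−200, t)` | `[t+1, t+201)` | motif-search input FASTA |

The pancRNA strand is always opposite the gene strand (divergent
transcription). A promoter window is **excluded** — never truncated — when
it overlaps the span of any other gene on either strand (conservative
reading: mRNA reads must not contaminate the pancRNA pool) or does not fit
on the chromosome, so every usable window is exactly 1 kb and RPKMs are
length-comparable. A neighboring gene *closer* than 1 kb but not overlapping
the window never clips it. The body window of a gene shorter than 500 bp is
truncated to the span and flagged.

## Counting and RPKM

Read-to-interval assignment uses the 5′-end position only: a read counts for
an interval iff its 5′ end is inside and its strand matches. This is
unambiguous for 50-bp single-end reads at window boundaries and cannot
double-count between promoter and gene body. For BAM input, the 5′ end is
the first aligned base in read orientation; secondary/supplementary records
are ignored (each fragment counted once at its primary alignment), and a
`reverse_stranded` switch accommodates dUTP-style protocols. Reads are not
deduplicated. RPKM uses the 1 kb window for pancRNAs and the exon-union
length for mRNAs; the library size is the total read count of the sample.
Replicate QC uses Pearson r on log2(RPKM+1) — the pseudocount bounds the
influence of high expressors; strandedness QC is the correct-strand fraction
among reads falling in exactly one gene span.

## Screen thresholds (all exposed as config keys / flags)

* candidate: mean pancRNA RPKM ≥ **1.0** across replicates (matches the
  "RPKM > 1" convention of the follow-up criteria; the source analysis did
  not publish its candidate cutoff);
* expressed (co-expression): mean RPKM > **0.5**, the complement of the
  "RPKM < 0.5 = silent" criterion;
* fold changes: pseudocount **0.5** RPKM so genes silent at one stage stay
  finite; the ≥10-fold motif-search selection uses the same pseudocount;
* follow-up: RPKM < 0.5 (MII), > 1 (2-cell), > 1 (ESC), ranked by ESC
  pancRNA RPKM;
* groups: B/C are the n = 100 weakest/strongest pancRNAs among co-expressed
  pairs; A is expressed mRNAs with no expressed pancRNA; C>A and C>B are
  one-sided Mann–Whitney tests.

Every ranking breaks numeric ties lexically by gene_id, so all selections
are deterministic. The differential test is a Welch t on log2(RPKM+1) with
BH adjustment — a deliberately simple, fully testable replacement for an
external count-model tool; when both groups have zero variance, p = 1 for
equal means and p = 0 otherwise (the t statistic degenerates).

## Motif scanning

Scores are summed log2 probabilities under the PWM with a uniform
background; identity is min–max normalized per matrix, so "0.9 identity"
means within the top 10 % of the achievable score range — the semantics of
classical PWM-matching tools. Hits are reported on both strands (− strand by
scanning the reverse complement), windows containing N are skipped, and
overlapping hits are all kept: the downstream statistic is per-region
presence/absence, which no overlap policy can change. Asymmetry profiles
re-express hit strand relative to the mRNA direction and report per-gene
presence fractions *and* raw hit counts (aggregation by gene vs by hit can
rank categories differently). De novo discovery is out of scope: the PWM is
an input (JASPAR count matrix or MEME minimal), and the generator emits the
matrix it plants.

## CpG islands

Classical sliding-window definition: every 200-bp window (1-bp step) with
G+C ≥ 0.5 and obs/exp CpG ≥ 0.6, where obs/exp = #CpG·L/(#C·#G); overlapping
passing windows are merged and the merged interval's statistics recomputed
(trimmed from the right in the rare case a merged interval dips below a
threshold — it always contains a passing window, so termination is
guaranteed). N breaks windows. A promoter is CpGi-type iff any island
overlaps the 1-kb window by ≥ 1 bp; note that divergent neighbors can share
one island, as real bidirectional promoters do.

## Mann–Whitney U

Observation unit: the per-clone methylated fraction (clones are the
independent sequencing units; missing calls are excluded, never imputed).
U counts (x, y) pairs with x > y, ties as ½. For n+m ≤ 12 the p-value is
exact by enumerating all C(n+m, n) labelings of the pooled values (ties ride
through via midranks; ≤ 924 labelings); otherwise a normal approximation
with tie-corrected variance and continuity correction is used. Two-sided
p = min(1, 2·one-sided). The exact null at these sample sizes is discrete in
steps much larger than 0.01, so exact and approximate p agree tightly in the
decision-relevant tail but can differ by several percent mid-range — an
inherent property of the statistic, not of the implementation.

## The synthetic-data generator

Defaults are the study conditions: 400 single-exon genes (1–2 kb) on two
600-kb chromosomes with ≥ 1.1 kb intergenic clearance, 30 % pancRNA-
partnered, 5 % of promoters deliberately broken by a small "decoy" gene
planted inside the window (exercising the exclusion rule), 4 replicates per
stage at 200 k reads/sample, NB counts with var = µ + αµ² (α = 0.1), strand
flip rate 1 % (observed directional libraries run 0.9–3.1 % error), and a
CT-rich consensus (`CTCTCTCC`) planted per strand/region category at the
asymmetric rates of partnered (promoter-sense 0.6, body-antisense 0.5)
versus lacking (antisense 0.4) genes, boosted ×1.25 in CpGi-type promoters.
Expression truth: lognormal baselines; partnered pancRNA and mRNA
MII→2-cell log2 fold changes share correlation 0.7; 55 % of partnered
pancRNAs are already maternal (on in MII); non-partnered mRNAs decay by
2⁻⁰·⁷ on average (maternal clearance at ZGA); partnered mRNA baselines rise
with pancRNA level (the group-C-over-A association). Methylation: three
loci, 24 clones × 12 CpGs, levels 0.85/0.80/0.75 in MII/sperm/1-cell and
0.10 at the 2-cell stage, i.i.d. Bernoulli calls with 2 % missing.

Deliberate numerical conventions:

* α = 0 means deterministic counts = round(µ), not a Poisson limit — the
  noise-free regime must reproduce the truth table *exactly*;
* expressed features are floored at 5 RPKM (pre-normalization) so that "on"
  and "off" are separated from every screening threshold by orders of
  magnitude; silent features are exactly 0;
* truth RPKMs are rescaled per stage so Σ(RPKM·length_kb) = 1e6 — the
  identity any real RPKM table satisfies — making realized pipeline RPKM
  numerically equal to truth instead of merely proportional. A few-hundred-
  gene transcriptome therefore carries large absolute RPKMs;
* the genomic background is GC-poor (40 %) with 85 % of CpG dinucleotides
  destroyed, emulating vertebrate CpG depletion; without it the classical
  island definition would fire on half of any uniform random sequence;
* all randomness flows through per-stage `numpy` Generator streams derived
  from (seed, stream-id), so one seed fixes every emitted byte.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spliced/multi-exon genes, 5′/3′ coverage bias,
sequencing errors and quality scores, PCR duplicates, alignment artifacts,
isoform-level promoters, chromatin context, and methylation autocorrelation
along a clone (calls are independent per CpG). At synthetic scale the
per-read RPKM quantum is large, so the 1 % strand-flip leak between
overlapping divergent promoter windows produces a visible false-candidate
tail that real, deeper libraries would not show at the same thresholds; the
noise-free closed loop and the dedicated recovery checks quantify the
pipeline itself, not that artifact.

## Problem sizes in the test suite

Per-module tests run a reduced architecture (120 genes, two 220-kb
chromosomes, 50 k reads/sample); the exact-recovery and end-to-end checks
use the full default conditions; the coordination-recovery check uses 500
all-partnered pairs at 250 k reads/sample with fold-change sd 2.0, sized so
that the irreducible NB attenuation of Pearson r stays well inside the
recovery tolerance. The whole suite completes in well under a minute.

## Known limitations

Single promoter per gene (5′-most TSS); no alternative-promoter or enhancer
annotation; RPKM only (no TPM/FPKM variants); uniform-background PWM scoring
without Markov background models; no conversion-efficiency modeling for
bisulfite data; external count-model differential tools are intentionally replaced by
the documented Welch/BH procedure.
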