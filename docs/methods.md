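# Methods

`vlincseq` quantifies the "dark matter" of a transcriptome: the share of
cellular RNA mass that maps outside annotated protein-coding exons, and the
very long intergenic non-coding (vlinc) domains that produce much of it.
The package implements the analysis as a testable pipeline over synthetic
data with known ground truth; this note records the models, the parameter
choices, and the places where the design was genuinely open.

## Read model and quality control

Single-molecule sequencing of randomly primed, dA-tailed cDNA yields short
reads (25–55 nt after trimming, mean ~34 nt) with a deletion-dominant error
profile and occasional leading-T homopolymer artifacts from the poly-dT
capture chemistry. QC runs in a fixed order — leading-T trimming, minimum
trimmed length (default 25 nt), alignment scoring, normalized-score
threshold, unique-best-placement filter, ribosomal/mitochondrial exclusion
— and every stage only removes or annotates reads. Survivors are the
*informative reads*, the normalization denominator for everything
downstream.

An alignment is scored

```
raw        = 5 · matches − 4 · errors
normalized = raw / tag length
```

where errors count substitutions plus gaps in either row and the tag length
is the ungapped trimmed read length. Two interpretation points were open
and are resolved as follows:

* **"Errors" include gaps on both strands.** The canonical worked example
  (32-nt tag, one tag gap + one ref gap, 31 matches) is scored as 2 errors
  with an 8-point penalty, raw 147, normalized 147/32 = 4.59375 — which
  fixes the interpretation.
* **The denominator is the ungapped tag length** (32 in that example, not
  the 33-column display length).

The maximal normalized score is 5.0, attained exactly by error-free
alignments. Default retention threshold is 4.5 (human), 4.3 (fly). Ties in
the unique-best filter drop the read entirely (a conservative reading of
"unique best"); overlap of ≥ 1 bp with a masked rRNA repeat interval
triggers exclusion.

The bundled aligner is a semi-global dynamic program (+5 match, −4 per
substitution or gapped column, whole tag aligned, reference overhangs
free) intended for window-scale re-alignment and for auditing scores; the
pipeline's native interchange format carries gapped tag/ref strings so
every score can be recomputed from disk. Genome-scale seeded alignment is
out of scope. The DP is validated against an exhaustive enumeration oracle
on all short sequence pairs.

## Read partition and normalization

A read is **exonic** if its aligned genomic footprint overlaps ≥ 1 exonic
base of any transcript on either strand, else **intronic** if it overlaps
any transcript span, else **intergenic**. The precedence (exon > intron >
intergenic) is the conservative choice: ambiguous overlap is counted as
annotated, deflating the dark-matter estimate. Classification is
strand-agnostic because reverse transcription produces spurious
second-strand cDNA, making per-read strand unreliable; both strands are
combined.

Per-base density tracks and per-feature counts are normalized to reads per
10 million informative reads; a feature's *relative mass* is its read
count as a percentage of informative reads. Read counts rather than
covered bases estimate mass because read lengths vary. "Density per
genomic base" is implemented as coverage depth; an alternative reading
(reads starting per base) exists but depth matches how browser density
graphs are drawn and thresholded.

The intron/exon density screen considers spliced transcripts with at least
50 normalized reads over their exons+introns and flags those with ≥ 1
intron whose mean per-base depth is at least the mean exonic depth.

## vlinc domain calling

Intergenic reads (pooled across samples before normalizing by the pooled
informative total) give a per-chromosome density graph segmented with
three parameters: `threshold_percentile` (default 80), `max_gap` (default
5,000 bp) and `min_run` (default 50,000 bp). Bases at or above the
threshold form runs; runs separated by ≤ max_gap merge gap-inclusive;
merged runs spanning ≥ min_run are reported.

Numerical choices, since browser-style thresholding semantics are not
fully standardized:

* **Percentile population = positive (nonzero) density values per
  chromosome.** An 80th percentile over all bases of a mostly-zero genome
  would be 0 and call everything.
* **Nearest-rank percentile** — deterministic, no interpolation.
* **Clipping after merging:** merged runs are clipped against transcript
  spans so a merged gap crossing a gene edge cannot leak genic sequence
  into a domain; clipped fragments are re-checked against min_run so the
  reported-domain length invariant always holds.
* Domain ids are assigned in genome order (`vlinc_1`, `vlinc_2`, …).

The caller is monotone by construction: raising min_run never adds
domains; raising max_gap never splits one.

## Synthetic data: what it emulates and what it does not

The generator produces random genomes plus `rDNA`/`chrM` decoy contigs, a
non-overlapping multi-exon annotation confined to a leading fraction of
each chromosome (the remainder is a gene desert), planted vlinc domains
(≥ 50 kb, pairwise disjoint, never overlapping genes), and reads drawn
from a category mixture over ribosomal / mitochondrial / exonic /
intronic / intergenic origins. Key defaults:

* **Read length** = 25 + truncated geometric, giving the stated 25–55
  range with mean ~34 nt. (A uniform 25–55 draw would have mean 40 and
  contradict the observed 33–36 nt averages.)
* **Error model**: per-base error rate 0.04 with 70% deletions, the rest
  substitutions. The true instrument error rate is not published; this is
  a configurable stand-in, not a calibration. The first tag base is always
  an error-free copy and read starts land on non-T bases, so leading-T
  trimming can never consume genuine sequence — a simplification that
  keeps ground truth exact.
* **Default mixture** (RiboMinus-like): 20% rRNA, 5% mt, 34% exonic, 30%
  intronic, 11% intergenic, i.e. an informative pool of ~45/40/15 —
  non-exonic ≈ 55% of informative reads, in the range observed for
  rRNA-depleted human samples.
* **Planted-domain density multiplier** = 50× the intergenic background.
  The caller's fixed merge distance (5 kb) forces this scale: recovery at
  Jaccard ≥ 0.95 needs within-domain read spacing ≪ 5 kb *and* background
  spacing ≫ 5 kb simultaneously, so the contrast must be large. In the
  domain-recovery study (~2,000 intergenic reads, 8 Mb genome, four
  domains totalling ~600 kb) domain read spacing is ~350 bp
  (P[gap > 5 kb] ≈ e⁻¹⁴ per gap) and background spacing ~17 kb
  (P[gap ≤ 5 kb] ≈ 0.25, and a ≥ 50 kb false run needs ~10 consecutive
  short gaps, probability ~10⁻⁶ per run).
* **Negative control**: multiplier 1 with the intergenic read count
  matched to the positive run's *background* rate — the like-for-like
  control (same quiescent desert, no signal). Expected domain calls ≈ 0.
* Recovery is summarized as the mean Jaccard over all planted domains
  across five replicate genomes: QC thinning occasionally (a few percent
  of genomes) stretches one within-domain gap past the merge distance and
  splits a domain, and a 4-domain single-genome mean would be dominated
  by that rare event rather than typical boundary accuracy.

What the generator does **not** model: instrument optics/chemistry, real
rDNA repeat sequence (a random decoy contig plays its role), repeat
structure and mappability, transcript isoforms, strandedness, and
expression correlation between neighbouring features. Passing tests
therefore demonstrate correctness of the *computations* under known
truth, not performance on real genomes.

## Comparative statistics

* **Ranks**: descending competition ranking; ties share the best rank and
  the next rank skips ([10, 5, 5, 1] → [1, 2, 2, 4]). Reproducible and
  order-independent. Group summaries (average/minimum rank) are computed
  over the named sample group only.
* **Fold ratios**: per feature, (max normalized count over tumours +
  pseudocount) / (max over normals + pseudocount); pseudocount defaults to
  one normalized read so features absent in normals get finite ratios.
  Significance is a one-sample t-test of log₂ ratios against 0 — ratios
  are strictly positive and skewed, so the log scale is the defensible
  choice among unspecified t-test variants. Ratios are scale-invariant at
  pseudocount 0.
* **Spearman matrices**: optional top-two-quartile filter keeps the top
  half of features by expression summed across samples, avoiding
  correlation inflation from unexpressed features. Constant vectors give
  undefined correlations reported as missing, never 0. Pair classes
  (same-patient, different-patient, tumour-vs-normal,
  tumour-vs-other-tumour) require group, patient and cohort labels in the
  design; cohort was added precisely so two tumour types are
  distinguishable.
* **Interval overlap**: counts of intervals overlapping the other set by a
  minimum number of base pairs (default rule: a single partner interval
  must supply the minimum), total overlapping bp, and a chi-square test
  without continuity correction on the 2×2 base-pair contingency over a
  stated universe (bp-resolution counts are enormous, making the
  correction immaterial).
* **Median lengths**: set medians with a Welch t-test on raw lengths.

## Cellular RNA bookkeeping

With ~340 g/mol per internal ribonucleotide residue, a 35-nt read
represents 35 · 340 / N_A ≈ 2 × 10⁻²⁰ g of RNA. Sequencing through the
whole ~20 pg RNA pool of one mammalian cell therefore needs ~1 × 10⁹
reads — the divisor is the *total* undepleted mass, because the ~6%
informative fraction cannot be physically pre-selected without loss; the
informative-mass-only reading would give ~6 × 10⁷ and is exposed as
`informative_reads_among`. PolyA selection yields 1–2% of input mass, half
of it still ribosomal/mitochondrial, so the polyA fraction of informative
RNA is bounded by (yield × 0.5) / informative-fraction evaluated at the
extreme pairings: 6.25%–25%.

## Problem sizes

The validation studies run at desk scale by design: 1.5–8 Mb genomes,
2,000–100,000 reads, 4 planted domains per genome with 5 replicates for
recovery, 200–300 features and 6–9 samples for the statistical panels.
These sizes give the binomial/Jaccard margins quoted above while keeping
the whole suite fast and deterministic.

## Known limitations

* The aligner is quadratic and window-scale; importing genome-scale
  alignments is supported via the SAM subset reader instead.
* Density arrays are dense per-chromosome vectors; genomes far beyond
  ~100 Mb per chromosome would need a sparse or binned representation.
* Strand-specific classification and antisense calling are deliberately
  out of scope (combined strands), as is transcript-structure inference
  within called domains.
* Dataset-level published figures (e.g. hundreds of domains on a real
  genome) depend on deposited sequencing data and genome-scale alignment
  and are not reproduced here; the synthetic studies validate the
  operations, not those numbers.
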