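# Methods

## The problem

Standard RNA-seq alignment discards the reads it cannot place. Some of
those reads are not noise: a read spanning an unannotated intron, for
instance, carries a long internal gap that a transcript-naive aligner
cannot accommodate, and the transcript it comes from may be expressed
too weakly for assembly tools (which deliberately prune low-abundance
paths) to reconstruct. `readbait` implements the computational half of a
bait-and-extend strategy for such reads: salvage the informative
fraction of the unmapped pool, pick an anchor ("model") read, and — once
targeted resequencing has produced fragments around the anchor — decide
which nearby fragments belong to the same transcript and report the
implied full-length genomic span.

## The screening cascade

The unmapped fraction is partitioned by a fixed-order, first-match
cascade:

1. **unpaired** — the mate is missing from the input;
2. **contaminant** — the read id appears in the external contaminant
   screen's hit list (rRNA, mitochondrial, microbial);
3. **low_quality** — mean Phred < 15 or length < 36 (explicit,
   version-independent replacement for a trimmer's "default
   arguments"; both configurable);
4. **annotated** — mapped to the transcript annotation by either of two
   mappers (the union of their hit sets);
5. **low_score** — best BLAT score < 130; reads absent from the score
   table score 0, since only scored survivors can proceed;
6. **new_annotated** — matched a novel-but-known transcript by BLAST;
7. **candidate** — everything that survives.

The aligners themselves are out of scope by design: they are mature
external tools, and the contribution is the decision logic. The cascade
consumes their outputs as id sets (plain text), score tables (PSL; score
= matches + repMatches − misMatches − qNumInsert − tNumInsert, best row
per query) and SAM flags.

Candidates are then filtered by the **gap rule**: a read qualifies as a
novel-transcript anchor when its alignment CIGAR contains an N or D
operation strictly longer than 20 bp (`min_gap = 21`), long gaps being
likely introns. Gap coordinates come from walking the CIGAR over the
reference; insertions and clips do not consume reference and are
ignored. One read can yield several gap features.

## The length law

Transcript lengths are heavy-tailed. After discarding transcripts
longer than the sample median — long transcripts are over-sampled by
shotgun sequencing, and the median cut (strictly greater-than; lower
central value on even samples, configurable to the mean) yields a more
uniform set — the retained lengths are binned at 100 bp and the bin
counts follow a power law in the bin rank k:

    count_k ∝ k^(−alpha)

`fit_loglog` estimates alpha by ordinary least squares of ln(count) on
ln(k), exactly as published: the regression x is the **rank index**
(not the bin midpoint), rank 1 is the first bin, zero-count bins are
dropped (log undefined), and `C = exp(intercept)`. Reported
diagnostics: R², adjusted R² = 1 − (1 − R²)(n−1)/(n−2), and the
two-sided slope p-value.

**Accuracy of the binned refit.** On noiseless log-linear input the fit
is exact (tested to 1e−9). On sampled data the estimator is consistent
only in the shallow-exponent regime where bin counts stay large across
the support: at alpha ≈ 0.6 (the regime transcript lengths actually
occupy) it recovers the exponent to within ~0.06 at n = 1e5. For steep
exponents (alpha ≳ 1.5) the tail bins hold few counts, and OLS on
ln(count) is biased upward by Jensen's inequality plus the zero-bin
truncation; the acceptance suite documents this by comparing against an
exact discrete maximum-likelihood oracle, which stays within ±0.01 of
truth across alpha ∈ {0.6, 1.5, 2.5}. The binned procedure is kept
as-is because it is the published method; users needing steep-exponent
estimates should rely on likelihood-based fitters.

## The membership model

The fitted law is recycled as a spatial prior. If transcript lengths
follow a power law, then the probability that a transcript is long
enough to cover both the anchor center and a fragment center a distance
x away is the upper tail P(X ≥ x). Two modes:

* **truncated** (default): the proper tail of the power law restricted
  to [x_min, x_max],

      P(X ≥ x) = (x_max^(1−a) − x^(1−a)) / (x_max^(1−a) − x_min^(1−a)),

  with the log-ratio form at a = 1. x_min defaults to 1 bp, x_max to
  the overlong-median cutoff. The normalization constant cancels
  (verified by a C-scaling invariance test). Distances below x_min
  clamp to probability 1, beyond x_max to 0.
* **literal**: the printed closed form 1 − F(x) with
  F(x) = 1 − C/(a−1)·x^(−(a−1)), using the stored C, clamped into
  [0, 1] with a warning. This form is an improper distribution whenever
  a < 1 — with the published a = 0.594 the tail is negative everywhere
  — so the mode exists purely to audit published parameter sets, and
  the truncated form is the default.

A fragment is retained when its probability **strictly exceeds** the
threshold (default 0.3). The threshold has a geometric reading: the
**critical distance**, the unique x where the tail crosses the
threshold (closed-form inversion; ≈ 2.96 kb at the published
parameters). Fragments closer than it are always retained.

## Span estimation

Fragments are collected from SAM/BAM (mates merged into one template
fragment spanning outermost coordinates — the library is sonicated
double-stranded cDNA sequenced paired-end, so the template is the
natural unit; secondary/supplementary alignments dropped; a lone mapped
mate stands alone) or from BED. Centers are floor midpoints (< 1 bp
bias on even lengths); the scan window defaults to x_max, beyond which
the probability is 0 by construction. Distance 0 is clamped to x_min
before scoring.

The estimate is the interval union of the anchor span with all retained
fragment spans — no chaining or coverage-continuity requirement, since
the method exists precisely to keep isolated low-coverage fragments.
Left/right extensions are relabelled 5′/3′ by strand (swapped on "−";
flagged unresolved when the strand is unknown). The invariants
`full_length = span length = anchor span + total extension` and
`span ⊇ anchor span` are property-tested. Internally all coordinates
are 1-based inclusive (SAM convention); BED I/O converts through
lossless 0-based half-open round trips.

## The synthetic-data generators

* **Length samples** — inverse-CDF draws from the truncated power law
  (closed form for alpha ≠ 1, log-uniform branch at alpha = 1), rounded
  to integers and clipped to the support, so the discrete law is
  P(k) ≈ F(k+½) − F(k−½). Defaults: alpha 0.594, support [1, 6932] bp,
  n = 1e5 — the study conditions.
* **Planted locus** — one random-sequence chromosome (uniform base
  composition) carrying a single-exon transcript of 1556 bp; a 149 bp
  model read aligned inside it with one 23 bp N gap (split-match
  CIGAR); and Normal(200, 30) bp fragments (clipped at 20 bp,
  sonication-scale) whose centers are uniform over the positions a real
  cDNA fragment can occupy — fully inside the transcript and within
  x_max of the anchor. Confining fragments to the transcript is
  deliberate: fragments of a transcript cannot overhang its ends, and
  it is what makes full-length recovery well-posed for any x_max ≥ the
  transcript length. The model read is centered by default;
  `model_read_offset` places it asymmetrically (the published locus has
  it ~1117 bp from the 5′ end). Everything is emitted as
  FASTA/GTF/SAM/BED/FASTQ plus a truth JSON recording every fragment's
  distance.
* **Screen fixture** — reads planted per category with the evidence
  files that force the cascade to reproduce the truth table: unpaired
  reads lack an R2 mate, low-quality reads carry Q2 bases, low-score
  reads get PSL score 90, survivors 150. Default counts follow the
  published category proportions (32.4 / 3.2 / 0.2 / 46.4 / 16.7 /
  0.46 / 0.58 percent over ~1e4 reads).

What the generators do **not** emulate: sequencing errors and quality
heterogeneity, multi-exon structure, strand-specific library artefacts,
background fragments from neighbouring genes, and microsatellite
slippage (the known cause of NGS/Sanger disagreement in repeat-rich
extensions). Passing tests therefore demonstrate the correctness of the
decision rules and arithmetic, not robustness to alignment noise or
annotation ambiguity in real data.

## Numerical choices and degenerate inputs

* Regression needs ≥ 3 non-empty bins and non-zero spread of ln(rank);
  otherwise a degenerate-regression error.
* Median tie on even samples: lower central value (configurable).
* Bin boundary: length exactly at k·width belongs to bin k
  (half-open `((k−1)w, kw]`).
* Fragment retention and the low-score and gap thresholds are strict
  comparisons (> 0.3, < 130, > 20 bp); the quality thresholds are
  inclusive (mean Q ≥ 15 passes).
* Empty retained set → zero extensions, full length = anchor span.
* Probability evaluation clamps floating wobble at the support edges.
* Pipeline outputs are timestamp-free JSON, so identical config + seed
  reruns are byte-identical (tested).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data: length samples of n = 1e5, loci with 100 fragments (~13×
coverage of the 1556 bp transcript), screen fixtures of 1e2–1e4 reads,
and 1e3 random CIGARs for the gap-walk cross-check. These sizes keep
every oracle comparison sharp while the whole suite completes in a few
seconds.

## Known limitations

* The binned log-log estimator's steep-exponent bias (above).
* Reproducing the published numbers on the real inputs (the public GTF
  annotation and the targeted-resequencing accession) requires
  downloading those datasets; the CLI accepts them directly
  (`readbait fitlaw --gtf ...`, `readbait extend --aln ...`) but no
  fetching is built in.
* The published gap locus is quoted with an inclusive span of 25 bp for
  a 23 bp gap; this package always reports inclusive coordinates
  consistent with its own CIGAR walk and documents the 2 bp
  bookkeeping discrepancy rather than guessing the original
  convention.
* Paired-end merging uses the template (outermost mate coordinates) as
  the distance-bearing unit; if the original analysis scored individual
  reads instead, retained-set counts on real data may differ.
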