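# Methods

This note documents the models, the estimators, the synthetic-data
generator and the numerical choices behind `tailscape`, and what the test
suite does and does not establish about real data.

## Data model and conventions

The unit of observation is a sequenced molecule (`ReadRecord`): transcript
assignment, sample and condition (`control` / `stimulated`), estimated
poly(A) tail length in nucleotides, the tail's base sequence when
available, the 0-based genomic coordinate of the last templated base
(`end_pos`), and a QC tag (`PASS` / `SUFFCLIP` / `FAIL`). Reads tagged
`FAIL` are parsed and retained but excluded by every analysis filter, so
composition audits can still see them. Transcript assignment is taken as
given in the input table; the package does not realign reads.

All internal coordinates are 0-based half-open. GTF-lite annotation
(1-based closed) is converted at the parse boundary and back on write; BED
is used natively. Sequences live in the DNA alphabet; RNA input (U) is
normalised to T with the original alphabet recorded. Using the *last
templated base* as a single-nucleotide 3′-end anchor keeps clustering and
window extraction free of interval bookkeeping.

## Differential adenylation (tailstats)

Tail lengths are compared between unpaired read populations, so the test
is the two-sample Wilcoxon rank-sum (Mann–Whitney U). The p-value is exact
(no ties and min group size ≤ 8) and otherwise uses the normal
approximation with tie and continuity corrections. Transcripts enter the
test only with ≥ `min_reads` (default 10) QC-passing reads in *both*
conditions, and Benjamini–Hochberg adjustment runs across exactly the
tests performed — not the whole annotation.

Significance is a dual rule: adjusted p < α (0.05) **and** |median
difference| > 5 nt. The median is the primary Δ metric (tails are
right-skewed); the mean difference is also reported, since effect
summaries on real data are often quoted as means. Cohen's *d* uses the
pooled sample SD and is binned on |d| with lower-inclusive boundaries at
0.2 / 0.5 / 0.8 (negligible / small / medium / large). A zero pooled SD
yields d = 0 with a `degenerate_sd` flag.

A tail is *decorated* iff its sequence contains any non-adenosine. This is
a sequence-level definition: signal-space classification of raw nanopore
squiggles is out of scope, so composition statistics describe the tail
sequences as given.

## Differential expression (expression)

Counts per transcript and sample are normalised with median-of-ratios size
factors. Per gene, condition means are compared on the log2 scale with a
0.5 pseudo-count; the variance of each condition mean uses the NB variance
μ + αμ², with α a per-gene moment estimate pooled across conditions
(df-weighted) and floored at 1e-8. The Wald z is referred to the standard
normal, followed by BH. With fewer than two replicates in a condition a
per-gene moment estimate does not exist; the model then uses one common
dispersion, the median of per-gene moment estimates computed by pooling
both conditions' samples — valid when most genes are null, which is the
intended use of that fallback.

This estimator is intentionally simpler than shrinkage-based NB GLM
packages: no empirical-Bayes dispersion shrinkage, no LFC shrinkage, no
outlier refitting. Under the default null calibration (500 genes, ~50
reads/condition over 4 replicates) its raw type-I error is ≈ 0.06 at
α = 0.05 — mildly above nominal, as expected for a moment estimator with
few replicates, and within the package's acceptance band (≤ 1.5×).

Note that median-of-ratios normalisation absorbs folds shared by most of
the library: a simulation in which *every* gene is induced 4-fold will
correctly estimate log2FC ≈ 0 for all of them. Planted-effect recovery is
therefore always evaluated with non-null genes in the minority.

## Alternative polyadenylation (apa)

Read 3′ ends are clustered per gene by single linkage with a maximum gap
of 24 nt — chosen at the scale of nanopore end-position jitter — and
clusters with < 3 supporting reads are dropped. The anchor is the modal
end position, ties broken toward the 3′-most position in mRNA
orientation. Feature assignment uses the precedence 3′UTR > exon > intron
> within-transcript > unassigned against the gene's transcripts. Because
the anchor is modal over jittered ends, a cluster at an annotated UTR
terminus can land 1–2 nt past the annotation and be reported `unassigned`
— the same boundary effect that inflates unassigned fractions on real
annotations.

Differential usage contrasts each PAS against the gene's other PASs in a
2×2 (PAS vs rest × condition) two-sided Fisher exact test; BH runs across
all tested PASs transcriptome-wide, and a PAS is differential at adjusted
p ≤ 0.1. Proximal and distal are the 5′-most and 3′-most PASs in mRNA
orientation; their usage shifts are log2 ratios of normalised support with
a 0.5 pseudo-count. The hexamer profile counts canonical AATAAA/ATTAAA
(optionally ten common single-substitution variants) by offset of the
hexamer start from the anchor within a 40-nt upstream window, in mRNA
sense.

## PWM scanning with exact p-values (motifs)

Letter-probability matrices (MEME minimal text) are converted to log-odds
s(i,b) = log2((p(i,b) + c·q_b) / (1 + c) / q_b) with pseudocount c = 0.01
against a 0-order background — by default estimated (Laplace-smoothed)
from the scanned sequences. Scores are rounded to integers at 1000 units
per log2; the null distribution of the total integer score is computed
exactly by convolving the per-position four-atom distributions under the
background, so p(score ≥ t) is exact up to the integer rounding. The DP is
verified against exhaustive 4^W enumeration for W ≤ 6 to 1e-9. Scanning is
sense-strand only (CPEs are mRNA elements), reports every window with
p ≤ 1e-4 by default, and skips windows containing non-ACGT letters.

The shipped CPE matrices (`example_cpe_motifs`) are **synthetic**
demonstrations with U-rich consensi, not published CPEB-binding matrices;
real scans should supply matrices from the literature via MEME files.

## Semi-templated tails (semitemplated)

Candidate windows are the last 60 nt of each annotated 3′UTR (mRNA sense,
minus-strand UTRs reverse-complemented) plus the 60 nt ending at each
called PAS anchor. A window is A/T-rich under rule 1 (A/T fraction
strictly > 0.60) or rule 2 (an A/T run ≥ 13 nt anywhere in the window
*and* the window's final 3 nt — those adjacent to the tail — all A/T).
The run-length reading of rule 2 binds the "last three" to the window
terminus; when the qualifying run is itself terminal the two readings
coincide. Rules are evaluated per window and OR-ed per transcript.
Candidates from both sources are merged and deduplicated (source recorded
as `reference_utr`, `pas_predicted` or `both`), then filtered to
transcripts with ≥ 10 QC-passing reads and ≥ 3 decorated tails. All
intermediate set sizes (per rule, per source, union, post-filter) are
reported.

## The synthetic-data generator (simulate)

The generator emulates a two-condition nanopore per-read tail table with
its annotation and genome, one contig per gene (a two-exon transcript with
a 200-nt 3′UTR), under a single seed; per-gene substreams are derived by
CRC-hashing the gene id so extending a simulation never reshuffles
existing genes.

* **Counts**: per gene/sample negative binomial, mean
  `baseline_mean_expression / n_replicates` (the baseline parameter is
  reads per *condition*; default 50 over 4 replicates, matching the depth
  at which the per-transcript tail test is just well-powered), dispersion
  0.05.
* **Tails**: rounded log-normal, baseline median 100 nt, log-sd 0.35.
* **Mechanisms** (per gene): `null`; `transcriptional_induction`
  (stimulated counts × 4; the *excess* molecules drawn at median + 40 nt
  while preexisting ones keep the baseline — a mixture, which is exactly
  what makes induction distinguishable from cytoplasmic elongation);
  `cytoplasmic_polyadenylation` (counts unchanged, all stimulated tails
  +40 nt); `deadenylation_decay` (counts ÷ 4, tails −40 nt);
  `translation_deadenylation` (counts unchanged, tails −10 nt). Default
  mix: 10 % / 10 % / 10 % / 0 %, remainder null.
* **Decoration**: each polymerized position mutates to a non-A with
  probability ε = 0.002, the base drawn G/C/U with weights 0.5/0.3/0.2, so
  P(decorated | L) = 1 − (1 − ε)^L rises with tail length and G ≥ C ≥ U
  among decorations. At 100-nt tails this yields ~18 % decorated reads —
  deliberately on the generous side of real global rates (a few percent)
  so composition statistics are testable at desk-scale depth; ε is a free
  parameter, not a biological claim.
* **APA**: 10 % of genes (drawn from the null block) carry a proximal PAS
  150 nt upstream of the distal end with usage 0.3 (control) → 0.6
  (stimulated); a canonical AATAAA is planted with its start 20 nt
  upstream of every background-gene anchor. Read ends jitter by a clipped
  normal (sd 3, |jitter| ≤ 6).
* **Semi-templated genes**: 10 % of genes (null block, disjoint from the
  two-PAS set) get a terminal 60-nt window with A/T fraction ≥ 0.85 ending
  in a fixed 19-nt suffix (`AAAAG` + 14 A): a guaranteed ≥ 13-nt terminal
  A run with a fixed-position G. Every read of such a gene carries that
  genomic suffix fused to its tail, so its non-adenosines sit at fixed
  positions, and `end_pos` points at the last base *before* the A-rich
  stretch — where a tail-caller would place the poly(A) start.
* **Guarantees**: background terminal windows (and ± margins covering the
  jitter around every background PAS anchor) are built from 6-nt blocks
  with exactly two free A/T characters and G/C breaks, so any 60-nt window
  near an anchor has A/T fraction ≤ 0.55 and no A/T run above 10 — neither
  semi-templated rule can fire on a background gene, which is what makes
  exact-recovery assertions sound.

What the generator does **not** emulate: basecalling or alignment error in
the transcript body, multi-isoform splicing, transcript-assignment
ambiguity, signal-level tail-length estimation noise beyond the log-normal
spread, batch effects, or library-composition bias. Passing tests
therefore establish the correctness and calibration of the estimators
under the stated generative model, not performance on any real library.

## Mechanism discrimination (pipeline)

Expression state (up / down / unchanged, from the NB Wald significance
flag and the sign of log2FC) is crossed with tail state (elongated /
shortened / unchanged, from the adenylation flag and the sign of Δ
median): up+elongated → transcriptional induction; unchanged+elongated →
cytoplasmic-polyadenylation candidate; down+shortened → deadenylation
decay; (up or unchanged)+shortened → translation-deadenylation-like;
otherwise stable. "Unchanged" means *not significant* — the map reasons
from significance flags, as the underlying biological argument does. This
quadrant map is this package's explicit operationalisation; it is reported
as such, and its accuracy is measured against planted truth in the
acceptance suite. The expression/adenylation Pearson correlation (t test,
df = n − 2) is restricted by default to genes with a significant tail
change.

## Numerical and design choices

* Exact rank-sum p only when enumeration is cheap (min n ≤ 8, no ties);
  tie-corrected normal approximation with continuity correction otherwise.
* Fisher's two-sided p sums hypergeometric point probabilities ≤ the
  observed one within a 1e-7 relative tolerance.
* BH adjustment universes: transcripts actually tested (tails), genes with
  any counts (expression), all tested PASs (APA).
* PWM integer scale 1000, pseudocount 0.01; exactness against enumeration
  is part of the acceptance suite.
* log2 ratios use a 0.5 pseudo-count throughout for stability at low
  support.
* |r| within 1e-12 of 1 in the Pearson test is reported as r = ±1,
  p = 0, t = ±inf.
* Problem sizes in tests and the acceptance script (500-gene calibrations,
  20 simulation seeds, 50 count-level seeds, 200-gene recovery runs) were
  chosen to give stable Monte-Carlo estimates at interactive runtimes on a
  single CPU.

## Known limitations

* The NB Wald test is anti-conservative with very few replicates; use ≥ 4
  replicates per condition or interpret raw p-values with the measured
  ≈ 1.2× inflation in mind.
* PAS feature assignment is anchor-based; a 1–2-nt anchor offset at an
  annotated UTR terminus flips the label to `unassigned`.
* The semi-templated decoration requirement counts sequence-level non-A
  bases; tails whose decorations are only visible in raw signal are
  invisible here.
* `cytoplasmic_polyadenylation_candidate` is a *candidate* label: an
  unchanged-expression gene with elongated tails is consistent with, not
  proof of, cytoplasmic polyadenylation.
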