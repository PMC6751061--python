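# Methods

## The measurement model

End-enriched RNA-seq converts transcript boundaries into count spikes: sparse
fragmentation keeps a fragment's original 5′ end with some probability and
its original 3′ end with another, while internal breakpoints spread uniformly.
After size selection and alignment, counting read 5′ and 3′ ends per genomic
position therefore yields tracks in which a transcription start site appears
as a single-nucleotide 5′ spike and a terminator as a 3′ spike, over a smooth
internal-fragment background. Everything downstream — peak calling, shadow
correction, differential promoter calling, operon inference, motif
discovery — operates on these end tracks.

Assumptions inherited from this model: ends are preserved exactly (no
exonucleolytic nibbling), fragmentation has no sequence bias, and a read maps
uniquely up to one substitution. Reads are single-end; coordinates are
1-based inclusive everywhere a user sees them and 0-based half-open
internally.

## Alignment and 5′ reassignment

Mapping uses one-mismatch, single-reported-hit semantics. The aligner is
exact for this policy: a 7-mer pigeonhole index guarantees every locus with
at most one substitution is scored for reads ≥ 14 nt (shorter reads fall back
to a full scan), the minimal-mismatch locus is reported, and ties are broken
deterministically (reference id, then coordinate, then + before −) with an
`ambiguous` flag. Ambiguous alignments are retained in the tracks, matching
single-reported-hit behaviour. Alignment across the origin of a circular
reference is not supported.

Reverse transcription prepends one untemplated base to a fraction of cDNAs,
shifting the apparent 5′ end one base upstream and placing a mismatch at read
offset 0. Such reads have their 5′ terminus moved one base downstream
(+ strand: start+1; − strand: rightmost−1) before counting; the operation is
idempotent. The 15–45 nt length filter is applied after reassignment, so the
corrected extent is what is filtered.

## Tracks and normalization

A read contributes exactly one 5′ and one 3′ count to its strand's tracks.
Reads overlapping an rRNA/tRNA mask feature by ≥ 1 nt are excluded from the
tracks *and* from the normalization denominator, which is the number of
aligned non-masked reads **before** the length filter ("reads", not filtered
ends). Normalization multiplies every count by 1e6/denominator and is
guarded against double application. Tracks round-trip through text wiggle
(variableStep, 6 decimal places).

## Peaks and shadows

- Background at *i*: mean count over [i−50, i+50] excluding [i−2, i+2],
  zero positions included, truncated at reference ends.
- Peak: count ≥ `min_count` (5 normalized units) and ≥ `z_threshold` (10) ×
  background. Enrichment factor `E = count / max(background, 0.25)`.
- Shadow removal is read-attributed when alignments are available: every
  retained read whose (reassigned) 5′ end sits on a 5′ peak has its 3′-end
  contribution multiplied by 1/E of that peak, and symmetrically for 3′
  peaks shadowing the 5′ track. All factors are frozen from the
  pre-correction tracks, so the two directions commute. A wig-only fallback
  divides opposite-end counts within one fragment-length window
  ([p+15, p+45], strand-oriented) by E; it equals read attribution only when
  peak reads share uniform opposite ends. Corrected tracks carry a flag and
  a second application is rejected.
- **Peak confirmation (pipeline):** a candidate end must be a peak on both
  the observed and the corrected track. Shadow spikes are peaks only before
  correction; conversely, a position can clear the 10× background test only
  because correction emptied its neighbourhood — requiring both removes each
  failure mode without a new threshold.

## Promoter calling, operons

Fold change at *i* is `(A+c)/(B+c)` with A, B the ±2 nt window sums of the
induced and control normalized 5′ tracks and pseudocount c = 0.5 normalized
units (the control signal of a silent promoter is near zero). The window
absorbs residual ±1 nt TSS jitter. Peaks closer than 5 nt merge to the
higher one before calling. A promoter is called when FC ≥ 10 (inclusive —
"at least 10-fold"); the peak position is the +1 site.

The −40..+1 window (41 nt, transcription orientation, +1 base last) is
extracted for motif work. The transcript 3′ end is the nearest downstream
3′ peak within 15 kb; operon genes are same-strand genes with ≥ 50% of their
length inside [TSS, end3], named for the first gene (or `orphan:<tss>`).

At desk-scale depths (~5×10⁴ reads) the `min_count` floor of 5 normalized
units corresponds to well under one read, so isolated single-read 3′
positions in a weakly expressed transcript are treated as peaks and their
shadow correction depletes the weak condition's 5′ signal. On the standard
benchmark this inflates measured fold changes of induced promoters (median
≈ 46–73 across seeds, against a compositional expectation of ≈ 34; see
below) without changing which promoters are called. At production depths
(10⁶–10⁷ reads) the same floor corresponds to several reads and the effect
vanishes.

## Motif discovery and consensus scanning

One-occurrence-per-sequence (OOPS) expectation–maximization, fully
deterministic: every window of every input sequence seeds a soft PWM (0.7 on
the seed base, 0.1 elsewhere); each iteration assigns every sequence its
best-scoring offset (log-odds in bits against the input-composition
background, floored at 1e-3 per base; ties to the leftmost offset) and
rebuilds the PWM with pseudocount 0.5 × background; iteration stops when
offsets stabilize or after 100 rounds. The converged model with the highest
total information content (2 − column entropy, bits) wins; ties within 1e-9
bits keep the first seed in scan order. Width defaults to 30, wide enough to
span both the −35-like and −10-like blocks, whose spacing shifts by a couple
of nucleotides between promoters — the reason anchored counting without
offset inference would smear them. Hard (assignment-based) EM does not
formally guarantee monotone information content, but on all tested inputs
the trajectory is non-decreasing and the suite asserts it.

Consensus string: uppercase where the top base ≥ 0.5, lowercase where
> 0.25, else `n` (a uniform column is uninformative).

Genome scanning scores both strands, keeps windows at or above a threshold,
and collapses same-strand hits closer than width/2 to the best. **Predicted
regulon members** are scan hits that (i) score ≥ minimum training-occurrence
score + 2 bits, (ii) sit in the promoter region of a coding gene (downstream
edge within 150 nt of a same-strand gene start), and (iii) are the best hit
for that gene. The +2 bit offset reflects that the weakest training promoter
scores ≈ 6.7 bits — a level chance sites reach every few tens of kilobases
in AT-rich sequence — while the next-weakest scores 22; the gene-proximity
and per-gene rules implement "sequences upstream of the coding region" as a
promoter table lists them. On a plasmid-sized stand-in carrying all 19
published pBS32 promoter windows in composition-matched random background
(the real plasmid sequence is not bundled; the stand-in is labelled
synthetic), a motif trained on the 17 Rend-seq-detected windows predicts
exactly the 2 published non-detected targets in 99 of 100 background seeds;
the residual case is a chance site as strong as a weak genuine promoter.

The inverted-repeat search (SOS-box/LexA-operator style) matches an IUPAC
half-site, a spacer within stated bounds, then the reverse complement of the
half-site, each half tolerating a bounded mismatch count; all
(position, spacer) combinations are reported. The half-site consensus is
user-supplied.

## Synthetic data

The generator plants non-overlapping transcription units (each covering at
least one annotated gene) and one rRNA-like mask locus per reference in
random sequence, then draws reads TU-proportionally to per-condition
abundance. Per read: true-5′ / true-3′ / internal class with probabilities
(p_true5, p_true3, remainder) — defaults 0.25/0.25, a free protocol choice
since only "a smaller amount" of internal fragments is specified; fragment
length uniform on [20, 40] nt clipped to the transcript; one prepended
non-templated base differing from the templated base with probability 0.05;
substitution errors at 1e-3 per base; 10% of reads from mask loci (a
realistic post-depletion rRNA carryover). Quality strings are constant
("I"); the analysis never reads them. Identical seeds give byte-identical
FASTQ.

The **standard benchmark** used by the test suite and acceptance script: one
60 kb reference, 12 TUs (1.5–2.25 kb, alternating strands, 1–3 genes each),
8 induced (abundance 0.05 → 5.0, a 100-fold induction) and 4 constitutive
(5.0 throughout), 50,000 reads per condition. These problem sizes keep a
full two-condition run around 15 s while leaving every spike estimate
hundreds of reads deep. Because normalization is per million reads, a
100-fold abundance induction maps to a normalized fold change of
100 × (control library share)/(induced library share) ≈ 34 when 8 of 12 TUs
induce together — the measured values, not the planted ratio, are what the
10-fold rule sees.

What the generator does **not** emulate: positional fragmentation bias, PCR
duplicates, GC bias, indels, paired ends, multi-base non-template additions,
partial transcript ends (processing/degradation), or overlapping operons.
Passing the synthetic benchmark therefore demonstrates correctness of the
pipeline's logic under its own measurement model, not robustness to every
artifact of real libraries.

## Degenerate inputs and numerical choices

- depth 0 → empty read set; all abundances 0 with no rRNA source and
  depth > 0 → error.
- Empty reads are skipped with a warning; a 5′ reassignment that would leave
  no bases drops the read with a warning.
- Zero or already-used normalization denominators, double normalization,
  double shadow correction, raw tracks fed to peak calling or fold changes,
  and peak positions absent from a track are all rejected loudly.
- Corrected counts clamp at 0 against floating-point undershoot.
- Fold-change positions where both windowed sums are zero are omitted.
- Wiggle values are written to 6 decimals; round-trip equality is asserted
  to 5e-7.

## Limitations

- The aligner supports at most one substitution and no indels; `-k 1`-style
  reporting means multireads contribute a single deterministic locus.
- Real-data fold changes for the published regulon require the original
  sequencing libraries and reference sequences, which are not bundled; the
  package validates against planted ground truth and the published promoter
  windows instead.
- The consensus-scan stand-in embeds published windows in synthetic
  background; scanning the genuine plasmid could add or remove borderline
  hits near the threshold.
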