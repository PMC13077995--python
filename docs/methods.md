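# Methods

## Scope and data model

`ms2drs` analyses direct RNA sequencing (DRS) of the MS2 bacteriophage: a
3,569 nt positive-sense ssRNA genome with four ORFs (*mat*, *coat*, *lys*,
*rep*; *lys* overlaps the *coat*–*rep* boundary region). All coordinates
are 0-based half-open internally and 1-based inclusive in every TSV/BED
report. Negative-strand reads (replication intermediates) are stored in the
genome frame with a strand flag; the biological 5' of a '-' read is its
highest genome coordinate. Every stage that reasons about read ends —
anchoring classification, hotspot start/end counting — uses biological
orientation, not file orientation.

Input alignments pass the standard DRS quality filter: unmapped and
secondary records dropped, primary records kept only when the arithmetic
mean of their base qualities is ≥ 10 (mean-PHRED is a deliberate choice;
per-base filtering is not part of long-read practice and read-level
aggregation is deterministic). Supplementary records are surfaced to the
chimera stage only, never counted in coverage or class proportions, to
avoid double counting.

## Read classification

Span (reference extent) defines read length; it is robust to small
deletions and consistent with genome-frame coverage. Classes are assigned
by precedence:

1. `full_length`: span ≥ 0.90 · L;
2. `three_prime_anchored`: reaches within δ of the genomic 3' end but not
   the 5' end (DRS sequences 3'→5', so truncations keep the 3' end);
3. `five_prime_anchored`: reaches the 5' end only (degradation trims 3'
   ends);
4. `coat_lys_subgenomic` then `coat_subgenomic`: ≥ 90% coverage of the
   ORF(s), mirroring the full-length convention;
5. `other_internal`.

Terminal anchoring outranks ORF content because it is the primary
explanatory axis (technology bias vs degradation) for short reads. The
anchoring tolerance δ = 25 nt covers typical DRS 5'-end raggedness while
keeping classes separable; it is exposed on the CLI. Length fractions use
the < 800 nt and > 3,000 nt cuts that delimit the short-read and
full-length populations.

## Start/end hotspot statistic

Per strand, the genome is tiled with non-overlapping 5-bp windows. For each
window: depth = mean per-base coverage, start_count = reads whose
biological 5' lies in the window (ends analogous), ratio = count/depth, and
fold = ratio divided by the genome-wide **median** ratio over windows with
depth ≥ 50. The median baseline is robust to the true hotspots themselves;
min_depth = 50 suppresses low-coverage ratio blow-ups. A window is a
hotspot when fold ≥ 5 (a permissive fold-2 preset exists) and it lies
within the 1-based reporting ranges 100–3500 (starts) / 0–3400 (ends),
which exclude the trivially anchored genome termini. The fold-threshold
rule is a declared substitute for a visual "peaks of significance"
procedure that has no published formula.

Hotspots are annotated with ATG/stop motifs within ±10 nt (both strands,
purely annotational) and with an AG-richness test: the purine fraction of
the 20 nt flank 5' of the hotspot (strand-aware) against the genome-wide
purine fraction on that strand, one-sided exact binomial, BH-FDR across
tested hotspots.

## Chimera detection

Segment finding is seed-and-extend rather than full quadratic alignment:
exact 13-mers of the read are located in the genome (and, via the
reverse-complemented read, on the '-' strand); seeds sharing a diagonal are
extended to the maximal-scoring ungapped run (Kadane scan, match +1 /
mismatch −2); candidates on diagonals ≤ 15 apart are merged through a local
affine-gap alignment (open −4, extend −2, Biopython PairwiseAligner).
Segments scoring < 60 are dropped. On substitution-dominated reads this is
equivalent to exhaustive local alignment, and the test suite enforces that
equivalence against an independent full Smith–Waterman (Gotoh) oracle on
random reads. The diagonal-merge tolerance (15 nt) is deliberately below
the 20 nt minimum of the deletion/duplication range of interest, so true
template-switch junctions are never absorbed as alignment gaps.

Chaining is greedy by score with query-overlap tolerance 20 nt; the chain
is the best run of query-adjacent segments (gap ≤ 20 nt). A read is hybrid
iff its chain covers ≥ 2 distinct loci (reference intervals with < 50%
reciprocal overlap, or differing strand). Junction typing:

* same strand → `pos_pos`/`neg_neg`, with signed offset Δ computed in
  transcript orientation ('-' junctions on the reverse-complement frame).
  The raw reference gap is corrected by the query gap/overlap between the
  chained segments: bases at the junction that happen to match both
  templates extend both alignments symmetrically, and subtracting the query
  gap cancels that wobble exactly, making Δ exact on substitution-only
  reads. Δ > 0 = deletion, Δ < 0 = duplication, 20 ≤ |Δ| ≤ 60 flagged as
  the characteristic replicase recombination range (other Δ are reported
  unflagged).
* opposite strands with ≥ 50% reference overlap (relative to the shorter
  segment) → `foldback` (copyback/snapback); otherwise `neg_pos`/`pos_neg`
  strand switches.

Junction-flanking complementarity is not used as a filter. The score
threshold of 60 stands in for a BLAST E-value cutoff; on a 3.6 kb genome an
E-value adds no discrimination over a raw-score bound.

## Modification stoichiometry and dynamics

Per-read, per-site call probabilities (the pileup substrate) are
thresholded strictly at 0.8 — a read counts as modified iff its probability
exceeds 80% — and per-site stoichiometry is n_modified / coverage, computed
per sample and per length fraction. The threshold applies per read; per-site
thresholding is available by filtering the output. Sites need coverage ≥ 30
in every compared sample (stabilises stoichiometry at the ±0.1 level).

DRS modified-base calling has a high false-positive rate, so an unmodified
in vitro transcribed (IVT) control defines the background: a site is
retained only when stoichiometry(test) − stoichiometry(IVT) > 0 (strict;
sites absent from the IVT table count as background 0). Significance per
site is a two-sided Fisher exact test on the 2×2 modified/unmodified ×
sample table — an open substitution for pileup-internal MAP-based testing,
chosen because it is exact at these depths and auditable against the
hypergeometric tail. BH-FDR is applied within each comparison family
(timepoint pair × modification type × length fraction), mirroring per-panel
testing; q < 0.05 is significant.

Temporal dynamics: for each consecutive pair of ordered timepoints a site
is labelled increase/decrease (q < 0.05, by sign of change) or
no_difference; the ordered tuple is the site's dynamic label, with named
presets for the recurring patterns (full-length fraction:
decrease–increase "blue", decrease–no_difference "purple",
increase–no_difference "brown"; short fraction single-pair: increase
"cyan", no_difference "red"). m6A and inosine are carried by the data model
but have no presets. A 5-mer sequence context is emitted per retained site
as an annotation.

## Synthetic data generator

The generator emulates the observed read populations, not the sequencing
physics. Genome: random sequence with ATG/stop codons planted at each ORF
boundary and a purine-rich (Shine–Dalgarno-like) hexamer 8–12 nt upstream
of each start; default ORF layout uses the classic MS2 coordinates
(mat 130–1311, coat 1335–1727, lys 1678–1905, rep 1761–3398, 1-based),
rescaled for non-default lengths and fully configurable.

Read classes: full-length spans ≥ 0.93 L; 3'-anchored reads end within
10 nt of L with interior-uniform starts; 5'-anchored reads start within
10 nt of 0; coat-subgenomic reads contain the coat ORF within ≤ 780 nt;
other internal fragments take an exponential-tail length distribution
(scale 300 nt — the degraded-length distribution is not characterised, so
a memoryless decay is the neutral choice, and the scale is exposed).
Class generators sample with small margins away from the classifier's
decision boundaries (interior spans ≤ 0.893 L; coat reads stay below 85%
lys coverage), so truth labels are well defined and recovery failures
indicate classifier defects rather than boundary ambiguity.

Errors are substitution-only by default (default rate 3%, a realistic DRS
mismatch level) so chimera junctions stay exact in the truth table;
per-base qualities are Normal(14, 3) clipped to [2, 40]. Hybrids are
constructed literally: deletion = genome[a:j1] + genome[j1+Δ:b],
duplication re-copies Δ nt, neg_neg analogues on the reverse-complement
frame, foldback = segment + reverse complement of a suffix of itself.
Modification calls are Bernoulli(stoichiometry) per covering
positive-strand read, with call probabilities Uniform(0.85, 1) when
modified and Uniform(0, 0.30) when not; IVT runs force stoichiometry 0
except at planted artifact sites. All randomness flows from one integer
seed through `numpy.random.default_rng`; identical seeds give
byte-identical outputs.

What the generator does **not** model — signal-level noise, indels,
homopolymer effects, poly(A) tails, quality/length correlation, host
transcripts — bounds what passing tests show: they validate the inference
logic under the declared population model, not basecaller- or
aligner-specific behaviour on real flow cells.

## Numerical and procedural choices

* Windows with depth below min_depth are flagged missing, never given
  ratios; an all-missing strand yields no fold values rather than NaN
  cascades.
* Hotspot output is sorted by fold descending with a stable sort;
  all tabular outputs are deterministic (no timestamps), so identical
  configs and seeds reproduce byte-identical TSVs.
* Fisher tests skip sites with zero coverage in either sample.
* Fold changes across timepoints report both the raw ratio and a
  pseudo-count-adjusted (count+1)/(baseline+1) ratio, since the earliest
  timepoint can have zero counts for whole classes.
* SAM records lacking base qualities are retained (the PHRED filter cannot
  be evaluated); CIGAR-less records are skipped with a warning.

## Problem sizes used in validation

The acceptance script and end-to-end tests use 20,000 reads for class
recovery, 500 planted same-strand hybrids + 100 foldbacks against 5,000
non-hybrid reads at 2% error for chimera detection, 10,000 reads for
hotspot power and five uniform backgrounds for type-I control, 50 random
reads ≤ 200 nt for oracle equivalence, and 100 replicates per modification
panel at depths 300–1,000 — sizes at which the binomial noise floor sits
well below every acceptance margin.

## Known limitations

* The segment finder assumes substitution-dominated errors; reads with
  dense indels can fragment segments (the gapped merge handles indel gaps
  ≤ 15 nt). Real-data use at high indel rates would warrant a chaining DP.
* Hotspot fold changes are undefined on strands without depth-qualified
  windows.
* The hybrid strand assignment (first segment's strand) is a convention;
  foldback reads are intrinsically double-stranded.
* IVT matching assumes the control shares the test samples' site keys;
  fraction-specific IVT controls are supported but not required.
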