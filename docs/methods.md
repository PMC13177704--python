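# Methods

`yprime` re-implements, as a tested library and CLI, a bottom-up procedure
for discovering, classifying and characterizing the subtelomeric Y′
elements of *Saccharomyces cerevisiae* in telomere-to-telomere genome
assemblies, together with a synthetic chromosome-end generator that makes
every stage verifiable against planted truth at desk scale.

## The detection procedure

Y′ elements are multi-kilobase repeats found in 0–many tandem copies just
inside the telomeres. Detection proceeds bottom-up rather than from a
single reference:

1. **Telomere scan.** Yeast telomeric DNA is a degenerate C(1–3)A /
   TG(1–3) repeat. Each position is marked if covered by a maximal motif
   run of ≥ 8 bp on either strand; sliding 20 bp windows average the
   coverage, and maximal runs of window scores ≥ 0.8 become calls, refined
   to exact motif-run boundaries and merged across gaps ≤ 10 bp. Calls
   within 50 bp of a contig edge are terminal telomeres; internal calls of
   ≥ 20 bp are interstitial telomeric sequences (ITSs). The window,
   threshold, merge-gap and margin defaults were fixed by Monte-Carlo
   calibration on random sequence (no call on ≥ 99% of random 10 kb
   fragments) before any downstream tuning; all are exposed in
   `PipelineConfig`. An external caller's GFF3 can be substituted for the
   internal scanner.

2. **Window self-repeats.** With telomeres and ITSs masked (replaced by
   N, which the aligner never matches), each contig's terminal 100 kb is
   scanned with 25 kb windows at a 5 kb step; each window is aligned
   against itself and off-diagonal repeats of 4.0–9.5 kb at ≥ 90%
   identity are kept (hits whose two spans overlap reciprocally by more
   than 50% are the trivial diagonal and are dropped).

3. **High-confidence database.** A repeat copy is promoted iff (a) it
   matches a reference Y′ sequence over ≥ 500 bp at ≥ 80% identity and
   (b) both of its ends lie within 50 bp of telomeric sequence (terminal
   or ITS) — the "directly flanked" rule that guarantees complete copies.
   The reference sequences themselves are appended and duplicates
   collapsed. The 500 bp / 80% / 50 bp operationalizations are package
   choices (the qualitative rules do not quantify them) and are exposed in
   config.

4. **Exhaustive detection.** Every database entry is spliced-mapped onto
   every contig on both strands, allowing internal gaps up to 1 kb so that
   differences in internal repeat-stretch length between query and target
   are absorbed as single gaps. Terminal alignment blocks shorter than
   20 bp separated from the next block by more than 100 bp are trimmed
   (overextension artifacts). Hits from different entries that overlap
   reciprocally by more than 50% are reconciled to the highest score (ties
   to the lower start, then lexical entry id); residual partial overlaps
   are clipped against the better hit. Elements shorter than 1 kb are
   dropped; elements whose interval adjoins a contig end (≤ 10 bp) are
   flagged edge-truncated and excluded from downstream analyses; the count
   above 3.5 kb is logged but not used as a filter. Orientation is
   normalized so that coordinates run from the centromere-proximal end
   toward the telomere.

## Alignment engine

The seeded aligner uses exact 15-mer anchors, groups them by diagonal
bands, selects the maximum collinear anchor subset per band by longest
increasing subsequence (greedy first-fit chaining can jump between repeat
units), and extends:

* short candidate windows (≤ 1.5 kb per side): exact affine-gap local DP
  (match +1, mismatch −2, gap open −4, gap extend −1);
* long spans in spliced mode: anchor-guided piecewise alignment — exact
  anchors pin the path, inter-anchor segments are aligned globally with
  edlib, and head/tail segments with a free target end; the maximum-scoring
  sub-path is then extracted, which trims extension into unrelated flanks.

Gap runs longer than 30 bp in spliced mode are treated as splices: scored
with a flat penalty, excluded from the identity denominator, and reported
as block gaps; zones of gaps interleaved with sub-12 bp blocks are
coalesced into one net gap so a repeat-length difference appears as a
single spliced gap rather than scattered micro-blocks. Masked (N) bases
never match. The aligner is checked against an independent affine local
alignment oracle (Biopython `PairwiseAligner`) on seeded homologous pairs.

MSA defaults to the MAFFT executable in its deterministic two-round
progressive mode (FFT-NS-2, single thread; `mafft-auto` selects MAFFT's
`--auto`); a deterministic internal progressive aligner (guide order from
edlib pairwise distances, profile Needleman–Wunsch with linear gaps) is
the fallback and the reference for small exact tests. MSA rows always
reproduce their inputs after gap removal.

## Internal repeats of Y′ elements

**36-mer stretches.** A 36 bp window slides along the oriented element;
each position scores `(36 − d)/36` with `d` the Levenshtein distance to
the best motif of the database (initially all concrete expansions of a
degenerate consensus; one bootstrap round pools all detected indel-free
units, deduplicates, and rescans). Peaks are local maxima ≥ 0.85 separated
by ≥ 30 positions (plateaus resolve to their leftmost index; spacing is
enforced greedily from the highest score down). The stretch runs from the
first peak to the end of the last peak window; `unit_count` is the number
of 36 bp periods spanned, `round(span/36)`, while the `units` list keeps
only peak windows whose optimal alignment to the best motif is indel-free
— detected exactly by comparing minimum Hamming and Levenshtein distances
(they coincide iff an indel-free optimal alignment exists). The interval
convention includes the final window's 36 bp.

**CA-rich regions.** 100 bp windows qualify when A+C ≥ 0.8 and
min(A, C) ≥ 0.25; qualifying runs merged across sub-window gaps form
candidate regions, and a region is rejected as telomere-like when its
overall C/(C+A) ≥ 0.55 or its telomere-motif-run coverage is ≥ 0.8 —
telomeric tracts are strongly C-biased (62.5% C / 37.5% A on the CA
strand) while CA-rich repeats have near-equal A and C. The coverage-based
guard is structural, not compositional: composition alone leaves a few
percent of short telomeric tracts within sampling noise of the 0.55
boundary. Pattern segmentation reuses the sliding edit-distance peak
procedure with pattern-specific window lengths (37 bp Pattern-1-like,
33 bp Pattern-2-like fixtures); each base takes the label of the
highest-scoring covering peak window.

Masking removes stretch intervals while recording enough to reinsert them
exactly (`original length = masked length + removed lengths` holds for
every element). Clustering uses 36-mer-masked sequences; the CA
re-clustering additionally removes CA regions.

## Clustering

Pairwise similarity between two MSA rows is the percentage of identical
residues over the union of the two sequences: shared-gap columns are
ignored, one-sided gaps count as differences — so the measure is dominated
by structural differences, not SNPs. Average-linkage hierarchical
clustering on distance (100 − similarity) is cut at every k from 2 to 100
(capped at n−1) and the cut maximizing mean silhouette wins, ties to the
smallest k. Cluster ids are deterministic (size-descending, then first
member). Elements containing CA regions are re-clustered on CA-masked
sequences in a separate `CA*` namespace, replacing their labels only.
Clusters are retained iff they hold ≥ 5 elements from ≥ 2 strains with
mean intra-cluster heterogeneity (100 − mean similarity) ≤ 15 percentage
points; the heterogeneity threshold quantifies an originally qualitative
filter and is exposed in config. Consensi are per-column majorities over
the cluster MSA (ties prefer bases over gaps, then alphabetical order;
gap-majority columns are dropped).

## ORFs and profiles

ORFs are intervals of ≥ 300 bases from an ATG to the next in-frame stop
(TAA/TAG/TGA), inclusive, over the three forward frames of the
orientation-normalized element; nested ATGs do not spawn separate ORFs,
unterminated ORFs are not reported, and ambiguous codons are sense. Each
member's any-frame ORF mask is lifted through its MSA row (gap columns
contribute absence) and averaged across the cluster into a per-column ORF
probability profile.

## Statistics

Distribution tables (per strain, per extremity, cluster × strain, tandem
array histogram) retain zero rows. Interstitial calls are classified as
tandem-junction (between two elements within a 500 bp association window),
centromere-proximal (within the window of an element's
centromere-proximal end), or unassigned. Within- vs between-strain
diversity uses pairwise divergence over an MSA of a conserved region,
partitioned by strain pair. Telomere-length analysis divides each
extremity's mean length by its strain mean, groups extremities by the
cluster of the telomere-adjacent element versus "no Y′", and applies a
two-tailed two-sample t-test (Welch by default; a config switch selects
the pooled-variance form) with effect `1 − mean(class)/mean(no-Y′)`;
per-class Spearman correlations relate strain copy numbers to strain mean
lengths. Raw p-values are reported; a Benjamini–Hochberg helper is
available but never applied silently. A chi-square independence test
(no continuity correction) serves categorical tables, warning on expected
counts below 5.

## The synthetic-data generator

The generator emits multi-contig FASTA plus exact truth. Six templates
derive from one 6,256 bp "long" backbone carrying planted ORFs: removing
two internal blocks of 465 and 600 bp yields the short class (5,191 bp);
removing either single block yields mid1/mid2; the two CA classes share
the proximal 3,128 bp and replace the distal half with distinct 1.7 and
1.8 kb domains hosting the CA repeats. Per chromosome end the generator
draws 0–3 elements (weights 0.64/0.30/0.05/0.01, matching observed
extremity occupancy), orients them toward the nearer telomere, separates
tandem copies by ITSs with probability 0.62 (20–500 bp, log-uniform) and
precedes arrays by a proximal ITS with probability 0.5; every contig ends
in telomeric tracts (length ~N(330, 75) bp, floor 100) built from C{1,3}A
units with E[C]/E[C+A] = 0.625, resampled if a tract's C fraction is not
strictly above 0.52. 36-mer stretch unit counts follow Binomial(36, 0.28)
(median ≈ 10, range 0–36); CA stretches draw 8–40 units of the two
pattern fixtures. Background sequence is i.i.d. uniform ACGT — the
simplest null that does not mimic repeats — and an inert 500 bp
placeholder stands in for the X element.

Two divergence mechanisms are deliberately distinct. Element bodies
receive i.i.d. substitutions at `substitution_rate` (default 0.5%,
assembly-grade). Repeat units receive *controlled* divergence: exactly
`round(d × unit length)` substitutions per unit at positions drawn without
replacement. A unit at the default 8–10% divergence then always scores
≥ 0.85 against its consensus, so the planted unit count is a well-defined
quantity the scanner can be held to; an i.i.d. per-base model at the same
mean would place ~15% of units below the peak threshold purely by
Binomial noise and make "exact recovery" an ill-posed target. CA-unit
substitutions draw replacement bases from the CA composition
(45/42/7.5/5.5) so the compositional signature is stationary under
divergence. Telomere tracts and ITSs are not additionally mutated — they
are already stochastic by construction. The motif fixtures (degenerate
36-mer consensus, Pattern 1/2) are synthetic stand-ins with the documented
structural properties, not the published motifs, which are available only
as supplementary material; every scanner accepts user-supplied motif
databases.

The truth table is self-consistent by construction: re-extracting any
truth interval from the emitted FASTA reproduces the planted, mutated
sequence exactly, which the tests verify.

Telomere-length tables draw per-extremity lengths from the same normal
law, scale extremities whose distal element belongs to class c by
(1 − effect_c), and apply per-strain multiplicative factors for
copy-number (trans) effects — giving planted cis effects, null
calibration, and a planted monotone copy-number/length relation.

What the simulator does **not** emulate: long-read homopolymer errors
(and hence frameshifted ORFs), assembly collapse or overassembly of
tandem arrays, real subtelomeric X-element structure, biased base
composition of genuine intergenic sequence, and recombination-generated
mosaic elements. Passing the recovery tests therefore demonstrates
correctness of the algorithms under the stated generative model, not
performance on real assemblies; on real data the manual-curation steps
the original analysis applied (read remapping and end trimming) have no
algorithmic counterpart here and are out of scope.

## Numerical and determinism choices

All coordinates are 0-based half-open internally; GFF3 emission converts
to 1-based inclusive and percent-escapes attributes so records round-trip
losslessly. Every stochastic component takes an explicit seed; fixed
seeds make simulator output, pipeline TSV/FASTA/GFF3 outputs and MAFFT
invocations byte-reproducible. Tie-breaks are specified everywhere a
ranking exists (peak plateaus leftmost; hit reconciliation by score, then
start, then entry id; consensus residues by base-over-gap then
alphabetical; silhouette ties to smallest k; guide-tree ties to input
order). Degenerate inputs raise typed errors (`InputError`,
`GenerationError`, `DegenerateInputError`) rather than returning
undefined values — e.g. clustering refuses an all-zero distance matrix,
where silhouettes are undefined.

## Problem sizes used in the shipped experiments

The acceptance experiments run the full detection pipeline on 60–100
simulated strains of 5 contigs (~20–40 kb each), stretch recovery on 100
elements spanning 0–36 units, cluster recovery on 50 seeds of 60
elements, oracle comparisons on 200 sequences/pairs, association
calibration on 500 power and 1,000 null replicates at 54 strains × 32
extremities, and telomere/ITS recovery on 100 seeded genomes with 1,000
tracts per class for discrimination. These sizes give binomial standard
errors comfortably below the margins being asserted while keeping a full
run in the minutes range on one core.

## Known limitations

* The internal aligner contracts only the hit semantics, not bit-level
  agreement with BLAST/BLAT; on real genomes the hit sets may differ in
  low-identity or highly repetitive corners.
* Identity of spliced hits is computed excluding splice gaps; tools that
  count them will report lower values for the same alignment.
* The silhouette criterion inherits its known bias toward balanced,
  spherical clusters; very small true classes may be absorbed (the
  retention filter is designed to make that visible rather than hide it).
* The CA-region thresholds assume the ~45/42 A/C signature; CA-like
  repeats with materially different composition would need the config
  knobs.
* ORF profiling treats sequences as given: frameshifts from assembly
  errors depress profiles and no correction is attempted.
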