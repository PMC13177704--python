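# yprime

Discovery, classification and characterization of subtelomeric **Y′
elements** in budding-yeast (*Saccharomyces cerevisiae*) genome
assemblies — with a synthetic chromosome-end generator that makes every
stage of the pipeline verifiable against planted ground truth.

Y′ elements are multi-kilobase repeats found in 0–many tandem copies just
inside the telomeres, in two canonical length classes (short ≈ 5.2 kb,
long ≈ 6.7 kb) plus intermediate and CA-repeat-containing families. They
carry a variable stretch of tandemly repeated, degenerate 36 bp units,
one or two conserved ORFs, and are often separated from each other and
from unique sequence by interstitial telomeric sequences (ITSs). The
package is aimed at researchers with telomere-to-telomere assemblies who
want a reproducible, bottom-up Y′ catalog rather than annotation against
a single reference copy.

## What it does

1. **Telomere/ITS scan** — degenerate C(1–3)A / TG(1–3) motif-run
   coverage in sliding windows; terminal and interstitial calls.
2. **Self-repeat discovery** — with telomeres masked, 25 kb windows (5 kb
   step) over the terminal 100 kb of each contig are aligned against
   themselves; off-diagonal repeats of 4.0–9.5 kb at ≥ 90% identity are
   candidate Y′ copies.
3. **High-confidence database** — candidates that match a reference Y′
   and are directly flanked by telomeric sequence on both sides, plus the
   reference entries.
4. **Exhaustive detection** — spliced mapping of every database entry
   onto every contig (internal gaps ≤ 1 kb absorb 36-mer stretch length
   variation), trimming of spurious terminal blocks, overlap
   reconciliation, orientation normalization, edge-truncation flags.
5. **Repeat profiling** — sliding Levenshtein scoring of 36 bp windows
   against a motif database with peak calling (height 0.85, spacing 30),
   one bootstrap refinement round, CA-rich region detection
   (A≈45%/C≈42% composition) and Pattern-1/2 segmentation, masking with
   exact length accounting.
6. **Clustering** — pairwise percent similarity from an MSA of masked
   elements (shared-gap columns ignored), average-linkage clustering with
   the cluster count chosen by silhouette over k = 2..100, CA
   re-clustering after CA removal, retention filters (≥ 5 elements, ≥ 2
   strains, bounded heterogeneity), majority-rule consensi.
7. **ORF profiling** — three-frame ORF detection (≥ 300 bp, ATG→stop) and
   per-cluster ORF-probability profiles on MSA coordinates.
8. **Statistics** — count tables, ITS context classification, within- vs
   between-strain diversity, telomere-length association tests (per-class
   two-tailed t-tests vs Y′-free extremities, Spearman copy-number
   correlations, chi-square for categorical tables).

The scientific conventions, parameter defaults, simulator design and
known limitations are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Simulate two strains of four chromosome-end contigs, run the full
pipeline, and inspect the outputs:

```bash
yprime simulate --seed 4 --strains 2 --contigs 3 --out sim/
yprime all sim/strain00.fasta sim/strain01.fasta \
    --telomere-table sim/telomere_lengths.tsv --out run/
```

which prints

```
wrote 2 strains, 11 planted elements
11 elements, 1 retained clusters -> run/
```

Eleven planted elements were recovered. `run/` now holds per-strain GFF3
annotations (telomeres, elements, stretches, ORFs), element and masked
FASTA, the Y′ database, the similarity matrix, cluster assignments and
summaries, consensus sequences, ORF profiles, ITS and count tables,
association tests and a `manifest.json` recording parameters and the
detection funnel. A typical annotation line:

```
chr01  yprime  yprime  240  6819  .  -  .  ID=strain00.chr01.000;length=6580;telomere_flanked=distal_only;edge_truncated=false;cluster=C1
```

— a 6,580 bp element on the left arm (reverse orientation: its
coordinates run centromere→telomere), directly flanked by its telomere,
assigned to cluster C1. With only 11 elements across 2 strains, most
clusters fail the ≥ 5-element retention filter; one canonical cluster is
retained. Re-running the same command reproduces every output file
byte-for-byte.

The same stages are available as library functions
(`yprime.detect.detect_elements`, `yprime.repeats.detect_36mer_stretch`,
`yprime.cluster.cluster_elements`, …) and as individual subcommands
(`scan-telomeres`, `build-db`, `detect`, `profile-repeats`, `cluster`,
`orf-profile`, `stats`).

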