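# Methods

`primarytx` reimplements, as a reusable library, the analysis chain of a
bacterial dRNA-seq (differential RNA-seq) primary-transcriptome study:
paired sequencing libraries are prepared with and without terminator
exonuclease (TEX), an enzyme that degrades 5'-monophosphorylated
(processed) RNA while sparing 5'-triphosphorylated (primary) transcripts,
so that genuine transcription start sites (TSSs) appear as 5'-end positions
enriched in the TEX-treated half. Everything downstream — TSS
classification, 5'UTR annotation, differential expression, sRNA discovery,
operon validation, start-codon correction — is driven by the stranded
per-nucleotide coverage and 5'-end tracks of those libraries.

## Coordinates, tracks and normalization

All coordinates are 1-based inclusive (GFF3 convention); BED input is
converted at the boundary. For every library two stranded tracks are kept:
full coverage (reads overlapping each position) and 5'-end counts (read
start on the forward strand, read end on the reverse strand — the
biological 5' end either way). Tracks are normalized per library to
reads-per-million mapped reads (RPM); gene expression uses RPKM
(reads x 1e9 / (gene length x total mapped)). Reads are assigned to genes
by same-strand overlap of at least one nucleotide, with multi-counting
allowed for overlapping genes; the rule is deliberately the simplest
deterministic one and is recorded here because other conventions
(fractional assignment, majority-overlap) would shift RPKM values slightly.
The chromosome is treated as circular: intervals wrapping the origin are
split internally and upstream-window arithmetic wraps.

## TSS detection

Position *p* on a strand is a per-sample TSS candidate when three gates all
pass on the (TEX+, TEX-) track pair:

1. **height** — TEX+ 5'-end height at *p* ≥ `min_step_height` (RPM);
2. **step** — TEX+ full coverage at *p* divided by the coverage at the
   strand-aware upstream neighbour ≥ `min_step_factor` (default 2.0), with
   an empty neighbour replaced by a machine minimum;
3. **enrichment** — TEX+ 5'-end height divided by (TEX- 5'-end height +
   `pseudocount`) ≥ `min_enrichment` (default 2.0, pseudocount 1 RPM).

Candidates from the six samples are chain-clustered within
`cluster_window` = 3 nt per strand; the representative position is the
candidate with maximal height over all samples, ties resolved to the most
upstream position (strand-aware), and `detected_samples` is the union of
contributing samples.

`min_step_height` defaults to 100 RPM. The value is expressed in RPM but
its meaning is "a handful of reads": at the bundled generator's default
depth of 50,000 reads per library one read equals 20 RPM, so the default
demands five coincident 5' ends. That sits roughly at the logarithmic
midpoint between the Poisson coincidence tail of TEX-surviving processed
5' ends (which decays ~25-fold per additional read at realistic body
coverage) and the weakest planted TSS signal (~2,800 RPM). For deeply
sequenced real libraries (1e7–1e8 reads) the conventional operating point
is 0.1–1 RPM; the parameter is exposed precisely because it must track
library depth.

## TSS classification

Five positional categories, assigned against the annotation with
multi-category membership across different genes allowed:

- **primary / secondary** — for each gene, every TSS on the sense strand
  within `primary_window` = 500 nt upstream of the annotated translation
  start (distance 0 allowed: a TSS on the start codon is a leaderless
  primary) is a candidate; the one with the strongest expression (maximal
  normalized 5'-end height over all libraries, ties to the most upstream)
  is primary, all others secondary.
- **internal** — sense-strand TSS strictly inside a gene body.
- **antisense** — opposite-strand TSS inside a gene or within
  `antisense_window` = 100 nt of its boundaries.
- **orphan** — a TSS with no link to any gene.

## 5'UTRs, riboswitch candidates, re-annotation

The 5'UTR of a gene is the distance from its primary TSS to the annotated
translation start; negative lengths (TSS downstream of the start) are
excluded with a warning rather than clamped. Classes use strict
inequalities: leaderless < 10 nt, long > 100 nt, standard otherwise. UTRs
strictly longer than 70 nt are exported as FASTA for an external Rfam
riboswitch search; no covariance-model scoring happens here.

Start-codon correction: an internal TSS lying 1–50 nt downstream of the
annotated start codon flags the gene as potentially mis-annotated. The scan
walks 40–100 nt downstream of the TSS in the annotated reading frame and
returns the nearest ATG/GTG/TTG that carries a Shine-Dalgarno match — at
least 4 of 6 positions of AGGAGG with the hexamer's 3' end 5–9 nt upstream
of the candidate start. The "~7 bp ribosome-binding spacing" is
operationalized as that 5–9 nt window because no scoring scheme beyond the
consensus is defensible at this resolution.

## Differential expression

No statistical model is fitted — with one unreplicated library per
condition there is nothing to estimate dispersion from. A gene is up in A
versus B when all three strict filters hold: RPKM fold change > 2, RPKM in
A > 2, raw reads in A > 50, computed from the TEX-untreated libraries.
Zero-denominator folds are reported as infinity with an explicit flag; the
RPKM-floor filter already guards their significance. The down direction is
the swapped comparison. Standard comparisons: SE#9h vs SE#6h and RS#9h vs
RS#6h (growth phase within each soil-extract medium) and RS#9h vs SE#9h
(root-exudate effect at middle stationary phase).

## Intergenic segment discovery

Segmentation runs on the TEX-untreated full-coverage track of each library
separately (TEX+ libraries are depleted of exactly the body coverage that
defines a transcript's extent; pooling six libraries saturates the
background occupancy). Per strand: maximal runs with coverage ≥ `min_cov`
(2 RPM), sub-threshold gaps ≤ `max_gap` (10 nt) bridged; runs are split at
valleys and trimmed at boundaries where coverage falls below
`min_boundary_reads` = 2.5 overlapping reads (converted through the
library's normalization scale). The read-unit floor is the load-bearing
choice: chains of isolated stray reads never stack three deep, while any
segment abundant enough to survive the raw-read filter keeps a body
coverage an order of magnitude above it; a peak-relative trim fails here
because the 5'-end spike is read-length wide and dominates short runs.
Runs are intersected with strand-specific intergenic space, and a piece
whose coverage crosses an IGR/gene boundary with no sub-threshold hole is
discarded as an mRNA extension rather than an independent transcript.
Per-library candidates are consolidated by overlap; the representative is
the candidate from the library with the most supporting reads, and
segments are retained only when that count strictly exceeds
`min_raw_reads` = 50.

Retained segments are classified in a fixed order — antisense to a CDS
(≥ 1 nt opposite-strand CDS overlap), antisense to a UTR (overlap with an
assigned 5'UTR or an inferred 3'UTR, approximated as up to 100 nt
downstream of each stop codon unless a neighbouring gene intervenes),
small-ORF mRNA (a Shine-Dalgarno-led ORF of 30–99 aa on the segment
strand), else trans-encoded sRNA candidate. The order is a declared
reconstruction: antisense overlap is the strongest positional evidence, an
encoded protein the next, and the sRNA label is the residual. Flags are
additive: `three_prime_utr_derived` when the segment's 5' end lies in the
upstream gene's 3' region, `excludon_like` when an antisense segment spans
two or more opposite-strand genes, `known_homolog` from a user-supplied
locus table.

## Operon validation

For each adjacent pair in a predicted operon, junction support is the
minimum full coverage across the inter-gene junction divided by the mean
coverage of the weaker flanking gene; a prediction is validated when every
junction reaches `alpha` = 0.5 in at least one TEX-untreated library. The
manual, by-eye validation this replaces has no published threshold; 0.5 is
the exposed default. Monocistronic detection asks a different question —
whether an internal gene's transcription arrives through the junction at
all — so there the junction minimum is divided by that gene's own mean
coverage: with the weaker-flank denominator, residual basal transcription
of the upstream gene (a near-zero mean) would make any junction look
supported and mask a genuine alternative TSS. A gene is reported
monocistronic in sample *s* when it owns a primary TSS detected in *s* and
its upstream junction support in that sample's TEX- library is below
`alpha`.

## The synthetic-data generator

The generator is the package's test bed: it lays out a 50-kb circular
chromosome with 60 genes and 82 transcripts in a fixed scene containing
every structure the pipeline claims to find — three operons (two
continuous, one switching to an internal alternative TSS at middle
stationary phase), two falsely predicted operon pairs transcribed
separately, eight mis-annotated genes, five leaderless and five long-UTR
genes (two of the latter with antisense RNAs over their UTRs), five genes
with secondary TSSs, five with internal TSSs, four antisense-RNA target
genes, one excludon-like locus, nine intergenic transcripts (six plain
sRNAs, one 3'UTR-derived, two small-ORF mRNAs), and fourteen
differential-expression genes (six growth-up, two growth-down, four
root-exudate-responsive, two constitutive controls). Structural placement
is deterministic; sequence content, exact offsets and read sampling are
driven by one seeded generator, so a fixed seed gives byte-identical
output. Gene starts carry planted AGGAGG hexamers at 7-nt spacing; the +1
position of every transcript is a purine with probability 0.8; planted
sRNA segments are actively scrubbed of accidental qualifying ORFs and
mis-annotated genes of competing in-frame start codons, so that the
planted geometry is unambiguous under the classification rules (the
generator verifies this at build time and refuses to emit an ambiguous
scene).

Reads are simulated per library at exactly 50,000 reads. Each read's 5'
end is drawn from a mixture: with 2% probability uniform genomic
background; otherwise a transcript chosen proportional to its
per-sample activity, then within the transcript a source — primary
(fraction 0.30; position = TSS with probability 0.7, else one of the next
five nucleotides), discrete processing sites (0.10; at least one site per
transcript, Poisson 0.5/kb, kept ≥ 30 nt from any planted TSS), or
body-wide decay intermediates uniform along the transcript (0.60). In
TEX+ libraries processed sources (sites and body) survive with probability
`tex_depletion` = 0.1 and the mixture renormalizes, so the TEX contrast is
a composition shift at constant depth — which is also why the expected
enrichment ratio at a TSS is (0.30/0.37)/0.30 ≈ 2.7, comfortably above the
2.0 gate, and the ratio at a processing site is ~0.04, comfortably below.
Body-wide processed ends are deliberately part of the model: with 50-nt
reads and purely site-anchored processing, gene bodies would be uncovered
and the coverage-continuity signals the method itself relies on (operon
junctions, segment extents) could not exist at any depth. Reads are 50 nt,
truncated at the transcript 3' end (25 nt past the stop codon).

What the generator does *not* emulate: sequencing errors and quality
scores, rRNA/tRNA load, replicate variability, transcription bubbles or
partial termination, condition-dependent processing, GC-content bias.
Passing the planted-truth suites therefore demonstrates that the
implementation applies its stated rules correctly at realistic
signal-to-noise, not that the thresholds are optimal for any particular
real dataset.

## Problem sizes and determinism

The default scene (50 kb, 60 genes, 12 x 50,000 reads) makes the full
pipeline run in about two seconds, so the test suite re-simulates freely:
planted-recovery properties are asserted across ten independent seeds and
oracle-equivalence checks across a hundred randomized small instances. All
randomness flows from explicit seeds; `scripts/acceptance.py` derives
every quantity from a fresh simulation under the seed given on the command
line.

## Known limitations

- One library per sample is assumed throughout (as in the study design);
  replicate handling would change the DE module fundamentally.
- Primary/secondary ranking uses the maximum height over libraries; a
  per-condition ranking could re-order genes whose alternative promoters
  dominate in different conditions.
- The 3'UTR approximation (≤ 100 nt after the stop) is a geometric proxy;
  without termination signals, genuine 3' ends are unknowable here.
- Segment consolidation keeps the single best library's boundaries rather
  than merging boundaries across libraries; condition-dependent isoforms
  collapse to the most abundant one.
- The arithmetic-check table reproduces one internal inconsistency of the
  published headline counts (the antisense share) on purpose; it reports,
  it does not reconcile.
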