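# Methods

## Overview

`mirqc` judges miRNA-seq sample quality comparatively: each of 34 QC
attributes is ranked by empirical percentile against reference corpora of
comparable samples, stratified by kingdom, species, kingdom+protocol,
species+protocol and low-input status. This note documents the processing
model, the parameter defaults and why they were chosen, the numerical
conventions, what the synthetic-data generator does and does not emulate,
and known limitations.

## Adapter trimming

Small-RNA reads run through the insert into the 3′ adapter, so trimming is
adapter *location*, not quality clipping.

* **Protocol presets.** Each preset carries an adapter sequence plus layout:
  NextFlex-style randomized bases flanking the insert (4+4), Qiagen-style
  12-nt UMI placed after the 3′ adapter (discarded with the adapter; it
  never touches the insert), or no adapter at all (`adapter_trimmed`, for
  libraries trimmed upstream — such reads are treated as bare inserts and
  classified by length). The shipped adapter sequences are conventional
  defaults and fully configurable; they are data, not code.
* **Locating the adapter.** The leftmost occurrence of the adapter's first
  12 nt with ≤1 substitution wins (vectorised window scan, `N` never
  matches). If absent, adapter prefixes of length 6–11 anchored at the
  read's 3′ end are tried longest-first (≤1 mismatch for ≥10 nt, exact
  below). The 12-nt seed / 1-mismatch budget balances sensitivity against
  spurious matches (a random 12-mer window passes with probability
  ≈ 2×10⁻⁶); the 6-nt floor for 3′-anchored partials keeps the
  false-positive rate of short anchors acceptable by requiring exactness.
* **Length classes.** adapter-dimer 0–2 nt, ultra-short 3–14 nt, short read
  15–17 nt, valid ≥18 nt; reads with no adapter found form their own class
  and are excluded from the valid denominator, because their insert length
  is unknown and counting the full read would distort the length
  distribution. Short reads (15–17 nt) are flagged as a library-quality
  attribute but *retained* inside the valid set and annotated — the 15-nt
  minimum-length filter implies retention, and discarding them would bias
  composition estimates.
* **Protocol detection.** A catalogue scan: the fraction of the first
  10,000 reads containing each preset's 12-nt adapter seed (≤1 mismatch)
  anywhere; highest fraction wins, ties resolve by catalogue order, and
  below a 0.20 floor the `adapter_trimmed` fallback is returned with a
  warning. NextFlex shares the Illumina adapter sequence and therefore
  cannot be distinguished by content alone; it must be requested explicitly.

## Read annotation

Inserts ≥15 nt are collapsed to unique sequences (multiplicities kept — the
collapse is also what the unique-reads complexity attribute needs) and
aligned end-to-end, both strands, with at most **one substitution** (no
indels; the Bowtie `-v 1` alignment model). Matching is seed-and-verify:

* A 12-mer seed table over both strands of every reference. For inserts
  ≥24 nt, a single substitution leaves either the first or last 12-mer
  exact, so those two anchors suffice.
* For inserts of 15–23 nt the first and last 12-mers overlap, and one
  substitution inside the overlap corrupts both. The pigeonhole argument is
  instead applied to the two *halves* of the insert (one must be clean),
  each anchored through a secondary 7-mer table. This keeps matching exact
  for every mappable length; the test suite proves equality with a naive
  all-offsets scan.
* Candidate anchors are verified over the full insert with early exit.

Assignment is two-step. Step 1: query genome and contaminant indexes; any
genome hit wins over contaminant hits (reference-genome preference for
multi-mapping reads); contaminant-only reads are bacterial or viral (fewer
mismatches win, bacterial wins ties); otherwise unmapped. Step 2:
genome-mapped reads are annotated in fixed priority order miRNA (mature,
then hairpin) → rRNA → tRNA → other ncRNA → mRNA — the first set with any
hit decides, and mismatch counts break ties only *within* a set, never
across sets. Genome-mapped reads with no annotation are `genomeOther`.
Within the miRNA set, equal-mismatch multi-mappers go to the
lexicographically smallest miRNA id — an arbitrary but deterministic
tie-break.

This matcher is exact but deliberately simple; genome-scale alignment
performance (FM-indexes etc.) is out of scope.

## The 34 attributes

A declarative registry (`quality_features.ATTRIBUTE_REGISTRY`) enumerates
every attribute with its report section and ranking orientation, in seven
sections: yield (5), library quality (5), complexity (8), contamination
(3), length distribution (5), RNA composition (4), sequencing quality (4).

Conventions that matter:

* **Denominators.** Library-prep artefacts (dimers, ultra-short, the
  minimum-length filter) are fractions of *total input reads*; biological
  composition (miRNA yield, rRNA, tRNA, mRNA, contamination, genome-other)
  is over *valid reads* (short + valid classes). The minimum-length-filter
  attribute equals dimers + ultra-short, computed over disjoint classes.
* **Missing values.** Undefined quantities (e.g. %miRNA with zero valid
  reads, skewness of a length spike) are explicit nulls, never zeros, and
  are excluded from corpus distributions and from ranking.
* **Length statistics** use miRNA-assigned reads only (the canonical
  21–23 nt peak is a property of miRNA reads) and **population** moments
  (no Bessel correction) — invariants such as "mirror the histogram,
  negate the skewness" then hold exactly. sd is reported for any N ≥ 3
  (0 for a spike); skewness additionally requires nonzero variance.
* **Sequencing quality** summarises the untrimmed per-position Phred
  matrix: mean, median, 25th and 10th percentile per position, averaged
  over positions. Positions covered by fewer than min(100, n_reads) reads
  are dropped so a handful of unusually long reads cannot dominate the
  tail; the min() guard keeps small samples well-defined.
* **Orientation.** higher-better: %valid, detected miRNAs, %miRNA reads,
  peak fraction, miRNAs-to-50/75/95%, the four Phred summaries.
  lower-better: trimming artefacts, %rRNA, total/unique ratio, top-1/5/20
  shares, contamination, length sd, skewness (ranked on |skewness| — a
  distribution skewed in either direction signals degradation; the raw
  signed value is displayed). neutral (displayed, never coloured): read
  totals, unique inserts, mean and mode length.

## Percentiles, strata, colours

* **Midrank percentile**: `100·(#{v<x} + ½·#{v=x})/n`. Ties are neither
  under- nor over-ranked; a sample identical to the whole corpus sits at 50.
* **Quartile colours** on the orientation-corrected goodness g (=percentile
  or 100−percentile): g ≥ 75 green, [50,75) yellow, [25,50) orange, <25
  red — half-open bins, boundaries going to the better colour.
* The displayed percentile is always the raw value percentile; orientation
  (and the |skewness| transform) affects only the colour.
* **Minimum stratum size 20**: quartiles from fewer than ~20 points are
  noise, so smaller strata are reported as unavailable instead of ranked.
* The corpus is a single versioned JSON file (sorted value arrays per
  attribute per stratum) — diffable, serializable, no database; a
  round-trip reproduces every percentile bit-exactly.
* Low-input is user-declared metadata: whether a library came from bodily
  fluids is a wet-lab fact that cannot be computed from reads.

## Multi-sample reports

* **PCA**: top 50 miRNAs by mean reads-per-million across samples,
  log10(x+1), column-centred (no unit-variance scaling — miRNA expression
  spans orders of magnitude and the log already compresses it), top two
  components with explained-variance fractions. Component signs are fixed
  by making the largest-magnitude loading positive, so output is
  deterministic. RPM normalisation makes coordinates invariant to
  sequencing depth.
* **Group summaries**: five-number summary per attribute per group with
  Tukey outliers (beyond 1.5·IQR).
* The JSON/TSV bundle contains every attribute × stratum cell, ranked or
  explicitly flagged unavailable; no timestamps are written, so identical
  inputs produce byte-identical reports.

## The synthetic-data generator

The generator inverts the QC artefact taxonomy into a read simulator and is
the package's test bed; its defaults define the study conditions used
throughout the tests.

* **References** (seeded): a ~20 kb genome assembled from 60 hairpins (each
  containing its mature miRNA verbatim; mature lengths 20–24 nt peaked at
  22), rRNA/tRNA/other-ncRNA/mRNA sequences embedded verbatim, random
  spacers, and a 4 kb annotation-free region for intergenic fragments.
  Contaminant genomes (2 bacterial, 1 viral) are rejection-sampled to share
  no 15-mer with the genome on either strand, which makes ground truth for
  the genome-preference rule unambiguous.
* **Samples**: each read draws a category from the recipe proportions
  (defaults: miRNA .55, rRNA .08, tRNA .03, other ncRNA .03, mRNA .04,
  genome-other .08, bacterial .02, viral .01, adapter-dimer .05,
  ultra-short .06, unmappable random .05 — a plausible mid-quality animal
  library), an insert (miRNA: Zipf-weighted mature sequence, exponent 1.0
  over 60 miRNAs so the top-1 share lands near 20%; degradation
  categories: uniform 16–28 nt fragments of their source; dimers: 0–2
  random nt; unmappable: random sequence 15-mer-disjoint from all
  references), an optional single substitution (rate 0.02), then 5′/3′
  randomized bases, the 3′ adapter, a post-adapter UMI where the protocol
  has one, random padding, truncation to 50 nt, and per-position Gaussian
  qualities (mean 36 − 0.08·position, sd 3, clipped to [2, 40], rounded).
* **Corpora**: per-sample recipes drawn from a Dirichlet prior around the
  base proportions (concentration 250) with ±20% jitter on the Zipf
  exponent; metadata assigns one synthetic species/kingdom/protocol and
  alternating group labels.
* **Determinism**: everything flows from `numpy.random.default_rng(seed)`
  (PCG64, integer state), so a fixed seed gives byte-identical FASTA/FASTQ
  on any platform.

What the generator does **not** emulate: position- or quality-correlated
sequencing errors, homopolymer artefacts, isomiRs (templated or not), UMI
collisions, multi-chromosome genomes, realistic k-mer composition, or
adapter sequence variants. Passing recovery tests therefore demonstrates
that the pipeline measures what was planted under a clean generative model
— not that it is robust to every artefact of real instruments. Sizes used
in tests (depths 400–10,000, corpora of 8–40 samples) were chosen so the
binomial error model, not runtime, limits precision.

## Numerical choices and degenerate inputs

* Phred encoding fixed at +33; scores validated into [0, 93].
* `N` bases are legal in reads and never match any reference base.
* Empty FASTQ → empty stream with a warning; malformed records raise with
  the record index; duplicate FASTA ids raise.
* Zero valid reads: yield/composition attributes become nulls, library
  quality still reports trimming fractions; an empty sample is a hard error.
* `mirnas_to_reach` uses a 1e-9 tolerance on the cumulative threshold so
  exact-percentage ties (e.g. 50.0%) count as reached.
* Percentile of an empty distribution is null with a warning, never 0.

## Known limitations

* The 1-substitution model has no indels; reads with a single indel
  relative to the reference are unmapped.
* The contaminant screen shares the annotation matcher's sensitivity
  limits; at real genome scale a dedicated aligner would be required.
* Protocol detection is content-based and cannot separate protocols that
  share an adapter (NextFlex vs Illumina).
* The percentile machinery is only as good as the corpus behind it;
  synthetic corpora exercise the mechanics, not real-world heterogeneity
  across tissues, kits and species.
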