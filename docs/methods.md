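# Methods

This note documents the models, conventions and numerical choices behind
`baculoprom`, in the order the pipeline runs them.

## Coordinate model

All coordinates are 1-based, fully closed intervals (the GenBank
convention), fixed once in `genome_io` and used unchanged everywhere.
The chromosome is treated as circular by default (taken from the LOCUS
topology): any position is normalised modulo the genome length, an
interval with `start > end` denotes an origin-spanning region whose
sequence is tail + head of the plus strand, and genome-wide motif scans
include windows that straddle the junction. Extracted regions are
already linearised, so region-level scans are linear.

Strand handling is reduced to one rule: `cds_start` is always the
genomic position of the A of the ATG on the coding strand (numerically
the larger end of the plus-strand interval for minus-strand ORFs), and
every extraction walks the coding strand with a signed step. The
invariant "a minus-strand region equals the reverse complement of the
plus-strand slice at the same interval" is property-tested.

### Anchors and distances

* 5′UTR: strictly between the last G of TAAG and the A of ATG (both
  excluded; length 0 is legal).
* Upstream window: `window` nt (default 225, configurable — the source
  analyses describe the window as approximately that size) immediately
  5′ of the T of TAAG.
* TIS flank: positions −up..+down with A of ATG = +1, no position 0
  (defaults 10/6, covering −7..+5).
* TSS flank: first A of TAAG = +1, T = −1, no position 0 (defaults
  15/15, covering −12..+12).

Distances between elements use the **gap convention**: the count of
nucleotides strictly between the 3′ end of the upstream element and the
5′ base of the downstream one. Under it the coding strand tiles exactly
as `upstream | TAAG | 5′UTR | ATG`, giving the checkable identity
`gap(octamer→ATG) − gap(octamer→TAAG) = 4 + |5′UTR|`. Because published
spacings are sometimes quoted from the 5′ end of a motif instead, the
spacing report also carries `offset_5p_to_taag`; the genome-anchored
validation accepts either reading and reports which one matches.

## Expression classes

The shipped scheme is the five-bin RPKM partition (Very High ≥ 50 000 …
Very Low < 1 000). Printed range notation for the inner bins is
typographically ambiguous; the implementation is lower-inclusive /
upper-exclusive, which is the only reading consistent with the top bin
"RPKM ≥ 50 000". Classing is a total partition of [0, ∞): tallies
conserve counts, ORFs without RPKM are listed and excluded rather than
silently dropped, and monotonicity (more RPKM never ranks lower) is
property-tested.

## Motif scanning

The scanner byte-encodes the sequence and, for each of the k query
offsets, accumulates per-position mismatch indicators — O(n·k) with
numpy inner loops, exact (no heuristics), and cross-checked in the test
suite against an independent brute-force oracle on every input up to
10 kb, including circular wrap. Conventions, each of which is a flag:

* overlapping matches all count (per-position semantics);
* both-strand scans are two independent scans — a self-complementary
  hit counts twice, there is no palindrome deduplication;
* circular genome scans include origin-spanning windows; region scans
  do not.

Degenerate IUPAC letters are accepted only at 0 mismatches, since
Hamming distance against an ambiguity code is ill-defined. Background
calibration uses the Hamming-ball cardinality: 277 words lie within
distance 2 of any 8-mer (1 + 8·3 + 28·9), so a uniform i.i.d. genome
yields 277/4⁸ ≈ 0.42% hits per position per strand; the null-genome
test requires agreement within 3 binomial standard deviations over
100 kb.

## Composition statistics

A+T content is (#A + #T)/length on {A,C,G,T}; empty UTRs are missing,
not zero. The between-class test is a two-sided Welch t-test by default:
classes are small (down to n = 5) and unbalanced with no reason to
assume equal variances; Mann–Whitney U is available where normality is
doubtful, and Holm correction is available but off by default so the
per-pair stars match the uncorrected-looking convention of the source
figures. Calibration is simulated: type-I error over 1 000 null draws
must sit within 5% ± 2%, and the planted +0.15 A+T shift in the
five-vs-rest design must reach p < 0.01.

## hr distances

The literal statistic is `5′(hr) − 5′(ORF)` with the ORF 5′ end defined
strand-aware (the start codon, not the plus-strand interval minimum).
The sign therefore encodes which side of the hr the ORF start lies on
along the plus-strand axis; a circular variant wraps to the
minimal-magnitude signed arc in (−L/2, L/2], with the boundary tie at
exactly L/2 assigned to +L/2 (this is the one point where antisymmetry
under role exchange is broken; it is documented rather than hidden).
Nearest-hr ties break toward the lexicographically lower hr id.

## Consensus

Flank windows are anchored at fixed biological reference points and
share a width, so the per-class "alignment" is an exact positional
stack: no gapped MSA is run, because anchored equal-length windows
admit no meaningful gaps, and the stack is deterministic where a
general aligner need not be. Per column, the top base is emitted when
its fraction reaches the plurality threshold (default 0.5), with ties
covered by the minimal IUPAC code rather than broken arbitrarily;
below plurality, the minimal code covering all bases at the secondary
threshold (default 0.25) is emitted, else N. Conservation flags mark
top fractions ≥ 0.5 and ≥ 0.8; these two cutoffs are configurable
because the highlighting convention they mirror is not numerically
specified anywhere. Multi-TSS ORFs contribute the TSS nearest the ATG.
The "Curated" group is Very High ∪ High minus polh and p10, the two
very-late promoters whose TSS context is known to be atypical.

## Synthetic data

The generator emulates the statistical shape of the AcMNPV case study:
149 ORFs with class quotas 5/6/17/65/56, a ~59% A+T background, eight
hr blocks, strand-alternating non-overlapping cassettes
`[240-nt upstream pad | TAAG | 5′UTR | ATG…stop]`. Defaults chosen
where the real system only constrains the shape:

* RPKM values are log-uniform strictly inside each class's bin (only
  the classing, not the distribution shape, matters downstream);
  Very High draws are capped at 4×10⁵.
* 5′UTR lengths are uniform on 20–150 nt, the range typical of late
  transcripts; base A+T is 0.60 with a +0.15 shift for Very High
  (mirroring the real contrast the composition stage must detect).
* Promoter-motif labels follow per-class probabilities (TATA/CAGT
  frequent only in the low classes, absent in High/Very High; TAAG
  labels near-universal), with the *realised* proportions recorded in
  the manifest so recovery is checked exactly, not in expectation.
* Planted octamers are written at recorded gaps upstream of the TAAG,
  and every generated upstream pad is scrubbed of accidental exact
  copies first, so the 0-mismatch per-region table equals the manifest
  with no false positives. Scrubbing is deliberately limited to
  upstream pads: chance copies elsewhere in the genome are left in
  place (editing assembled coding sequence could corrupt planted
  features) and genome-wide counts are therefore reported, not
  asserted, against the manifest.

Everything is reproducible bit-for-bit from the seed. What the
generator does **not** emulate — and what green tests therefore do not
establish about real genomes — includes overlapping and nested ORFs,
polycistronic transcripts, multiple TSSs per ORF, non-stationary base
composition, and any correlation between expression class and genome
position.

## Problem sizes

Test and acceptance runs use a 160-kb synthetic genome (149 ORFs), a
100-kb null genome, 1 000 null simulations for test calibration, and
10-kb sequences for oracle equivalence — sizes at which every check
runs in seconds while keeping estimator noise far below the asserted
margins (e.g. 3 binomial SD on ~420 expected null hits).

## Known limitations

* The genome-anchored validation needs the user to fetch the public
  AcMNPV GenBank record once (`scripts/fetch_reference.py`); the
  library itself never downloads.
* GFF3/BED input is out of scope; hr elements absent from the GenBank
  annotation are supplied via the hr table, which wins on conflict.
* Compound CDS locations are accepted only when they span the circular
  origin; trans-spliced or multi-exon joins are skipped with a warning.
* No PWM/HMM motif models and no de-novo discovery: the scanner
  answers the fixed-query questions the analysis actually asks.
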