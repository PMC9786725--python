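# baculoprom

Promoter-landscape analysis for baculovirus genomes.

Baculovirus expression vectors (BEVS) borrow their promoters from the
virus itself, and choosing a promoter means understanding the regulatory
architecture of a ~134-kb circular dsDNA genome: which ORFs are
transcribed at which level, what sits upstream of their transcription
start sites, and whether any sequence feature explains the differences.
`baculoprom` packages that analysis for computational virologists and
BEVS engineers working from an annotated GenBank record plus a
transcriptome (RPKM) table.

## What it computes

* **Expression classing.** Each ORF is binned by steady-state transcript
  abundance: Very High (RPKM ≥ 50 000), High [20 000, 50 000), Medium
  [10 000, 20 000), Low [1 000, 10 000), Very Low [0, 1 000) — all bins
  lower-inclusive. The scheme is configurable.
* **Region extraction** under explicit 1-based closed coordinates on a
  circular chromosome: the 5′UTR (strictly between the late-promoter
  TAAG motif and the ATG), a fixed 225-nt window upstream of the TAAG,
  and flanks anchored at the translation start (A of ATG = +1) and the
  transcription start (first A of TAAG = +1; no position 0).
* **Motif scanning.** Exact and Hamming-distance-tolerant search of
  regions and whole genomes (windows spanning the circular origin
  included), per-kbp background rates, per-region match histograms,
  shared-octamer tallies, and octamer spacing relative to ATG and TAAG.
  The classic candidate octamers 5′-ATTGCAAG-3′ (upstream) and
  5′-ATTAGGAA-3′ (downstream) ship as defaults.
* **5′UTR composition statistics**: per-class length and A+T content
  with pairwise Welch t-tests (Mann–Whitney optional) and the usual
  significance stars.
* **hr distances**: the signed offset from each homologous-repeat (hr)
  enhancer's 5′ end to every ORF start codon, literally
  `5′(hr) − 5′(ORF)` with an optional minimal-arc circular variant, plus
  a class-coloured circular genome map.
* **Anchored consensus**: per-class, gap-free positional stacks of TIS-
  and TSS-flank windows with IUPAC consensus and conservation flags,
  including the "Curated" group (Very High ∪ High minus the very-late
  polh and p10).
* **Synthetic data.** A generator that plants all of the above —
  class quotas, TAAG anchors, octamers at recorded offsets, hr blocks,
  an A+T shift in the top class — and records everything in a manifest,
  so every stage is testable without a download.

## Worked example

Simulate a genome with the AcMNPV-like class quotas, then scan it:

```
$ baculoprom simulate --outdir demo --seed 3 --genome-length 170000
$ baculoprom scan --genbank demo/genome.gb --query ATTGCAAG --mm 2
{
  "query": "ATTGCAAG",
  "max_mismatches": 2,
  "strands": "both",
  "total_matches": 1764,
  "per_strand": { "plus": 886, "minus": 878 },
  "rate_per_kbp": 10.376
}
```

1 764 windows lie within two mismatches of the octamer across both
strands — about 10 hits per kbp, the background level expected from the
genome's base composition (on a uniform genome the per-position,
per-strand chance is 277/4⁸ ≈ 0.42%, since 277 8-mers sit within
Hamming distance 2 of any octamer). A biologically meaningful octamer
would have to stand out against this rate, which is the package's core
negative control.

```
$ baculoprom consensus --genbank demo/genome.gb --rpkm-table demo/rpkm.tsv \
      --tss-table demo/tss.tsv --curated
Very High	TSAAKWAYAAGTYTTAAGWRAWWWWTTAWA	(n=5)
...
Curated	BBWHHAAMWWDWHHTAAGWDWDWWWKTWHW	(n=11)
```

Every class consensus shows the invariant TAAG anchor at positions
−1..+3 surrounded by A/T-rich (W) background — exactly what an anchored
stack of late-promoter windows should give when no other position is
constrained.

The full pipeline (`baculoprom all --genbank … --rpkm-table …
--tss-table … --hr-table …`) writes TSV tables, FASTA region files, the
genome map and a versioned `summary.json` into a report directory.

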