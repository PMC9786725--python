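"""Extraction of promoter-associated regions, coding-strand oriented.

Anchors and numbering:

* 5'UTR — the bases strictly between the last G of the TAAG start motif
  and the A of the ATG start codon (both excluded; length may be 0).
* upstream window — a fixed number of bases (default 225) immediately
  5' of the T of TAAG, TAAG excluded; wraps the origin on circular
  genomes.
* TIS flank — positions -up..+down with the A of ATG = +1; there is no
  position 0.
* TSS flank — positions -up..+down with the first A of TAAG = +1 (so the
  T of TAAG is -1); no position 0.

All distances elsewhere in the package use the *gap* convention: the
count of nucleotides strictly between the 3' end of one element and the
5' base of the next.  Under it the coding strand tiles exactly as
``upstream | TAAG | 5'UTR | ATG...``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from baculoprom.genome_io import GenomeRecord, OrfFeature, TssAnnotation

REGION_KINDS = ("utr5", "upstream", "tis_flank", "tss_flank", "named_promoter")

#: Published genomic coordinates (plus-strand closed intervals) of the
#: AcMNPV promoter fragments used as reference cases, NC_001623.1 axis.
NAMED_PROMOTERS = (
    ("polh", 4428, 4519, "+"),
    ("p6.9", 86_889, 87_204, "-"),
    ("ctx", 2246, 2447, "-"),
    ("orf75", 63_528, 63_912, "-"),
    ("vp39", 76_578, 77_103, "-"),
    ("39k", 30_070, 30_398, "-"),
    ("gp64", 109_718, 110_022, "-"),
    ("38k", 85_984, 86_276, "-"),
    ("dp10", 118_635, 118_808, "+"),
)


@dataclass(frozen=True)
class ExtractedRegion:
    """A strand-resolved subsequence with genomic provenance.

    ``interval`` is the plus-strand closed interval (start, end); on a
    circular genome start > end denotes an origin-spanning region.
    ``sequence`` is always coding-strand oriented.
    """

    orf_id: str
    kind: str
    sequence: str
    interval: tuple
    strand: str
    anchor: str
    short: bool = False

    def __len__(self):
        return len(self.sequence)


def _step(strand: str) -> int:
    """Plus-axis step that moves 3' (downstream) on the coding strand."""
    return 1 if strand == "+" else -1


def _extract(genome: GenomeRecord, orf_id, kind, strand, plus_start, plus_end, anchor,
             short=False) -> ExtractedRegion:
    """Build a region from a plus-strand interval, handling wrap + strand."""
    start = genome.normalize(plus_start)
    end = genome.normalize(plus_end)
    seq = genome.fetch(start, end, strand)
    return ExtractedRegion(orf_id, kind, seq, (start, end), strand, anchor, short)


def check_taag(genome: GenomeRecord, orf: OrfFeature, tss: TssAnnotation) -> bool:
    """True when the 4-mer at taag_pos on the coding strand reads TAAG."""
    step = _step(orf.strand)
    a, b = tss.taag_pos, tss.taag_pos + 3 * step
    return genome.fetch(min(a, b), max(a, b), orf.strand) == "TAAG"


def utr5_length(orf: OrfFeature, tss: TssAnnotation) -> int:
    """Gap (nt strictly between) the last G of TAAG and the A of ATG."""
    step = _step(orf.strand)
    gap = (orf.cds_start - (tss.taag_pos + 3 * step)) * step - 1
    return gap


def extract_5utr(genome: GenomeRecord, orf: OrfFeature, tss: TssAnnotation) -> ExtractedRegion:
    """The 5' untranslated region between TAAG and ATG, both excluded."""
    if tss.orf_id != orf.orf_id:
        raise ValueError(f"TSS {tss.orf_id} does not belong to ORF {orf.orf_id}")
    gap = utr5_length(orf, tss)
    if gap < 0:
        raise ValueError(
            f"{orf.orf_id}: TAAG at {tss.taag_pos} lies downstream of the ATG"
        )
    step = _step(orf.strand)
    if gap == 0:
        # empty region anchored just 5' of the ATG
        return ExtractedRegion(orf.orf_id, "utr5", "",
                               (orf.cds_start, orf.cds_start), orf.strand,
                               "between TAAG and ATG, both excluded")
    first = tss.taag_pos + 4 * step
    last = orf.cds_start - step
    plus_start, plus_end = (first, last) if orf.strand == "+" else (last, first)
    return _extract(genome, orf.orf_id, "utr5", orf.strand, plus_start, plus_end,
                    "between TAAG and ATG, both excluded")


def extract_upstream(genome: GenomeRecord, orf: OrfFeature, tss: TssAnnotation,
                     window: int = 225) -> ExtractedRegion:
    """``window`` nucleotides immediately 5' of the T of TAAG (excluded)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    step = _step(orf.strand)
    short = False
    w = window
    if not genome.is_circular:
        room = tss.taag_pos - 1 if orf.strand == "+" else genome.length_nt - tss.taag_pos
        if room < window:
            w = room
            short = True
            warnings.warn(f"{orf.orf_id}: upstream window truncated to {w} nt")
    first = tss.taag_pos - w * step   # 5'-most base
    last = tss.taag_pos - step        # base just before the T
    if orf.strand == "+":
        plus_start, plus_end = first, last
    else:
        plus_start, plus_end = last, first
    return _extract(genome, orf.orf_id, "upstream", orf.strand, plus_start, plus_end,
                    f"{w} nt 5' of the T of TAAG", short)


def extract_tis_flank(genome: GenomeRecord, orf: OrfFeature,
                      up: int = 10, down: int = 6) -> ExtractedRegion:
    """Positions -up..+down around the start codon; A of ATG = +1, no 0."""
    if up < 1 or down < 1:
        raise ValueError("up and down must be >= 1")
    step = _step(orf.strand)
    first = orf.cds_start - up * step          # position -up
    last = orf.cds_start + (down - 1) * step   # position +down
    if not genome.is_circular:
        for p in (first, last):
            if not 1 <= p <= genome.length_nt:
                raise ValueError(f"{orf.orf_id}: TIS flank exceeds linear genome")
    plus_start, plus_end = (first, last) if orf.strand == "+" else (last, first)
    return _extract(genome, orf.orf_id, "tis_flank", orf.strand, plus_start, plus_end,
                    f"TIS -{up}..+{down}, A of ATG = +1")


def extract_tss_flank(genome: GenomeRecord, orf: OrfFeature, tss: TssAnnotation,
                      up: int = 15, down: int = 15) -> ExtractedRegion:
    """Positions -up..+down around the TSS; first A of TAAG = +1, T = -1."""
    if up < 1 or down < 1:
        raise ValueError("up and down must be >= 1")
    step = _step(orf.strand)
    plus1 = tss.taag_pos + step               # the first A of TAAG
    first = plus1 - up * step                 # position -up
    last = plus1 + (down - 1) * step          # position +down
    if not genome.is_circular:
        for p in (first, last):
            if not 1 <= p <= genome.length_nt:
                raise ValueError(f"{orf.orf_id}: TSS flank exceeds linear genome")
    plus_start, plus_end = (first, last) if orf.strand == "+" else (last, first)
    return _extract(genome, orf.orf_id, "tss_flank", orf.strand, plus_start, plus_end,
                    f"TSS -{up}..+{down}, first A of TAAG = +1")


def extract_named_promoters(genome: GenomeRecord, table=NAMED_PROMOTERS):
    """Extract published promoter fragments given (name, start, end, strand)."""
    regions = []
    for name, start, end, strand in table:
        if not (1 <= start <= genome.length_nt and 1 <= end <= genome.length_nt):
            raise ValueError(f"{name}: coordinates {start}..{end} out of range")
        regions.append(
            _extract(genome, name, "named_promoter", strand, start, end,
                     "published coordinates")
        )
    return regions


def nearest_tss(orf: OrfFeature, tss_list) -> TssAnnotation | None:
    """The ORF's TAAG TSS nearest the start codon (smallest 5'UTR gap).

    Annotations whose TAAG lies downstream of the ATG are ignored.
    Returns None when the ORF has no usable TSS.
    """
    best = None
    for t in tss_list:
        if t.orf_id != orf.orf_id:
            continue
        gap = utr5_length(orf, t)
        if gap < 0:
            continue
        if best is None or gap < utr5_length(orf, best):
            best = t
    return best
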