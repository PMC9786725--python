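"""Exact and Hamming-distance-tolerant motif scanning.

The scanner is a vectorised sliding-window Hamming counter: the sequence
is encoded as a byte array and, for each query offset, per-position
mismatch indicators are summed, so a scan is O(n * k) with numpy inner
loops.  Overlapping matches are all reported, and both-strand scans are
two independent scans (a position matched on both strands counts twice;
there is no palindrome deduplication).  Genome scans on circular records
also test windows that span the origin.

Degenerate IUPAC letters are allowed in a query only for exact scans
(mismatch counting against an ambiguous letter is ill-defined).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from baculoprom.genome_io import GenomeRecord, revcomp

#: Candidate cis-regulatory octamers found upstream of strong late promoters.
UPSTREAM_OCTAMER = "ATTGCAAG"
DOWNSTREAM_OCTAMER = "ATTAGGAA"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifQuery:
    """A fixed-length DNA query with a mismatch tolerance."""

    sequence: str
    max_mismatches: int = 0
    strands: str = "both"  # plus | minus | both

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.strands not in ("plus", "minus", "both"):
            raise ValueError(f"bad strands {self.strands!r}")
        bad = set(self.sequence) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC letters in query: {sorted(bad)}")
        degenerate = set(self.sequence) - set("ACGT")
        if degenerate and self.max_mismatches > 0:
            raise ValueError("degenerate letters are only allowed at 0 mismatches")
        if not 0 <= self.max_mismatches < len(self.sequence):
            raise ValueError("max_mismatches must be in [0, len(query))")


@dataclass(frozen=True)
class MotifMatch:
    """One window within tolerance of the query.

    ``position`` is the 1-based start of the window on the plus strand;
    ``matched_text`` is the window read in query orientation (i.e. the
    reverse complement of the plus-strand window for minus-strand hits).
    """

    seq_id: str
    position: int
    strand: str
    mismatches: int
    matched_text: str


@dataclass
class ScanSummary:
    query: MotifQuery
    genome_id: str
    total_matches: int
    per_strand: tuple  # (plus, minus)
    rate_per_kbp: float
    matches: list = field(default_factory=list, repr=False)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_profile(arr: np.ndarray, query: str) -> np.ndarray:
    """Mismatch count of the window starting at each position (ACGT query)."""
    k = len(query)
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    q = _encode(query)
    mm = np.zeros(n, dtype=np.int32)
    for j in range(k):
        mm += arr[j : j + n] != q[j]
    return mm


def _iupac_hits(seq: str, query: str) -> np.ndarray:
    """Exact-match start indices (0-based) for a degenerate query."""
    arr = _encode(seq)
    k = len(query)
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j, letter in enumerate(query):
        allowed = _encode(IUPAC[letter])
        ok &= np.isin(arr[j : j + n], allowed)
    return np.nonzero(ok)[0]


def _scan_one_strand(seq: str, query: MotifQuery, seq_id: str, strand: str,
                     max_start: int | None = None) -> list:
    """Scan one strand; minus-strand hits are reported by plus-strand start."""
    q = query.sequence if strand == "+" else revcomp(query.sequence)
    degenerate = bool(set(q) - set("ACGT"))
    k = len(q)
    matches = []
    if degenerate:
        starts = _iupac_hits(seq, q)
        mms = np.zeros(starts.size, dtype=np.int32)
    else:
        mm = _mismatch_profile(_encode(seq), q)
        starts = np.nonzero(mm <= query.max_mismatches)[0]
        mms = mm[starts]
    for i, d in zip(starts.tolist(), mms.tolist()):
        if max_start is not None and i >= max_start:
            continue  # duplicate of a wrapped window
        window = seq[i : i + k]
        matches.append(
            MotifMatch(seq_id, i + 1, strand, int(d),
                       window if strand == "+" else revcomp(window))
        )
    return matches


def fuzzy_scan(sequence: str, query: MotifQuery, seq_id: str = "seq",
               circular: bool = False) -> list:
    """All windows of ``sequence`` within Hamming tolerance of the query.

    A sequence shorter than the query yields an empty list.  With
    ``circular=True`` windows spanning the end/start junction are also
    tested and reported at their (1-based) plus-strand start.
    """
    sequence = sequence.upper()
    k = len(query.sequence)
    scan_seq, max_start = sequence, None
    if circular and len(sequence) >= k:
        scan_seq = sequence + sequence[: k - 1]
        max_start = len(sequence)
    matches = []
    if query.strands in ("plus", "both"):
        matches += _scan_one_strand(scan_seq, query, seq_id, "+", max_start)
    if query.strands in ("minus", "both"):
        matches += _scan_one_strand(scan_seq, query, seq_id, "-", max_start)
    matches.sort(key=lambda m: (m.position, m.strand))
    return matches


def genome_scan(genome: GenomeRecord, query: MotifQuery,
                circular: bool | None = None) -> ScanSummary:
    """Scan a whole genome; reports counts and the per-kbp hit rate."""
    if circular is None:
        circular = genome.is_circular
    matches = fuzzy_scan(genome.sequence, query, genome.accession, circular=circular)
    plus = sum(1 for m in matches if m.strand == "+")
    minus = len(matches) - plus
    return ScanSummary(
        query=query,
        genome_id=genome.accession,
        total_matches=len(matches),
        per_strand=(plus, minus),
        rate_per_kbp=1000.0 * len(matches) / genome.length_nt,
        matches=matches,
    )


def per_region_match_table(regions, query: MotifQuery):
    """Match counts per region plus a histogram of regions by count.

    Returns ``(table, histogram, matches_by_region)`` where ``table`` is
    a DataFrame (region, n_matches), ``histogram`` maps match count ->
    fraction of regions, and ``matches_by_region`` maps region id to its
    match list (used by :func:`shared_octamers`).
    """
    rows, by_region = [], {}
    for r in regions:
        ms = fuzzy_scan(r.sequence, query, seq_id=r.orf_id, circular=False)
        rows.append({"region": r.orf_id, "n_matches": len(ms)})
        by_region[r.orf_id] = ms
    table = pd.DataFrame(rows, columns=["region", "n_matches"])
    hist: dict = {}
    if rows:
        counts = Counter(row["n_matches"] for row in rows)
        hist = {k: counts[k] / len(rows) for k in sorted(counts)}
    return table, hist, by_region


def shared_octamers(matches_by_region: dict) -> dict:
    """Matched texts present in >= 2 distinct regions, lexicographic order.

    Duplicate occurrences of a text within one region count that region
    once (set semantics).
    """
    seen: dict = {}
    for region, matches in matches_by_region.items():
        for text in {m.matched_text for m in matches}:
            seen.setdefault(text, set()).add(region)
    return {t: len(rs) for t, rs in sorted(seen.items()) if len(rs) >= 2}


def motif_presence_by_class(tss_annotations, classified_orfs,
                            motifs=("TATA", "CAGT", "TAAG")) -> pd.DataFrame:
    """Per-class proportion of ORFs carrying each promoter motif label.

    An ORF counts once per motif if *any* of its TSS annotations carries
    it.  Classes with zero ORFs get missing (NaN) proportions.
    """
    by_orf: dict = {}
    for t in tss_annotations:
        by_orf.setdefault(t.orf_id, set()).update(t.motifs)
    classes = sorted({o.expr_class for o in classified_orfs if o.expr_class})
    rows = []
    for cls in classes:
        members = [o for o in classified_orfs if o.expr_class == cls]
        row = {"class": cls, "n_orfs": len(members)}
        for motif in motifs:
            if not members:
                row[motif] = float("nan")
            else:
                row[motif] = sum(
                    1 for o in members if motif in by_orf.get(o.orf_id, set())
                ) / len(members)
        rows.append(row)
    return pd.DataFrame(rows, columns=["class", "n_orfs", *motifs])


def octamer_spacing_report(genome: GenomeRecord, orf, tss, query: MotifQuery,
                           window: int = 225) -> list:
    """Spacing of exact octamer matches in an ORF's upstream region.

    For each exact (0-mismatch, coding-strand) occurrence of the query in
    the ``window`` nt upstream of the TAAG, reports under the gap
    convention (nt strictly between):

    * ``gap_to_atg`` — octamer 3' end to the A of ATG,
    * ``gap_to_taag`` — octamer 3' end to the T of TAAG,
    * ``offset_5p_to_taag`` — octamer 5' end to the T of TAAG.

    The tiling identity ``gap_to_atg - gap_to_taag == 4 + 5'UTR length``
    holds for every upstream octamer.  Reports carry
    ``multiple=True`` when more than one exact match exists.
    """
    from baculoprom.region_extraction import extract_upstream, utr5_length

    region = extract_upstream(genome, orf, tss, window=window)
    exact = MotifQuery(query.sequence, 0, "plus")
    hits = fuzzy_scan(region.sequence, exact, seq_id=orf.orf_id, circular=False)
    utr = utr5_length(orf, tss)
    reports = []
    w = len(region.sequence)
    k = len(query.sequence)
    for m in hits:
        # coding-strand offset of the octamer inside the upstream window:
        # position 1 = 5'-most base of the window; the T of TAAG sits at w+1.
        gap_to_taag = w - (m.position + k - 1)           # 3' end -> T of TAAG
        offset_5p_to_taag = w - m.position               # 5' end -> T of TAAG
        gap_to_atg = gap_to_taag + 4 + utr               # tiling identity
        reports.append(
            {
                "orf_id": orf.orf_id,
                "octamer": query.sequence,
                "gap_to_atg": gap_to_atg,
                "gap_to_taag": gap_to_taag,
                "offset_5p_to_taag": offset_5p_to_taag,
                "utr5_length": utr,
                "multiple": len(hits) > 1,
            }
        )
    return reports


def hamming_ball_size(k: int, d: int, alphabet: int = 4) -> int:
    """Number of length-k words within Hamming distance <= d of a word."""
    return sum(comb(k, i) * (alphabet - 1) ** i for i in range(d + 1))


def additional_genome_matches(summary: ScanSummary, regions) -> int:
    """Exact genome matches falling outside the given upstream regions.

    Counts matches of the (typically 0-mismatch) genome scan whose window
    start lies outside every region's plus-strand interval — the
    "elsewhere in the genome" tally that complements the per-region
    match table.
    """
    def contains(interval, pos, L):
        s, e = interval
        if s <= e:
            return s <= pos <= e
        return pos >= s or pos <= e  # wrapped

    L = None
    outside = 0
    for m in summary.matches:
        inside = any(contains(r.interval, m.position, L) for r in regions)
        if not inside:
            outside += 1
    return outside
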