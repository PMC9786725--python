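"""Genome-anchored validation against the published AcMNPV reference.

These checks need the annotated NC_001623.1 GenBank record, which the
library never downloads itself (``scripts/fetch_reference.py`` does).
Given that record, :func:`reference_report` recomputes the quantities a
user can check against the literature:

* exact genome-wide occurrence counts of the upstream (ATTGCAAG) and
  downstream (ATTAGGAA) octamers, split into hits inside vs outside the
  vp39/p6.9 upstream promoter windows,
* 2-mismatch genome-wide totals and per-kbp rates on both strands,
* octamer spacing around vp39 and p6.9 (gaps to the ATG and to the
  nearest TAAG).
"""

from __future__ import annotations

from pathlib import Path

from baculoprom.genome_io import GenomeRecord, TssAnnotation, read_genbank
from baculoprom.motif_scan import (
    DOWNSTREAM_OCTAMER,
    UPSTREAM_OCTAMER,
    MotifQuery,
    additional_genome_matches,
    fuzzy_scan,
    genome_scan,
    octamer_spacing_report,
)
from baculoprom.region_extraction import extract_upstream

#: conventional location of the user-fetched reference record
DEFAULT_REFERENCE_PATH = Path("data") / "NC_001623.1.gb"


def find_orf(genome: GenomeRecord, *name_parts: str):
    """First ORF whose id or name contains any of the given substrings."""
    for o in genome.orfs:
        hay = f"{o.orf_id} {o.name}".lower()
        if any(p.lower() in hay for p in name_parts):
            return o
    raise KeyError(f"no ORF matching {name_parts}")


def derive_taag_tss(genome: GenomeRecord, orf, search: int = 300) -> TssAnnotation:
    """The TAAG nearest the ATG, found by scanning upstream of the CDS.

    Used when no transcriptome TSS table is available: the nearest
    coding-strand TAAG within ``search`` nt 5' of the start codon is the
    canonical late-promoter TSS.
    """
    step = 1 if orf.strand == "+" else -1
    region = extract_upstream(
        genome, orf,
        TssAnnotation(orf.orf_id, orf.cds_start),  # pseudo-anchor at ATG
        window=search,
    )
    # region is the `search` nt 5' of the ATG, coding-oriented; the TAAG
    # nearest the ATG is the rightmost match in that window
    hits = fuzzy_scan(region.sequence, MotifQuery("TAAG", 0, "plus"), circular=False)
    if not hits:
        raise ValueError(f"{orf.orf_id}: no TAAG within {search} nt of the ATG")
    last = max(h.position for h in hits)
    offset_from_atg = len(region.sequence) - last + 1  # T of TAAG, 5' of ATG
    taag_pos = orf.cds_start - offset_from_atg * step
    return TssAnnotation(orf.orf_id, taag_pos, frozenset({"TAAG"}), source="derived")


def reference_report(genbank_path=DEFAULT_REFERENCE_PATH) -> dict:
    """Recompute the genome-anchored promoter-landscape quantities."""
    genome = read_genbank(genbank_path)
    report: dict = {"accession": genome.accession, "length_nt": genome.length_nt}

    focal = {}
    for label, parts in (("vp39", ("vp39",)), ("p6.9", ("p6.9", "6.9", "p6.9k"))):
        orf = find_orf(genome, *parts)
        focal[label] = (orf, derive_taag_tss(genome, orf))
    upstream_regions = [
        extract_upstream(genome, orf, tss, window=225) for orf, tss in focal.values()
    ]

    for octamer in (UPSTREAM_OCTAMER, DOWNSTREAM_OCTAMER):
        exact = genome_scan(genome, MotifQuery(octamer, 0, "both"))
        fuzzy = genome_scan(genome, MotifQuery(octamer, 2, "both"))
        report[octamer] = {
            "exact_total": exact.total_matches,
            "exact_outside_focal_upstream": additional_genome_matches(
                exact, upstream_regions
            ),
            "mm2_total": fuzzy.total_matches,
            "mm2_per_strand": list(fuzzy.per_strand),
            "mm2_rate_per_kbp": round(fuzzy.rate_per_kbp, 2),
        }

    spacings = {}
    for label, (orf, tss) in focal.items():
        for octamer in (UPSTREAM_OCTAMER, DOWNSTREAM_OCTAMER):
            reps = octamer_spacing_report(genome, orf, tss, MotifQuery(octamer))
            spacings[f"{label}:{octamer}"] = reps
    report["spacings"] = spacings
    return report
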