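"""Shared fixtures: a hand-built toy genome with known coordinates and a
session-scoped synthetic bundle with planted structure."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from baculoprom.genome_io import GenomeRecord, OrfFeature, TssAnnotation, revcomp
from baculoprom.synthetic_data import SyntheticSpec, generate


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def naive_scan(seq: str, query: str, max_mm: int, strands: str = "both",
               circular: bool = False):
    """Independent brute-force scanner: (position, strand, mismatches)."""
    k = len(query)
    n = len(seq)
    scan = seq + (seq[: k - 1] if circular and n >= k else "")
    limit = n if circular else len(scan) - k + 1
    out = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        if strands == "plus" and strand == "-":
            continue
        if strands == "minus" and strand == "+":
            continue
        for i in range(max(limit, 0)):
            if i + k > len(scan):
                break
            d = hamming(scan[i : i + k], q)
            if d <= max_mm:
                out.append((i + 1, strand, d))
    return sorted(out)


@pytest.fixture
def toy_genome():
    """A small circular genome with one ORF per strand, built base by base.

    Returns (genome, info) where info records every planted coordinate.
    """
    info = {}
    seq = ""

    seq += "GCGCGCGCGCCGGCCGGCCG"  # 20 nt pad, motif-free

    # plus-strand ORF: TAAG, 5-nt UTR, ATG + 6 nt + stop
    info["taag_plus"] = len(seq) + 1            # T of TAAG
    seq += "TAAG"
    info["utr_plus"] = "TTCTT"
    seq += info["utr_plus"]
    info["atg_plus"] = len(seq) + 1             # A of ATG
    seq += "ATG" + "AAACCC" + "TAA"
    info["end_plus"] = len(seq)

    seq += "GGCCGGCCGGCCGGCCGGCC"  # spacer

    # minus-strand ORF: coding cassette then reverse-complemented
    cassette = "TAAG" + "ACACA" + "ATG" + "GGGTTT" + "TAA"
    start = len(seq) + 1
    seq += revcomp(cassette)
    end = len(seq)
    # coding position i (1-based) sits at plus position end - (i - 1)
    info["taag_minus"] = end                    # T of TAAG
    info["utr_minus"] = "ACACA"
    info["atg_minus"] = end - 9                 # A of ATG (cassette pos 10)
    info["end_minus"] = start
    seq += "CCGGCCGGCCGGCCGGCCGG"

    orf_p = OrfFeature("orfP", "orfP", "+", info["atg_plus"], info["end_plus"],
                       rpkm=60_000.0)
    orf_m = OrfFeature("orfM", "orfM", "-", info["atg_minus"], info["end_minus"],
                       rpkm=500.0)
    tss = [
        TssAnnotation("orfP", info["taag_plus"]),
        TssAnnotation("orfM", info["taag_minus"]),
    ]
    genome = GenomeRecord("TOY0001", seq, is_circular=True,
                          orfs=[orf_p, orf_m], hrs=[], tss=tss)
    return genome, info


@pytest.fixture(scope="session")
def bundle():
    """Synthetic genome with the reference class quotas and planted octamers."""
    spec = SyntheticSpec(
        seed=20260927,
        planted_octamers=[("ATTGCAAG", 150, 10), ("ATTAGGAA", 40, 7)],
    )
    genome, rpkm, tss, hrs, manifest = generate(spec)
    return {"spec": spec, "genome": genome, "rpkm": rpkm, "tss": tss,
            "hrs": hrs, "manifest": manifest,
            "tss_by_orf": {t.orf_id: t for t in tss}}
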