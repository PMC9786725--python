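"""Region extraction: anchors, strand handling and tiling identities."""

import pytest

from baculoprom.genome_io import (
    GenomeRecord,
    OrfFeature,
    TssAnnotation,
    revcomp,
)
from baculoprom.region_extraction import (
    NAMED_PROMOTERS,
    extract_5utr,
    extract_named_promoters,
    extract_tis_flank,
    extract_tss_flank,
    extract_upstream,
    nearest_tss,
    utr5_length,
)


def test_5utr_between_taag_and_atg(toy_genome):
    g, info = toy_genome
    for orf_id, expected in (("orfP", info["utr_plus"]), ("orfM", info["utr_minus"])):
        orf = g.orf(orf_id)
        tss = nearest_tss(orf, g.tss)
        utr = extract_5utr(g, orf, tss)
        assert utr.sequence == expected
        assert len(utr) == 5


def test_taag_atg_adjacency_gives_empty_utr():
    seq = "GCGCGCGCGC" + "TAAG" + "ATG" + "AAATAA" + "GCGCGCGCGC"
    orf = OrfFeature("o", "o", "+", 15, 23)
    g = GenomeRecord("X", seq, is_circular=True, orfs=[orf])
    tss = TssAnnotation("o", 11)
    assert extract_5utr(g, orf, tss).sequence == ""
    assert utr5_length(orf, tss) == 0


def test_taag_downstream_of_atg_is_error():
    seq = "GCGC" + "ATG" + "AAA" + "TAAG" + "GCGC"
    orf = OrfFeature("o", "o", "+", 5, 10)
    g = GenomeRecord("X", seq, is_circular=True, orfs=[orf])
    with pytest.raises(ValueError, match="downstream"):
        extract_5utr(g, orf, TssAnnotation("o", 11))


def test_upstream_window_lengths(toy_genome, bundle):
    g, info = toy_genome
    orf = g.orf("orfP")
    tss = nearest_tss(orf, g.tss)
    # window=1 is the single base immediately 5' of the T of TAAG
    r1 = extract_upstream(g, orf, tss, window=1)
    assert len(r1) == 1
    assert r1.sequence == g.sequence[info["taag_plus"] - 2]
    # default window on an interior synthetic TSS
    sg = bundle["genome"]
    o = sg.orfs[3]
    r = extract_upstream(sg, o, bundle["tss_by_orf"][o.orf_id])
    assert len(r) == 225


def test_upstream_wraps_origin_on_circular_genome():
    # TAAG near the origin: the window must wrap around position 1
    seq = "AG" + "TAAG" + "ATGAAATAA" + "CCCCCCCCGT"
    orf = OrfFeature("o", "o", "+", 7, 15)
    g = GenomeRecord("X", seq, is_circular=True, orfs=[orf])
    r = extract_upstream(g, orf, TssAnnotation("o", 3), window=4)
    assert r.sequence == "GTAG"  # last two genome bases + first two
    assert r.interval == (len(seq) - 1, 2)


def test_upstream_truncated_on_linear_genome():
    seq = "AG" + "TAAG" + "ATGAAATAA" + "CC"
    orf = OrfFeature("o", "o", "+", 7, 15)
    g = GenomeRecord("X", seq, is_circular=False, orfs=[orf])
    with pytest.warns(UserWarning, match="truncated"):
        r = extract_upstream(g, orf, TssAnnotation("o", 3), window=10)
    assert r.short and r.sequence == "AG"


def test_minus_strand_upstream_is_revcomp_of_plus_slice(toy_genome):
    g, info = toy_genome
    orf = g.orf("orfM")
    tss = nearest_tss(orf, g.tss)
    r = extract_upstream(g, orf, tss, window=6)
    s, e = r.interval
    assert r.sequence == revcomp(g.slice_plus(s, e))
    assert (s, e) == (info["taag_minus"] + 1, info["taag_minus"] + 6)


def test_tis_flank_numbering(toy_genome):
    g, info = toy_genome
    for orf_id in ("orfP", "orfM"):
        orf = g.orf(orf_id)
        fl = extract_tis_flank(g, orf, up=3, down=3)
        assert len(fl) == 6
        assert fl.sequence[3:6] == "ATG"  # +1..+3


def test_tis_flank_strand_oracle(toy_genome):
    """Minus-strand flank equals the plus computation on the revcomp genome."""
    g, info = toy_genome
    orf = g.orf("orfM")
    fl = extract_tis_flank(g, orf, up=4, down=5)
    L = g.length_nt
    flipped = GenomeRecord("F", revcomp(g.sequence), is_circular=True)
    # position p on the plus axis maps to L - p + 1 on the flipped axis
    orf_f = OrfFeature("orfM", "orfM", "+", L - orf.cds_start + 1, L - orf.cds_end + 1)
    fl_f = extract_tis_flank(flipped, orf_f, up=4, down=5)
    assert fl.sequence == fl_f.sequence


def test_tss_flank_contains_taag(toy_genome):
    g, info = toy_genome
    for orf_id in ("orfP", "orfM"):
        orf = g.orf(orf_id)
        tss = nearest_tss(orf, g.tss)
        fl = extract_tss_flank(g, orf, tss, up=2, down=3)
        # positions -2,-1,+1,+2,+3: one 5' base then T A A G
        assert len(fl) == 5
        assert fl.sequence[1:] == "TAAG"


def test_tss_flank_default_covers_discussed_positions(bundle):
    """Positions +6/+9/+10/+12 and -12..-1 exist for every TAAG TSS."""
    g = bundle["genome"]
    o = g.orfs[0]
    fl = extract_tss_flank(g, o, bundle["tss_by_orf"][o.orf_id])
    assert len(fl) == 30
    assert fl.sequence[14:18] == "TAAG"  # -1..+3 after 15 upstream positions... -15..-2


def test_named_promoter_lengths():
    # a long synthetic axis so the published coordinates are in range
    import numpy as np

    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=140_000))
    g = GenomeRecord("X", seq, is_circular=True)
    regions = {r.orf_id: r for r in extract_named_promoters(g, NAMED_PROMOTERS)}
    assert len(regions["polh"]) == 4519 - 4428 + 1 == 92
    assert len(regions["p6.9"]) == 87_204 - 86_889 + 1 == 316
    assert len(regions["dp10"]) == 118_808 - 118_635 + 1 == 174
    # minus-strand promoters come back reverse-complemented
    s, e = regions["p6.9"].interval
    assert regions["p6.9"].sequence == revcomp(g.slice_plus(s, e))


def test_named_promoter_out_of_range_errors():
    g = GenomeRecord("X", "ACGT" * 10, is_circular=True)
    with pytest.raises(ValueError, match="out of range"):
        extract_named_promoters(g, (("x", 1, 1000, "+"),))


def test_region_reslice_reproduces_sequence(bundle):
    """Re-slicing the genome at each region's interval + strand is identity."""
    g = bundle["genome"]
    for o in g.orfs[:20]:
        t = bundle["tss_by_orf"][o.orf_id]
        for r in (
            extract_upstream(g, o, t),
            extract_5utr(g, o, t),
            extract_tss_flank(g, o, t),
            extract_tis_flank(g, o),
        ):
            if not r.sequence:
                continue
            s, e = r.interval
            assert g.fetch(s, e, r.strand) == r.sequence


def test_tiling_upstream_taag_utr_atg(bundle):
    """upstream | TAAG | 5'UTR | ATG tile contiguously on the coding strand."""
    g = bundle["genome"]
    for o in g.orfs[:20]:
        t = bundle["tss_by_orf"][o.orf_id]
        up = extract_upstream(g, o, t, window=30)
        utr = extract_5utr(g, o, t)
        fl = extract_tis_flank(g, o, up=10, down=3)
        stitched = up.sequence + "TAAG" + utr.sequence + fl.sequence[-3:]
        # read the same stretch directly from the genome on the coding strand
        step = 1 if o.strand == "+" else -1
        first = t.taag_pos - 30 * step
        last = o.cds_start + 2 * step
        lo, hi = (first, last) if o.strand == "+" else (last, first)
        assert g.fetch(lo, hi, o.strand) == stitched


def test_nearest_tss_picks_smallest_gap(toy_genome):
    g, info = toy_genome
    orf = g.orf("orfP")
    far = TssAnnotation("orfP", info["taag_plus"] - 8)
    near = TssAnnotation("orfP", info["taag_plus"])
    assert nearest_tss(orf, [far, near]) == near
    assert nearest_tss(orf, []) is None
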