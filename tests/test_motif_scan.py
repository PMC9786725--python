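"""Fuzzy scanning against a brute-force oracle, Hamming combinatorics,
strand symmetry and the summary/tally operations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baculoprom.genome_io import GenomeRecord, OrfFeature, TssAnnotation, revcomp
from baculoprom.motif_scan import (
    DOWNSTREAM_OCTAMER,
    UPSTREAM_OCTAMER,
    MotifQuery,
    additional_genome_matches,
    fuzzy_scan,
    genome_scan,
    hamming_ball_size,
    motif_presence_by_class,
    octamer_spacing_report,
    per_region_match_table,
    shared_octamers,
)
from baculoprom.region_extraction import ExtractedRegion, extract_upstream

from conftest import naive_scan

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


def as_tuples(matches):
    return sorted((m.position, m.strand, m.mismatches) for m in matches)


def test_identity_match():
    ms = fuzzy_scan("ATTGCAAG", MotifQuery("ATTGCAAG", 0, "plus"))
    assert as_tuples(ms) == [(1, "+", 0)]


def test_short_sequence_empty():
    assert fuzzy_scan("ACG", MotifQuery("ATTGCAAG", 2, "both")) == []


def test_query_validation():
    with pytest.raises(ValueError):
        MotifQuery("ATTGCAAG", 8)  # tolerance must be < length
    with pytest.raises(ValueError):
        MotifQuery("TAWG", 1)  # degenerate letters only at 0 mismatches
    with pytest.raises(ValueError):
        MotifQuery("ATXG", 0)


def test_degenerate_exact_scan():
    ms = fuzzy_scan("AATTGCAATGG", MotifQuery("ATTGCAAN", 0, "plus"))
    assert as_tuples(ms) == [(2, "+", 0)]


@settings(deadline=None, max_examples=100)
@given(dna, st.integers(0, 3), st.booleans())
def test_matches_naive_oracle(seq, mm, circular):
    query = "ATTGCAAG"
    mm = min(mm, len(query) - 1)
    got = as_tuples(fuzzy_scan(seq, MotifQuery(query, mm, "both"), circular=circular))
    assert got == naive_scan(seq, query, mm, "both", circular=circular)


def test_oracle_on_seeded_10kb():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    for q in (UPSTREAM_OCTAMER, DOWNSTREAM_OCTAMER):
        got = as_tuples(fuzzy_scan(seq, MotifQuery(q, 2, "both")))
        assert got == naive_scan(seq, q, 2, "both")


@settings(deadline=None, max_examples=50)
@given(dna)
def test_monotone_in_tolerance(seq):
    """matches(d) is a subset of matches(d+1)."""
    q = "TTAGGA"
    sets = [
        {(m.position, m.strand) for m in fuzzy_scan(seq, MotifQuery(q, d, "both"))}
        for d in range(3)
    ]
    assert sets[0] <= sets[1] <= sets[2]


@settings(deadline=None, max_examples=50)
@given(dna)
def test_strand_symmetry(seq):
    """Both-strand totals are invariant under query reverse complement."""
    q = "ATTGCAAG"
    a = fuzzy_scan(seq, MotifQuery(q, 1, "both"))
    b = fuzzy_scan(seq, MotifQuery(revcomp(q), 1, "both"))
    assert len(a) == len(b)
    plus_a = sum(m.strand == "+" for m in a)
    minus_b = sum(m.strand == "-" for m in b)
    assert plus_a == minus_b


def test_hamming_ball_277_combinatorial_and_enumerated():
    assert hamming_ball_size(8, 2) == 1 + 8 * 3 + 28 * 9 == 277
    word = UPSTREAM_OCTAMER
    n = sum(
        sum(a != b for a, b in zip("".join(w), word)) <= 2
        for w in itertools.product("ACGT", repeat=8)
    )
    assert n == 277


def test_all_a_circular_genome_rotations():
    g = GenomeRecord("X", "A" * 50, is_circular=True)
    s = genome_scan(g, MotifQuery("AAAAAAAA", 0, "both"))
    assert s.per_strand == (50, 0)  # every rotation matches on the plus strand
    both = genome_scan(g, MotifQuery("AAAAAAAA", 0, "plus"))
    assert both.total_matches == 50


def test_genome_scan_rate_definition(bundle):
    g = bundle["genome"]
    s = genome_scan(g, MotifQuery(UPSTREAM_OCTAMER, 2, "both"))
    assert s.total_matches == s.per_strand[0] + s.per_strand[1]
    assert s.rate_per_kbp == pytest.approx(1000 * s.total_matches / g.length_nt)


def test_genome_scan_counts_origin_spanning_window():
    # the only exact match straddles the origin
    core = "CCCCCCGGGGGG" * 4
    seq = "CAAG" + core + "ATTG"
    g = GenomeRecord("X", seq, is_circular=True)
    s = genome_scan(g, MotifQuery("ATTGCAAG", 0, "plus"))
    assert s.total_matches == 1
    assert s.matches[0].position == len(seq) - 3
    linear = genome_scan(g, MotifQuery("ATTGCAAG", 0, "plus"), circular=False)
    assert linear.total_matches == 0


def _region(orf_id, seq):
    return ExtractedRegion(orf_id, "upstream", seq, (1, len(seq)), "+", "x")


def test_per_region_histogram():
    regions = [_region("a", "GGGG" + UPSTREAM_OCTAMER + "GGGG"),
               _region("b", "G" * 16)]
    table, hist, by_region = per_region_match_table(
        regions, MotifQuery(UPSTREAM_OCTAMER, 0, "plus")
    )
    assert dict(zip(table.region, table.n_matches)) == {"a": 1, "b": 0}
    assert hist == {0: 0.5, 1: 0.5}


def test_planted_octamers_match_manifest(bundle):
    """0-mismatch per-region counts equal the generator manifest exactly."""
    g = bundle["genome"]
    man = bundle["manifest"]
    tally = {}
    regions = [
        extract_upstream(g, o, bundle["tss_by_orf"][o.orf_id]) for o in g.orfs
    ]
    for key, planted in man["octamer_regions"].items():
        octamer = key.split("@")[0]
        table, hist, by_region = per_region_match_table(
            regions, MotifQuery(octamer, 0, "plus")
        )
        found = sorted(table[table.n_matches > 0].region)
        assert found == planted
        assert set(table.n_matches) <= {0, 1}  # no accidental extra copies


def test_shared_octamers_set_semantics():
    m = {
        "r1": [type("M", (), {"matched_text": "ATTGCAAG"})()] * 2,
        "r2": [type("M", (), {"matched_text": "ATTGCAAG"})()],
        "r3": [type("M", (), {"matched_text": "CCCCCCCC"})()],
    }
    shared = shared_octamers(m)
    assert shared == {"ATTGCAAG": 2}  # r1 counted once; singleton excluded


def test_shared_octamers_empty_when_disjoint():
    m = {"r1": [type("M", (), {"matched_text": "AAAATTTT"})()],
         "r2": [type("M", (), {"matched_text": "CCCCGGGG"})()]}
    assert shared_octamers(m) == {}


def test_motif_presence_by_class():
    orfs = [
        OrfFeature("a", "a", "+", 1, 10, expr_class="Very High"),
        OrfFeature("b", "b", "+", 21, 30, expr_class="Very High"),
        OrfFeature("c", "c", "+", 41, 50, expr_class="Very Low"),
    ]
    tss = [
        TssAnnotation("a", 1, frozenset({"TAAG"})),
        TssAnnotation("b", 21, frozenset({"TAAG"})),
        TssAnnotation("c", 41, frozenset({"TATA", "CAGT"})),
    ]
    df = motif_presence_by_class(tss, orfs).set_index("class")
    assert df.loc["Very High", "TAAG"] == 1.0
    assert df.loc["Very High", "TATA"] == 0.0
    assert df.loc["Very Low", "TATA"] == 1.0


def test_motif_presence_recovers_manifest_proportions(bundle):
    from baculoprom.expression_classes import classify_orfs

    _, classified, _ = classify_orfs(bundle["genome"].orfs)
    df = motif_presence_by_class(bundle["tss"], classified).set_index("class")
    for cls, props in bundle["manifest"]["motif_proportions"].items():
        for motif in ("TATA", "CAGT", "TAAG"):
            assert df.loc[cls, motif] == pytest.approx(props[motif])


def test_spacing_gap_convention():
    # octamer ending exactly 10 nt before the TAAG, UTR of 7 nt
    pad = "C" * 30 + UPSTREAM_OCTAMER + "C" * 10
    seq = "G" * 5 + pad + "TAAG" + "TTTTTTT" + "ATG" + "AAATAA" + "G" * 5
    atg = 5 + len(pad) + 4 + 7 + 1
    orf = OrfFeature("o", "o", "+", atg, atg + 8)
    g = GenomeRecord("X", seq, is_circular=True, orfs=[orf])
    tss = TssAnnotation("o", 5 + len(pad) + 1)
    reps = octamer_spacing_report(g, orf, tss, MotifQuery(UPSTREAM_OCTAMER),
                                  window=len(pad))
    assert len(reps) == 1
    r = reps[0]
    assert r["gap_to_taag"] == 10
    assert r["gap_to_atg"] == 10 + 4 + 7  # tiling identity
    assert r["offset_5p_to_taag"] == 10 + 7
    assert r["multiple"] is False


def test_spacing_identity_on_synthetic(bundle):
    g = bundle["genome"]
    man = bundle["manifest"]
    for key, planted in man["octamer_regions"].items():
        octamer, gap = key.split("@")[0], int(key.split("@")[1])
        for orf_id in planted:
            orf = g.orf(orf_id)
            reps = octamer_spacing_report(
                g, orf, bundle["tss_by_orf"][orf_id], MotifQuery(octamer)
            )
            assert len(reps) == 1
            r = reps[0]
            assert r["gap_to_taag"] == gap
            assert r["gap_to_atg"] - r["gap_to_taag"] == 4 + r["utr5_length"]


def test_additional_matches_outside_regions():
    seq = "T" * 20 + UPSTREAM_OCTAMER + "T" * 20 + UPSTREAM_OCTAMER + "T" * 20
    g = GenomeRecord("X", seq, is_circular=False)
    s = genome_scan(g, MotifQuery(UPSTREAM_OCTAMER, 0, "plus"))
    assert s.total_matches == 2
    region = ExtractedRegion("r", "upstream", seq[15:35], (16, 35), "+", "x")
    assert additional_genome_matches(s, [region]) == 1
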