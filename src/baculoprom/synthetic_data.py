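"""Synthetic circular genomes with planted, manifest-recorded structure.

The generator emulates the statistical shape of a baculovirus genome and
its companion transcriptome annotation: a circular A/T-rich chromosome
carrying strand-alternating non-overlapping ORF cassettes, each with a
TAAG transcription start motif at a recorded position, a 5'UTR of known
length and composition, per-class RPKM values drawn strictly inside the
class bounds, optional planted promoter motifs (TATA/CAGT) and planted
octamers at recorded offsets, and hr blocks between cassettes.  Every
planted item is recorded in a JSON-serialisable manifest, so each
pipeline stage can be checked against exact ground truth.

Layout of one cassette, coding orientation::

    [upstream pad, 240 nt][TAAG][5'UTR][ATG ... stop]

The pad is wider than the default 225-nt upstream scan window, so
upstream windows never leak into a neighbouring cassette.  Planted
octamer sequences are scrubbed from all generated upstream pads before
planting, so at 0 mismatches the per-region match table equals the
manifest exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from baculoprom.expression_classes import DEFAULT_SCHEME, assign_class
from baculoprom.genome_io import (
    GenomeRecord,
    HrRegion,
    OrfFeature,
    TssAnnotation,
    revcomp,
)

UPSTREAM_PAD = 240  # nt of background 5' of the TAAG inside each cassette

#: default per-class planting probabilities for promoter-motif labels
DEFAULT_MOTIF_RULES = {
    "Very High": {"TAAG": 1.0, "TATA": 0.0, "CAGT": 0.0},
    "High": {"TAAG": 1.0, "TATA": 0.0, "CAGT": 0.0},
    "Medium": {"TAAG": 1.0, "TATA": 0.15, "CAGT": 0.2},
    "Low": {"TAAG": 0.85, "TATA": 0.35, "CAGT": 0.4},
    "Very Low": {"TAAG": 0.55, "TATA": 0.6, "CAGT": 0.6},
}

#: RPKM sampling bounds per class (log-uniform, strictly inside class bins)
RPKM_BOUNDS = {
    "Very High": (50_000.0, 400_000.0),
    "High": (20_000.0, 50_000.0),
    "Medium": (10_000.0, 20_000.0),
    "Low": (1_000.0, 10_000.0),
    "Very Low": (1.0, 1_000.0),
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic genome; defaults mirror the AcMNPV case.

    ``class_quotas`` defaults to the 5/6/17/65/56 split of the 149
    classified AcMNPV ORFs.  The background composition approximates the
    ~41% GC AcMNPV chromosome.  ``planted_octamers`` entries are
    ``(sequence, gap_to_taag, multiplicity)``: the octamer is planted in
    ``multiplicity`` distinct ORFs with the given number of nucleotides
    strictly between its 3' end and the T of TAAG.
    """

    genome_length: int = 160_000
    class_quotas: dict = field(
        default_factory=lambda: {
            "Very High": 5, "High": 6, "Medium": 17, "Low": 65, "Very Low": 56,
        }
    )
    hr_count: int = 8
    hr_length: int = 300
    composition: tuple = (0.295, 0.205, 0.205, 0.295)  # A, C, G, T
    planted_octamers: list = field(default_factory=list)
    motif_rules: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_MOTIF_RULES.items()
    })
    utr_length_range: tuple = (20, 150)
    base_utr_at: float = 0.60
    at_shift: dict = field(default_factory=lambda: {"Very High": 0.15})
    orf_length_range: tuple = (300, 900)  # body length (nt, multiple of 3)
    seed: int = 0

    @property
    def n_orfs(self) -> int:
        return sum(self.class_quotas.values())

    def validate(self):
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        for seq, gap, mult in self.planted_octamers:
            if gap < 0 or gap + len(seq) > UPSTREAM_PAD - 10:
                raise ValueError(f"planted octamer {seq} offset {gap} does not fit")
            if mult > self.n_orfs:
                raise ValueError("multiplicity exceeds ORF count")


def _draw(rng, n, composition):
    return "".join(rng.choice(list("ACGT"), size=n, p=list(composition)))


def _scrub(seq: str, forbidden, rng, composition) -> str:
    """Remove exact occurrences of forbidden words by redrawing one base."""
    if not forbidden:
        return seq
    seq = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for word in forbidden:
            i = s.find(word)
            while i != -1:
                j = i + len(word) // 2
                alternatives = [b for b in "ACGT" if b != seq[j]]
                seq[j] = alternatives[int(rng.integers(len(alternatives)))]
                changed = True
                s = "".join(seq)
                i = s.find(word)
    return "".join(seq)


def _scrub_outside(seq: str, forbidden, keep_spans, rng) -> str:
    """Scrub forbidden words whose span is not exactly a planted span."""
    if not forbidden:
        return seq
    seq = list(seq)
    keep = set(keep_spans)
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for word in forbidden:
            start = 0
            while (i := s.find(word, start)) != -1:
                span = (i, i + len(word))
                if span in keep:
                    start = i + 1
                    continue
                # redraw a base of this occurrence outside every planted span
                editable = [
                    j for j in range(*span)
                    if not any(a <= j < b for a, b in keep)
                ]
                j = editable[len(editable) // 2]
                alternatives = [b for b in "ACGT" if b != seq[j]]
                seq[j] = alternatives[int(rng.integers(len(alternatives)))]
                changed = True
                s = "".join(seq)
                start = i + 1
    return "".join(seq)


def _biased(rng, n, at_fraction):
    """n background bases with the given A+T fraction (A/T and C/G equal)."""
    p = (at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2)
    return _draw(rng, n, p)


def generate(spec: SyntheticSpec):
    """Build the synthetic bundle.

    Returns ``(genome, rpkm, tss, hrs, manifest)``; fully reproducible
    from ``spec.seed``; raises when the cassettes cannot be packed into
    ``spec.genome_length``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scheme = DEFAULT_SCHEME

    # class label per ORF, shuffled so classes interleave around the circle
    labels = [c for c, n in spec.class_quotas.items() for _ in range(n)]
    rng.shuffle(labels)

    # which ORFs receive which planted octamer
    octamer_targets: dict = {}
    forbidden = sorted({seq for seq, _, _ in spec.planted_octamers})
    order = rng.permutation(len(labels))
    cursor = 0
    for seq, gap, mult in spec.planted_octamers:
        octamer_targets[(seq, gap)] = set(order[cursor : cursor + mult].tolist())
        cursor += mult

    chunks: list = []
    pos = 0  # 0-based running genomic offset
    orfs, tss_list, hr_list = [], [], []
    manifest_orfs = {}
    hr_every = max(1, len(labels) // max(spec.hr_count, 1))

    for idx, label in enumerate(labels):
        # hr blocks interleaved between cassettes
        if spec.hr_count and idx % hr_every == 0 and len(hr_list) < spec.hr_count:
            unit = _biased(rng, 30, 0.75)
            hr_seq = (unit * (spec.hr_length // 30 + 1))[: spec.hr_length]
            hr_list.append(HrRegion(f"hr{len(hr_list) + 1}", pos + 1, pos + len(hr_seq)))
            chunks.append(hr_seq)
            pos += len(hr_seq)

        orf_id = f"orf{idx + 1:03d}"
        strand = "+" if idx % 2 == 0 else "-"
        utr_len = int(rng.integers(spec.utr_length_range[0], spec.utr_length_range[1] + 1))
        at = min(0.95, spec.base_utr_at + spec.at_shift.get(label, 0.0))
        body_len = int(rng.integers(spec.orf_length_range[0] // 3,
                                    spec.orf_length_range[1] // 3 + 1)) * 3

        pad = _scrub(_draw(rng, UPSTREAM_PAD, spec.composition), forbidden, rng,
                     spec.composition)
        planted_here = []
        planted_spans = []
        for (oseq, gap), targets in octamer_targets.items():
            if idx in targets:
                # gap nt strictly between octamer 3' end and the T of TAAG
                start_off = UPSTREAM_PAD - gap - len(oseq)  # 0-based within pad
                pad = pad[:start_off] + oseq + pad[start_off + len(oseq):]
                planted_here.append({"sequence": oseq, "gap_to_taag": gap,
                                     "pad_offset": start_off})
                planted_spans.append((start_off, start_off + len(oseq)))
        # planting seams may recreate a scrubbed word; redraw outside the plants
        pad = _scrub_outside(pad, forbidden, planted_spans, rng)

        rules = spec.motif_rules.get(label, {"TAAG": 1.0})
        motif_labels = {m for m, prob in rules.items() if rng.random() < prob}
        # geometry always carries a TAAG anchor (extraction needs one); the
        # label set models what the transcriptome annotation reported
        utr = _biased(rng, utr_len, at)
        body = _draw(rng, body_len, spec.composition)
        cassette = pad + "TAAG" + utr + "ATG" + body + "TAA"

        start = pos + 1  # 1-based genomic start of cassette on plus strand
        end = pos + len(cassette)
        if strand == "+":
            taag_pos = start + UPSTREAM_PAD
            cds_start = taag_pos + 4 + utr_len
            cds_end = end
            chunks.append(cassette)
        else:
            taag_pos = end - UPSTREAM_PAD
            cds_start = taag_pos - 4 - utr_len
            cds_end = start
            chunks.append(revcomp(cassette))
        pos = end

        rpkm_lo, rpkm_hi = RPKM_BOUNDS[label]
        rpkm = float(10 ** rng.uniform(np.log10(rpkm_lo), np.log10(rpkm_hi)))
        if assign_class(rpkm, scheme) != label:  # numeric edge guard
            rpkm = float(np.sqrt(rpkm_lo * rpkm_hi))

        orfs.append(OrfFeature(orf_id, orf_id, strand, cds_start, cds_end, rpkm=rpkm))
        tss_list.append(
            TssAnnotation(orf_id, taag_pos, frozenset(motif_labels), source="synthetic")
        )
        manifest_orfs[orf_id] = {
            "class": label, "rpkm": rpkm, "strand": strand,
            "cds_start": cds_start, "cds_end": cds_end, "taag_pos": taag_pos,
            "utr_length": utr_len, "utr_at_target": at,
            "motif_labels": sorted(motif_labels),
            "planted_octamers": planted_here,
        }

        # inter-cassette spacer
        spacer = _scrub(_draw(rng, 60, spec.composition), forbidden, rng, spec.composition)
        chunks.append(spacer)
        pos += len(spacer)

    if pos > spec.genome_length:
        raise ValueError(
            f"cassettes need {pos} nt but genome_length is {spec.genome_length}"
        )
    tail = _scrub(_draw(rng, spec.genome_length - pos, spec.composition), forbidden,
                  rng, spec.composition)
    sequence = "".join(chunks) + tail

    genome = GenomeRecord("SYNTH0001", sequence, is_circular=True,
                          orfs=orfs, hrs=hr_list, tss=tss_list)
    rpkm_table = {o.orf_id: o.rpkm for o in orfs}

    # realized per-class motif-label proportions (ground truth for recovery)
    motif_props: dict = {}
    for label in spec.class_quotas:
        members = [m for m in manifest_orfs.values() if m["class"] == label]
        motif_props[label] = {
            motif: (sum(1 for m in members if motif in m["motif_labels"]) / len(members)
                    if members else None)
            for motif in ("TATA", "CAGT", "TAAG")
        }

    octamer_regions = {
        f"{seq}@{gap}": sorted(f"orf{int(i) + 1:03d}" for i in targets)
        for (seq, gap), targets in octamer_targets.items()
    }

    manifest = {
        "seed": spec.seed,
        "genome_length": spec.genome_length,
        "class_quotas": dict(spec.class_quotas),
        "orfs": manifest_orfs,
        "hrs": [{"hr_id": h.hr_id, "start": h.start, "end": h.end} for h in hr_list],
        "motif_proportions": motif_props,
        "octamer_regions": octamer_regions,
    }
    return genome, rpkm_table, tss_list, hr_list, manifest


def null_genome(length: int, composition=(0.25, 0.25, 0.25, 0.25), seed: int = 0,
                accession: str = "NULL0001") -> GenomeRecord:
    """A featureless i.i.d. background genome for rate calibration."""
    if length <= 0:
        raise ValueError("length must be positive")
    if abs(sum(composition) - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    rng = np.random.default_rng(seed)
    return GenomeRecord(accession, _draw(rng, length, composition), is_circular=True)


def write_bundle(genome: GenomeRecord, rpkm, tss, hrs, manifest, outdir):
    """Write the bundle in the dialects :mod:`baculoprom.genome_io` reads."""
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    from baculoprom.genome_io import write_tables

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rec = SeqRecord(Seq(genome.sequence), id=genome.accession,
                    name=genome.accession, description="synthetic genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.is_circular else "linear"
    for o in genome.orfs:
        lo, hi = sorted((o.cds_start, o.cds_end))
        loc = SimpleLocation(lo - 1, hi, strand=1 if o.strand == "+" else -1)
        rec.features.append(SeqFeature(loc, type="CDS",
                                       qualifiers={"locus_tag": [o.orf_id],
                                                   "gene": [o.name]}))
    for h in genome.hrs:
        loc = SimpleLocation(h.start - 1, h.end, strand=1)
        rec.features.append(SeqFeature(loc, type="repeat_region",
                                       qualifiers={"note": [h.hr_id]}))
    from Bio import SeqIO

    gb_path = outdir / "genome.gb"
    SeqIO.write(rec, gb_path, "genbank")
    paths = write_tables(outdir, rpkm=rpkm, tss=tss, hrs=hrs)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"genbank": gb_path, "manifest": manifest_path, **paths}
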