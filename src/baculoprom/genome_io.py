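"""Genome and table I/O and the internal data model.

Coordinate convention (used by the whole package): positions are 1-based
and intervals are fully closed, as in GenBank flat files.  On circular
genomes an interval may wrap the origin; a wrapped interval is stored as
``(start, end, wraps=True)`` with ``start > end`` and its sequence is the
concatenation of the tail and the head of the plus strand.

Strand convention: ``cds_start`` is always the genomic coordinate of the
A of the ATG on the coding strand.  For a minus-strand ORF this is the
numerically *larger* end of the plus-strand interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class OrfFeature:
    """An annotated protein-coding gene.

    ``cds_start`` is the A of the ATG on the coding strand; ``cds_end``
    the last base of the stop codon.  For minus-strand ORFs
    ``cds_start > cds_end`` on the plus-strand axis (unless the CDS wraps
    the origin).
    """

    orf_id: str
    name: str
    strand: str  # '+' or '-'
    cds_start: int
    cds_end: int
    rpkm: float | None = None
    expr_class: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cds_start == self.cds_end:
            raise ValueError(f"{self.orf_id}: cds_start == cds_end")
        if self.rpkm is not None and self.rpkm < 0:
            raise ValueError(f"{self.orf_id}: negative RPKM {self.rpkm}")


@dataclass(frozen=True)
class TssAnnotation:
    """A putative transcription start site tied to a TAAG motif.

    ``taag_pos`` is the genomic coordinate of the T of TAAG on the ORF's
    coding strand.  One ORF may carry several annotations.
    """

    orf_id: str
    taag_pos: int
    motifs: frozenset = frozenset({"TAAG"})
    source: str = ""


@dataclass(frozen=True)
class HrRegion:
    """A homologous-repeat (hr) element; start/end on the plus strand."""

    hr_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.hr_id}: bad interval {self.start}..{self.end}")


@dataclass
class GenomeRecord:
    """A circular (or linear) annotated genome."""

    accession: str
    sequence: str
    is_circular: bool = True
    orfs: list = field(default_factory=list)
    hrs: list = field(default_factory=list)
    tss: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTRYSWKMBDHVN")
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        ids = [o.orf_id for o in self.orfs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ORF ids")

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    # -- coordinate arithmetic -------------------------------------------

    def normalize(self, pos: int) -> int:
        """Map any integer onto [1, length] by circular wrapping."""
        if not self.is_circular and not (1 <= pos <= self.length_nt):
            raise ValueError(f"position {pos} outside linear genome")
        return (pos - 1) % self.length_nt + 1

    def slice_plus(self, start: int, end: int) -> str:
        """Plus-strand sequence of the closed interval [start, end].

        On a circular genome ``start > end`` denotes an origin-spanning
        interval and the returned sequence is tail + head.
        """
        L = self.length_nt
        start, end = self.normalize(start), self.normalize(end)
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.is_circular:
            raise ValueError(f"wrapped interval {start}..{end} on linear genome")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Coding-strand-oriented sequence of [start, end]."""
        s = self.slice_plus(start, end)
        return revcomp(s) if strand == "-" else s

    def interval_length(self, start: int, end: int) -> int:
        start, end = self.normalize(start), self.normalize(end)
        if start <= end:
            return end - start + 1
        return self.length_nt - start + 1 + end

    def orf(self, orf_id: str) -> OrfFeature:
        for o in self.orfs:
            if o.orf_id == orf_id or o.name == orf_id:
                return o
        raise KeyError(orf_id)


# ---------------------------------------------------------------------------
# GenBank input
# ---------------------------------------------------------------------------


def _feature_strand(feat) -> str:
    return "-" if feat.location.strand == -1 else "+"


def _looks_like_hr(feat) -> bool:
    for key in ("label", "note", "standard_name", "gene", "locus_tag"):
        for val in feat.qualifiers.get(key, []):
            if "hr" == val.lower()[:2] and (len(val) <= 4 or not val[2].isalpha()):
                return True
    return False


def read_genbank(path) -> GenomeRecord:
    """Read a GenBank flat file into a :class:`GenomeRecord`.

    One :class:`OrfFeature` is created per CDS feature.  Compound (join)
    locations are accepted only when they span the circular origin; other
    compound CDSs are skipped with a warning.  hr elements are recognised
    among repeat_region/misc_feature features whose label or note starts
    with "hr".  Topology is taken from the LOCUS line (default linear).
    """
    rec = SeqIO.read(path, "genbank")
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: GenBank record has no sequence")
    is_circular = rec.annotations.get("topology", "linear") == "circular"
    L = len(rec.seq)

    orfs, hrs = [], []
    seen_ids = set()
    n_hr = 0
    for feat in rec.features:
        if feat.type == "CDS":
            parts = feat.location.parts
            if len(parts) > 1:
                # accept origin-spanning joins only
                spans_origin = (
                    is_circular
                    and len(parts) == 2
                    and int(parts[0].end) == L
                    and int(parts[1].start) == 0
                )
                if not spans_origin:
                    q = feat.qualifiers
                    fid = (q.get("locus_tag") or q.get("gene") or ["?"])[0]
                    logger.warning("skipping compound-location CDS %s", fid)
                    continue
            start1 = int(feat.location.parts[0].start) + 1  # 1-based
            end1 = int(feat.location.parts[-1].end)
            strand = _feature_strand(feat)
            if strand == "+":
                cds_start, cds_end = start1, end1
            else:
                cds_start, cds_end = end1, start1
            q = feat.qualifiers
            orf_id = (q.get("locus_tag") or q.get("gene") or q.get("protein_id") or [f"cds{len(orfs)+1}"])[0]
            if orf_id in seen_ids:
                orf_id = f"{orf_id}.{len(orfs)+1}"
            seen_ids.add(orf_id)
            name = (q.get("gene") or q.get("product") or [orf_id])[0]
            orfs.append(OrfFeature(orf_id, name, strand, cds_start, cds_end))
        elif feat.type in ("repeat_region", "misc_feature") and _looks_like_hr(feat):
            n_hr += 1
            label = None
            for key in ("label", "standard_name", "note"):
                if key in feat.qualifiers:
                    label = feat.qualifiers[key][0].split()[0]
                    break
            hrs.append(
                HrRegion(label or f"hr{n_hr}", int(feat.location.start) + 1, int(feat.location.end))
            )

    return GenomeRecord(
        accession=rec.id, sequence=str(rec.seq), is_circular=is_circular, orfs=orfs, hrs=hrs
    )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_tsv(path, required: tuple) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        if row[list(required)].isna().any():
            raise ValueError(f"{path}: malformed row at line {i + 2}")
    return df


def read_tables(rpkm_path=None, tss_path=None, hr_path=None, known_orf_ids=None):
    """Read the RPKM, TSS and hr TSV tables.

    Returns ``(rpkm: dict orf_id -> float, tss: list[TssAnnotation],
    hrs: list[HrRegion])``.  Any path may be None (empty result for that
    slot).  orf_ids not in ``known_orf_ids`` (when given) are reported
    via warnings, never silently dropped.
    """
    rpkm: dict = {}
    tss: list = []
    hrs: list = []
    unknown = set()

    if rpkm_path is not None:
        df = _read_tsv(rpkm_path, ("orf_id", "rpkm"))
        for i, row in df.iterrows():
            try:
                val = float(row["rpkm"])
            except ValueError as exc:
                raise ValueError(f"{rpkm_path}: bad rpkm at line {i + 2}: {row['rpkm']!r}") from exc
            rpkm[row["orf_id"]] = val
            if known_orf_ids is not None and row["orf_id"] not in known_orf_ids:
                unknown.add(row["orf_id"])

    if tss_path is not None:
        df = _read_tsv(tss_path, ("orf_id", "taag_pos"))
        seen = set()
        for i, row in df.iterrows():
            key = (row["orf_id"], int(row["taag_pos"]))
            if key in seen:
                warnings.warn(f"duplicate TSS {key} dropped")
                continue
            seen.add(key)
            raw_motifs = row.get("motifs")
            raw_source = row.get("source")
            motifs = frozenset(
                m
                for m in (str(raw_motifs).split(",") if pd.notna(raw_motifs) else [])
                if m
            )
            tss.append(
                TssAnnotation(
                    orf_id=row["orf_id"],
                    taag_pos=int(row["taag_pos"]),
                    motifs=motifs,
                    source=str(raw_source) if pd.notna(raw_source) else "",
                )
            )
            if known_orf_ids is not None and row["orf_id"] not in known_orf_ids:
                unknown.add(row["orf_id"])

    if hr_path is not None:
        df = _read_tsv(hr_path, ("hr_id", "start", "end"))
        for _, row in df.iterrows():
            hrs.append(HrRegion(row["hr_id"], int(row["start"]), int(row["end"])))

    if unknown:
        warnings.warn(f"orf_ids not present in the genome annotation: {sorted(unknown)}")
    return rpkm, tss, hrs


def write_tables(outdir, rpkm=None, tss=None, hrs=None):
    """Write RPKM/TSS/hr tables in the dialect :func:`read_tables` reads."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if rpkm is not None:
        p = outdir / "rpkm.tsv"
        pd.DataFrame(
            {"orf_id": list(rpkm), "rpkm": [rpkm[k] for k in rpkm]}
        ).to_csv(p, sep="\t", index=False)
        paths["rpkm"] = p
    if tss is not None:
        p = outdir / "tss.tsv"
        pd.DataFrame(
            {
                "orf_id": [t.orf_id for t in tss],
                "taag_pos": [t.taag_pos for t in tss],
                "motifs": [",".join(sorted(t.motifs)) for t in tss],
                "source": [t.source for t in tss],
            }
        ).to_csv(p, sep="\t", index=False)
        paths["tss"] = p
    if hrs is not None:
        p = outdir / "hr.tsv"
        pd.DataFrame(
            {
                "hr_id": [h.hr_id for h in hrs],
                "start": [h.start for h in hrs],
                "end": [h.end for h in hrs],
            }
        ).to_csv(p, sep="\t", index=False)
        paths["hr"] = p
    return paths


# ---------------------------------------------------------------------------
# FASTA output for extracted regions
# ---------------------------------------------------------------------------


def write_regions_fasta(regions, path):
    """Write extracted regions to FASTA.

    Headers encode ``orf_id|kind|start-end|strand``; sequences are
    coding-strand oriented.  Duplicate headers are suffixed with a
    running index (warned).
    """
    if not regions:
        raise ValueError("no regions to write")
    records = []
    seen: dict = {}
    for r in regions:
        start, end = r.interval
        header = f"{r.orf_id}|{r.kind}|{start}-{end}|{r.strand}"
        if header in seen:
            seen[header] += 1
            warnings.warn(f"duplicate FASTA header {header}, suffixing")
            header = f"{header}|{seen[header]}"
        else:
            seen[header] = 0
        records.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(records, path, "fasta")
    return path


def read_regions_fasta(path):
    """Round-trip reader for :func:`write_regions_fasta` output."""
    from baculoprom.region_extraction import ExtractedRegion

    regions = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        orf_id, kind, interval, strand = parts[:4]
        start, end = (int(x) for x in interval.split("-"))
        regions.append(
            ExtractedRegion(
                orf_id=orf_id,
                kind=kind,
                sequence=str(rec.seq),
                interval=(start, end),
                strand=strand,
                anchor="fasta",
            )
        )
    return regions
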