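"""Distances between hr enhancer elements and ORF start codons.

The literal distance is ``5'(hr) - 5'(ORF)`` on the plus-strand axis,
where the ORF 5' end is its strand-aware start codon position
(``cds_start``) and the hr 5' end is its plus-strand start.  Because the
chromosome is circular a wrapped variant is available that reports the
minimal-magnitude signed arc distance, constrained to
(-L/2, L/2] for genome length L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from baculoprom.genome_io import GenomeRecord, HrRegion, OrfFeature

#: deterministic colour per transcript-abundance class (map rendering)
CLASS_COLORS = {
    "Very High": "#b2182b",
    "High": "#ef8a62",
    "Medium": "#fddbc7",
    "Low": "#67a9cf",
    "Very Low": "#2166ac",
}
UNCLASSIFIED_COLOR = "#999999"


@dataclass(frozen=True)
class HrDistanceRecord:
    orf_id: str
    hr_id: str
    distance: int
    orientation: str  # orf_before_hr | orf_after_hr | coincident
    expr_class: str | None = None


def wrap_signed(d: int, length: int) -> int:
    """Map a signed offset to the minimal-magnitude arc in (-L/2, L/2]."""
    d = d % length
    if d > length / 2:
        d -= length
    return d


def hr_orf_distance(hr: HrRegion, orf: OrfFeature, genome: GenomeRecord,
                    circular: bool = False) -> HrDistanceRecord:
    """Signed distance between the hr 5' end and the ORF start codon.

    ``circular=False`` applies the literal subtraction; ``circular=True``
    wraps to the shorter arc.  Positive values place the ORF 5' end
    counterclockwise of (before) the hr on the plus-strand axis.
    """
    d = hr.start - orf.cds_start
    if circular:
        d = wrap_signed(d, genome.length_nt)
    if d == 0:
        orientation = "coincident"
    else:
        orientation = "orf_before_hr" if d > 0 else "orf_after_hr"
    return HrDistanceRecord(orf.orf_id, hr.hr_id, d, orientation, orf.expr_class)


def distance_table(genome: GenomeRecord, orfs=None, circular: bool = False):
    """All hr x ORF distances plus the nearest hr per ORF.

    Nearest-hr ties (equal |distance|) break toward the lower hr_id.
    Returns ``(table, nearest)`` DataFrames; empty with a warning when
    the genome carries no hr elements.
    """
    if orfs is None:
        orfs = genome.orfs
    if not genome.hrs:
        warnings.warn("genome has no hr regions; empty distance table")
        cols = ["orf_id", "hr_id", "distance", "orientation", "class"]
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=cols)
    rows = []
    for orf in orfs:
        for hr in genome.hrs:
            rec = hr_orf_distance(hr, orf, genome, circular=circular)
            rows.append(
                {"orf_id": rec.orf_id, "hr_id": rec.hr_id, "distance": rec.distance,
                 "orientation": rec.orientation, "class": rec.expr_class}
            )
    table = pd.DataFrame(rows)
    nearest = (
        table.assign(absd=table["distance"].abs())
        .sort_values(["orf_id", "absd", "hr_id"], kind="mergesort")
        .groupby("orf_id", as_index=False)
        .first()
        .drop(columns="absd")
    )
    return table, nearest


def class_genome_map(genome: GenomeRecord, classified_orfs, path=None, title=None):
    """Circular ideogram of ORFs coloured by transcript-abundance class.

    One track per strand; hr elements drawn as black blocks on an outer
    ring.  Unclassified ORFs render grey.  Returns the matplotlib figure
    (saved to ``path`` when given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    L = genome.length_nt
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # clockwise, position 1 at the top

    def theta(pos):
        return 2 * np.pi * ((pos - 1) % L) / L

    track = {"+": (0.80, 0.08), "-": (0.68, 0.08)}
    for orf in classified_orfs:
        lo, hi = sorted((orf.cds_start, orf.cds_end))
        t0, t1 = theta(lo), theta(hi)
        if t1 < t0:
            t1 += 2 * np.pi
        r, h = track[orf.strand]
        color = CLASS_COLORS.get(orf.expr_class, UNCLASSIFIED_COLOR)
        ax.bar(x=(t0 + t1) / 2, height=h, width=max(t1 - t0, 0.004), bottom=r,
               color=color, edgecolor="none", align="center")
    for hr in genome.hrs:
        t0, t1 = theta(hr.start), theta(hr.end)
        if t1 < t0:
            t1 += 2 * np.pi
        ax.bar(x=(t0 + t1) / 2, height=0.05, width=max(t1 - t0, 0.01), bottom=0.92,
               color="black", align="center")
    ax.set_ylim(0, 1)
    ax.set_xticks([])
    ax.set_yticks([])
    handles = [plt.Rectangle((0, 0), 1, 1, color=c) for c in CLASS_COLORS.values()]
    ax.legend(handles, list(CLASS_COLORS), loc="center", fontsize=8, frameon=False)
    ax.set_title(title or f"{genome.accession} ({L:,} bp)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
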