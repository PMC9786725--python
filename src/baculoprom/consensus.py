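"""Anchored per-class consensus of TIS- and TSS-flank windows.

Because every window is anchored at its biological reference point (the
A of ATG or the first A of TAAG) and has a fixed width, the "alignment"
is an exact positional stack — no gapped MSA is needed and the result is
deterministic.  Consensus calling per column: if the top base fraction
reaches the plurality threshold (default 0.5) that base is emitted
(ties covered by the minimal IUPAC code, never broken arbitrarily);
otherwise the minimal IUPAC code covering all bases at or above the
secondary threshold (default 0.25), or N.  Conservation flags:
``conserved`` at top fraction >= 0.5, ``highly_conserved`` at >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"

# minimal IUPAC code for each non-empty base subset
CODE_FOR_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class ConsensusResult:
    label: str
    anchor_kind: str  # 'tis' | 'tss'
    positions: list  # -up..-1, +1..+down numbering (no 0)
    column_frequencies: list  # per position: dict base -> fraction
    consensus: str
    conserved_flags: list  # per position: none | conserved | highly_conserved
    n_rows: int


def flank_positions(up: int, down: int) -> list:
    """-up..-1 then +1..+down (no position 0)."""
    return list(range(-up, 0)) + list(range(1, down + 1))


def stack_regions(regions, anchor_kind: str = "tis") -> np.ndarray:
    """Stack equal-width anchored windows into a rows x positions matrix.

    All regions must share kind and width; offenders are named.
    """
    if not regions:
        raise ValueError("no regions to stack")
    kinds = {r.kind for r in regions}
    if len(kinds) > 1:
        raise ValueError(f"mixed region kinds: {sorted(kinds)}")
    width = len(regions[0].sequence)
    bad = [r.orf_id for r in regions if len(r.sequence) != width]
    if bad:
        raise ValueError(f"width mismatch for regions: {bad}")
    return np.array([list(r.sequence) for r in regions], dtype="U1")


def consensus_string(matrix: np.ndarray, plurality_threshold: float = 0.5,
                     secondary_threshold: float = 0.25, degenerate: bool = True,
                     conserved_at: float = 0.5, highly_conserved_at: float = 0.8,
                     label: str = "", anchor_kind: str = "tis",
                     positions=None) -> ConsensusResult:
    """IUPAC consensus with per-column frequencies and conservation flags."""
    if matrix.size == 0 or matrix.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 rows")
    n_rows, width = matrix.shape
    if positions is None:
        positions = list(range(1, width + 1))
    freqs, cons, flags = [], [], []
    for j in range(width):
        col = matrix[:, j]
        f = {b: float(np.mean(col == b)) for b in BASES}
        freqs.append(f)
        top = max(f.values())
        top_bases = frozenset(b for b in BASES if f[b] == top)
        if top >= plurality_threshold:
            code = CODE_FOR_SET[top_bases]  # ties -> minimal covering code
        elif degenerate:
            qual = frozenset(b for b in BASES if f[b] >= secondary_threshold)
            code = CODE_FOR_SET[qual] if qual else "N"
        else:
            code = "N"
        cons.append(code)
        if top >= highly_conserved_at:
            flags.append("highly_conserved")
        elif top >= conserved_at:
            flags.append("conserved")
        else:
            flags.append("none")
    return ConsensusResult(label, anchor_kind, list(positions), freqs,
                           "".join(cons), flags, n_rows)


def curated_class(classified_orfs, exclusions=("polh", "p10"),
                  top_labels=("Very High", "High")) -> list:
    """The most abundantly transcribed ORFs minus named exclusions.

    Very High + High membership with the named ORFs (matched on orf_id
    or name) removed; the classical use excludes the two very-late
    hyperexpressed genes, whose promoters behave atypically.
    """
    pool = [o for o in classified_orfs if o.expr_class in top_labels]
    known = {o.orf_id for o in pool} | {o.name for o in pool}
    unknown = [e for e in exclusions if e not in known]
    if unknown:
        import warnings

        warnings.warn(f"exclusions not found among {'/'.join(top_labels)} ORFs: {unknown}")
    kept = [o for o in pool if o.orf_id not in exclusions and o.name not in exclusions]
    if not kept:
        raise ValueError("curated class is empty after exclusions")
    return kept
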