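"""Transcript-abundance classing of ORFs from RPKM values.

The shipped default scheme is the five-class scheme used for AcMNPV:
Very High (RPKM >= 50,000), High [20,000, 50,000), Medium
[10,000, 20,000), Low [1,000, 10,000), Very Low [0, 1,000).  All bounds
are lower-inclusive, upper-exclusive.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ExpressionClassScheme:
    """An ordered, contiguous partition of [0, inf) into labelled RPKM bins.

    ``bins`` is ordered from the most to the least abundant class; each
    entry is (label, lower_bound inclusive, upper_bound exclusive or inf).
    """

    bins: tuple

    def __post_init__(self):
        labels = [b[0] for b in self.bins]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate class labels")
        # descending, contiguous, covering [0, inf)
        if not math.isinf(self.bins[0][2]):
            raise ValueError("top class must be unbounded above")
        for _, lo, hi in self.bins:
            if not lo < hi:
                raise ValueError("empty bin")
        for above, below in zip(self.bins, self.bins[1:]):
            if below[2] != above[1]:
                raise ValueError("bins not contiguous")
        if self.bins[-1][1] != 0:
            raise ValueError("bottom class must start at 0")

    @property
    def labels(self) -> tuple:
        return tuple(b[0] for b in self.bins)

    def rank(self, label: str) -> int:
        """0 for the most abundant class, increasing downwards."""
        return self.labels.index(label)


DEFAULT_SCHEME = ExpressionClassScheme(
    bins=(
        ("Very High", 50_000.0, math.inf),
        ("High", 20_000.0, 50_000.0),
        ("Medium", 10_000.0, 20_000.0),
        ("Low", 1_000.0, 10_000.0),
        ("Very Low", 0.0, 1_000.0),
    )
)


def assign_class(rpkm: float, scheme: ExpressionClassScheme = DEFAULT_SCHEME) -> str:
    """Return the unique class label whose RPKM bin contains ``rpkm``."""
    if rpkm < 0:
        raise ValueError(f"negative RPKM {rpkm}")
    for label, lo, hi in scheme.bins:
        if lo <= rpkm < hi:
            return label
    raise AssertionError("scheme does not cover value")  # pragma: no cover


def classify_orfs(orfs, scheme: ExpressionClassScheme = DEFAULT_SCHEME):
    """Assign every ORF with an RPKM value to exactly one class.

    Returns ``(tally, classified, excluded)``: a Counter of class label
    -> ORF count, the annotated ORFs, and the list of ORFs excluded for
    missing RPKM (warned, listed, never silently dropped).
    """
    tally: Counter = Counter({label: 0 for label in scheme.labels})
    classified, excluded = [], []
    for orf in orfs:
        if orf.rpkm is None:
            excluded.append(orf)
            continue
        label = assign_class(orf.rpkm, scheme)
        classified.append(replace(orf, expr_class=label))
        tally[label] += 1
    if excluded:
        warnings.warn(
            f"{len(excluded)} ORFs lack RPKM and were not classified: "
            f"{[o.orf_id for o in excluded]}"
        )
    return tally, classified, excluded
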