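"""Per-class 5'UTR length and A+T-content statistics.

The pairwise comparison defaults to a two-sided Welch t-test (unequal
variances; the classes are small and unbalanced).  A Mann-Whitney U
alternative is available via ``method``.  Significance stars follow the
usual convention: ``*`` for p < 0.05, ``**`` for p < 0.01.  Holm
correction is off by default and available via ``correct``.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def at_content(sequence: str) -> float:
    """Fraction of A+T in a non-empty A/C/G/T sequence.

    Empty input returns NaN (missing); degenerate letters are an error.
    """
    if not sequence:
        return float("nan")
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"degenerate letters not allowed: {sorted(bad)}")
    return (sequence.count("A") + sequence.count("T")) / len(sequence)


def gc_content(sequence: str) -> float:
    if not sequence:
        return float("nan")
    return 1.0 - at_content(sequence)


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def class_composition_table(genome, classified_orfs, tss_list) -> pd.DataFrame:
    """Per-ORF 5'UTR length and A+T content (nearest-TSS rule).

    ORFs without a usable TAAG TSS are omitted.  Zero-length UTRs get a
    missing A+T value.
    """
    from baculoprom.region_extraction import extract_5utr, nearest_tss

    rows = []
    for orf in classified_orfs:
        tss = nearest_tss(orf, tss_list)
        if tss is None:
            continue
        utr = extract_5utr(genome, orf, tss)
        rows.append(
            {
                "orf_id": orf.orf_id,
                "class": orf.expr_class,
                "utr_length": len(utr),
                "at_content": at_content(utr.sequence) if len(utr) else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["orf_id", "class", "utr_length", "at_content"])


def compare_classes(values: dict, method: str = "welch", pairs: str = "all",
                    correct: bool = False) -> pd.DataFrame:
    """Pairwise two-sided tests between classes.

    ``values`` maps class label -> list of reals.  ``pairs`` is ``all``
    or ``vs`` (compare each class against the first label only, e.g.
    Very High vs the rest).  Classes with fewer than 2 finite values are
    excluded with a warning.
    """
    clean = {}
    for label, vals in values.items():
        finite = [v for v in vals if np.isfinite(v)]
        if len(finite) < 2:
            warnings.warn(f"class {label!r} has <2 values; excluded from tests")
            continue
        clean[label] = np.asarray(finite, dtype=float)
    labels = list(clean)
    if len(labels) < 2:
        raise ValueError("need at least two classes with >=2 values each")

    if pairs == "all":
        combos = list(itertools.combinations(labels, 2))
    elif pairs == "vs":
        ref = labels[0]
        combos = [(ref, other) for other in labels[1:]]
    else:
        raise ValueError(f"bad pairs mode {pairs!r}")

    rows = []
    for a, b in combos:
        xa, xb = clean[a], clean[b]
        if method == "welch":
            res = stats.ttest_ind(xa, xb, equal_var=False)
        elif method == "mannwhitney":
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {"class_a": a, "class_b": b, "n_a": xa.size, "n_b": xb.size,
             "statistic": float(res.statistic), "pvalue": float(res.pvalue)}
        )
    df = pd.DataFrame(rows)
    if correct:
        # Holm step-down on the family of pairwise p-values
        order = np.argsort(df["pvalue"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["pvalue"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["pvalue"] = adj
    df["stars"] = [stars(p) for p in df["pvalue"]]
    return df
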