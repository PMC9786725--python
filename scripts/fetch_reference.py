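"""Fetch the annotated AcMNPV reference genome (NC_001623.1) from NCBI.

The library itself never touches the network; this helper downloads the
GenBank record once, to ``data/NC_001623.1.gb``, for the genome-anchored
validation tests and ``baculoprom.validation.reference_report``.

Usage:  python scripts/fetch_reference.py [--out data/NC_001623.1.gb]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id=NC_001623.1&rettype=gbwithparts&retmode=text"
)


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="data/NC_001623.1.gb", type=Path)
    args = ap.parse_args(argv)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    print(f"fetching NC_001623.1 -> {args.out}", file=sys.stderr)
    with urllib.request.urlopen(EFETCH, timeout=120) as resp:
        data = resp.read()
    if b"LOCUS" not in data[:200]:
        print("unexpected response from NCBI efetch", file=sys.stderr)
        return 1
    args.out.write_bytes(data)
    print(f"wrote {len(data):,} bytes", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
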