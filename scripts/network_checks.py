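#!/usr/bin/env python
"""Optional, network-dependent sanity checks against GenBank accessions.

NOT part of the default test suite: it downloads sequence data and is only
meaningful on a machine with internet access.  Checks:

  1. accession GQ214225.1 (the z1B BAC contig) is at least 260 kb long;
  2. the B73 (GQ214225.1-matching region of the B73 reference) vs BSSS53
     z1B overlap reaches >= 97% identity over conserved blocks.

Usage:
    python scripts/network_checks.py
"""

from __future__ import annotations

import sys
import urllib.request

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


def fetch(acc: str) -> str:
    with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=120) as resp:
        text = resp.read().decode()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


def main() -> int:
    seq_z1b = fetch("GQ214225.1")
    print(f"GQ214225.1 length: {len(seq_z1b):,} bp")
    ok_len = len(seq_z1b) >= 260_000
    print("length >= 260 kb:", "PASS" if ok_len else "FAIL")

    # identity of the two z1B haplotype sequences over conserved blocks
    from zeinhap.locus_annotation import conserved_coverage

    seq_other = fetch("GQ214224.1")
    pct = conserved_coverage(seq_other, seq_z1b, min_identity=0.97, min_block=1000)
    print(f"conserved (>=97% identity blocks) coverage: {pct:.1f}%")
    return 0 if ok_len else 1


if __name__ == "__main__":
    sys.exit(main())
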