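#!/usr/bin/env python
"""Verify the deposited draft assembly's headline statistics.

Downloads the AMYG01000000 contig set from NCBI (network access required;
the 2.5 Mb FASTA is cached under scratch/, which is not part of the
deliverable) and recomputes total length and G+C content.  Expected:
2,573,514 bp and 34.35% G+C.
"""

import sys
import urllib.request
from pathlib import Path

from thermoclades.io import read_fasta
from thermoclades.types import genome_statistics

CACHE = Path(__file__).resolve().parent.parent / "scratch" / "AMYG01.fasta"
URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id=AMYG01000000&rettype=fasta&retmode=text"
)


def main():
    if not CACHE.exists():
        CACHE.parent.mkdir(parents=True, exist_ok=True)
        print(f"fetching {URL}")
        try:
            urllib.request.urlretrieve(URL, CACHE)
        except OSError as exc:
            print(f"download failed ({exc}); this step needs network access",
                  file=sys.stderr)
            return 1
    stats = genome_statistics(read_fasta(CACHE))
    print(f"{stats.n_contigs} contigs, {stats.total_length} bp, "
          f"G+C {stats.gc_percent:.2f}%")
    ok = stats.total_length == 2_573_514 and round(stats.gc_percent, 2) == 34.35
    print("matches deposited statistics" if ok else "MISMATCH vs deposited statistics")
    return 0 if ok else 1


if __name__ == "__main__":
    raise SystemExit(main())
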