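#!/usr/bin/env python
"""Optional validation against the real mouse Dbx1/Dbx2 records.

Downloads the two NCBI protein records (Dbx1 NP_001005232.1, Dbx2
NP_997416.2) via EUtils and reports their global percent identity under the
package defaults (BLOSUM62, gap open 10, gap extend 0.5, mutually-ungapped
denominator). Requires network access; nothing in the test suite or the
acceptance script depends on it.

Usage:
    python scripts/fetch_real_dbx.py [--out pair.fa]
"""

from __future__ import annotations

import argparse
import tempfile
import urllib.request
from pathlib import Path

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=protein&id=NP_001005232.1,NP_997416.2"
          "&rettype=fasta&retmode=text")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=None,
                        help="where to keep the downloaded FASTA")
    args = parser.parse_args()

    with urllib.request.urlopen(EFETCH, timeout=60) as response:
        fasta = response.read().decode()
    out = args.out or Path(tempfile.mkstemp(suffix=".fa")[1])
    out.write_text(fasta)
    print(f"downloaded records to {out}")

    from acidtrace.pairwise import global_align
    from acidtrace.seqio import read_fasta

    a, b = read_fasta(out)
    for denominator in ("ungapped", "shorter"):
        res = global_align(a, b, denominator=denominator)
        print(f"{a.id} vs {b.id} [{denominator}]: "
              f"identity {res.identity_pct:.1f}% "
              f"({res.n_identical}/{res.n_scored_cols}), score {res.score}")


if __name__ == "__main__":
    main()
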