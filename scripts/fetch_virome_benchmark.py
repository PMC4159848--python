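#!/usr/bin/env python
"""One-time download of the human-virome benchmark contigs (needs network).

Fetches the 29 public GenBank contigs JQ680349.1-JQ680377.1 from NCBI
E-utilities into ``data/virome/contigs.fasta``. After this, the virome
benchmark test in tests/test_acceptance.py runs; without the file it fails
with a pointer to this script.

Usage: python scripts/fetch_virome_benchmark.py [--out data/virome]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = [f"JQ680{n}.1" for n in range(349, 378)]


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        text = resp.read().decode()
    if not text.startswith(">"):
        raise RuntimeError(f"unexpected response for {accession}")
    return text


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data/virome"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    out_path = args.out / "contigs.fasta"
    entries = []
    for acc in ACCESSIONS:
        print(f"fetching {acc} ...")
        text = fetch(acc)
        # normalize the header to the bare accession used by the tests
        lines = text.strip().splitlines()
        lines[0] = f">{acc}"
        entries.append("\n".join(lines))
        time.sleep(0.4)  # E-utilities rate courtesy
    out_path.write_text("\n".join(entries) + "\n")
    print(f"wrote {len(entries)} contigs to {out_path}")


if __name__ == "__main__":
    main()
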