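"""Fetch 16S reference sequences from NCBI for an accession list (user-run).

The vregions library itself never performs network access; this helper is
for users who want to rebuild a real reference panel, e.g. the 18 rhizobial
genus type species. It downloads plain FASTA via NCBI E-utilities.

Usage:
    python scripts/fetch_references.py --accessions accessions.txt \
        --email you@example.org --out refs.fasta

The accession file holds one accession per line, optionally followed by a
``start..stop`` range (recommended: the annotated 16S rRNA locus of a genome
accession — delineating a multi-megabase genome by alignment is not
practical). Lines starting with '#' are ignored.
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str, email: str, start: int | None, stop: int | None) -> str:
    params = {
        "db": "nuccore",
        "id": accession,
        "rettype": "fasta",
        "retmode": "text",
        "email": email,
        "tool": "vregions",
    }
    if start is not None:
        params["seq_start"], params["seq_stop"] = start, stop
    with urllib.request.urlopen(f"{EFETCH}?{urllib.parse.urlencode(params)}") as fh:
        return fh.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--accessions", required=True)
    parser.add_argument("--email", required=True, help="identifies you to NCBI")
    parser.add_argument("--out", required=True)
    args = parser.parse_args()

    entries = []
    for line in open(args.accessions):
        line = line.split("#")[0].strip()
        if not line:
            continue
        fields = line.split()
        acc = fields[0]
        start = stop = None
        if len(fields) > 1 and ".." in fields[1]:
            start, stop = (int(x) for x in fields[1].split(".."))
        entries.append((acc, start, stop))

    with open(args.out, "w") as out:
        for acc, start, stop in entries:
            sys.stderr.write(f"fetching {acc}\n")
            out.write(fetch(acc, args.email, start, stop))
            time.sleep(0.4)  # NCBI rate courtesy


if __name__ == "__main__":
    main()
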