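#!/usr/bin/env python
"""Optional network helper: fetch reference sequences from NCBI E-utilities.

This script is deliberately outside the package core: the pipeline never
needs the network.  It exists for the two external worked examples -- the
toxin/antitoxin protein lengths and the genome-wide CDS motif count -- which
can only be checked against live NCBI records.

Usage:
    python scripts/fetch_ncbi.py protein WP_012302900.1 > mazf.fasta
    python scripts/fetch_ncbi.py cds NC_010424.1 > cds.fasta
"""

from __future__ import annotations

import sys
import urllib.parse
import urllib.request

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def _efetch(db: str, accession: str, rettype: str, timeout: float) -> str:
    params = urllib.parse.urlencode(
        {"db": db, "id": accession, "rettype": rettype, "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{params}", timeout=timeout) as resp:
        return resp.read().decode()


def fetch_protein_fasta(accession: str, timeout: float = 10.0) -> str:
    """Fetch a protein record as FASTA text."""
    return _efetch("protein", accession, "fasta", timeout)


def fetch_cds_fasta(accession: str, timeout: float = 60.0) -> str:
    """Fetch every annotated CDS of a nucleotide record as FASTA text."""
    return _efetch("nuccore", accession, "fasta_cds_na", timeout)


def main(argv: list[str]) -> int:
    if len(argv) != 3 or argv[1] not in ("protein", "cds"):
        print(__doc__, file=sys.stderr)
        return 2
    kind, accession = argv[1], argv[2]
    text = fetch_protein_fasta(accession) if kind == "protein" else fetch_cds_fasta(accession)
    sys.stdout.write(text)
    return 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv))
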