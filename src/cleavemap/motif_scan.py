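"""Scan coding sequences for a (possibly degenerate) ribonuclease recognition motif.

The biological question: how many protein-coding sequences carry at least
one copy of the enzyme's recognition sequence on the mRNA (sense) strand and
are therefore potential in vivo cleavage targets?  Scanning is exact-match
over IUPAC-expanded positions, case-insensitive, T/U-agnostic, and counts
overlapping occurrences at every start.  Only the sense strand is scanned by
default -- a MazF-family toxin attacks single-stranded mRNA -- with antisense
available behind a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from cleavemap.io_formats import SequenceRecord

#: IUPAC nucleotide codes expanded over the RNA alphabet.
IUPAC_EXPAND: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class ScanResult:
    """Per-CDS motif hits; positions are 1-based starts on the scanned strand."""

    motif: str
    per_cds: tuple[tuple[str, int, tuple[int, ...]], ...]  # (cds_id, n_hits, positions)
    n_cds_with_hit: int
    n_cds_total: int


def _motif_regex(motif: str, n_matches_any: bool) -> re.Pattern[str]:
    motif = motif.upper().replace("T", "U")
    parts = []
    for ch in motif:
        if ch not in IUPAC_EXPAND:
            raise ValueError(f"illegal IUPAC code {ch!r} in motif {motif!r}")
        chars = IUPAC_EXPAND[ch]
        if n_matches_any:
            chars += "N"
        parts.append(f"[{chars}]")
    # lookahead so overlapping occurrences are all counted
    return re.compile("(?=" + "".join(parts) + ")")


def scan_cds(
    cds_records: Sequence[SequenceRecord],
    motif: str,
    *,
    both_strands: bool = False,
    n_matches_any: bool = False,
) -> ScanResult:
    """Count motif occurrences per coding sequence.

    Records may be DNA or RNA (normalized to RNA internally).  ``N`` in a CDS
    matches nothing unless ``n_matches_any``.  With ``both_strands`` the
    reverse complement of each CDS is also scanned and its 1-based hit starts
    (on the antisense strand) are merged into the per-CDS counts.
    """
    if not cds_records:
        raise ValueError("empty CDS input")
    pattern = _motif_regex(motif, n_matches_any)
    per_cds = []
    n_with_hit = 0
    for rec in cds_records:
        seq = rec.residues.upper().replace("T", "U")
        positions = [m.start() + 1 for m in pattern.finditer(seq)]
        if both_strands:
            rc = seq.translate(_COMPLEMENT)[::-1]
            positions += [m.start() + 1 for m in pattern.finditer(rc)]
            positions.sort()
        if positions:
            n_with_hit += 1
        per_cds.append((rec.id, len(positions), tuple(positions)))
    return ScanResult(
        motif=motif.upper().replace("T", "U"),
        per_cds=tuple(per_cds),
        n_cds_with_hit=n_with_hit,
        n_cds_total=len(cds_records),
    )


def scan_report(result: ScanResult, path: str | Path) -> None:
    """Write a TSV: one row per CDS with >= 1 hit, plus a summary footer.

    Columns: cds_id, n_hits, comma-joined 1-based hit positions.  The footer
    reads ``#n_cds_with_hit/n_cds_total`` style, e.g. ``# 153/2157``.
    """
    for cds_id, _, _ in result.per_cds:
        if "\t" in cds_id or "\n" in cds_id:
            raise ValueError(f"CDS id {cds_id!r} contains tab/newline; refusing to write TSV")
    with open(path, "w") as fh:
        fh.write("cds_id\tn_hits\tpositions\n")
        for cds_id, n_hits, positions in result.per_cds:
            if n_hits == 0:
                continue
            fh.write(f"{cds_id}\t{n_hits}\t{','.join(map(str, positions))}\n")
        fh.write(
            f"# {result.n_cds_with_hit}/{result.n_cds_total} CDSs contain >=1 "
            f"{result.motif} motif\n"
        )
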