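"""Readers and writers for the external representations the pipeline touches.

All internal coordinates are 1-based inclusive; conversion to 0-based
half-open coordinates happens only at the BED/bedGraph boundary.  Coverage is
exchanged as a plain TSV (``substrate_id  position  coverage``) which is the
native dialect; the bedGraph dialect is accepted behind an explicit flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cleavemap")

_RNA = set("ACGU")
_DNA = set("ACGT")
_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYX*")
_AMBIGUOUS_NT = {"N"}

ALPHABETS = ("RNA", "DNA", "protein")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with an explicit alphabet, residues in uppercase canonical form."""

    id: str
    alphabet: str
    residues: str

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CoverageTrack:
    """Per-position read coverage for one substrate; values[i] is 1-based position i+1."""

    substrate_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("coverage values must be a nonempty 1-D array")
        if (self.values < 0).any():
            raise ValueError(f"{self.substrate_id}: negative coverage")

    def __len__(self) -> int:
        return int(self.values.size)


def _valid_chars(alphabet: str, allow_gaps: bool) -> set[str]:
    base = {"RNA": _RNA, "DNA": _DNA, "protein": _PROTEIN}[alphabet]
    chars = set(base)
    if alphabet in ("RNA", "DNA"):
        chars |= _AMBIGUOUS_NT
    if allow_gaps:
        chars.add("-")
    return chars


def _normalize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == "RNA":
        return seq.replace("T", "U")
    if alphabet == "DNA":
        return seq.replace("U", "T")
    return seq


def read_fasta(path: str | Path, alphabet: str, *, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and U/T are interconverted to match ``alphabet``.
    ``N`` is accepted in nucleotide records but flagged with a warning.
    Errors name the offending line number.
    """
    if alphabet not in ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    valid = _valid_chars(alphabet, allow_gaps)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    rec_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _flush() -> None:
        if rec_id is None:
            return
        seq = _normalize("".join(chunks), alphabet)
        if not seq:
            raise ParseError(f"{path}: line {header_line}: record {rec_id!r} has no sequence")
        records.append(SequenceRecord(rec_id, alphabet, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                rec_id = line[1:].split()[0] if line[1:].strip() else ""
                if not rec_id:
                    raise ParseError(f"{path}: line {lineno}: empty FASTA header")
                if rec_id in seen:
                    raise ParseError(f"{path}: line {lineno}: duplicate record id {rec_id!r}")
                seen.add(rec_id)
                chunks = []
                header_line = lineno
            else:
                if rec_id is None:
                    raise ParseError(f"{path}: line {lineno}: sequence before first header")
                norm = _normalize(line, alphabet)
                bad = set(norm) - valid
                if bad:
                    raise ParseError(
                        f"{path}: line {lineno}: illegal character(s) {sorted(bad)} "
                        f"for alphabet {alphabet}"
                    )
                if set(norm) & _AMBIGUOUS_NT and alphabet != "protein":
                    logger.warning("%s: line %d: ambiguous base N in record %s", path, lineno, rec_id)
                chunks.append(norm)
    _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 70) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_coverage(
    path: str | Path,
    *,
    dialect: str = "tsv",
    lengths: Mapping[str, int] | None = None,
) -> list[CoverageTrack]:
    """Read per-position coverage into dense :class:`CoverageTrack` objects.

    The native dialect is a TSV with columns ``substrate_id``, ``position``
    (1-based) and ``coverage``; positions absent from the file get coverage 0.
    ``dialect="bedgraph"`` selects the 0-based half-open 4-column dialect.
    ``lengths`` (substrate_id -> length) extends each track to its substrate's
    full length with zeros.
    """
    if dialect == "tsv":
        sparse = _read_coverage_tsv(path)
    elif dialect == "bedgraph":
        sparse = _read_coverage_bedgraph(path)
    else:
        raise ValueError(f"unknown coverage dialect {dialect!r}")

    tracks = []
    for sid, pos_cov in sparse.items():
        max_pos = max(pos_cov)
        length = max_pos
        if lengths is not None:
            if sid not in lengths:
                raise ParseError(f"{path}: substrate {sid!r} has no declared length")
            length = int(lengths[sid])
            if max_pos > length:
                raise ParseError(
                    f"{path}: substrate {sid!r}: position {max_pos} exceeds declared length {length}"
                )
        values = np.zeros(length, dtype=np.int64)
        for pos, cov in pos_cov.items():
            values[pos - 1] = cov
        tracks.append(CoverageTrack(sid, values))
    return tracks


def _read_coverage_tsv(path: str | Path) -> dict[str, dict[int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 3:
        raise ParseError(f"{path}: expected 3 tab-separated columns, got {df.shape[1]}")
    # tolerate a header row naming the columns
    if df.iloc[0, 1].strip().lower() == "position":
        df = df.iloc[1:]
    sparse: dict[str, dict[int, int]] = {}
    for row_i, (sid, pos_s, cov_s) in enumerate(df.itertuples(index=False), start=1):
        try:
            pos, cov = int(pos_s), int(cov_s)
        except ValueError as exc:
            raise ParseError(f"{path}: row {row_i}: non-integer position/coverage") from exc
        if pos <= 0:
            raise ParseError(f"{path}: row {row_i}: position {pos} must be >= 1")
        if cov < 0:
            raise ParseError(f"{path}: row {row_i}: negative coverage")
        track = sparse.setdefault(sid, {})
        if pos in track:
            raise ParseError(f"{path}: row {row_i}: duplicate position {pos} for {sid!r}")
        track[pos] = cov
    if not sparse:
        raise ParseError(f"{path}: no coverage rows")
    return sparse


def _read_coverage_bedgraph(path: str | Path) -> dict[str, dict[int, int]]:
    sparse: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            sid, start_s, end_s, cov_s = fields
            try:
                start, end, cov = int(start_s), int(end_s), int(cov_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field") from exc
            if start < 0 or end <= start:
                raise ParseError(f"{path}: line {lineno}: bad interval [{start}, {end})")
            if cov < 0:
                raise ParseError(f"{path}: line {lineno}: negative coverage")
            track = sparse.setdefault(sid, {})
            for pos in range(start + 1, end + 1):  # to 1-based inclusive
                if pos in track:
                    raise ParseError(f"{path}: line {lineno}: overlapping interval at position {pos}")
                track[pos] = cov
    if not sparse:
        raise ParseError(f"{path}: no coverage rows")
    return sparse


def write_coverage(tracks: Iterable[CoverageTrack], path: str | Path) -> None:
    """Write dense tracks as the native coverage TSV (every position, 1-based)."""
    with open(path, "w") as fh:
        fh.write("substrate_id\tposition\tcoverage\n")
        for track in tracks:
            sid = track.substrate_id
            for i, cov in enumerate(track.values, start=1):
                fh.write(f"{sid}\t{i}\t{int(cov)}\n")


def write_sites_bed(sites: Sequence, path: str | Path) -> None:
    """Write called cleavage sites as BED6.

    A site at 1-based position n becomes chromStart n-1, chromEnd n; the score
    is min(1000, round(RCI x 100)); strand is "+" (the ribonuclease acts on
    the single sense strand).
    """
    with open(path, "w") as fh:
        for i, site in enumerate(sites, start=1):
            score = min(1000, round(site.rci * 100))
            fh.write(
                f"{site.substrate_id}\t{site.position - 1}\t{site.position}"
                f"\tsite_{i}\t{score}\t+\n"
            )
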