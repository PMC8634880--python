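"""Pairwise global alignment and MSA column-conservation annotation.

Pairwise alignment is Needleman-Wunsch with affine gaps (BLOSUM62, gap open
10, gap extend 0.5 by default, in the EMBOSS-needle style: a gap of length k
costs open + (k-1) x extend, end gaps included).  Percent identity is the
fraction of alignment columns with identical residues; percent similarity
additionally admits columns whose residue pair scores positively in the
substitution matrix.  The dynamic programming is delegated to Biopython's
PairwiseAligner; among co-optimal alignments the aligner's first traceback
is reported, deterministically for a given Biopython version.

MSA annotation reproduces the familiar conservation line: '*' marks columns
where every sequence carries the same residue (no gaps), '.' marks columns
where at least a threshold fraction (default 80%) of the non-gap residues
fall into one "strong" similarity group, and ' ' everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from cleavemap.io_formats import SequenceRecord

#: Conventional strong residue-similarity groups (clustal-style).
STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment with identity/similarity percentages."""

    aligned_a: str
    aligned_b: str
    score: float
    pct_identity: float
    pct_similarity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    def __str__(self) -> str:
        marks = []
        for x, y in zip(self.aligned_a, self.aligned_b):
            marks.append("|" if x == y and x != "-" else " ")
        return f"{self.aligned_a}\n{''.join(marks)}\n{self.aligned_b}"


@dataclass(frozen=True)
class MsaConservation:
    """An MSA with its conservation mark line and reference-mapped conserved sites."""

    ids: tuple[str, ...]
    msa: tuple[str, ...]
    marks: str
    #: (MSA column 1-based, reference residue, reference position 1-based)
    conserved_sites: tuple[tuple[int, str, int], ...]


def global_align(
    seq_a: str | SequenceRecord,
    seq_b: str | SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences with affine gaps.

    ``gap_open`` is charged for the first position of a gap and
    ``gap_extend`` for each further position.  Raises on empty input or on a
    residue missing from the substitution matrix.
    """
    a = seq_a.residues if isinstance(seq_a, SequenceRecord) else seq_a.upper()
    b = seq_b.residues if isinstance(seq_b, SequenceRecord) else seq_b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    subs = substitution_matrices.load(matrix)
    for ch in set(a) | set(b):
        if ch not in subs.alphabet:
            raise ValueError(f"residue {ch!r} absent from matrix {matrix}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = subs
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignments = aligner.align(a, b)
    aln = alignments[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])

    n_ident = n_sim = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            n_ident += 1
            n_sim += 1
        elif subs[x, y] > 0:
            n_sim += 1
    length = len(aligned_a)
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        pct_identity=100.0 * n_ident / length,
        pct_similarity=100.0 * n_sim / length,
    )


def annotate_msa(
    msa: Sequence[SequenceRecord] | Sequence[str],
    similarity_groups: Sequence[frozenset[str]] = STRONG_GROUPS,
    threshold: float = 0.8,
    *,
    ids: Sequence[str] | None = None,
) -> MsaConservation:
    """Annotate each MSA column with '*', '.' or ' '.

    '*': all rows share one residue, no gaps.  '.': at least ``threshold`` of
    the non-gap residues in the column belong to a single similarity group
    (gap rows are excluded from the denominator; at least two non-gap rows
    required).  Conserved sites are mapped to first-row (reference)
    positions, skipping columns where the reference is gapped.
    """
    if ids is None:
        if msa and isinstance(msa[0], SequenceRecord):
            ids = [r.id for r in msa]
        else:
            ids = [f"seq{i + 1}" for i in range(len(msa))]
    rows = [r.residues if isinstance(r, SequenceRecord) else r.upper() for r in msa]
    if len(rows) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged MSA: aligned sequences differ in length")

    marks = []
    for j in range(width):
        col = [r[j] for r in rows]
        residues = [c for c in col if c != "-"]
        if len(residues) == len(rows) and len(set(residues)) == 1:
            marks.append("*")
            continue
        mark = " "
        if len(residues) >= 2:
            for group in similarity_groups:
                frac = sum(1 for c in residues if c in group) / len(residues)
                if frac >= threshold:
                    mark = "."
                    break
        marks.append(mark)
    marks_str = "".join(marks)

    sites = []
    ref = rows[0]
    ref_pos = 0
    for j in range(width):
        if ref[j] == "-":
            continue
        ref_pos += 1
        if marks_str[j] in "*.":
            sites.append((j + 1, ref[j], ref_pos))
    return MsaConservation(tuple(ids), tuple(rows), marks_str, tuple(sites))


def conserved_site_report(conservation: MsaConservation, reference_id: str | None = None) -> list[tuple[int, str, str]]:
    """Conserved columns mapped onto a chosen reference sequence.

    Rows are (reference position, residue, mark) for every '*' or '.' column
    where the reference is not gapped -- the shortlist from which
    mutagenesis candidates are picked.
    """
    if reference_id is None:
        ref_row = conservation.msa[0]
    else:
        try:
            idx = conservation.ids.index(reference_id)
        except ValueError as exc:
            raise ValueError(f"unknown reference id {reference_id!r}") from exc
        ref_row = conservation.msa[idx]
    out = []
    pos = 0
    for j, ch in enumerate(ref_row):
        if ch == "-":
            continue
        pos += 1
        if conservation.marks[j] in "*.":
            out.append((pos, ch, conservation.marks[j]))
    return out
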