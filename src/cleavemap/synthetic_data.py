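"""Seeded simulator of the cleavage -> fragment -> read -> coverage process.

The generative model mirrors how a sequencing library is made from the
digestion products of a single-strand-specific endoribonuclease: every input
molecule is cut independently at each planted recognition-site variant with a
per-variant efficiency, and at every other phosphodiester bond with a small
background breakage rate; every resulting fragment is sequenced exactly once
by a single-end, 5'-anchored, fixed-length read.  Read 5' ends therefore pile
up at the first base downstream of each cut, producing the coverage step-up
that the RCI statistic detects.

A planted site is addressed by its *step base* n (1-based): the variant
6-mer occupies positions n-1 .. n+4 and the cut falls between n-1 and n,
i.e. after the U of U^ACAAA.

Depth is controlled purely by the number of molecules; there is no separate
read-sampling layer.  Default per-variant efficiencies encode the enzyme's
qualitative preference order (UACAAA strongest; UACUAA > UACGAA > UACCAA
weak; near-cognate 6th-base variants marginal) and are configuration values,
not measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cleavemap.io_formats import CoverageTrack, SequenceRecord, write_coverage, write_fasta

_RNA_BASES = "ACGU"

#: Per-molecule cut probabilities per recognition-site variant.  Artifact
#: defaults respecting the enzyme's qualitative preference ordering; override
#: via config or the CLI, never treated as measured quantities.
DEFAULT_EFFICIENCIES: dict[str, float] = {
    "UACAAA": 0.9,
    "UACUAA": 0.4,
    "UACGAA": 0.3,
    "UACCAA": 0.1,
    "UACAAC": 0.02,
    "UACAAG": 0.02,
    "UACAAU": 0.02,
}

#: The eight-substrate panel geometry: artificial RNAs of 533, 1033 (x5),
#: 1533 and 2033 nt.
PANEL_LENGTHS: dict[str, int] = {
    "500-2": 533,
    "1000-1": 1033,
    "1000-2": 1033,
    "1000-3": 1033,
    "1000-4": 1033,
    "1000-5": 1033,
    "1500-1": 1533,
    "2000-1": 2033,
}

#: Default planted-site roster: step-base position -> variant.  Exactly ten
#: top-efficiency UACAAA sites across the panel, weaker variants on four
#: substrates, and one motif-free decoy substrate (1000-5).
DEFAULT_ROSTER: dict[str, list[tuple[int, str]]] = {
    "500-2": [(300, "UACAAA")],
    "1000-1": [(200, "UACAAA"), (600, "UACUAA")],
    "1000-2": [(300, "UACAAA"), (700, "UACGAA")],
    "1000-3": [(450, "UACAAA"), (800, "UACCAA")],
    "1000-4": [(250, "UACAAA"), (750, "UACAAA")],
    "1000-5": [],
    "1500-1": [(400, "UACAAA"), (900, "UACAAA")],
    "2000-1": [(500, "UACAAA"), (1200, "UACAAA"), (1700, "UACUAA")],
}


@dataclass(frozen=True)
class EnzymeModel:
    """Map from 6-mer variant to per-molecule cleavage probability, plus background."""

    efficiency: Mapping[str, float]
    background_break_rate: float = 1e-4

    def __post_init__(self) -> None:
        for variant, p in self.efficiency.items():
            if len(variant) != 6 or set(variant) - set(_RNA_BASES):
                raise ValueError(f"variant {variant!r} is not an RNA 6-mer")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"efficiency[{variant}]={p} outside [0, 1]")
        if not 0.0 <= self.background_break_rate < 1.0:
            raise ValueError("background_break_rate outside [0, 1)")


@dataclass(frozen=True)
class LibraryConfig:
    """Sequencing-library parameters: depth (molecules), read length and seed."""

    n_molecules: int = 5000
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass(frozen=True)
class SubstrateRNA:
    """A substrate RNA with the ground-truth planted recognition sites.

    ``planted_sites`` holds (step-base position n, variant); the variant
    occupies positions n-1 .. n+4 and the cut lies between n-1 and n.
    """

    record: SequenceRecord
    planted_sites: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_sites", tuple(self.planted_sites))
        seq, L = self.record.residues, len(self.record)
        for n, variant in self.planted_sites:
            if n < 7 or L - n < 6:
                raise ValueError(
                    f"{self.record.id}: planted step base {n} too close to an end "
                    f"(need n >= 7 and n <= L-6 for L={L})"
                )
            if seq[n - 2 : n + 4] != variant:
                raise ValueError(
                    f"{self.record.id}: residues at {n - 1}..{n + 4} do not spell {variant!r}"
                )

    @property
    def id(self) -> str:
        return self.record.id

    def __len__(self) -> int:
        return len(self.record)


def generate_substrate(
    length: int,
    gc_fraction: float = 0.5,
    planted: Sequence[tuple[int, str]] = (),
    seed: int = 0,
    *,
    forbidden_motifs: Sequence[str] | None = None,
    substrate_id: str = "substrate",
) -> SubstrateRNA:
    """Draw a random substrate RNA and write the planted variants over it.

    The background is i.i.d. with the requested GC fraction.  Any accidental
    occurrence of a motif in ``forbidden_motifs`` (default: every variant in
    :data:`DEFAULT_EFFICIENCIES`) outside the planted spans is resampled until
    the only occurrences are the planted ones, so the planted roster is the
    exact ground truth.  Deterministic given ``seed``.
    """
    if length < 50:
        raise ValueError("substrate length must be >= 50")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction outside [0, 1]")
    planted = sorted(planted)
    for n, variant in planted:
        if len(variant) != 6 or set(variant) - set(_RNA_BASES):
            raise ValueError(f"variant {variant!r} is not an RNA 6-mer")
        if n < 7 or length - n < 6:
            raise ValueError(f"planted step base {n} violates margins for length {length}")
    spans = [(n - 1, n + 4) for n, _ in planted]  # 1-based inclusive occupied spans
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            raise ValueError("planted windows overlap")

    if forbidden_motifs is None:
        forbidden_motifs = tuple(DEFAULT_EFFICIENCIES)
    forbidden = {m.upper().replace("T", "U") for m in forbidden_motifs}
    forbidden |= {v for _, v in planted}

    rng = np.random.default_rng(seed)
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    seq = list(rng.choice(list(_RNA_BASES), size=length, p=probs))
    planted_mask = np.zeros(length, dtype=bool)
    for n, variant in planted:
        seq[n - 2 : n + 4] = list(variant)
        planted_mask[n - 2 : n + 4] = True
    planted_starts = {n - 2 for n, _ in planted}  # 0-based starts of planted 6-mers

    for _ in range(10_000):
        text = "".join(seq)
        dirty = False
        for motif in forbidden:
            start = text.find(motif)
            while start != -1:
                if start not in planted_starts or text[start : start + 6] != _variant_at(planted, start):
                    free = [i for i in range(start, start + 6) if not planted_mask[i]]
                    if not free:
                        start = text.find(motif, start + 1)
                        continue
                    for i in free:
                        seq[i] = rng.choice(list(_RNA_BASES), p=probs)
                    dirty = True
                    break
                start = text.find(motif, start + 1)
            if dirty:
                break
        if not dirty:
            break
    else:  # pragma: no cover - astronomically unlikely with free positions available
        raise RuntimeError("could not purge accidental motif occurrences")

    record = SequenceRecord(substrate_id, "RNA", "".join(seq))
    return SubstrateRNA(record, tuple(planted))


def _variant_at(planted: Sequence[tuple[int, str]], start0: int) -> str | None:
    for n, variant in planted:
        if n - 2 == start0:
            return variant
    return None


def digest_and_sequence(
    substrate: SubstrateRNA,
    enzyme: EnzymeModel,
    lib: LibraryConfig,
) -> tuple[CoverageTrack, pd.DataFrame]:
    """Digest ``lib.n_molecules`` copies of the substrate and sequence every fragment.

    Each planted site is cut independently with its variant's efficiency; each
    of the other L-1 bonds breaks with the background rate.  Every fragment
    yields one 5'-anchored read of length min(read_length, fragment length).
    Returns the per-position coverage track and the read-start table with one
    row per read (columns ``start``, ``length``; start is 1-based).
    Deterministic given ``lib.seed``.
    """
    L = len(substrate)
    rng = np.random.default_rng(lib.seed)
    n_mol = lib.n_molecules
    rl = lib.read_length

    # downstream-fragment start position for each planted cut (cut between n-1 and n)
    site_starts = np.array(
        [n for n, v in substrate.planted_sites], dtype=np.int64
    )
    site_p = np.array(
        [enzyme.efficiency.get(v, 0.0) for _, v in substrate.planted_sites], dtype=float
    )
    n_sites = site_starts.size

    if n_sites:
        cut_matrix = rng.random((n_mol, n_sites)) < site_p  # (molecule, site)
    else:
        cut_matrix = np.zeros((n_mol, 0), dtype=bool)

    b = enzyme.background_break_rate
    if b > 0.0 and L > 1:
        n_bg = rng.binomial(L - 1, b, size=n_mol)
    else:
        n_bg = np.zeros(n_mol, dtype=np.int64)

    diff = np.zeros(L + 1, dtype=np.int64)
    read_counts: dict[tuple[int, int], int] = {}

    def _add_fragments(starts: list[int], count: int) -> None:
        # starts: sorted 1-based fragment starts, first is 1
        for i, s in enumerate(starts):
            end = (starts[i + 1] - 1) if i + 1 < len(starts) else L
            read_len = min(rl, end - s + 1)
            diff[s - 1] += count
            diff[s - 1 + read_len] -= count
            key = (s, read_len)
            read_counts[key] = read_counts.get(key, 0) + count

    plain = n_bg == 0
    if n_sites:
        # group background-free molecules by their planted-cut pattern
        weights = (1 << np.arange(n_sites))
        codes = cut_matrix[plain] @ weights
        uniq, counts = np.unique(codes, return_counts=True)
        for code, count in zip(uniq, counts):
            starts = [1] + [int(site_starts[j]) for j in range(n_sites) if code >> j & 1]
            _add_fragments(sorted(starts), int(count))
    else:
        _add_fragments([1], int(plain.sum()))

    # molecules with at least one background break are handled individually
    for mol in np.nonzero(~plain)[0]:
        bg_starts = rng.integers(2, L + 1, size=int(n_bg[mol]))
        starts = {1} | {int(s) for s in bg_starts}
        if n_sites:
            starts |= {int(site_starts[j]) for j in range(n_sites) if cut_matrix[mol, j]}
        _add_fragments(sorted(starts), 1)

    coverage = np.cumsum(diff[:-1])
    track = CoverageTrack(substrate.id, coverage)

    keys = sorted(read_counts)
    starts_arr = np.repeat([k[0] for k in keys], [read_counts[k] for k in keys])
    lens_arr = np.repeat([k[1] for k in keys], [read_counts[k] for k in keys])
    reads = pd.DataFrame({"start": starts_arr, "length": lens_arr})
    return track, reads


def make_toy_cds(
    n_cds: int = 60,
    length: int = 900,
    motif: str = "UACAAA",
    fraction_with_motif: float = 0.4,
    seed: int = 0,
) -> tuple[list[SequenceRecord], int]:
    """Generate a synthetic DNA coding-sequence panel for motif-scan demos.

    A chosen fraction of the records carry exactly one planted copy of the
    motif (in its DNA spelling); the rest are purged of accidental copies by
    rejection-resampling, so the returned expected hit count is exact ground
    truth.  Returns (records, number of CDSs carrying the motif).
    """
    rng = np.random.default_rng(seed)
    dna_motif = motif.upper().replace("U", "T")
    k = len(dna_motif)
    n_with = int(round(n_cds * fraction_with_motif))
    records = []
    for i in range(n_cds):
        plant = i < n_with
        seq = list(rng.choice(list("ACGT"), size=length))
        if plant:
            pos = int(rng.integers(0, length - k + 1))
        for _ in range(1000):
            text = "".join(seq)
            hit = text.find(dna_motif)
            extra = -1
            while hit != -1:
                if not (plant and hit == pos):
                    extra = hit
                    break
                hit = text.find(dna_motif, hit + 1)
            if extra == -1:
                break
            for j in range(extra, extra + k):
                if not (plant and pos <= j < pos + k):
                    seq[j] = rng.choice(list("ACGT"))
        if plant:
            seq[pos : pos + k] = list(dna_motif)
            # planting may butt against background and create a second copy; purge again
            for _ in range(1000):
                text = "".join(seq)
                extra = -1
                hit = text.find(dna_motif)
                while hit != -1:
                    if hit != pos:
                        extra = hit
                        break
                    hit = text.find(dna_motif, hit + 1)
                if extra == -1:
                    break
                free = [j for j in range(extra, extra + k) if not pos <= j < pos + k]
                for j in free:
                    seq[j] = rng.choice(list("ACGT"))
        records.append(SequenceRecord(f"cds_{i + 1:04d}", "DNA", "".join(seq)))
    order = rng.permutation(n_cds)
    return [records[i] for i in order], n_with


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of the eight-substrate fixture panel."""

    master_seed: int = 0
    n_molecules: int = 5000
    read_length: int = 150
    gc_fraction: float = 0.5
    efficiencies: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFICIENCIES))
    background_break_rate: float = 1e-4
    lengths: Mapping[str, int] = field(default_factory=lambda: dict(PANEL_LENGTHS))
    roster: Mapping[str, Sequence[tuple[int, str]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ROSTER.items()}
    )


def make_fixture_panel(
    config: PanelConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[SubstrateRNA], list[CoverageTrack], dict]:
    """Generate the eight-substrate panel with planted ground truth.

    Returns the substrates, their simulated coverage tracks, and a manifest
    recording the planted truth (for scoring recovery).  With ``out_dir``,
    writes ``panel.fasta``, ``coverage.tsv`` and ``manifest.json``.
    Byte-identical for a fixed master seed.
    """
    if config is None:
        config = PanelConfig()
    enzyme = EnzymeModel(dict(config.efficiencies), config.background_break_rate)
    master = np.random.SeedSequence(config.master_seed)
    children = master.spawn(2 * len(config.lengths))

    substrates: list[SubstrateRNA] = []
    tracks: list[CoverageTrack] = []
    manifest: dict = {
        "master_seed": config.master_seed,
        "n_molecules": config.n_molecules,
        "read_length": config.read_length,
        "background_break_rate": config.background_break_rate,
        "efficiencies": dict(config.efficiencies),
        "substrates": {},
    }
    for i, (name, length) in enumerate(config.lengths.items()):
        roster = list(config.roster.get(name, []))
        substrate = generate_substrate(
            length,
            config.gc_fraction,
            roster,
            seed=children[2 * i],
            forbidden_motifs=tuple(config.efficiencies),
            substrate_id=name,
        )
        lib = LibraryConfig(config.n_molecules, config.read_length, seed=children[2 * i + 1])
        track, _ = digest_and_sequence(substrate, enzyme, lib)
        substrates.append(substrate)
        tracks.append(track)
        manifest["substrates"][name] = {
            "length": length,
            "planted_sites": [[n, v] for n, v in substrate.planted_sites],
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([s.record for s in substrates], out / "panel.fasta")
        write_coverage(tracks, out / "coverage.tsv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return substrates, tracks, manifest
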