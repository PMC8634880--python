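"""The cleavage-site detection pipeline built on the relative coverage increase.

The statistic: after replacing zero coverage with a pseudocount of 1, the
RCI at position n (n >= 2) is coverage(n) / coverage(n-1).  A cut between
n-1 and n makes read 5' ends pile up at n, so a genuine cleavage site shows
as a coverage step-up with a large RCI.  Site calling applies two criteria:
(i) coverage(n) is at least the median of the substrate's (pseudocounted)
coverage distribution, and (ii) RCI >= 3 (the threshold is configurable).
The 11-nt window spanning five bases either side of each passing position is
extracted -- the step-up base sits at window position 6 and the cut falls
between window positions 5 and 6 -- and the ten windows with the highest RCI
across all substrates feed the motif model.

RCI tables are plain pandas DataFrames with columns ``substrate_id``,
``position``, ``cov_n``, ``cov_nm1``, ``rci``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cleavemap.io_formats import CoverageTrack, SequenceRecord
from cleavemap.motif_model import build_motif, iupac_consensus

logger = logging.getLogger("cleavemap")

RCI_COLUMNS = ["substrate_id", "position", "cov_n", "cov_nm1", "rci"]

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class CleavageSite:
    """A called cleavage site: the step-up base and its 11-nt window.

    ``position`` is the 1-based step-up base n; the cut lies between n-1 and
    n; ``window`` covers n-5 .. n+5 so the step-up base is window position 6
    (1-based).
    """

    substrate_id: str
    position: int
    cov_n: int
    cov_nm1: int
    rci: float
    window: str
    rank: int = 0

    def __post_init__(self) -> None:
        if len(self.window) != 11:
            raise ValueError("window must be 11 nt")


def apply_pseudocount(track: CoverageTrack) -> CoverageTrack:
    """Replace zero coverage with 1 so every RCI ratio is defined.

    Zero-replacement (not add-one): positive values pass through unchanged,
    so the operation is idempotent.
    """
    values = track.values.copy()
    values[values == 0] = 1
    return CoverageTrack(track.substrate_id, values)


def compute_rci(track: CoverageTrack) -> pd.DataFrame:
    """Compute the RCI table for a pseudocounted track.

    One row per position n in 2..L, in order; RCI = cov(n)/cov(n-1).  A track
    containing zeros is rejected: the pseudocount must be applied first.
    """
    v = track.values
    if (v == 0).any():
        raise ValueError(
            f"{track.substrate_id}: track contains zero coverage; apply the pseudocount first"
        )
    cov_n = v[1:]
    cov_nm1 = v[:-1]
    return pd.DataFrame(
        {
            "substrate_id": track.substrate_id,
            "position": np.arange(2, len(v) + 1),
            "cov_n": cov_n,
            "cov_nm1": cov_nm1,
            "rci": cov_n / cov_nm1,
        },
        columns=RCI_COLUMNS,
    )


def filter_by_median(records: pd.DataFrame, track: CoverageTrack) -> pd.DataFrame:
    """Drop positions whose coverage is below the substrate's median coverage.

    The median is taken over all L positions of the pseudocounted track (for
    even L, the mean of the two central order statistics); the test applies
    to cov_n and the boundary is inclusive (cov_n == median is kept).
    """
    ids = records["substrate_id"].unique()
    if len(ids) > 1 or (len(ids) == 1 and ids[0] != track.substrate_id):
        raise ValueError(
            f"records are for {sorted(ids)} but track is {track.substrate_id!r}"
        )
    med = float(np.median(track.values))
    return records[records["cov_n"] >= med].reset_index(drop=True)


def call_sites(
    records: pd.DataFrame,
    substrate: SequenceRecord,
    rci_threshold: float = 3.0,
    flank: int = 5,
) -> list[CleavageSite]:
    """Call sites from median-filtered records: RCI >= threshold, full window.

    Positions whose window n-flank .. n+flank does not fit inside the
    substrate are dropped (logged); windows are attached from the substrate
    sequence.  The threshold is inclusive.
    """
    seq = substrate.residues
    L = len(seq)
    sites: list[CleavageSite] = []
    passing = records[records["rci"] >= rci_threshold]
    for row in passing.itertuples(index=False):
        n = int(row.position)
        if n - flank < 1 or n + flank > L:
            logger.info(
                "%s: position %d passes RCI %.2f but its window does not fit; dropped",
                substrate.id, n, row.rci,
            )
            continue
        window = seq[n - flank - 1 : n + flank]
        sites.append(
            CleavageSite(
                substrate_id=str(row.substrate_id),
                position=n,
                cov_n=int(row.cov_n),
                cov_nm1=int(row.cov_nm1),
                rci=float(row.rci),
                window=window,
            )
        )
    return sites


def top_k_sites(sites: Sequence[CleavageSite], k: int = 10) -> list[CleavageSite]:
    """The k sites with the highest RCI, pooled across substrates.

    Ties are broken by substrate id then position (both ascending).  If fewer
    than k sites exist, all are returned with a warning.  Ranks are 1..k.
    """
    if len(sites) < k:
        logger.warning("only %d sites available for top-%d ranking", len(sites), k)
    ordered = sorted(sites, key=lambda s: (-s.rci, s.substrate_id, s.position))[:k]
    return [
        CleavageSite(s.substrate_id, s.position, s.cov_n, s.cov_nm1, s.rci, s.window, rank=i)
        for i, s in enumerate(ordered, start=1)
    ]


def detect_recognition_sequence(
    substrates: Sequence[SequenceRecord],
    tracks: Sequence[CoverageTrack],
    *,
    rci_threshold: float = 3.0,
    flank: int = 5,
    top_k: int = 10,
    min_fraction: float = 0.5,
) -> dict:
    """Run the full pipeline and return a JSON-serializable report.

    Pipeline: pseudocount -> RCI -> median filter -> threshold + window
    extraction -> top-k ranking -> motif model (PWM, per-column information
    content, IUPAC consensus with the cut marked between window positions 5
    and 6).  A coverage track naming a substrate absent from the sequence
    input is fatal.
    """
    by_id = {s.id: s for s in substrates}
    missing = [t.substrate_id for t in tracks if t.substrate_id not in by_id]
    if missing:
        raise ValueError(f"coverage names substrates absent from FASTA: {sorted(missing)}")

    all_sites: list[CleavageSite] = []
    per_substrate: dict[str, list[dict]] = {}
    for track in tracks:
        substrate = by_id[track.substrate_id]
        if len(track) != len(substrate):
            raise ValueError(
                f"{track.substrate_id}: coverage length {len(track)} != "
                f"sequence length {len(substrate)}"
            )
        pseudo = apply_pseudocount(track)
        records = compute_rci(pseudo)
        records = filter_by_median(records, pseudo)
        sites = call_sites(records, substrate, rci_threshold, flank)
        all_sites.extend(sites)
        per_substrate[track.substrate_id] = [
            {
                "position": s.position,
                "cov_n": s.cov_n,
                "cov_nm1": s.cov_nm1,
                "rci": round(s.rci, 6),
                "window": s.window,
            }
            for s in sites
        ]

    top = top_k_sites(all_sites, top_k)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "params": {
            "rci_threshold": rci_threshold,
            "flank": flank,
            "top_k": top_k,
            "consensus_min_fraction": min_fraction,
        },
        "n_sites": len(all_sites),
        "sites": per_substrate,
        "top_sites": [
            {
                "rank": s.rank,
                "substrate_id": s.substrate_id,
                "position": s.position,
                "rci": round(s.rci, 6),
                "window": s.window,
            }
            for s in top
        ],
    }
    if top:
        model = build_motif([s.window for s in top], cut_offset=flank)
        consensus = iupac_consensus(model, min_fraction=min_fraction)
        motif_core = consensus[flank - 1 : flank + 5]
        report["motif"] = {
            "counts": {b: model.counts[i].tolist() for i, b in enumerate("ACGU")},
            "probs": {b: [round(p, 6) for p in model.probs[i]] for i, b in enumerate("ACGU")},
            "info_bits": [round(x, 6) for x in model.info],
            "consensus": consensus,
            "cut_offset": model.cut_offset,
            "consensus_with_cut": consensus[: flank] + "^" + consensus[flank:],
            "recognition_sequence": motif_core,
            "recognition_with_cut": motif_core[0] + "^" + motif_core[1:],
        }
    else:
        report["motif"] = None
    return report
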