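"""Position weight matrix, information content and IUPAC consensus from aligned windows.

This is the logo stage of the pipeline: the top-ranked 11-nt windows around
called cleavage sites are stacked into a 4 x W count matrix (rows A, C, G, U),
column probabilities p_bj, and per-column information content

    info_j = 2 + sum_b p_bj * log2(p_bj)     (bits; 0*log 0 := 0)

which is 2 bits for a fixed base and 0 for a uniform column.  No small-sample
correction is applied by default (the window sets here are tiny, typically
ten, and the logo is read qualitatively); the conventional correction
e_N = 3 / (2 ln2 N) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Smallest IUPAC code for each base set.
IUPAC_CODES: dict[frozenset[str], str] = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("U"): "U",
    frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("CG"): "S", frozenset("AU"): "W",
    frozenset("GU"): "K", frozenset("AC"): "M",
    frozenset("CGU"): "B", frozenset("AGU"): "D", frozenset("ACU"): "H", frozenset("ACG"): "V",
    frozenset("ACGU"): "N",
}


@dataclass(frozen=True)
class MotifModel:
    """PWM over RNA windows of width W with the cut between columns cut_offset and cut_offset+1."""

    counts: np.ndarray  # (4, W) ints, rows A,C,G,U
    probs: np.ndarray   # (4, W) column-stochastic
    info: tuple[float, ...]  # bits per column, in [0, 2]
    consensus: str
    cut_offset: int = 5

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    @property
    def n_windows(self) -> int:
        return int(self.counts[:, 0].sum())


def build_motif(
    windows: Sequence[str],
    cut_offset: int = 5,
    *,
    small_sample_correction: bool = False,
) -> MotifModel:
    """Tally aligned equal-width RNA windows into a :class:`MotifModel`.

    ``info[j] = 2 + sum_b p * log2 p`` with 0 log 0 = 0; with
    ``small_sample_correction`` the e_N = 3/(2 ln2 N) term is subtracted and
    the column floored at 0.  Deterministic.
    """
    if not windows:
        raise ValueError("need at least one window")
    W = len(windows[0])
    counts = np.zeros((4, W), dtype=np.int64)
    for w in windows:
        w = w.upper().replace("T", "U")
        if len(w) != W:
            raise ValueError(f"window {w!r} has width {len(w)}, expected {W}")
        for j, base in enumerate(w):
            if base not in _BASE_INDEX:
                raise ValueError(f"illegal character {base!r} in window {w!r}")
            counts[_BASE_INDEX[base], j] += 1
    N = len(windows)
    probs = counts / N
    plogp = np.zeros_like(probs)
    mask = probs > 0
    plogp[mask] = probs[mask] * np.log2(probs[mask])
    info = 2.0 + plogp.sum(axis=0)
    if small_sample_correction:
        info = np.maximum(0.0, info - 3.0 / (2.0 * np.log(2) * N))
    model = MotifModel(
        counts=counts,
        probs=probs,
        info=tuple(float(x) for x in info),
        consensus="",
        cut_offset=cut_offset,
    )
    consensus = iupac_consensus(model)
    object.__setattr__(model, "consensus", consensus)
    return model


def iupac_consensus(model: MotifModel, min_fraction: float = 0.5) -> str:
    """Call a degenerate consensus from the PWM, one IUPAC code per column.

    Per column: the smallest code covering every base with frequency
    >= ``min_fraction``; if no base reaches it, the smallest code covering
    bases taken in descending frequency (ties alphabetical) until their
    cumulative frequency reaches 0.75.
    """
    out = []
    for j in range(model.width):
        col = model.probs[:, j]
        strong = {BASES[i] for i in range(4) if col[i] >= min_fraction}
        if strong:
            out.append(IUPAC_CODES[frozenset(strong)])
            continue
        order = sorted(range(4), key=lambda i: (-col[i], BASES[i]))
        picked: set[str] = set()
        cum = 0.0
        for i in order:
            picked.add(BASES[i])
            cum += col[i]
            if cum >= 0.75:
                break
        out.append(IUPAC_CODES[frozenset(picked)])
    return "".join(out)


_LOGO_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "U": "#D62839"}


def render_logo(model: MotifModel, path: str | Path, *, title: str | None = None) -> None:
    """Render a stacked-letter information-content logo to an image file.

    Column stack heights equal ``info[j]`` (bits), letters within a stack are
    scaled by base probability with the most frequent on top; the X axis runs
    1..W so the step-up base sits at column cut_offset+1 and a dashed marker
    shows the cut between columns cut_offset and cut_offset+1.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    font = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(0.6 * model.width + 1.2, 2.6))
    for j in range(model.width):
        y = 0.0
        stack = sorted(range(4), key=lambda i: model.probs[i, j])  # tallest drawn last, on top
        for i in stack:
            h = model.probs[i, j] * model.info[j]
            if h <= 0:
                continue
            tp = TextPath((0, 0), BASES[i], size=1.0, prop=font)
            bbox = tp.get_extents()
            sx = 0.9 / bbox.width
            sy = h / bbox.height
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(sx, sy)
                .translate(j + 1 - 0.45, y)
            )
            ax.add_patch(PathPatch(tp.transformed(transform), color=_LOGO_COLORS[BASES[i]], lw=0))
            y += h
    ax.axvline(model.cut_offset + 0.5, color="black", ls="--", lw=1)
    ax.set_xlim(0.4, model.width + 0.6)
    ax.set_ylim(0, 2.05)
    ax.set_xticks(range(1, model.width + 1))
    ax.set_ylabel("bits")
    ax.set_xlabel("window position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
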