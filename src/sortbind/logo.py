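"""Sequence-logo rendering from energy matrices.

Two views of a matrix:

- an *information logo*: Boltzmann base probabilities per position, letters
  stacked to the Schneider information content (0–2 bits);
- a *mean-centered energy logo*: letters scaled by the matrix entries after
  per-position mean centering, with favorable (negative-energy) bases above
  the axis and unfavorable below.

Letters are drawn as matplotlib TextPaths stretched to the stack heights.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .energy_matrix import EnergyMatrix, base_probabilities
from .sequences import ALPHABET

_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def _draw_letter(ax, letter: str, x: float, y: float, width: float, height: float) -> None:
    if height <= 0:
        return
    tp = TextPath((0, 0), letter, size=1.0, prop=FontProperties(weight="bold"))
    bb = tp.get_extents()
    transform = (Affine2D()
                 .translate(-bb.x0, -bb.y0)
                 .scale(width / bb.width, height / bb.height)
                 .translate(x, y))
    ax.add_patch(PathPatch(transform.transform_path(tp), facecolor=_COLORS[letter],
                           edgecolor="none"))


def _stack(ax, heights: np.ndarray, baseline_split: bool = False) -> None:
    L = heights.shape[0]
    for i in range(L):
        pos = heights[i]
        up = [(ALPHABET[j], pos[j]) for j in range(4) if pos[j] > 0]
        up.sort(key=lambda t: t[1])
        y = 0.0
        for letter, h in up:
            _draw_letter(ax, letter, i + 0.05, y, 0.9, h)
            y += h
        if baseline_split:
            down = [(ALPHABET[j], -pos[j]) for j in range(4) if pos[j] < 0]
            down.sort(key=lambda t: t[1])
            y = 0.0
            for letter, h in down:
                _draw_letter(ax, letter, i + 0.05, y - h, 0.9, h)
                y -= h
    ax.set_xlim(0, L)
    ax.set_xticks(np.arange(L) + 0.5)
    ax.set_xticklabels(np.arange(1, L + 1), fontsize=7)


def information_logo_figure(m: EnergyMatrix):
    """Matplotlib figure of the information logo (heights in bits)."""
    heights = base_probabilities(m).letter_heights
    fig, ax = plt.subplots(figsize=(0.45 * len(m) + 1, 2.2))
    _stack(ax, heights)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    fig.tight_layout()
    return fig


def energy_logo_figure(m: EnergyMatrix):
    """Mean-centered energy logo: favorable bases (negative energy) point up."""
    centered = m.fix_gauge("position_mean").values
    heights = -centered  # favorable = negative energy = upward
    fig, ax = plt.subplots(figsize=(0.45 * len(m) + 1, 2.6))
    _stack(ax, heights, baseline_split=True)
    lim = float(np.abs(heights).max()) * 1.05 or 1.0
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="black", lw=0.5)
    unit = "kBT" if m.units == "kBT" else "a.u."
    ax.set_ylabel(f"-energy ({unit})")
    ax.set_xlabel("position")
    fig.tight_layout()
    return fig


def write_logo_tsv(path, m: EnergyMatrix) -> None:
    """Underlying logo numbers: probabilities, information, letter heights."""
    bp = base_probabilities(m)
    rows = {"pos": np.arange(1, len(m) + 1), "information_bits": bp.information}
    for j, b in enumerate(ALPHABET):
        rows[f"prob_{b}"] = bp.probs[:, j]
    for j, b in enumerate(ALPHABET):
        rows[f"height_{b}"] = bp.letter_heights[:, j]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def save_logos(m: EnergyMatrix, prefix) -> list[str]:
    """Write information + energy logos (SVG) and the logo TSV; returns paths."""
    prefix = Path(prefix)
    out = []
    fig = information_logo_figure(m)
    p = prefix.with_suffix(".info.svg")
    fig.savefig(p)
    plt.close(fig)
    out.append(str(p))
    fig = energy_logo_figure(m)
    p = prefix.with_suffix(".energy.svg")
    fig.savefig(p)
    plt.close(fig)
    out.append(str(p))
    p = prefix.with_suffix(".logo.tsv")
    write_logo_tsv(p, m)
    out.append(str(p))
    return out
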