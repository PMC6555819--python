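"""Figure rendering: sequence logos, spacer landscapes, ROC curves.

Logos are information-content scaled: at each position the stack height
is the Kullback-Leibler information in bits and letters are stacked in
order of frequency.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .motifs import PFM, UNIFORM_BACKGROUND, information_content
from .sequences import DNA_ALPHABET

LETTER_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
_FONT = FontProperties(family="DejaVu Sans", weight="bold")


def _draw_letter(ax, letter, x, y, width, height):
    if height <= 0:
        return
    tp = TextPath((0, 0), letter, size=1.0, prop=_FONT)
    bb = tp.get_extents()
    transform = (
        Affine2D()
        .translate(-bb.x0, -bb.y0)
        .scale(width / bb.width, height / bb.height)
        .translate(x, y)
    )
    ax.add_patch(PathPatch(tp, transform=transform + ax.transData,
                           facecolor=LETTER_COLORS[letter], edgecolor="none"))


def plot_logo(pfm: PFM, background=UNIFORM_BACKGROUND, ax=None, title=None):
    """Information-content sequence logo of a PFM."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(3, pfm.length * 0.4), 2.2))
    info = information_content(pfm, background)
    for pos in range(pfm.length):
        y = 0.0
        order = np.argsort(pfm.probs[pos])
        for bi in order:
            h = pfm.probs[pos, bi] * info[pos]
            _draw_letter(ax, DNA_ALPHABET[bi], pos + 0.05, y, 0.9, h)
            y += h
    ax.set_xlim(0, pfm.length)
    ax.set_ylim(0, max(2.0, float(info.max()) if pfm.length else 2.0))
    ax.set_xticks(np.arange(pfm.length) + 0.5)
    ax.set_xticklabels(np.arange(1, pfm.length + 1), fontsize=7)
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title, fontsize=9)
    return ax


def plot_landscape(landscape, ax=None, title=None, rng_seed: int = 0):
    """Strip plot of per-seed zmax by spacer length, colored by mode."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    mode_colors = {"full": "#D62839", "5prime_half": "#255C99",
                   "3prime_half": "#109648", "none": "#AAAAAA"}
    rng = np.random.default_rng(rng_seed)
    for mode, grp in landscape.groupby("mode"):
        x = grp["spacer_len"] + rng.uniform(-0.25, 0.25, len(grp))
        ax.scatter(x, grp["zmax"], s=14, alpha=0.8,
                   color=mode_colors.get(mode, "black"), label=mode)
    ax.set_xlabel("spacer length (bp)")
    ax.set_ylabel("max z-score (seed + SNVs)")
    ax.set_xticks(sorted(landscape["spacer_len"].unique()))
    ax.legend(fontsize=7, frameon=False)
    if title:
        ax.set_title(title, fontsize=9)
    return ax


def plot_roc(results: dict, ax=None, title=None):
    """ROC curves with AUC annotations; ``results`` maps label -> ROCResult."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for label, res in results.items():
        ax.plot(res.curve["fpr"], res.curve["tpr"],
                label=f"{label} (AUC={res.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7, frameon=False)
    if title:
        ax.set_title(title, fontsize=9)
    return ax


def plot_concordance(profile_a, profile_b, r2: float, ax=None, title=None):
    """Scatter of per-sequence z-scores from two experiments."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    merged = profile_a.data[["sequence", "mean_z"]].merge(
        profile_b.data[["sequence", "mean_z"]], on="sequence",
        suffixes=("_a", "_b"))
    ax.scatter(merged["mean_z_a"], merged["mean_z_b"], s=4, alpha=0.4,
               color="#255C99")
    ax.set_xlabel("z-score (experiment A)")
    ax.set_ylabel("z-score (experiment B)")
    ax.annotate(f"$R^2$ = {r2:.3f}", xy=(0.05, 0.92), xycoords="axes fraction")
    if title:
        ax.set_title(title, fontsize=9)
    return ax
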