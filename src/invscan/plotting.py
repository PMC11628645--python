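"""Diagnostic plots: per-individual H_Ind segments and oriented PC1 profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .hetsplit import SegmentationResult
from .windowpca import WindowPCAProfile

__all__ = ["plot_het_segments", "plot_window_pc1"]


def plot_het_segments(segmentations: list[SegmentationResult], lg: int, ax=None):
    """Step plot of segment H_Ind means along one linkage group, one line per
    individual; bifurcations/trifurcations over a split cluster indicate an
    inversion."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for seg in segmentations:
        if seg.lg != lg:
            continue
        xs, ys = [], []
        for lo, hi, h in seg.segments:
            xs += [lo, hi]
            ys += [h, h]
        ax.plot(xs, ys, lw=0.8, alpha=0.5, color="steelblue")
    ax.set_xlabel("map position (cM)")
    ax.set_ylabel("$H_{Ind}$")
    ax.set_title(f"LG{lg} heterozygosity segments")
    return ax


def plot_window_pc1(profiles: list[WindowPCAProfile], ax=None):
    """Oriented PC1 scores per 1-cM window (one point column per window);
    three persistent score bands across consecutive windows indicate an
    inversion's karyotype clusters."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for prof in profiles:
        x = np.full(prof.pc1_scores.shape, prof.window + 0.5)
        ax.plot(x, prof.pc1_scores, ".", ms=2, alpha=0.5, color="darkorange")
    ax.set_xlabel("window (cM)")
    ax.set_ylabel("oriented PC1")
    return ax
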