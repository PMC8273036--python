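"""QC overlay figures: masks drawn over their source channels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import Channel, Mask


def _show(ax, ch: Channel, title: str) -> None:
    vmax = np.percentile(ch.values, 99.5) or 1.0
    ax.imshow(ch.values, cmap="gray", vmax=vmax)
    ax.set_title(title, fontsize=8)
    ax.set_axis_off()


def _contour(ax, mask: Mask, color: str) -> None:
    if mask.values.any():
        ax.contour(mask.values, levels=[0.5], colors=color, linewidths=0.6)


def save_recruitment_overlay(
    mtor: Channel,
    lamp1: Channel,
    in_mask: Mask,
    out_mask: Mask,
    dendrite_mask: Mask,
    path: "str | Path",
) -> None:
    """Write a two-panel PNG: LAMP1 with the IN mask, mTOR with IN (green),
    OUT ring (magenta) and dendrite outline (blue)."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), dpi=120)
    _show(axes[0], lamp1, "LAMP1 + IN mask")
    _contour(axes[0], in_mask, "lime")
    _show(axes[1], mtor, "mTOR + IN/OUT/dendrite")
    _contour(axes[1], in_mask, "lime")
    _contour(axes[1], out_mask, "magenta")
    _contour(axes[1], dendrite_mask, "deepskyblue")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_activity_overlay(
    pps6: Channel,
    map2_mask: Mask,
    soma_mask: Mask,
    path: "str | Path",
) -> None:
    """Write a PNG of the P-pS6 channel with the neuronal mask (blue) and
    soma mask (orange) outlined."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5), dpi=120)
    _show(ax, pps6, "P-pS6 + MAP2/soma masks")
    _contour(ax, map2_mask, "deepskyblue")
    _contour(ax, soma_mask, "orange")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
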