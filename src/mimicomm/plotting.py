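"""Quick-look figures: segmentation overlays, scan curves, kymographs.

All functions return the matplotlib figure and optionally write a PNG;
they are deliberately thin -- publication styling is left to the caller.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["segmentation_overlay", "radius_scan_curve", "kymograph_heatmap"]

_LABEL_COLORS = {
    "receiver": "tab:green",
    "star_sender": "tab:red",
    "trigger_sender": "magenta",
    "dual_sender": "tab:orange",
    "unclassified": "gray",
}


def segmentation_overlay(brightfield, records, path: str | Path | None = None):
    """Bright-field frame with detected circles coloured by class."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(brightfield, cmap="gray")
    for rec in records:
        ax.add_patch(
            plt.Circle(
                rec.center_px,
                rec.radius_px,
                fill=False,
                lw=1.2,
                color=_LABEL_COLORS.get(rec.label, "gray"),
            )
        )
    ax.set_axis_off()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def radius_scan_curve(scan, path: str | Path | None = None):
    """Mean correlation versus neighbourhood radius, one line per population."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for pop, r in scan.mean_r.items():
        ax.plot(scan.radii, r, marker="o", ms=3, label=pop.replace("_", " "))
    ax.axvline(scan.joint_argmax_um, color="k", ls="--", lw=0.8)
    ax.set_xlabel("neighbourhood radius (μm)")
    ax.set_ylabel("mean Pearson r")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def kymograph_heatmap(ky, path: str | Path | None = None):
    """Distance x time intensity matrix of radial activation."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    im = ax.pcolormesh(
        ky.timepoints_min / 60.0, ky.distances_mm, ky.intensity, shading="nearest"
    )
    fig.colorbar(im, ax=ax, label="sfGFP (a.u.)")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("distance from senders (mm)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
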