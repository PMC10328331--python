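"""Debug overlays and the cohort z-score heatmap."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["overlay_figure", "zscore_heatmap"]

_GLYPHS = ["*", "s", "^", "o"]  # one marker per dendrite index


def overlay_figure(intermediates: dict, title: str = ""):
    """ROI with finalized tracks (per-dendrite glyphs) and feature boxes."""
    roi = intermediates["roi"]
    tracks = intermediates["tracks"]
    features = intermediates["features"]
    fig, ax = plt.subplots(figsize=(5, 8))
    ax.imshow(roi.pixels, cmap="gray")
    eff_roi = roi.scale.effective
    for tr in tracks:
        factor = tr.scale.resize_factor // roi.scale.resize_factor
        r0, r1 = tr.span
        rows = np.arange(r0, r1 + 1)
        ax.plot(tr.x_of_y[rows] / factor, rows / factor, lw=1,
                marker=_GLYPHS[(tr.index - 1) % 4], markevery=max(1, len(rows) // 12),
                markersize=5, label=f"dendrite {tr.index}")
    for f in features:
        cy, cx = (v / eff_roi for v in f.centroid_um)
        half = f.max_caliper_um / eff_roi / 2
        ax.add_patch(plt.Rectangle((cx - half, cy - half), 2 * half, 2 * half,
                                   fill=False, edgecolor="red", lw=1))
    ax.set_title(title)
    ax.legend(fontsize=6, loc="lower right")
    ax.set_axis_off()
    fig.tight_layout()
    return fig


def zscore_heatmap(zframe: pd.DataFrame):
    """Groups x metrics heatmap of z-scores versus control."""
    pivot = zframe.pivot(index="group", columns="metric", values="z")
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * pivot.shape[1]),
                                    1 + 0.5 * pivot.shape[0]))
    vmax = np.nanmax(np.abs(pivot.to_numpy())) or 1.0
    im = ax.imshow(pivot.to_numpy(), cmap="coolwarm", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="z vs control")
    fig.tight_layout()
    return fig
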