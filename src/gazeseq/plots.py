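"""Path and density visualizations of gaze on a single face item."""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .layout import AOILayout

__all__ = ["PathRender", "render_paths"]


@dataclass
class PathRender:
    """Output of :func:`render_paths`: the file plus the density grid."""

    path: str
    density: np.ndarray  # (ny, nx) fixation-count histogram over the face box
    x_edges: np.ndarray
    y_edges: np.ndarray


def render_paths(
    records: pd.DataFrame,
    layout: AOILayout,
    item_id: str,
    out_path,
    bins: int = 40,
    dpi: int = 120,
) -> PathRender:
    """Two-panel figure for one item: ordered gaze points and a density map.

    Left: target-face fixations of every participant, colored by their
    temporal order within the participant.  Right: a 2-D histogram of
    fixation positions over the face box.  Output is deterministic for
    fixed input (fixed figure geometry, no timestamps).
    Raises ``ValueError`` if the item has no target fixations.
    """
    sel = records[
        (records["item"] == item_id) & (records["event_type"] == "target")
    ].sort_values(["participant", "t_onset_ms"], kind="mergesort")
    if len(sel) == 0:
        raise ValueError(f"no target fixations for item {item_id!r}")

    x0, y0, x1, y1 = layout.face_box
    hist, xe, ye = np.histogram2d(
        sel["x_px"], sel["y_px"], bins=bins, range=[[x0, x1], [y0, y1]]
    )

    fig, (ax_path, ax_heat) = plt.subplots(1, 2, figsize=(10, 5.5))
    for _, grp in sel.groupby("participant", sort=True):
        order = np.linspace(0, 1, len(grp))
        ax_path.plot(grp["x_px"], grp["y_px"], color="0.8", lw=0.4, zorder=1)
        ax_path.scatter(
            grp["x_px"], grp["y_px"], c=order, cmap="viridis", s=12, zorder=2
        )
    for ax in (ax_path, ax_heat):
        for z in layout.zones:
            ax.add_patch(
                plt.Rectangle(
                    (z.x_min, z.y_min),
                    z.x_max - z.x_min,
                    z.y_max - z.y_min,
                    fill=False,
                    edgecolor="crimson",
                    lw=1.0,
                )
            )
            ax.annotate(z.label, (z.x_min + 5, z.y_min + 18), color="crimson",
                        fontsize=8)
        ax.set_xlim(x0 - 50, x1 + 50)
        ax.set_ylim(y1 + 50, y0 - 50)  # screen coords: y down
        ax.set_xlabel("x (px)")
    ax_path.set_ylabel("y (px)")
    ax_path.set_title(f"{item_id}: fixations by temporal order")
    ax_heat.imshow(
        hist.T,
        extent=(x0, x1, y1, y0),
        cmap="magma",
        aspect="auto",
        interpolation="nearest",
    )
    ax_heat.set_title("fixation density")
    fig.tight_layout()
    fig.savefig(out_path, dpi=dpi, metadata={"Software": "gazeseq"})
    plt.close(fig)
    return PathRender(path=str(out_path), density=hist.T, x_edges=xe, y_edges=ye)
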