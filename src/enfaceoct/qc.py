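"""Quality-control rendering: sector-grid overlay on an enface slab."""

from __future__ import annotations

import numpy as np

from .geometry import SECTOR_NAMES, SECTOR_STARTS_DEG, SectorGrid
from .enface import EnfaceStack


def render_overlay(stack: EnfaceStack, grid: SectorGrid, path, slab: int = 0) -> None:
    """Write a PNG of one slab with the 3.5 mm circle and sector boundaries.

    Intended for visual QC of the geometry (center, tilt, laterality), not
    for analysis. Matplotlib is imported lazily so the core pipeline does
    not depend on it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    radius_px = grid.radius_um / stack.transverse_scale_um_per_px
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(stack.slabs[slab], cmap="gray", vmin=0, vmax=1)
    angles = np.linspace(0, 360, 721)
    rows, cols = grid.pixel_of_grid_angle(angles, radius_px)
    ax.plot(cols, rows, color="tab:green", lw=1.0)
    for name, start in zip(SECTOR_NAMES, SECTOR_STARTS_DEG):
        r0, c0 = grid.pixel_of_grid_angle(start, radius_px * 0.9)
        r1, c1 = grid.pixel_of_grid_angle(start, radius_px * 1.1)
        ax.plot([c0, c1], [r0, r1], color="tab:red", lw=1.0)
        rl, cl = grid.pixel_of_grid_angle(
            start + {"TMP": 45, "NAS": 55}.get(name, 20), radius_px * 1.18
        )
        ax.annotate(name, (cl, rl), color="tab:red", ha="center", va="center", fontsize=9)
    ax.set_title(f"slab {slab} ({slab * 3.87:.2f} um below ILM), {grid.laterality}")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
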