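"""Bullseye rendering of per-segment values on the AHA 16-segment model."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_bullseye"]

#: ring (outer to inner) and angular span of each AHA segment id
_RINGS = {**{i: 0 for i in range(1, 7)}, **{i: 1 for i in range(7, 13)}, **{i: 2 for i in range(13, 17)}}


def plot_bullseye(values: dict[int, float], title: str = "", cmap: str = "viridis", ax=None):
    """Polar bullseye of per-segment values.

    ``values`` maps AHA segment ids (1-16) to numbers (e.g. MBF in
    mL/min/mL); missing segments are drawn hatched.  Returns the axes.
    """
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    vals = [v for v in values.values() if v is not None]
    if not vals:
        raise ValueError("no segment values to plot")
    vmin, vmax = min(vals), max(vals)
    norm = matplotlib.colors.Normalize(vmin=vmin, vmax=vmax if vmax > vmin else vmin + 1)
    cm = matplotlib.colormaps[cmap]
    radii = [(2.0, 3.0), (1.0, 2.0), (0.0, 1.0)]  # basal, mid, apical rings
    for seg, ring in _RINGS.items():
        n_seg = 4 if ring == 2 else 6
        width = 2 * np.pi / n_seg
        k = (seg - (1, 7, 13)[ring]) % n_seg
        theta0 = np.pi / 2 - (k + 1) * width  # segment 1 starts at the top, clockwise
        r0, r1 = radii[ring]
        v = values.get(seg)
        color = cm(norm(v)) if v is not None else "white"
        hatch = None if v is not None else "//"
        ax.bar(
            theta0 + width / 2, r1 - r0, width=width, bottom=r0,
            color=color, edgecolor="black", linewidth=0.8, hatch=hatch,
        )
        if v is not None:
            ax.text(theta0 + width / 2, (r0 + r1) / 2, f"{v:.2f}", ha="center", va="center", fontsize=7)
    ax.set_ylim(0, 3)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cm)
    plt.colorbar(sm, ax=ax, shrink=0.7)
    return ax
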