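"""Contour-map rendering for t-s fields."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .tsmap import TSMap

__all__ = ["render_map"]


def render_map(field: TSMap, path: str | Path, a_overlay: TSMap | None = None,
               cmap: str = "viridis", levels: int = 20,
               trough_paths=None, title: str | None = None) -> Path:
    """Filled contour map in the t-s plane, optionally with A-contour overlay.

    Angle contours are drawn at 10-degree intervals; the 0/30/60/90-degree
    lines dashed and the 85-degree line dotted (the conventional styling for
    these maps), remaining lines solid.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    tt, ss = np.meshgrid(field.t, field.s, indexing="ij")
    vals = np.ma.masked_invalid(field.values)
    cf = ax.contourf(tt, ss, vals, levels=levels, cmap=cmap)
    fig.colorbar(cf, ax=ax, label=f"{field.name} [{field.units}]".strip(" []"))
    if a_overlay is not None:
        av = np.ma.masked_invalid(a_overlay.values)
        at, as_ = np.meshgrid(a_overlay.t, a_overlay.s, indexing="ij")
        lo = np.floor(np.nanmin(a_overlay.values) / 10) * 10
        hi = np.ceil(np.nanmax(a_overlay.values) / 10) * 10
        lv = np.arange(lo, hi + 1, 10.0)
        solid = [v for v in lv if v not in (0.0, 30.0, 60.0, 90.0)]
        if solid:
            ax.contour(at, as_, av, levels=solid, colors="k", linewidths=0.7)
        dashed = [v for v in (0.0, 30.0, 60.0, 90.0) if lo <= v <= hi]
        if dashed:
            ax.contour(at, as_, av, levels=dashed, colors="k",
                       linewidths=0.9, linestyles="dashed")
        if lo <= 85.0 <= hi:
            ax.contour(at, as_, av, levels=[85.0], colors="k",
                       linewidths=0.9, linestyles="dotted")
    if trough_paths:
        for p in trough_paths:
            ax.plot(p.t, p.s, "k-", lw=2.2)
    ax.set_xlabel("t (h)")
    ax.set_ylabel("s (mm)")
    ax.set_title(title or field.name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
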