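"""Map rendering for correlation and superposed-epoch results.

Minimal matplotlib renderings: a signed correlation field with
significant cells stippled, and SEA composite-anomaly panels per month.
Axes are plain lat/lon degrees — no projection, no coastlines — which
is enough to eyeball a centre of action.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fieldstats import CorrelationMap, SEAResult

__all__ = ["plot_correlation_map", "plot_sea"]


def plot_correlation_map(cmap: CorrelationMap, path: str | Path,
                         title: str | None = None) -> None:
    """Render r as a diverging field, stippling cells with p ≤ alpha."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    mesh = ax.pcolormesh(cmap.lon, cmap.lat, cmap.r, cmap="RdBu_r",
                         vmin=-1, vmax=1, shading="nearest")
    sig_lat, sig_lon = np.where(cmap.p_adj <= cmap.alpha)
    if sig_lat.size:
        ax.plot(cmap.lon[sig_lon], cmap.lat[sig_lat], ".k", ms=1.5, alpha=0.6)
    fig.colorbar(mesh, ax=ax, label="Pearson r")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title or
                 f"months {list(cmap.months)} — "
                 f"{100 * cmap.frac_significant:.1f}% significant, "
                 f"field p = {cmap.p_field:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sea(res: SEAResult, path: str | Path, alpha: float = 0.1) -> None:
    """One composite-anomaly panel per month, significant cells stippled."""
    n = len(res.months)
    vmax = float(np.nanmax(np.abs(res.composite_anom))) or 1.0
    fig, axes = plt.subplots(1, n, figsize=(5.5 * n, 4), squeeze=False)
    for k, month in enumerate(res.months):
        ax = axes[0, k]
        mesh = ax.pcolormesh(res.lon, res.lat, res.composite_anom[k],
                             cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                             shading="nearest")
        sig_lat, sig_lon = np.where(res.p[k] <= alpha)
        if sig_lat.size:
            ax.plot(res.lon[sig_lon], res.lat[sig_lat], ".k", ms=1.5, alpha=0.6)
        ax.set_title(f"month {month}")
        fig.colorbar(mesh, ax=ax)
    fig.suptitle(f"composite over events {res.event_years.tolist()}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
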