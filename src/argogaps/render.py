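"""Map rendering.  Analysis is done on the geographic lattice with exact
spherical areas; the equal-area Mollweide projection is applied here only
to draw maps, never to resample data."""

from __future__ import annotations

import numpy as np

from .grid import GlobalGrid


def mollweide_xy(lon_deg, lat_deg, radius: float = 1.0,
                 tol: float = 1e-10, max_iter: int = 50):
    """Forward Mollweide projection of lon/lat degrees (Newton iteration)."""
    lam = np.deg2rad(np.asarray(lon_deg, dtype=float))
    phi = np.deg2rad(np.asarray(lat_deg, dtype=float))
    theta = np.array(phi, copy=True)
    target = np.pi * np.sin(phi)
    for _ in range(max_iter):
        f = 2 * theta + np.sin(2 * theta) - target
        df = 2 + 2 * np.cos(2 * theta)
        step = np.where(np.abs(df) > 1e-12, f / np.maximum(df, 1e-12), 0.0)
        theta = theta - step
        if np.max(np.abs(step)) < tol:
            break
    x = radius * (2 * np.sqrt(2) / np.pi) * lam * np.cos(theta)
    y = radius * np.sqrt(2) * np.sin(theta)
    return x, y


def render_map(raster: np.ndarray, grid: GlobalGrid, path,
               projection: str = "mollweide", cmap: str = "viridis",
               title: str | None = None, vmin=None, vmax=None) -> str:
    """Render a raster to an image file; the raster itself is never modified."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lon_c, lat_c = np.meshgrid(grid.lon_edges, grid.lat_edges)
    if projection == "mollweide":
        x, y = mollweide_xy(lon_c, lat_c)
    elif projection in ("plate-carree", "platecarree"):
        x, y = lon_c, lat_c
    else:
        raise ValueError(f"unknown projection {projection!r}")
    fig, ax = plt.subplots(figsize=(10, 5))
    pm = ax.pcolormesh(x, y, np.asarray(raster, dtype=float),
                       cmap=cmap, vmin=vmin, vmax=vmax, shading="flat")
    fig.colorbar(pm, ax=ax, shrink=0.7)
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return str(path)
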