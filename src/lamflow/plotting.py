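"""Laminar heatmap plots.  Warm colours mark current sinks."""

from __future__ import annotations

import numpy as np


def plot_csd_heatmap(csd, times_ms=None, ax=None, depths_mm=None):
    """Heatmap of a channel x time CSD, warm = sink (negative CSD).

    Returns the matplotlib Axes.  Sinks (negative values) are plotted warm
    by mapping -CSD onto a diverging colormap, following the field's
    convention for laminar CSD figures.
    """
    import matplotlib.pyplot as plt

    values = csd.values if hasattr(csd, "values") else np.asarray(csd)
    t = times_ms
    if t is None and hasattr(csd, "times_ms"):
        t = csd.times_ms
    if ax is None:
        _, ax = plt.subplots()
    vmax = np.nanmax(np.abs(values))
    extent = None
    if t is not None:
        d0, d1 = (0, values.shape[0]) if depths_mm is None else (
            depths_mm[0], depths_mm[-1]
        )
        extent = (t[0], t[-1], d0, d1)
    im = ax.imshow(
        -values,
        aspect="auto",
        origin="lower",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        extent=extent,
    )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("depth" + ("" if depths_mm is None else " (mm)"))
    ax.figure.colorbar(im, ax=ax, label="-CSD (warm = sink)")
    return ax


def plot_laminar_profile(rel_depth_mm, values, ax=None, **kwargs):
    """Profile of a per-depth quantity against relative depth."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(values, rel_depth_mm, **kwargs)
    ax.axhline(0.0, color="k", lw=0.5, ls="--")
    ax.set_ylabel("depth re 4C/5 boundary (mm)")
    return ax
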