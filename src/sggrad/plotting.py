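"""Quick-look plots of fields and trajectories (matplotlib optional)."""

from __future__ import annotations

import numpy as np


def plot_field(field, ax=None, **imshow_kw):
    """Heat map of the attractant concentration with axes in um."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    w, h = field.extent
    kw = dict(origin="lower", extent=(0, w, 0, h), cmap="viridis")
    kw.update(imshow_kw)
    im = ax.imshow(field.concentrations, **kw)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.figure.colorbar(im, ax=ax, label="attractant (nM)")
    return ax


def plot_trajectories(traj, ax=None, color_by_time=True):
    """All cell tracks; optionally colored by time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    reg = traj[traj["event"] == "none"]
    for _, track in reg.groupby("cell_id"):
        if color_by_time:
            t = track["time_s"].values
            ax.scatter(track["x_um"], track["y_um"], c=t, s=1,
                       cmap="plasma", vmin=0, vmax=reg["time_s"].max())
        else:
            ax.plot(track["x_um"], track["y_um"], lw=0.5, alpha=0.6)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    return ax


def plot_run(result, path=None):
    """Final field with trajectories overlaid; saves to ``path`` if given."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    plot_field(result.field, ax=ax)
    reg = result.trajectory[result.trajectory["event"] == "none"]
    end = reg["time_s"].max()
    last = reg[reg["time_s"] == end]
    for _, track in reg.groupby("cell_id"):
        ax.plot(track["x_um"], track["y_um"], color="w", lw=0.4, alpha=0.5)
    ax.plot(last["x_um"], last["y_um"], "wo", ms=2)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
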