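"""Heatmap of the per-column conservation profile.

Two stacked single-row heatmaps over alignment columns — residue identity
on top, amyloid fraction below — with gap-masked columns left blank, the
layout conventional for family-conservation figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .projection import ColumnProfile


def profile_heatmap(profile: ColumnProfile, path: str | Path) -> None:
    identity = np.where(profile.masked, np.nan, profile.identity)
    amyloid = np.where(profile.masked, np.nan, profile.amyloid_fraction)
    data = np.vstack([identity, amyloid])
    fig, ax = plt.subplots(figsize=(max(6.0, profile.n_columns / 120), 1.8))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("white")
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=1,
                   interpolation="nearest")
    ax.set_yticks([0, 1], ["identity", "amyloid fraction"])
    ax.set_xlabel("alignment column")
    fig.colorbar(im, ax=ax, fraction=0.025, pad=0.01)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
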