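"""Convenience raincloud-style plots of per-group metric distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .groupstats import GROUPS

GROUP_COLORS = {"OCD": "#2ca02c", "AC": "#1f77b4", "HC": "#d62728"}


def raincloud(cohort: pd.DataFrame, metric: str, path: str | Path | None = None,
              seed: int = 0):
    """Half-violin + box + jittered points per group for one metric."""
    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(seed)
    present = [g for g in GROUPS if g in set(cohort["group"])]
    for i, g in enumerate(present):
        vals = cohort.loc[cohort["group"] == g, metric].to_numpy(float)
        color = GROUP_COLORS.get(g, "gray")
        parts = ax.violinplot(vals, positions=[i], showextrema=False, widths=0.8)
        for body in parts["bodies"]:
            body.set_facecolor(color)
            body.set_alpha(0.3)
            # keep only the upper half of the violin
            verts = body.get_paths()[0].vertices
            verts[:, 0] = np.clip(verts[:, 0], i, None)
        ax.boxplot(vals, positions=[i], widths=0.12, showfliers=False)
        ax.scatter(i - 0.22 + rng.uniform(-0.06, 0.06, vals.size), vals,
                   s=12, color=color, alpha=0.7)
    ax.set_xticks(range(len(present)))
    ax.set_xticklabels(present)
    ax.set_ylabel(f"{metric} (Fisher z)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
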