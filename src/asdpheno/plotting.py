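"""Figure helpers: cohort/cluster scatter of the 2-D embedding and the
per-cluster DSM-5 radar chart."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dsm5 import DISPLAY_NAMES, PROFILE_CRITERIA


def plot_clusters(
    coordinates: Mapping[str, tuple[float, float]],
    labels: Mapping[str, int | str],
    path: str | Path,
    title: str = "Patient clusters (t-SNE of NMF loadings)",
) -> None:
    """Scatter of the 2-D patient embedding, colored by cluster or cohort."""
    fig, ax = plt.subplots(figsize=(6, 5))
    groups: dict = {}
    for pid, xy in coordinates.items():
        groups.setdefault(labels.get(pid, "?"), []).append(xy)
    for key in sorted(groups, key=str):
        xy = np.asarray(groups[key])
        ax.scatter(xy[:, 0], xy[:, 1], s=6, alpha=0.6, label=str(key))
    ax.legend(markerscale=2, fontsize=8)
    ax.set_title(title)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_radar(radar: pd.DataFrame, path: str | Path) -> None:
    """Radar chart of per-cluster criterion percentages (rows = clusters)."""
    crits: Sequence[str] = [c for c in PROFILE_CRITERIA if c in radar.columns]
    angles = np.linspace(0, 2 * np.pi, len(crits), endpoint=False)
    angles = np.concatenate([angles, angles[:1]])
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"polar": True})
    for cluster, row in radar.iterrows():
        vals = row[list(crits)].to_numpy(dtype=float)
        vals = np.concatenate([vals, vals[:1]])
        ax.plot(angles, vals, label=f"cluster {cluster}")
        ax.fill(angles, vals, alpha=0.08)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels([f"{c}\n{DISPLAY_NAMES[c]}" for c in crits], fontsize=7)
    ax.set_ylim(0, 100)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
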