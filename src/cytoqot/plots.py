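"""Minimal plotting helpers for the two analyses and the benchmark."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import timepoint_key  # noqa: E402
from .qot import DistanceMatrix  # noqa: E402


def plot_distance_heatmap(dm: DistanceMatrix, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(dm.values, cmap="Blues")
    ax.set_xticks(range(len(dm.sample_ids)))
    ax.set_yticks(range(len(dm.sample_ids)))
    ax.set_xticklabels(dm.sample_ids, rotation=90, fontsize=7)
    ax.set_yticklabels(dm.sample_ids, fontsize=7)
    fig.colorbar(im, ax=ax, label="QOT distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_subject_loo(records, path) -> None:
    """Per-subject line plot: baseline distance per timepoint, full vs
    each leave-one-out panel."""
    full = next(r for r in records if r.excluded_marker is None)
    tps = sorted(full.distances, key=timepoint_key)
    fig, ax = plt.subplots(figsize=(6, 4))
    for r in records:
        if r.excluded_marker is None:
            continue
        ax.plot(tps, [r.distances[t] for t in tps], alpha=0.5, lw=1,
                label=f"w/o {r.excluded_marker}")
    ax.plot(tps, [full.distances[t] for t in tps], color="black", lw=2.5,
            label="all markers")
    ax.set_xlabel("timepoint")
    ax.set_ylabel("distance from baseline")
    ax.set_title(full.subject_id)
    if len(records) <= 13:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rank_frequency(rank_summary, path, top_ranks: int = 3) -> None:
    """Bar chart of how often each marker lands at the top perturbation
    ranks across the cohort."""
    freq = rank_summary.rank_frequency
    ranks = list(freq.columns[:top_ranks])
    x = np.arange(len(freq.index))
    width = 0.8 / len(ranks)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, r in enumerate(ranks):
        ax.bar(x + i * width, freq[r].to_numpy(), width, label=f"Rank {r}")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(freq.index, rotation=90, fontsize=7)
    ax.set_ylabel("fraction of subjects")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_silhouette_by_size(scores, path) -> None:
    """Violin of silhouette scores per subset size."""
    sizes = sorted({s.subset_size for s in scores if not s.failed})
    data = [[s.silhouette for s in scores
             if s.subset_size == k and not s.failed] for k in sizes]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(data, positions=sizes, showmedians=True)
    ax.set_xlabel("markers per subset")
    ax.set_ylabel("silhouette (subject labels)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
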