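"""Optional figures: per-tRNA coverage panels and the stage heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .expression_profiles import HeatmapMatrix, StageProfile

__all__ = ["plot_coverage", "plot_heatmap"]


def plot_coverage(profiles: dict[str, StageProfile], path: str | Path) -> None:
    """One panel per stage: normalized coverage along the mature tRNA."""
    stages = list(profiles)
    fig, axes = plt.subplots(
        len(stages), 1, figsize=(6, 1.2 * len(stages)), sharex=True, sharey=True
    )
    peak = max(p.coverage.max() for p in profiles.values()) or 1.0
    for ax, stage in zip(np.atleast_1d(axes), stages):
        cov = profiles[stage].coverage
        ax.fill_between(np.arange(1, len(cov) + 1), cov, step="mid", color="#4a6fa5")
        ax.set_ylim(0, peak * 1.05)
        ax.set_ylabel(stage, rotation=0, ha="right", va="center", fontsize=8)
    np.atleast_1d(axes)[-1].set_xlabel("mature tRNA position (5' to 3')")
    fig.suptitle(next(iter(profiles.values())).gene_id, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(matrix: HeatmapMatrix, row_order: list[int], path: str | Path) -> None:
    """Row-relative expression of top variants across the six stages."""
    if matrix.values.shape[0] == 0:
        return
    values = matrix.values[row_order]
    labels = [matrix.row_labels[i] for i in row_order]
    fig, ax = plt.subplots(
        figsize=(4, 0.22 * len(labels) + 1.2), constrained_layout=True
    )
    im = ax.imshow(values, aspect="auto", cmap="RdYlGn_r", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.stage_order)), matrix.stage_order, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=5)
    fig.colorbar(im, ax=ax, label="relative normalized reads", shrink=0.6)
    fig.savefig(path, dpi=120)
    plt.close(fig)
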