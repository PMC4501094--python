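"""Spike-in normalization, positional coverage, heatmaps and clustering.

Libraries are normalized with two spike-in RNAs added at controlled
amounts: each stage's factor anchors its spike sum to the geometric mean
of all six spike sums, so normalization is scale-free and preserves
within-stage read-count ratios exactly.  Normalized tRF counts feed
per-position coverage profiles along each parental tRNA, a top-variant
heatmap matrix (row-relative, in [0, 1]) ordered by hierarchical
clustering with Cluster-3.0-compatible uncentered correlation, and a
coarse developmental-trend labelling of each variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

from .trf_mapping import TRFRecord
from .trna_catalog import MatureTRNA

__all__ = [
    "normalization_factors",
    "spike_counts_from_unique_reads",
    "StageProfile",
    "positional_coverage",
    "HeatmapMatrix",
    "heatmap_matrix",
    "cluster_rows",
    "expression_trend",
]


def normalization_factors(spike_counts: Mapping[str, Sequence[float]]) -> pd.Series:
    """Per-stage normalization factors from spike-in counts.

    ``spike_counts`` maps stage -> counts of the individual spikes.  With
    spikesum_s the per-stage total and K the geometric mean of all stage
    sums, factor_s = K / spikesum_s; a normalized count is raw x factor.
    All-equal spike sums give factors of exactly 1.
    """
    stages = list(spike_counts)
    sums = np.array([float(sum(spike_counts[s])) for s in stages])
    if (sums <= 0).any():
        bad = [s for s, v in zip(stages, sums) if v <= 0]
        raise ValueError(f"zero spike-in sum in stage(s): {', '.join(bad)}")
    K = float(np.exp(np.log(sums).mean()))
    return pd.Series(K / sums, index=stages, name="factor")


def spike_counts_from_unique_reads(
    unique_reads: Iterable, spikes: Sequence[str], stage_order: Sequence[str]
) -> dict[str, tuple[int, ...]]:
    """Count the two spike sequences per stage among unique reads."""
    by_seq = {r.sequence: r.counts for r in unique_reads}
    return {
        stage: tuple(
            by_seq.get(spike, tuple(0 for _ in stage_order))[i]
            for spike in spikes
        )
        for i, stage in enumerate(stage_order)
    }


@dataclass
class StageProfile:
    """Normalized per-position coverage of one parent tRNA in one stage."""

    gene_id: str
    stage: str
    coverage: np.ndarray  # length L, 1-based position p at index p-1

    @property
    def total(self) -> float:
        return float(self.coverage.sum())


def positional_coverage(
    trfs: Sequence[TRFRecord],
    parent: MatureTRNA,
    factors: pd.Series,
    stage_order: Sequence[str],
) -> dict[str, StageProfile]:
    """Per-stage coverage vectors along one mature tRNA (CCA included).

    Coverage at position p is the sum of normalized counts of all tRFs
    whose span on this parent covers p.
    """
    L = parent.length
    profiles = {
        stage: StageProfile(parent.gene_id, stage, np.zeros(L)) for stage in stage_order
    }
    for trf in trfs:
        span = trf.span_on(parent.gene_id)
        if span is None:
            continue
        start, end = span
        for si, stage in enumerate(stage_order):
            profiles[stage].coverage[start - 1 : end] += trf.counts[si] * factors[stage]
    return profiles


def coverage_frame(profiles: dict[str, StageProfile]) -> pd.DataFrame:
    """Position x stage coverage table (1-based position index)."""
    stages = list(profiles)
    L = len(next(iter(profiles.values())).coverage)
    return pd.DataFrame(
        {stage: profiles[stage].coverage for stage in stages},
        index=pd.RangeIndex(1, L + 1, name="position"),
    )


@dataclass
class HeatmapMatrix:
    """Row-relative normalized counts of top tRF variants across stages."""

    values: np.ndarray  # rows x 6, each row max 1 unless all-zero
    row_labels: list[str]
    stage_order: tuple[str, ...]
    zero_rows: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=list(self.stage_order)
        )


def heatmap_matrix(
    variants: Sequence[TRFRecord],
    factors: pd.Series,
    stage_order: Sequence[str],
    labels: Sequence[str] | None = None,
) -> HeatmapMatrix:
    """Relative expression matrix: normalized stage counts / row maximum.

    All-zero rows stay zero and are flagged in ``zero_rows``.
    """
    fvec = np.array([factors[s] for s in stage_order])
    values = np.array([np.asarray(v.counts, dtype=float) * fvec for v in variants])
    if values.size == 0:
        values = values.reshape(0, len(stage_order))
    zero_rows = []
    for i in range(values.shape[0]):
        peak = values[i].max()
        if peak > 0:
            values[i] /= peak
        else:
            zero_rows.append(i)
    if labels is None:
        labels = [
            f"{v.anticodon}|{v.sequence[:12]}..{len(v.sequence)}nt" for v in variants
        ]
    return HeatmapMatrix(
        values=values,
        row_labels=list(labels),
        stage_order=tuple(stage_order),
        zero_rows=zero_rows,
    )


def uncentered_correlation_distance(rows: np.ndarray) -> np.ndarray:
    """Condensed distance matrix of 1 - uncentered correlation.

    The uncentered correlation (Cluster 3.0's default similarity) of x, y
    is sum(x*y) / sqrt(sum(x^2) * sum(y^2)); all-zero rows are treated as
    orthogonal to everything and identical to each other.
    """
    n = rows.shape[0]
    norms = np.sqrt((rows ** 2).sum(axis=1))
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 and norms[j] == 0:
                sim = 1.0
            elif norms[i] == 0 or norms[j] == 0:
                sim = 0.0
            else:
                sim = float(rows[i] @ rows[j] / (norms[i] * norms[j]))
            out.append(1.0 - sim)
    return np.array(out)


def cluster_rows(matrix: HeatmapMatrix) -> tuple[list[int], "hierarchy.ClusterNode | None"]:
    """Average-linkage hierarchical clustering of heatmap rows.

    Distance is 1 - uncentered correlation.  Returns the deterministic
    leaf ordering (original row indices) and the dendrogram root; with
    fewer than two rows the identity ordering and no tree.
    """
    n = matrix.values.shape[0]
    if n < 2:
        return list(range(n)), None
    dists = uncentered_correlation_distance(matrix.values)
    linkage = hierarchy.linkage(np.clip(dists, 0.0, None), method="average")
    root = hierarchy.to_tree(linkage)
    order = hierarchy.leaves_list(linkage).tolist()
    return order, root


def dendrogram_newick(root, labels: Sequence[str]) -> str:
    """Serialize a scipy cluster tree to Newick with branch lengths."""
    if root is None:
        return ";"

    def render(node) -> str:
        if node.is_leaf():
            return _escape(labels[node.id])
        left, right = node.get_left(), node.get_right()
        parts = [
            f"{render(child)}:{max(node.dist - child.dist, 0.0):.6g}"
            for child in (left, right)
        ]
        return f"({','.join(parts)})"

    return render(root) + ";"


def _escape(label: str) -> str:
    for ch in "(),:;'\" ":
        label = label.replace(ch, "_")
    return label


def expression_trend(
    values: Sequence[float],
    *,
    rho_threshold: float = 0.8,
    egg_share: float = 0.5,
) -> str:
    """Coarse developmental trend of one variant's six stage values.

    Precedence: 'egg' when the egg (first-stage) value exceeds
    ``egg_share`` of the total; then 'increasing'/'decreasing' when the
    Spearman rank correlation with stage index passes +/-
    ``rho_threshold``; otherwise 'other'.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] != 6:
        raise ValueError("expression_trend expects exactly six stage values")
    total = v.sum()
    if total <= 0:
        return "other"
    if v[0] > egg_share * total:
        return "egg"
    rho = spearmanr(v, np.arange(6)).statistic
    if np.isnan(rho):
        return "other"
    if rho >= rho_threshold:
        return "increasing"
    if rho <= -rho_threshold:
        return "decreasing"
    return "other"
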