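"""OTU clustering at distance thresholds and threshold sweeps.

Agglomerative clustering under nearest (single), average (UPGMA-style) or
furthest (complete) linkage: merge the closest cluster pair while the
linkage distance is at or below the threshold.  Merge order is fully
deterministic — lowest distance first, ties broken by the lexicographically
smallest (smallest-member-id, smallest-member-id) pair — so partitions are
platform-stable.  The loop is written out rather than delegated because the
tie rule is part of the contract; sequence sets here are tens of items.

Linkages coarsen in the order nearest <= average <= furthest cluster counts
at every threshold, and the partition at a smaller threshold refines the
partition at a larger one under the same linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

LINKAGES = ("nearest", "average", "furthest")


@dataclass
class OTUPartition:
    threshold: float
    linkage: str
    assignment: dict[str, int]  # id -> contiguous cluster index from 0

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for seq_id, idx in self.assignment.items():
            out.setdefault(idx, []).append(seq_id)
        return [sorted(out[i]) for i in sorted(out)]


def _linkage_distance(
    values: np.ndarray, a: list[int], b: list[int], linkage: str
) -> float:
    block = values[np.ix_(a, b)]
    if linkage == "nearest":
        return float(block.min())
    if linkage == "furthest":
        return float(block.max())
    if linkage == "average":
        return float(block.mean())
    raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")


def cluster_at_threshold(
    matrix: DistanceMatrix, threshold: float, linkage: str = "average"
) -> OTUPartition:
    """Agglomerate while the minimum inter-cluster linkage distance is
    <= ``threshold``; identical sequences (distance 0) merge at threshold 0."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    labels = matrix.labels
    values = matrix.values
    clusters: list[list[int]] = [[i] for i in range(len(labels))]

    while len(clusters) > 1:
        best = None  # (distance, tie_key, i, j)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _linkage_distance(values, clusters[i], clusters[j], linkage)
                key = tuple(
                    sorted(
                        (
                            min(labels[k] for k in clusters[i]),
                            min(labels[k] for k in clusters[j]),
                        )
                    )
                )
                cand = (d, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        assert best is not None
        d, _, i, j = best
        if d > threshold:
            break
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]

    # contiguous indices ordered by first appearance in the matrix labels
    clusters.sort(key=min)
    assignment = {
        labels[member]: idx for idx, cl in enumerate(clusters) for member in cl
    }
    return OTUPartition(threshold=threshold, linkage=linkage, assignment=assignment)


def threshold_sweep(
    matrix: DistanceMatrix, grid: Sequence[float], linkage: str = "average"
) -> pd.DataFrame:
    """Cluster counts along an ascending threshold grid.

    Counts are non-increasing in the threshold (partition refinement).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if sorted(grid) != grid:
        raise ValueError("threshold grid must be sorted ascending")
    rows = [
        (t, linkage, cluster_at_threshold(matrix, t, linkage).n_clusters) for t in grid
    ]
    return pd.DataFrame(rows, columns=["threshold", "linkage", "n_clusters"])


DEFAULT_GRID = tuple(np.round(np.arange(0.0, 0.251, 0.01), 4))


def single_cluster_threshold(
    matrix: DistanceMatrix,
    linkage: str = "average",
    grid: Sequence[float] = DEFAULT_GRID,
) -> float:
    """Smallest grid threshold whose partition is a single cluster.

    If no grid value suffices, 1.0 is returned (every distance is <= 1, so a
    single cluster is guaranteed there).  Under furthest linkage with a fine
    grid this equals the maximum pairwise distance rounded up to the grid.
    """
    grid = list(grid)
    if sorted(grid) != grid:
        raise ValueError("threshold grid must be sorted ascending")
    for t in grid:
        if cluster_at_threshold(matrix, t, linkage).n_clusters == 1:
            return float(t)
    return 1.0
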