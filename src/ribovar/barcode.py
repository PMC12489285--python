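"""DNA barcode-gap statistics per species and conspecific thresholds.

A species shows a *barcode gap* when its maximum intraspecific (conspecific)
pairwise distance lies below its minimum distance to any non-conspecific
sequence (the "nearest non-conspecific" statistic).  Because no single gene
can be assumed to show a gap for every species, the module also computes an
*indicative conspecific threshold*: the q-quantile (default 0.95, order
statistic, no interpolation) of all conspecific pairwise distances — "q of
conspecific pairs differ by at most this much".

Singleton species carry an undefined (NaN) max_intra and no gap verdict but
still contribute to the min_inter of other species.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix


def _pair_masks(matrix: DistanceMatrix, species_labels: dict[str, str]):
    missing = set(matrix.labels) - set(species_labels)
    if missing:
        raise ValueError(f"unlabelled ids: {sorted(missing)}")
    species = np.array([species_labels[i] for i in matrix.labels])
    iu = np.triu_indices(len(matrix.labels), k=1)
    same = species[iu[0]] == species[iu[1]]
    return species, iu, same


def partition_distances(
    matrix: DistanceMatrix, species_labels: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Split all unordered pairwise distances into (conspecific,
    heterospecific) lists; every pair lands in exactly one."""
    _, iu, same = _pair_masks(matrix, species_labels)
    vals = matrix.values[iu]
    return vals[same], vals[~same]


def gap_table(matrix: DistanceMatrix, species_labels: dict[str, str]) -> pd.DataFrame:
    """One row per species: n, max_intra, min_inter, gap verdict.

    min_inter is the spider-style nearest non-conspecific distance: the
    minimum over members of the minimum distance to any other species.
    """
    species, _, _ = _pair_masks(matrix, species_labels)
    if len(set(species)) < 2:
        raise ValueError("gap analysis needs at least 2 species")
    rows = []
    for sp in sorted(set(species)):
        mask = species == sp
        idx = np.nonzero(mask)[0]
        other = np.nonzero(~mask)[0]
        if len(idx) >= 2:
            sub = matrix.values[np.ix_(idx, idx)]
            max_intra = float(sub[np.triu_indices(len(idx), k=1)].max())
        else:
            max_intra = math.nan
        min_inter = float(matrix.values[np.ix_(idx, other)].min())
        gap = (min_inter > max_intra) if not math.isnan(max_intra) else pd.NA
        rows.append((sp, int(len(idx)), max_intra, min_inter, gap))
    return pd.DataFrame(
        rows, columns=["species", "n", "max_intra", "min_inter", "gap"]
    )


def conspecific_threshold(
    matrix: DistanceMatrix, species_labels: dict[str, str], q: float = 0.95
) -> float:
    """Smallest distance d such that at least a fraction ``q`` of conspecific
    pairs have distance <= d (order statistic, no interpolation)."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    intra, _ = partition_distances(matrix, species_labels)
    if len(intra) == 0:
        raise ValueError("no conspecific pairs")
    ordered = np.sort(intra)
    k = math.ceil(q * len(ordered))
    return float(ordered[k - 1])
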