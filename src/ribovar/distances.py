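"""Pairwise distances on aligned rDNA/gene sequences with explicit gap rules.

The dissimilarity used throughout is the "each-gap" convention of mothur's
``dist.seqs`` with ``calc=eachgap, countends=F``: within the mutually covered
span (terminal gaps ignored), every column where the two sequences differ —
including a base against a gap — counts as one difference; columns gapped in
both, and columns with N in either sequence, are excluded from numerator and
denominator.  The N rule is the conservative choice for ambiguous bases and
is recorded in :class:`DistanceMatrix.convention`.

Distances are fractions in [0, 1].  They are symmetric and zero on identical
input but are *not* guaranteed to satisfy the triangle inequality (gap
conventions can violate it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord

EACHGAP_CONVENTION = "eachgap,countends=F,N-columns-excluded"

DEFAULT_SCORES = (1.0, -1.0, -2.0, -1.0)  # match, mismatch, gap open, gap extend


@dataclass
class AlignedSet:
    """Equal-length gapped sequences, optionally labelled by strain/species."""

    records: list[SequenceRecord]
    labels: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("AlignedSet requires at least one record")
        width = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != width:
                raise ValueError(
                    f"record {rec.id!r} has length {len(rec.residues)}, expected {width}"
                )
            if set(rec.residues) == {"-"}:
                raise ValueError(f"record {rec.id!r} is all gaps")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in AlignedSet")

    @property
    def width(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus the gap convention that made them."""

    labels: list[str]
    values: np.ndarray
    convention: str = EACHGAP_CONVENTION
    # pairs with zero comparable columns (distance reported as 0, flagged)
    zero_overlap_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(i) for i in ids]
        return DistanceMatrix(
            labels=list(ids),
            values=self.values[np.ix_(idx, idx)],
            convention=self.convention,
        )

    def to_square_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        with open(path, "w") as fh:
            fh.write(f"# convention: {self.convention}\n")
            frame.to_csv(fh, sep="\t", index_label="id")

    def to_column_tsv(self, path: str | Path) -> None:
        """Lower-triangle 'column' format: idA, idB, distance (mothur style)."""
        with open(path, "w") as fh:
            fh.write(f"# convention: {self.convention}\n")
            for i in range(1, len(self.labels)):
                for j in range(i):
                    fh.write(
                        f"{self.labels[i]}\t{self.labels[j]}\t{self.values[i, j]:.6f}\n"
                    )


class EachGapResult(NamedTuple):
    distance: float
    n_diff: int
    n_compared: int
    zero_overlap: bool


def percent(value: float, decimals: int = 1) -> float:
    """Fraction -> percent, rounded half-away-from-zero to ``decimals``.

    Raw fractions are always retained alongside in reports; this is only the
    human-facing rendering.
    """
    q = Decimal(10) ** -decimals
    # round on the shortest decimal rendering so printed halves (e.g. 4.55)
    # go away from zero instead of following binary representation noise
    return float(Decimal(repr(value * 100)).quantize(q, rounding=ROUND_HALF_UP))


def align_pair(
    a: str, b: str, scores: tuple[float, float, float, float] = DEFAULT_SCORES
) -> tuple[str, str, float]:
    """Optimal global pairwise alignment under affine-gap scoring.

    ``scores`` is (match, mismatch, gap_open, gap_extend); match must be
    positive and the penalties non-positive.  Ties are broken
    deterministically (first optimal path of the aligner's canonical
    ordering).  Empty sequences align against all gaps.
    Returns (aligned_a, aligned_b, score).
    """
    match, mismatch, gap_open, gap_extend = scores
    if match <= 0 or mismatch > 0 or gap_open > 0 or gap_extend > 0:
        raise ValueError(
            "invalid scores: need match > 0 and non-positive penalties, got "
            f"{scores}"
        )
    if "-" in a or "-" in b:
        raise ValueError("align_pair expects ungapped sequences")
    if not a and not b:
        return "", "", 0.0
    if not a or not b:
        other = a or b
        gap_score = gap_open + gap_extend * (len(other) - 1)
        gaps = "-" * len(other)
        return (other, gaps, gap_score) if a else (gaps, other, gap_score)

    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def _char_array(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype="S1")


def eachgap_distance(
    aligned_a: str, aligned_b: str, count_ends: bool = False
) -> EachGapResult:
    """Each-gap distance between two rows of one alignment.

    With ``count_ends=False`` the compared span runs from the later of the
    two first non-gap positions through the earlier of the two last non-gap
    positions (terminal gaps from unequal sequence lengths are not
    penalised).  A pair with no comparable columns gets distance 0 with the
    ``zero_overlap`` flag set, so matrix construction never aborts.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}"
        )
    a = _char_array(aligned_a.upper())
    b = _char_array(aligned_b.upper())
    gap = np.bytes_("-")
    n = np.bytes_("N")

    a_res = np.nonzero(a != gap)[0]
    b_res = np.nonzero(b != gap)[0]
    if count_ends or len(a_res) == 0 or len(b_res) == 0:
        lo, hi = 0, len(a)
    else:
        lo = max(a_res[0], b_res[0])
        hi = min(a_res[-1], b_res[-1]) + 1
    if hi <= lo:
        return EachGapResult(0.0, 0, 0, True)

    sa, sb = a[lo:hi], b[lo:hi]
    both_gap = (sa == gap) & (sb == gap)
    has_n = (sa == n) | (sb == n)
    keep = ~(both_gap | has_n)
    n_compared = int(keep.sum())
    if n_compared == 0:
        return EachGapResult(0.0, 0, 0, True)
    n_diff = int((sa[keep] != sb[keep]).sum())
    return EachGapResult(n_diff / n_compared, n_diff, n_compared, False)


def distance_matrix(aligned_set: AlignedSet, count_ends: bool = False) -> DistanceMatrix:
    """All unordered pairwise each-gap distances of an alignment."""
    if len(aligned_set) < 2:
        raise ValueError("distance_matrix needs at least 2 sequences")
    ids = aligned_set.ids
    n = len(ids)
    values = np.zeros((n, n))
    flagged: list[tuple[str, str]] = []
    rows = [r.residues for r in aligned_set.records]
    for i in range(n):
        for j in range(i + 1, n):
            res = eachgap_distance(rows[i], rows[j], count_ends=count_ends)
            values[i, j] = values[j, i] = res.distance
            if res.zero_overlap:
                flagged.append((ids[i], ids[j]))
    return DistanceMatrix(labels=ids, values=values, zero_overlap_pairs=flagged)


def pairwise_distance_matrix(
    records: Sequence[SequenceRecord],
    scores: tuple[float, float, float, float] = DEFAULT_SCORES,
) -> DistanceMatrix:
    """Each-gap distances between *unaligned* sequences via per-pair global
    alignment (the built-in alternative to an external MSA)."""
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [r.id for r in records]
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, _ = align_pair(records[i].ungapped(), records[j].ungapped(), scores)
            values[i, j] = values[j, i] = eachgap_distance(ga, gb).distance
    return DistanceMatrix(
        labels=ids,
        values=values,
        convention=EACHGAP_CONVENTION + ",pairwise-global-alignment",
    )


def group_summary(matrix: DistanceMatrix, labels: dict[str, str]) -> pd.DataFrame:
    """Per-group min/mean/max over within-group unordered pairs.

    Groups with fewer than two members get NaN statistics (explicit
    "undefined" marker).  Raises on ids in ``labels`` absent from the matrix
    and on matrix ids that are unlabelled.
    """
    unknown = set(labels) - set(matrix.labels)
    if unknown:
        raise ValueError(f"labels reference unknown ids: {sorted(unknown)}")
    missing = set(matrix.labels) - set(labels)
    if missing:
        raise ValueError(f"matrix ids without labels: {sorted(missing)}")

    groups: dict[str, list[int]] = {}
    for idx, seq_id in enumerate(matrix.labels):
        groups.setdefault(labels[seq_id], []).append(idx)

    rows = []
    for group in sorted(groups):
        idx = groups[group]
        if len(idx) < 2:
            rows.append((group, len(idx), np.nan, np.nan, np.nan))
            continue
        sub = matrix.values[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        rows.append((group, len(idx), vals.min(), vals.mean(), vals.max()))
    return pd.DataFrame(rows, columns=["group", "n", "min", "mean", "max"])
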