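"""Intragenomic SNP calling and windowed density tracks.

Short (merged) reads are aligned semi-globally to a single rDNA reference
(the read is global, the reference end-gaps are free), a per-position pileup
of A/C/G/T/deletion counts is accumulated, SNPs are called by simple
depth/fraction/count thresholds, and a sliding-window density track is
computed.  With reads drawn from a strain's divergent rDNA copies, the
density track reproduces the locus structure of intragenomic polymorphism
(quiet SSU, busy ITS).

Alignment is unit-cost edit alignment (edlib, infix mode); ``band`` bounds
the accepted edit distance of a read.  Calling thresholds default to
min_depth 20, min_alt_frac 0.05, min_alt_count 3 and are recorded in the
output headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import edlib
import numpy as np
import pandas as pd

from .io import SequenceRecord

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_COLS = ("A", "C", "G", "T", "del")


@dataclass
class Pileup:
    reference_id: str
    reference: str
    counts: np.ndarray  # (L, 5): A, C, G, T, deletion
    n_mapped: int = 0
    n_discarded: int = 0

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(_COLS))
        df.insert(0, "ref", list(self.reference))
        df.insert(0, "position", np.arange(1, len(self.reference) + 1))  # 1-based out
        df["depth"] = self.depth
        return df


def map_reads(
    reads: Sequence[Union[str, SequenceRecord]],
    reference: Union[str, SequenceRecord],
    band: int = -1,
    min_identity: float = 0.8,
) -> Pileup:
    """Align each read inside the reference and accumulate base counts.

    Reads whose best placement falls below ``min_identity`` (matches /
    alignment columns) or beyond the ``band`` edit bound are discarded and
    counted.  Insertions relative to the reference are ignored (the pileup
    is in reference coordinates); deletions are tallied in their own column.
    """
    if isinstance(reference, SequenceRecord):
        ref_id, ref_seq = reference.id, reference.residues
    else:
        ref_id, ref_seq = "reference", reference
    if not ref_seq:
        raise ValueError("empty reference")
    if "-" in ref_seq:
        raise ValueError("reference must be ungapped")

    counts = np.zeros((len(ref_seq), 5), dtype=np.int64)
    n_mapped = n_discarded = 0
    for read in reads:
        seq = read.residues if isinstance(read, SequenceRecord) else read
        res = edlib.align(seq, ref_seq, mode="HW", task="path", k=band)
        if res["editDistance"] == -1:
            n_discarded += 1
            continue
        nice = edlib.getNiceAlignment(res, seq, ref_seq)
        cols = len(nice["matched_aligned"])
        identity = nice["matched_aligned"].count("|") / cols if cols else 0.0
        if identity < min_identity:
            n_discarded += 1
            continue
        n_mapped += 1
        t = res["locations"][0][0]
        for rc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc == "-":  # insertion in the read; no reference coordinate
                continue
            if rc in _BASE_IDX:
                counts[t, _BASE_IDX[rc]] += 1
            t += 1
    return Pileup(
        reference_id=ref_id,
        reference=ref_seq,
        counts=counts,
        n_mapped=n_mapped,
        n_discarded=n_discarded,
    )


def call_snps(
    pileup: Pileup,
    min_depth: int = 20,
    min_alt_frac: float = 0.05,
    min_alt_count: int = 3,
) -> pd.DataFrame:
    """Positions where a non-reference *base* passes the thresholds.

    Deletions never count as SNPs.  Returns 0-based positions with the major
    alternate base, its count, fraction of depth, and depth.
    """
    depth = pileup.depth
    rows = []
    for pos, ref_base in enumerate(pileup.reference):
        d = int(depth[pos])
        if d < min_depth:
            continue
        best_alt, best_count = None, 0
        for base in "ACGT":
            if base == ref_base:
                continue
            c = int(pileup.counts[pos, _BASE_IDX[base]])
            if c > best_count:
                best_alt, best_count = base, c
        if (
            best_alt is not None
            and best_count >= min_alt_count
            and best_count / d >= min_alt_frac
        ):
            rows.append((pos, ref_base, best_alt, best_count, d, best_count / d))
    return pd.DataFrame(
        rows, columns=["position", "ref", "alt", "alt_count", "depth", "fraction"]
    )


def density_track(
    snp_positions: Sequence[int],
    reference_length: int,
    window: int = 100,
    step: int = 10,
) -> pd.DataFrame:
    """SNPs per bp in sliding windows [start, start + window) with the given
    step; window starts tile 0, step, 2*step, ... across the reference."""
    if not window >= step >= 1:
        raise ValueError("need window >= step >= 1")
    positions = np.asarray(sorted(snp_positions), dtype=int)
    starts = np.arange(0, max(reference_length, 1), step)
    rows = []
    for start in starts:
        n = int(((positions >= start) & (positions < start + window)).sum())
        rows.append((int(start), n / window))
    return pd.DataFrame(rows, columns=["start", "density"])


def write_snp_table(
    snps: pd.DataFrame, path: str | Path, params: dict | None = None
) -> None:
    """SNP calls as TSV; positions are converted to 1-based for humans."""
    out = snps.copy()
    out["position"] = out["position"] + 1
    with open(path, "w") as fh:
        if params:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in params.items()) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def write_density_track(
    track: pd.DataFrame,
    path: str | Path,
    reference_id: str = "reference",
    window: int = 100,
    bedgraph: bool = False,
) -> None:
    with open(path, "w") as fh:
        if bedgraph:
            for _, row in track.iterrows():
                fh.write(
                    f"{reference_id}\t{int(row.start)}\t{int(row.start) + window}"
                    f"\t{row.density:.6f}\n"
                )
        else:
            fh.write(f"# window={window}\n")
            track.to_csv(fh, sep="\t", index=False)
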