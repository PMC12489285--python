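"""Partition aligned rDNA operons into loci via reference-anchored coordinates.

Locus boundaries come from an annotated reference row (BED-like map in the
reference's ungapped coordinates) projected through that row's gap structure
onto alignment columns.  This replaces motif/HMM locus detection: the
synthetic generator and curated references carry annotations, and projection
is deterministic and testable.

Coordinates are 0-based half-open internally; the BED-like TSV on disk uses
the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from .distances import AlignedSet
from .io import SequenceRecord

CANONICAL_ORDER = ("SSU", "ITS1", "5.8S", "ITS2", "LSU")


class Window(NamedTuple):
    name: str
    start: int
    end: int


@dataclass
class LocusMap:
    """Ordered, non-overlapping locus windows with a coordinate-system tag.

    ``coordinates`` is either ``"reference"`` (ungapped positions in one
    sequence) or ``"alignment"`` (columns of an MSA).
    """

    windows: list[Window]
    coordinates: str = "reference"

    def __post_init__(self) -> None:
        if self.coordinates not in ("reference", "alignment"):
            raise ValueError(f"unknown coordinate system {self.coordinates!r}")
        self.windows = [Window(*w) for w in self.windows]
        prev_end = -1
        for w in self.windows:
            if w.end <= w.start:
                raise ValueError(f"window {w.name}: end must exceed start ({w})")
            if w.start < prev_end:
                raise ValueError(f"window {w.name} overlaps its predecessor")
            prev_end = w.end
        names = [w.name for w in self.windows]
        canonical = [n for n in names if n in CANONICAL_ORDER]
        if canonical != sorted(canonical, key=CANONICAL_ORDER.index):
            raise ValueError(
                f"canonical loci out of order: {canonical}; expected subsequence of "
                f"{CANONICAL_ORDER}"
            )

    def __getitem__(self, name: str) -> Window:
        for w in self.windows:
            if w.name == name:
                return w
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(w.name == name for w in self.windows)

    @property
    def names(self) -> list[str]:
        return [w.name for w in self.windows]


def read_locus_map(path: str | Path, coordinates: str = "reference") -> LocusMap:
    """Read a BED-like TSV (name, start, end; 0-based half-open)."""
    windows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: expected 3 columns, got {line!r}")
            windows.append(Window(parts[0], int(parts[1]), int(parts[2])))
    return LocusMap(windows=windows, coordinates=coordinates)


def write_locus_map(locus_map: LocusMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# coordinates: {locus_map.coordinates} (0-based half-open)\n")
        for w in locus_map.windows:
            fh.write(f"{w.name}\t{w.start}\t{w.end}\n")


def project_locus_map(
    aligned_set: AlignedSet, reference_id: str, ref_locus_map: LocusMap
) -> LocusMap:
    """Map reference-coordinate windows to alignment columns.

    Each ungapped reference position maps to its column; a window end ``e``
    maps to one column past the column of residue ``e - 1``.  Projection is
    monotone by construction.
    """
    if ref_locus_map.coordinates != "reference":
        raise ValueError("ref_locus_map must be in reference coordinates")
    try:
        ref_row = next(r for r in aligned_set.records if r.id == reference_id)
    except StopIteration:
        raise KeyError(f"reference id {reference_id!r} not in alignment") from None
    cols = [i for i, ch in enumerate(ref_row.residues) if ch != "-"]
    n_res = len(cols)
    windows = []
    for w in ref_locus_map.windows:
        if w.end > n_res:
            raise ValueError(
                f"window {w.name} end {w.end} exceeds reference ungapped length {n_res}"
            )
        windows.append(Window(w.name, cols[w.start], cols[w.end - 1] + 1))
    return LocusMap(windows=windows, coordinates="alignment")


def extract_locus(aligned_set: AlignedSet, locus_map: LocusMap, locus: str) -> AlignedSet:
    """Column slice of one locus; columns gapped in every record are removed.

    Record ids and per-record residue order/content are preserved (only
    all-gap columns go).
    """
    if locus_map.coordinates != "alignment":
        raise ValueError("extract_locus needs a locus map in alignment columns")
    if locus not in locus_map:
        raise KeyError(f"unknown locus {locus!r}")
    w = locus_map[locus]
    rows = [rec.residues[w.start : w.end] for rec in aligned_set.records]
    keep = [
        i for i in range(len(rows[0])) if any(row[i] != "-" for row in rows)
    ]
    records = [
        SequenceRecord(
            id=rec.id,
            residues="".join(row[i] for i in keep),
            description=rec.description,
        )
        for rec, row in zip(aligned_set.records, rows)
    ]
    return AlignedSet(records=records, labels=aligned_set.labels)


def krueger_window(
    locus_map: LocusMap, ssu_tail: int = 280, lsu_head: int = 800
) -> Window:
    """The ~1.5-kb taxonomic barcode window: last ``ssu_tail`` bp of the SSU
    through the first ``lsu_head`` bp of the LSU (clipped to locus bounds)."""
    for required in ("SSU", "LSU"):
        if required not in locus_map:
            raise KeyError(f"locus map lacks {required}")
    ssu, lsu = locus_map["SSU"], locus_map["LSU"]
    start = max(ssu.start, ssu.end - ssu_tail)
    end = min(lsu.start + lsu_head, lsu.end)
    return Window("krueger", start, end)


def extract_window(aligned_set: AlignedSet, window: Window) -> AlignedSet:
    """Slice an arbitrary window (e.g. the Krüger fragment) like a locus."""
    temp = LocusMap(windows=[window], coordinates="alignment")
    return extract_locus(aligned_set, temp, window.name)
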