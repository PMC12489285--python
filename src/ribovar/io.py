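"""Reading and writing of the standard formats the pipeline touches.

Every downstream module consumes :class:`SequenceRecord` collections and
:class:`SampleManifest` tables produced here; no other module reads files
directly (the CLI composes these readers).

Alphabet policy: residues are upper-cased at ingest and restricted to
``{A, C, G, T, N, -}``.  IUPAC ambiguity codes other than N are rejected with
an error naming the offending line, which keeps the distance semantics of the
analysis modules unambiguous.  Internal coordinates are 0-based half-open
throughout the package; human-facing reports are 1-based inclusive.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

VALID_RESIDUES = frozenset("ACGTN-")
VALID_UNGAPPED = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed input file (bad header, alphabet violation, truncation)."""


@dataclass
class SequenceRecord:
    """A single sequence: amplicon, gene, read, or aligned row.

    qualities, when present, are per-residue Phred scores (reads only) and
    must match the residue length.  The gap character '-' is only meaningful
    in aligned context.
    """

    id: str
    residues: str
    description: str = ""
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)}; "
                "allowed alphabet is A,C,G,T,N,-"
            )
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_unique_ids(records: Sequence[SequenceRecord], path) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file (aligned or not) into records, in file order.

    Gap characters are preserved, residues upper-cased.  A malformed header
    or a character outside {A,C,G,T,N,-} raises :class:`FormatError` naming
    the line number.  The parser is deliberately strict and line-aware, which
    is why it is written out rather than delegated.
    """
    records: list[SequenceRecord] = []
    header: Optional[str] = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no sequence")
        name, _, desc = header.partition(" ")
        records.append(SequenceRecord(id=name, residues=seq, description=desc))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                seq = line.upper()
                bad = set(seq) - VALID_RESIDUES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid characters {sorted(bad)}"
                    )
                chunks.append(seq)
    flush()
    _check_unique_ids(records, path)
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write standard FASTA, wrapped at ``line_width``; deterministic bytes."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with _open_text(path, "wt") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            s = rec.residues
            for i in range(0, len(s), line_width):
                fh.write(s[i : i + line_width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line-per-record FASTQ (Phred+33) via Bio.SeqIO.

    Length mismatches between sequence and quality lines, or truncated
    records, raise :class:`FormatError`.
    """
    from Bio import SeqIO

    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                seq = str(rec.seq).upper()
                bad = set(seq) - VALID_UNGAPPED
                if bad:
                    raise FormatError(
                        f"{path}: record {rec.id!r}: invalid characters {sorted(bad)}"
                    )
                records.append(
                    SequenceRecord(
                        id=rec.id,
                        residues=seq,
                        description=rec.description[len(rec.id) :].strip(),
                        qualities=list(rec.letter_annotations["phred_quality"]),
                    )
                )
        except ValueError as exc:  # Bio.SeqIO's malformed-FASTQ errors
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc
    _check_unique_ids(records, path)
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(min(q, 93) + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{qual}\n")


MANIFEST_COLUMNS = ("id", "strain", "species", "locus")


@dataclass
class SampleManifest:
    """Sequence id -> (strain, species, locus/gene) label table."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"manifest missing required columns: {missing}")
        ids = self.frame["id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"manifest has duplicate ids: {dups}")
        for col in MANIFEST_COLUMNS:
            if self.frame[col].astype(str).str.len().eq(0).any():
                raise ValueError(f"manifest column {col!r} contains empty labels")

    def __len__(self) -> int:
        return len(self.frame)

    def labels(self, column: str) -> dict[str, str]:
        """Mapping id -> label for one of strain/species/locus."""
        if column not in MANIFEST_COLUMNS[1:]:
            raise KeyError(column)
        return dict(zip(self.frame["id"], self.frame[column].astype(str)))


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a TSV manifest with header columns id/strain/species/locus."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing required columns {missing}")
    try:
        return SampleManifest(frame=frame.reset_index(drop=True))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.frame.to_csv(path, sep="\t", index=False)
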