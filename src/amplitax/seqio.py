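"""Streaming readers/writers for the sequence and metadata formats the
pipeline touches.

Supported sequence inputs: FASTQ (Phred+33), FASTA, FASTA + separate
``.qual`` file, each optionally gzip-compressed (detected by magic bytes,
never by extension).  Metadata: a QIIME-style tab-separated mapping file
(sample id, barcode, optional primers) and a ``key value`` option file.

Readers are generators and never materialise a whole file; writers
round-trip through the readers.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.SeqIO.QualityIO import PairedFastaQualIterator

PathLike = Union[str, Path]

GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class SequenceRead:
    """A single sequencing read.

    ``quals`` are Phred scores (one per base) or ``None`` for
    quality-less FASTA input.  ``sample`` is filled in by demultiplexing.
    """

    read_id: str
    bases: str
    quals: Optional[tuple[int, ...]] = None
    pair_role: str = "single"  # single | forward | reverse
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.quals)} quality values "
                f"for {len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: Optional[int] = None) -> "SequenceRead":
        """Return a copy restricted to ``bases[start:stop]`` with qualities
        trimmed identically."""
        q = self.quals[start:stop] if self.quals is not None else None
        return replace(self, bases=self.bases[start:stop], quals=q)

    def with_sample(self, sample: str) -> "SequenceRead":
        return replace(self, sample=sample)


@dataclass
class MappingRow:
    sample_id: str
    barcode: str
    fwd_primer: Optional[str] = None
    rev_primer: Optional[str] = None
    metadata: dict = field(default_factory=dict)


@dataclass
class MappingTable:
    """Sample sheet: one row per sample with its barcode and primers."""

    rows: list[MappingRow]

    def __post_init__(self) -> None:
        seen_samples: set[str] = set()
        seen_barcodes: set[str] = set()
        for row in self.rows:
            if row.sample_id in seen_samples:
                raise ValueError(f"duplicate sample id {row.sample_id!r}")
            if row.barcode and row.barcode in seen_barcodes:
                raise ValueError(f"duplicate barcode {row.barcode!r}")
            seen_samples.add(row.sample_id)
            seen_barcodes.add(row.barcode)

    def __iter__(self) -> Iterator[MappingRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]


def _open_text(path: PathLike) -> TextIO:
    """Open a possibly-gzipped text file, sniffing the gzip magic bytes."""
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _sniff_format(handle: TextIO) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    if first == "":
        return "empty"
    raise ValueError(f"unrecognised sequence format (first char {first!r})")


def _record_to_read(rec, pair_role: str = "single") -> SequenceRead:
    quals = rec.letter_annotations.get("phred_quality")
    bases = str(rec.seq).upper()
    if not bases:
        raise ValueError(f"read {rec.id!r}: empty sequence")
    if quals is not None and any(q < 0 for q in quals):
        raise ValueError(f"read {rec.id!r}: negative quality score")
    return SequenceRead(
        read_id=rec.id,
        bases=bases,
        quals=tuple(quals) if quals is not None else None,
        pair_role=pair_role,
    )


def _parse_single(path: PathLike, qual_path: Optional[PathLike],
                  pair_role: str) -> Iterator[SequenceRead]:
    if qual_path is not None:
        with _open_text(path) as fh, _open_text(qual_path) as qh:
            for rec in PairedFastaQualIterator(fh, qh):
                yield _record_to_read(rec, pair_role)
        return
    with _open_text(path) as fh:
        fmt = _sniff_format(fh)
        if fmt == "empty":
            return
        for rec in SeqIO.parse(fh, fmt):
            yield _record_to_read(rec, pair_role)


def read_sequences(
    path: PathLike,
    mate_path: Optional[PathLike] = None,
    qual_path: Optional[PathLike] = None,
) -> Iterator[Union[SequenceRead, tuple[SequenceRead, SequenceRead]]]:
    """Stream reads from FASTQ / FASTA / FASTA+qual, gzip-transparent.

    With ``mate_path`` given, yields ``(forward, reverse)`` pairs from two
    files in matched record order; a record-count mismatch raises at the
    first missing mate.  FASTQ qualities are decoded as Phred+33.
    """
    if mate_path is None:
        yield from _parse_single(path, qual_path, "single")
        return
    fwd_it = _parse_single(path, None, "forward")
    rev_it = _parse_single(mate_path, None, "reverse")
    sentinel = object()
    while True:
        f = next(fwd_it, sentinel)
        r = next(rev_it, sentinel)
        if f is sentinel and r is sentinel:
            return
        if f is sentinel or r is sentinel:
            raise ValueError("paired files have unequal record counts")
        yield f, r  # type: ignore[misc]


# mapping file dialect: first column = sample id, required column
# BarcodeSequence, optional LinkerPrimerSequence / ReversePrimer;
# '#'-lines after the header are comments (the header itself may start
# with '#', QIIME-style).

def read_mapping(path: PathLike) -> MappingTable:
    """Parse a tab-separated mapping file into a validated MappingTable."""
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ValueError("mapping file is empty")
        header = [h.strip().lstrip("#") for h in header_line.rstrip("\n").split("\t")]
        if "BarcodeSequence" not in header:
            raise ValueError("mapping file lacks a BarcodeSequence column")
        bc_col = header.index("BarcodeSequence")
        fwd_col = header.index("LinkerPrimerSequence") if "LinkerPrimerSequence" in header else None
        rev_col = header.index("ReversePrimer") if "ReversePrimer" in header else None
        rows = []
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            meta = {header[i]: fields[i] for i in range(len(fields))
                    if i not in (0, bc_col, fwd_col, rev_col) and i < len(header)}
            rows.append(MappingRow(
                sample_id=fields[0].strip(),
                barcode=fields[bc_col].strip().upper(),
                fwd_primer=(fields[fwd_col].strip().upper() or None)
                if fwd_col is not None and fwd_col < len(fields) else None,
                rev_primer=(fields[rev_col].strip().upper() or None)
                if rev_col is not None and rev_col < len(fields) else None,
                metadata=meta,
            ))
    return MappingTable(rows)


def write_fasta(reads: Iterable[SequenceRead], path: PathLike,
                line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n")
            for i in range(0, len(read.bases), line_width):
                fh.write(read.bases[i:i + line_width] + "\n")


def write_fastq(reads: Iterable[SequenceRead], path: PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            if read.quals is None:
                raise ValueError(
                    f"read {read.read_id!r} has no qualities; cannot write FASTQ"
                )
            qstr = "".join(chr(min(q, 93) + 33) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qstr}\n")


def read_option_file(path: PathLike) -> dict[str, str]:
    """Parse a ``key value`` option file; '#' starts a comment line."""
    opts: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            opts[parts[0]] = parts[1] if len(parts) > 1 else ""
    return opts


def write_option_file(options: dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in options.items():
            fh.write(f"{key} {value}\n")
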