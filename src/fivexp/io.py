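"""FASTQ/FASTA input-output helpers.

Thin wrappers around Biopython's fast FASTQ iterator and SeqIO, plus the
plain-text table formats the pipeline exchanges (truth tables, count tables,
sample sheets). All FASTQ is Phred+33; ``.gz`` paths are handled
transparently.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .records import ReadRecord

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: PathLike) -> Iterator[ReadRecord]:
    """Iterate over a FASTQ file as :class:`ReadRecord` objects.

    A malformed record raises ``ValueError`` naming the file and the
    approximate line of the offending record.
    """
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        n = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ record {n + 1} (around line {n * 4 + 1}): {exc}"
                ) from exc
            n += 1
            read_id = title.split()[0] if title else ""
            yield ReadRecord(read_id, seq.upper(), qual)


def write_fastq(records: Iterable[ReadRecord], path: PathLike) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a multi-FASTA into ``[(ref_id, sequence), ...]`` (uppercased)."""
    entries: list[tuple[str, str]] = []
    ref_id = None
    chunks: list[str] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if ref_id is not None:
                    entries.append((ref_id, "".join(chunks).upper()))
                ref_id = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if ref_id is not None:
        entries.append((ref_id, "".join(chunks).upper()))
    return entries


def write_fasta(entries: Iterable[tuple[str, str]], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for ref_id, seq in entries:
            handle.write(f">{ref_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
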