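"""FASTQ input/output helpers shared by the pipeline stages.

Reads and writes plain or gzip-compressed FASTQ via Biopython's fast
``FastqGeneralIterator``. Records are lightweight ``(id, seq, qual)``
tuples; qualities stay phred+33 encoded strings until a stage needs
numeric values.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


@dataclass(frozen=True)
class FastqRecord:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open plain or gzipped text transparently based on the suffix.

    Gzip members are written with a zeroed timestamp so that repeated
    runs with identical content produce byte-identical files.
    """
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode or "a" in mode or "x" in mode:
            import io as _io

            raw = gzip.GzipFile(path, mode.replace("t", "") + "b" if "b" not in mode else mode, mtime=0)
            return _io.TextIOWrapper(raw)  # type: ignore[return-value]
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    with open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            # cluster id = first whitespace-delimited token of the title
            yield FastqRecord(title.split(None, 1)[0], seq, qual)


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> int:
    n = 0
    with open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


class FastqWriter:
    """Incremental FASTQ writer (plain or gzip, chosen by suffix)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._handle = open_text(path, "wt")
        self.count = 0

    def write(self, rec: FastqRecord) -> None:
        self._handle.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
        self.count += 1

    def close(self) -> None:
        self._handle.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def quals_to_phred(qual: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in qual]


def phred_to_quals(phred: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in phred)
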