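"""Sample demultiplexing and four-read stream routing.

A MiSeq-style run delivers four synchronized FASTQ streams per cluster:
read 1 and read 2 over the antibody variable region, index read 1
(repurposed as the 12-nt subclass identifier) and index read 2 (the 8-nt
sample index). This module streams the four files in lock-step, assigns
each cluster to a sample by index 2, calls the subclass category from
index 1 plus the read-2 discriminator base, and routes read pairs to
per-(sample, category) outputs with a conservation-checked tally.

PhiX-like contaminant clusters lack a sample index and instead expose the
adaptor bases at the index-2 position; they are recognised by a reserved
contaminant index and counted separately from sample-undetermined reads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from ._io import FastqRecord, FastqWriter, read_fastq
from .scheme import CATEGORIES, SubtypeScheme, call_subtype, hamming, normalize

#: 8-mer read at the index-2 position of clusters built on the universal
#: (index-free) adaptor — in practice PhiX control clusters.
TRUSEQ_UNIVERSAL_INDEX = "TCTTTCCC"

CONTAMINANT = "contaminant"
SAMPLE_UNDETERMINED = "undetermined"


class DemuxError(RuntimeError):
    """Fatal demultiplexing error (e.g. desynchronized streams)."""


@dataclass(frozen=True)
class ReadQuad:
    """One cluster's four reads, sharing a single cluster id."""

    cluster_id: str
    r1: FastqRecord
    r2: FastqRecord
    i1: FastqRecord
    i2: FastqRecord


@dataclass(frozen=True)
class SampleSheet:
    """Ordered sample -> 8-nt index map plus the reserved contaminant index.

    The ambiguity guard requires every pair of sample indices to sit more
    than ``2 * i2_max_mismatch`` apart, so no read can fall within
    tolerance of two samples at once.
    """

    samples: Mapping[str, str]
    contaminant_index: str = TRUSEQ_UNIVERSAL_INDEX
    i2_max_mismatch: int = 1
    #: disable to admit index sets that violate the separation guard
    #: (ambiguous reads then fall back to the tie -> undetermined rule)
    enforce_separation: bool = True

    def __post_init__(self) -> None:
        entries = {name: normalize(idx) for name, idx in self.samples.items()}
        object.__setattr__(self, "samples", entries)
        object.__setattr__(self, "contaminant_index", normalize(self.contaminant_index))
        lengths = {len(i) for i in entries.values()} | {len(self.contaminant_index)}
        if len(lengths) > 1:
            raise ValueError(f"sample indices have mixed lengths: {sorted(lengths)}")
        if len(set(entries.values())) != len(entries):
            raise ValueError("sample indices are not unique")
        if not self.enforce_separation:
            return
        for (na, ia), (nb, ib) in itertools.combinations(entries.items(), 2):
            if hamming(ia, ib) <= 2 * self.i2_max_mismatch:
                raise ValueError(
                    f"samples {na!r} and {nb!r}: index distance "
                    f"{hamming(ia, ib)} <= 2*i2_max_mismatch={2 * self.i2_max_mismatch}"
                )

    @property
    def index_length(self) -> int:
        return len(self.contaminant_index)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if not {"sample", "index"} <= set(df.columns):
            raise ValueError("sample sheet needs 'sample' and 'index' columns")
        return cls(samples=dict(zip(df["sample"], df["index"])), **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample": list(self.samples), "index": list(self.samples.values())}
        ).to_csv(path, sep="\t", index=False)


def assign_sample(i2: str, sheet: SampleSheet) -> str:
    """Assign an index-2 read to a sample, the contaminant bin, or undetermined.

    Nearest candidate within ``i2_max_mismatch`` wins; a tie at the minimal
    distance (between two samples, or a sample and the contaminant index)
    is undetermined. Wrong-length reads are undetermined.
    """
    i2 = normalize(i2)
    if len(i2) != sheet.index_length:
        return SAMPLE_UNDETERMINED
    candidates = list(sheet.samples.items()) + [(CONTAMINANT, sheet.contaminant_index)]
    distances = [(hamming(idx, i2), name) for name, idx in candidates]
    best = min(d for d, _ in distances)
    if best > sheet.i2_max_mismatch:
        return SAMPLE_UNDETERMINED
    hits = [name for d, name in distances if d == best]
    return hits[0] if len(hits) == 1 else SAMPLE_UNDETERMINED


def read_quads(
    r1: str | Path, r2: str | Path, i1: str | Path, i2: str | Path
) -> Iterator[ReadQuad]:
    """Stream four synchronized FASTQ files as ReadQuads.

    Raises DemuxError on any cluster-id disagreement or length mismatch
    between the streams, naming the offending records.
    """
    streams = [read_fastq(p) for p in (r1, r2, i1, i2)]
    for recs in itertools.zip_longest(*streams):
        if any(r is None for r in recs):
            present = [r.id for r in recs if r is not None]
            raise DemuxError(
                f"desynchronized streams: records {present} lack counterparts "
                "(unequal file lengths)"
            )
        ids = {_strip_mate(r.id) for r in recs}
        if len(ids) != 1:
            raise DemuxError(f"desynchronized streams at records {[r.id for r in recs]}")
        yield ReadQuad(ids.pop(), *recs)


def _strip_mate(cluster_id: str) -> str:
    return cluster_id[:-2] if cluster_id.endswith(("/1", "/2", "/3", "/4")) else cluster_id


def demultiplex(
    quads: Iterable[ReadQuad],
    sheet: SampleSheet,
    scheme: SubtypeScheme,
    trim_prefix: int = 0,
    revcomp_i2: bool = False,
) -> Iterator[tuple[str, str | None, ReadQuad]]:
    """Classify each quad, yielding ``(sample_or_bin, category, quad)``.

    `category` is one of the six subclass categories for sample-assigned
    clusters and None for run-level bins (contaminant, sample-level
    undetermined). `trim_prefix` removes a fixed-length read-1 prefix
    (the 4 random primer nucleotides) when requested; default keeps them.
    """
    from .scheme import reverse_complement

    for quad in quads:
        i2_seq = reverse_complement(quad.i2.seq) if revcomp_i2 else quad.i2.seq
        sample = assign_sample(i2_seq, sheet)
        if trim_prefix:
            r1 = FastqRecord(quad.r1.id, quad.r1.seq[trim_prefix:], quad.r1.qual[trim_prefix:])
            quad = ReadQuad(quad.cluster_id, r1, quad.r2, quad.i1, quad.i2)
        if sample in (CONTAMINANT, SAMPLE_UNDETERMINED):
            yield sample, None, quad
        else:
            call = call_subtype(quad.i1.seq, quad.r2.seq, scheme)
            yield sample, call.label, quad


@dataclass
class DemuxTally:
    """Per-bucket cluster counts with the run-level totals."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    contaminant: int = 0
    sample_undetermined: int = 0
    total: int = 0

    def add(self, sample: str, category: str | None) -> None:
        self.total += 1
        if category is None:
            if sample == CONTAMINANT:
                self.contaminant += 1
            else:
                self.sample_undetermined += 1
        else:
            key = (sample, category)
            self.counts[key] = self.counts.get(key, 0) + 1

    def conserved(self) -> bool:
        return sum(self.counts.values()) + self.contaminant + self.sample_undetermined == self.total

    def to_frame(self, samples: Iterable[str] | None = None) -> pd.DataFrame:
        names = list(samples) if samples is not None else sorted({s for s, _ in self.counts})
        rows = [
            {"sample": s, "category": c, "count": self.counts.get((s, c), 0)}
            for s in names
            for c in CATEGORIES
        ]
        return pd.DataFrame(rows, columns=["sample", "category", "count"])


def demultiplex_run(
    r1: str | Path,
    r2: str | Path,
    i1: str | Path,
    i2: str | Path,
    sheet: SampleSheet,
    scheme: SubtypeScheme,
    outdir: str | Path | None = None,
    trim_prefix: int = 0,
    revcomp_i2: bool = False,
    gzip_output: bool = True,
) -> DemuxTally:
    """Demultiplex four FASTQ files into per-(sample, category) read pairs.

    When `outdir` is given, writes ``<sample>_<category>_R{1,2}.fastq[.gz]``
    plus run-level ``contaminant`` / ``undetermined`` pairs and a
    ``demux_tally.tsv`` mirroring the per-category count table.
    """
    for name, path in (("R1", r1), ("R2", r2), ("I1", i1), ("I2", i2)):
        if not Path(path).exists():
            raise FileNotFoundError(f"missing {name} stream: {path}")
    tally = DemuxTally()
    writers: dict[str, tuple[FastqWriter, FastqWriter]] = {}
    suffix = ".fastq.gz" if gzip_output else ".fastq"

    def bucket_writers(stem: str) -> tuple[FastqWriter, FastqWriter]:
        if stem not in writers:
            out = Path(outdir)  # type: ignore[arg-type]
            writers[stem] = (
                FastqWriter(out / f"{stem}_R1{suffix}"),
                FastqWriter(out / f"{stem}_R2{suffix}"),
            )
        return writers[stem]

    try:
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
        for sample, category, quad in demultiplex(
            read_quads(r1, r2, i1, i2), sheet, scheme, trim_prefix, revcomp_i2
        ):
            tally.add(sample, category)
            if outdir is not None:
                stem = sample if category is None else f"{sample}_{category}"
                w1, w2 = bucket_writers(stem)
                w1.write(quad.r1)
                w2.write(quad.r2)
    finally:
        for w1, w2 in writers.values():
            w1.close()
            w2.close()
    assert tally.conserved(), "demux conservation violated"
    if outdir is not None:
        frame = tally.to_frame(sheet.samples)
        extra = pd.DataFrame(
            [
                {"sample": "-", "category": CONTAMINANT, "count": tally.contaminant},
                {"sample": "-", "category": SAMPLE_UNDETERMINED, "count": tally.sample_undetermined},
            ]
        )
        pd.concat([frame, extra], ignore_index=True).to_csv(
            Path(outdir) / "demux_tally.tsv", sep="\t", index=False
        )
    return tally
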