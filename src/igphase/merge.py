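"""Paired-end read merging by 3'-overlap consensus.

Read 2 covers the reverse strand, so after reverse-complementing it the
two reads of a pair share a 3' overlap (about 100 nt for typical heavy
chains sequenced 2x250). Candidate overlap lengths of at least
``min_overlap`` (default 10 nt) are scored with a quality-weighted
match/mismatch objective; the best candidate must be unique and its
mismatch fraction below ``max_mismatch_frac``, otherwise the pair is
counted as unmerged rather than risking a guessed junction. Within the
overlap each consensus base is the higher-quality base (tie: read 1) and
the consensus quality is the larger of the two, so it never drops below
either input.

Scoring is vectorised: per-base indicator channels are convolved so that
match counts and quality-weighted scores for *all* candidate overlaps
come out of a handful of numpy convolutions per pair.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np
import pandas as pd

from ._io import PHRED_OFFSET, FastqRecord, FastqWriter
from .scheme import normalize, reverse_complement

_N_CODE = 4
_ENCODE = np.full(256, _N_CODE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MergedSequence:
    """A successfully stitched read pair in read-1 (coding) orientation."""

    cluster_id: str
    sequence: str
    quality: str
    overlap_length: int
    overlap_mismatches: int

    def to_fastq(self) -> FastqRecord:
        return FastqRecord(self.cluster_id, self.sequence, self.quality)


@dataclass(frozen=True)
class MergeFailure:
    """An unmergeable pair; `reason` is one of no_overlap/ambiguous/mismatch."""

    cluster_id: str
    reason: str


MergeResult = Union[MergedSequence, MergeFailure]


def merge_pair(
    r1: FastqRecord,
    r2: FastqRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergeResult:
    """Merge one read pair, or report why it cannot be merged.

    The score of a candidate overlap of length L is
    ``sum over overlap positions of s * (q1 + q2) / 2`` with s = +1 for a
    match and -1 for a mismatch; an N on either side is always a
    mismatch. The decomposition ``sum(s*q) = 2*sum(q over matches) -
    sum(q over the overlap)`` makes the whole profile computable from
    per-base-channel convolutions.
    """
    if not r1.seq or not r2.seq:
        return MergeFailure(r1.id, "no_overlap")
    a_str = normalize(r1.seq)
    b_str = reverse_complement(r2.seq)
    ea, eb = _encode(a_str), _encode(b_str)
    qa = np.frombuffer(r1.qual.encode("ascii"), dtype=np.uint8).astype(np.float64) - PHRED_OFFSET
    qb = (np.frombuffer(r2.qual.encode("ascii"), dtype=np.uint8).astype(np.float64) - PHRED_OFFSET)[::-1]
    n1, n2 = len(ea), len(eb)
    lmax = min(n1, n2)
    if lmax < min_overlap:
        return MergeFailure(r1.id, "no_overlap")

    conv_m = np.zeros(n1 + n2 - 1)
    conv_q1 = np.zeros(n1 + n2 - 1)
    conv_q2 = np.zeros(n1 + n2 - 1)
    for base in range(4):
        av = (ea == base).astype(np.float64)
        bv = (eb == base).astype(np.float64)[::-1]
        conv_m += np.convolve(av, bv)
        conv_q1 += np.convolve(av * qa, bv)
        conv_q2 += np.convolve(av, (((eb == base).astype(np.float64)) * qb)[::-1])

    lengths = np.arange(min_overlap, lmax + 1)
    idx = n1 + n2 - 1 - lengths  # conv index holding overlap length L
    matches = conv_m[idx]
    sum_qa = np.cumsum(qa[::-1])[lengths - 1]  # r1 suffix quality sums
    sum_qb = np.cumsum(qb)[lengths - 1]  # r2 prefix quality sums
    scores = (2.0 * conv_q1[idx] - sum_qa) / 2.0 + (2.0 * conv_q2[idx] - sum_qb) / 2.0

    best = int(np.argmax(scores))
    if int(np.sum(scores == scores[best])) > 1:
        return MergeFailure(r1.id, "ambiguous")
    overlap = int(lengths[best])
    mismatches = overlap - int(round(matches[best]))
    if mismatches / overlap > max_mismatch_frac:
        return MergeFailure(r1.id, "mismatch")

    a_ov, b_ov = ea[n1 - overlap:], eb[:overlap]
    qa_ov, qb_ov = qa[n1 - overlap:], qb[:overlap]
    take_b = (b_ov != _N_CODE) & ((a_ov == _N_CODE) | (qb_ov > qa_ov))
    cons = np.where(take_b, b_ov, a_ov)
    cons_q = np.maximum(qa_ov, qb_ov)
    sequence = (
        a_str[: n1 - overlap]
        + _DECODE[cons].tobytes().decode("ascii")
        + b_str[overlap:]
    )
    quality = (
        r1.qual[: n1 - overlap]
        + (cons_q.astype(np.uint8) + PHRED_OFFSET).tobytes().decode("ascii")
        + r2.qual[::-1][overlap:]
    )
    return MergedSequence(r1.id, sequence, quality, overlap, mismatches)


@dataclass
class MergeSummary:
    """Per-batch merge bookkeeping: counts, rate, and overlap histogram."""

    input: int = 0
    merged: int = 0
    failures: Counter = field(default_factory=Counter)
    overlap_histogram: Counter = field(default_factory=Counter)

    @property
    def merge_rate(self) -> float:
        return 100.0 * self.merged / self.input if self.input else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "input_pairs", "value": self.input},
            {"metric": "merged", "value": self.merged},
            {"metric": "merge_rate_percent", "value": round(self.merge_rate, 1)},
        ]
        rows += [
            {"metric": f"failed_{reason}", "value": n}
            for reason, n in sorted(self.failures.items())
        ]
        return pd.DataFrame(rows)


def merge_pairs(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Iterator[MergeResult]:
    for r1, r2 in pairs:
        yield merge_pair(r1, r2, min_overlap, max_mismatch_frac)


def merge_batch(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    out: str | Path | None = None,
    summary_path: str | Path | None = None,
) -> tuple[MergeSummary, list[MergedSequence]]:
    """Merge a stream of pairs; optionally write merged FASTQ and a summary TSV.

    Returns the summary and the list of merged sequences (kept in memory;
    pass `out` and ignore the list for large file-based runs).
    """
    summary = MergeSummary()
    merged: list[MergedSequence] = []
    writer = FastqWriter(out) if out is not None else None
    try:
        for result in merge_pairs(pairs, min_overlap, max_mismatch_frac):
            summary.input += 1
            if isinstance(result, MergedSequence):
                summary.merged += 1
                summary.overlap_histogram[result.overlap_length] += 1
                if writer is not None:
                    writer.write(result.to_fastq())
                else:
                    merged.append(result)
            else:
                summary.failures[result.reason] += 1
    finally:
        if writer is not None:
            writer.close()
    if summary_path is not None:
        summary.to_frame().to_csv(summary_path, sep="\t", index=False)
    return summary, merged
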