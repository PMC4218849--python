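"""End-to-end orchestration: demultiplex -> call -> merge -> report.

`run_all` chains the pipeline stages in memory over the four FASTQ
streams, enforces cluster conservation end-to-end, and emits a machine-
readable manifest (tool version, parameter snapshot, input checksums,
per-stage counts) alongside the counts and frequency tables.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from ._io import FastqRecord
from .demux import CONTAMINANT, SAMPLE_UNDETERMINED, DemuxTally, ReadQuad, SampleSheet, demultiplex, read_quads
from .merge import MergedSequence, merge_pair
from .report import (
    ASSIGNED_CATEGORIES,
    CountsTable,
    consensus_collapse,
    frequency_table,
    is_rearranged_standin,
    run_summary,
)
from .scheme import CATEGORIES, SubtypeScheme


class PipelineError(RuntimeError):
    """Fatal pipeline error, carrying the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    counts: CountsTable
    frequencies: pd.DataFrame
    manifest: dict
    collapsed: pd.DataFrame | None = None


def _checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_all(
    r1: str | Path,
    r2: str | Path,
    i1: str | Path,
    i2: str | Path,
    sheet: SampleSheet,
    scheme: SubtypeScheme,
    outdir: str | Path | None = None,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    trim_prefix: int = 0,
    collapse: bool = False,
    min_rearranged_length: int = 250,
    rearrangement_status: Mapping[str, bool] | None = None,
    log=sys.stderr,
) -> PipelineResult:
    """Run the full pipeline over four FASTQ files.

    Rearrangement status comes from `rearrangement_status` (an external
    annotator's cluster-id -> bool map) when provided, else from the
    length-heuristic stand-in (merged and >= `min_rearranged_length` nt);
    the manifest records which rule was used.
    """
    for name, path in (("R1", r1), ("R2", r2), ("I1", i1), ("I2", i2)):
        if not Path(path).exists():
            raise PipelineError("demux", f"missing {name} input stream: {path}")

    tally = DemuxTally()
    buckets: dict[tuple[str, str], list[tuple[FastqRecord, FastqRecord]]] = {}
    try:
        for sample, category, quad in demultiplex(
            read_quads(r1, r2, i1, i2), sheet, scheme, trim_prefix=trim_prefix
        ):
            tally.add(sample, category)
            if category is not None:
                buckets.setdefault((sample, category), []).append((quad.r1, quad.r2))
    except Exception as exc:  # re-tag stream errors with the stage name
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("demux", str(exc)) from exc

    rows = []
    merged_by_bucket: dict[tuple[str, str], list[MergedSequence]] = {}
    n_merged = n_rearranged = 0
    for sample in sheet.samples:
        for category in CATEGORIES:
            pairs = buckets.get((sample, category), [])
            row = {
                "sample": sample,
                "category": category,
                "assigned_pairs": len(pairs),
                "merged": np.nan,
                "rearranged": np.nan,
            }
            if category in ASSIGNED_CATEGORIES:
                merged = [
                    m
                    for m in (
                        merge_pair(a, b, min_overlap, max_mismatch_frac) for a, b in pairs
                    )
                    if isinstance(m, MergedSequence)
                ]
                merged_by_bucket[(sample, category)] = merged
                if rearrangement_status is not None:
                    rearranged = sum(
                        rearrangement_status.get(m.cluster_id, False) for m in merged
                    )
                else:
                    rearranged = sum(
                        is_rearranged_standin(len(m.sequence), min_rearranged_length)
                        for m in merged
                    )
                row["merged"] = len(merged)
                row["rearranged"] = rearranged
                n_merged += len(merged)
                n_rearranged += rearranged
            rows.append(row)

    counts = CountsTable(
        frame=pd.DataFrame(rows),
        total_reads=tally.total,
        sample_undetermined=tally.sample_undetermined + tally.contaminant,
        contaminant=tally.contaminant,
    )
    if not tally.conserved():
        raise PipelineError("report", "cluster conservation violated across stages")

    frequencies = frequency_table(counts)

    collapsed = None
    if collapse:
        records = [
            (m.sequence, category)
            for (sample, category), ms in merged_by_bucket.items()
            for m in ms
        ]
        collapsed = consensus_collapse(records)

    manifest = {
        "tool": "igphase",
        "version": __version__,
        "inputs": {name: _checksum(p) for name, p in
                   (("r1", r1), ("r2", r2), ("i1", i1), ("i2", i2))},
        "params": {
            "min_overlap": min_overlap,
            "max_mismatch_frac": max_mismatch_frac,
            "trim_prefix": trim_prefix,
            "collapse": collapse,
            "i2_max_mismatch": sheet.i2_max_mismatch,
            "rearrangement_rule": (
                "external" if rearrangement_status is not None
                else f"standin:min_length={min_rearranged_length}"
            ),
        },
        "stage_counts": {
            "input_clusters": tally.total,
            "contaminant": tally.contaminant,
            "sample_undetermined": tally.sample_undetermined,
            "subtype_assigned": sum(
                len(v) for (_, c), v in buckets.items() if c in ASSIGNED_CATEGORIES
            ),
            "merged": n_merged,
            "rearranged": n_rearranged,
        },
    }
    if log is not None:
        for stage, n in manifest["stage_counts"].items():
            print(f"igphase run: {stage} = {n}", file=log)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts.to_tsv(outdir / "counts.tsv")
        frequencies.to_csv(outdir / "frequencies.tsv", sep="\t")
        if collapsed is not None:
            collapsed.to_csv(outdir / "collapsed.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2)
        summary = run_summary(counts)
        with open(outdir / "run_summary.json", "w") as handle:
            json.dump(summary, handle, indent=2)

    return PipelineResult(counts, frequencies, manifest, collapsed)
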