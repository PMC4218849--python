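"""Category tallies, subclass frequencies, replicate aggregation, consensus.

Subclass frequencies are defined as the percentage of completely indexed,
full-length variable-region rearrangements: for a sample,
``freq(c) = 100 * rearranged(c) / sum over IgG1..IgG4 of rearranged``,
with the pooled light-chain/other-isotype category (klMA) and the
undetermined bin excluded from numerator and denominator. Whether a
merged sequence is a bona fide rearrangement is decided externally by a
V(D)J annotator in a production run; a clearly-labelled length heuristic
stands in when no annotation is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

IGG_SUBTYPES = ("IgG1", "IgG2", "IgG3", "IgG4")
ASSIGNED_CATEGORIES = IGG_SUBTYPES + ("klMA",)
COLUMNS = ("sample", "category", "assigned_pairs", "merged", "rearranged")

#: Stand-in rearrangement rule: merged and at least this long (nt).
DEFAULT_MIN_REARRANGED_LENGTH = 250


class ReportError(ValueError):
    """Raised for undefined report quantities (e.g. all-zero denominators)."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching tabular presentation."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CountsTable:
    """Per-(sample, category) pipeline counts plus run-level totals.

    `frame` holds one row per (sample, category) with assigned_pairs,
    merged and rearranged counts (NaN where a stage does not apply, e.g.
    merged counts of the subtype-undetermined bin). Run-level totals are
    carried separately: total passing-filter read pairs, pairs that could
    not be demultiplexed to a sample, and the subset of those carrying
    the reserved contaminant index.
    """

    frame: pd.DataFrame
    total_reads: int | None = None
    sample_undetermined: int | None = None
    contaminant: int | None = None

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"counts table lacks columns: {sorted(missing)}")
        self.validate()

    def validate(self) -> None:
        f = self.frame
        bad = f[(f["merged"] > f["assigned_pairs"]) | (f["rearranged"] > f["merged"])]
        if len(bad):
            raise ValueError(
                "count monotonicity violated (rearranged <= merged <= assigned): "
                f"{bad[['sample', 'category']].to_dict('records')}"
            )

    def sample_rows(self, sample: str) -> pd.DataFrame:
        rows = self.frame[self.frame["sample"] == sample]
        if rows.empty:
            raise KeyError(f"unknown sample {sample!r}")
        return rows

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample"]))

    # -- serialisation ---------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountsTable":
        """Read a counts TSV; ``#key<TAB>value`` lines carry run totals."""
        meta: dict[str, int] = {}
        with open(path) as handle:
            for line in handle:
                if line.startswith("#") and "\t" in line:
                    key, _, value = line[1:].partition("\t")
                    if value.strip().isdigit():
                        meta[key.strip()] = int(value)
        frame = pd.read_csv(
            path, sep="\t", comment="#", na_values=["na", "nd"], dtype={"sample": str}
        )
        return cls(
            frame=frame,
            total_reads=meta.get("total_reads"),
            sample_undetermined=meta.get("sample_undetermined"),
            contaminant=meta.get("contaminant"),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for key in ("total_reads", "sample_undetermined", "contaminant"):
                value = getattr(self, key)
                if value is not None:
                    handle.write(f"#{key}\t{value}\n")
            self.frame.to_csv(handle, sep="\t", index=False, na_rep="na")


def subtype_frequencies(counts: CountsTable, sample: str) -> pd.Series:
    """IgG1-4 frequencies (percent, one decimal) for one sample.

    klMA and undetermined never enter numerator or denominator.
    """
    rows = counts.sample_rows(sample).set_index("category")["rearranged"]
    values = {c: float(rows.get(c, np.nan)) for c in IGG_SUBTYPES}
    values = {c: 0.0 if np.isnan(v) else v for c, v in values.items()}
    denom = sum(values.values())
    if denom <= 0:
        raise ReportError(f"sample {sample!r}: no rearranged IgG sequences")
    return pd.Series(
        {c: round_half_up(100.0 * v / denom) for c, v in values.items()}, name=sample
    )


def frequency_table(counts: CountsTable) -> pd.DataFrame:
    """One frequency row per sample (samples with no IgG counts are skipped)."""
    rows = []
    for sample in counts.samples:
        try:
            rows.append(subtype_frequencies(counts, sample))
        except ReportError:
            continue
    return pd.DataFrame(rows)


def aggregate_preps(freq_rows: pd.DataFrame | Sequence[pd.Series], ddof: int = 0) -> pd.DataFrame:
    """Mean +/- SD over replicate library preparations, one decimal.

    SD uses the population convention (ddof=0) by default; with a single
    replicate the SD column is NaN. The convention used is recorded in
    the frame attrs.
    """
    frame = pd.DataFrame(list(freq_rows)) if not isinstance(freq_rows, pd.DataFrame) else freq_rows
    if frame.empty:
        raise ReportError("no replicate rows to aggregate")
    mean = frame.mean().map(round_half_up)
    if len(frame) >= 2:
        sd = frame.std(ddof=ddof).map(round_half_up)
    else:
        sd = pd.Series(np.nan, index=frame.columns)
    out = pd.DataFrame({"mean": mean, "sd": sd})
    out.attrs["ddof"] = ddof
    out.attrs["n_replicates"] = len(frame)
    return out


def _assigned_rows(counts: CountsTable) -> pd.DataFrame:
    return counts.frame[counts.frame["category"].isin(ASSIGNED_CATEGORIES)]


def run_assignment_rate(counts: CountsTable) -> float:
    """Percent of sample-demultiplexed pairs assigned a subclass category."""
    if counts.total_reads is None or counts.sample_undetermined is None:
        raise ReportError("run totals (total_reads, sample_undetermined) required")
    denom = counts.total_reads - counts.sample_undetermined
    if denom <= 0:
        raise ReportError("no reads demultiplexed to any sample")
    assigned = _assigned_rows(counts)["assigned_pairs"].sum(skipna=True)
    return 100.0 * float(assigned) / denom


def run_merge_rate(counts: CountsTable) -> float:
    """Percent of subclass-assigned pairs successfully stitched."""
    rows = _assigned_rows(counts)
    assigned = float(rows["assigned_pairs"].sum(skipna=True))
    if assigned <= 0:
        raise ReportError("no assigned pairs")
    return 100.0 * float(rows["merged"].sum(skipna=True)) / assigned


def run_summary(counts: CountsTable) -> dict[str, float]:
    """Run-level rates (percent, one decimal) and the rearranged grand total."""
    out: dict[str, float] = {}
    out["assignment_rate_percent"] = round_half_up(run_assignment_rate(counts))
    out["merge_rate_percent"] = round_half_up(run_merge_rate(counts))
    out["total_rearranged"] = int(_assigned_rows(counts)["rearranged"].sum(skipna=True))
    if counts.total_reads:
        if counts.sample_undetermined is not None:
            out["sample_undetermined_percent"] = round_half_up(
                100.0 * counts.sample_undetermined / counts.total_reads
            )
        if counts.contaminant is not None:
            out["contaminant_percent"] = round_half_up(
                100.0 * counts.contaminant / counts.total_reads
            )
    return out


# -- consensus collapse --------------------------------------------------


def consensus_collapse(
    records: Iterable[tuple[str, object]]
) -> pd.DataFrame:
    """Collapse identical variable-region sequences; vote on the subclass.

    `records` yields ``(sequence, call)`` where `call` is a subclass label
    or an object with a ``label`` attribute. Per identical-sequence group
    the consensus is the plurality subclass among non-undetermined calls;
    a tie at the top, or a group with only undetermined calls, stays
    undetermined. A group whose members all agree therefore always keeps
    its label.
    """
    groups: dict[str, dict[str, int]] = {}
    sizes: dict[str, int] = {}
    for seq, call in records:
        label = getattr(call, "label", call)
        sizes[seq] = sizes.get(seq, 0) + 1
        if label != "undetermined":
            groups.setdefault(seq, {})
            groups[seq][label] = groups[seq].get(label, 0) + 1
    rows = []
    for seq, size in sizes.items():
        votes = groups.get(seq, {})
        if not votes:
            consensus = "undetermined"
        else:
            top = max(votes.values())
            leaders = [lab for lab, n in votes.items() if n == top]
            consensus = leaders[0] if len(leaders) == 1 else "undetermined"
        rows.append({"sequence": seq, "consensus": consensus, "n_members": size})
    return pd.DataFrame(rows, columns=["sequence", "consensus", "n_members"])


# -- rearrangement status ------------------------------------------------


def is_rearranged_standin(
    merged_length: int, min_length: int = DEFAULT_MIN_REARRANGED_LENGTH
) -> bool:
    """Length-heuristic stand-in for external V(D)J annotation.

    A merged sequence counts as a full-length rearrangement when it is at
    least `min_length` nt. Outputs derived from this rule are labelled
    as stand-ins; ingest an annotator TSV for production use.
    """
    return merged_length >= min_length


def load_rearrangement_status(path: str | Path) -> Mapping[str, bool]:
    """Read an external annotator's TSV of ``cluster_id<TAB>status``.

    Status values {1, true, yes, rearranged} (case-insensitive) are
    treated as rearranged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    ids, status = df.columns[0], df.columns[1]
    truthy = {"1", "true", "yes", "rearranged"}
    return {
        row[ids]: str(row[status]).strip().lower() in truthy
        for _, row in df.iterrows()
    }
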