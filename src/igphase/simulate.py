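"""Ground-truthed four-read amplicon run simulator.

Emulates the amplicon and run structure the pipeline expects: each
cluster's insert is 4 random nucleotides + a leader stub + a random
V(D)J-like core + the subclass's CH1 5' stub, sequenced as read 1 (5'
end), read 2 (reverse complement of the 3' end), index read 1 (the
subclass identifier) and index read 2 (the sample index). A configurable
fraction of PhiX-like contaminant clusters carries random sequence and
the reserved adaptor-derived index. Substitution errors are injected
independently per read at configurable per-base rates; a fixed seed
makes the output byte-identical across runs.

Defaults mirror a 2x250 MiSeq run with ~360-nt heavy-chain V regions,
which puts the read-pair overlap around 100 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from ._io import FastqRecord, open_text, write_fastq
from .demux import ReadQuad, SampleSheet
from .scheme import KLMA, SubtypeScheme, reverse_complement

#: CH1 nt 1-6 per subclass; the third base is the read-2 discriminator
#: determinant (complemented: C -> G for IgG2, T -> A for IgG4).
CONSTANT_STUBS = {
    "IgG1": "GCCTCC",
    "IgG2": "GCCTCC",
    "IgG3": "GCTTCC",
    "IgG4": "GCTTCC",
    KLMA: "GGTACG",  # light-chain-like stub; klMA is identified by index 1 alone
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated cluster, joinable by cluster id."""

    cluster_id: str
    sample: str
    subtype: str
    template: str
    true_overlap: int


@dataclass(frozen=True)
class SimConfig:
    """Stated world of a simulated run.

    `mixtures` maps each sample to its subclass proportions (over IgG1-4
    and klMA; must sum to 1). Read geometry defaults to the 2x250 + 12 +
    8 cycle layout; the V-like core length is normal around 360 nt so
    that templates average ~400 nt and read pairs overlap by ~100 nt.
    Error rates are per-base substitution probabilities per read.
    """

    mixtures: Mapping[str, Mapping[str, float]]
    n_clusters: int = 10_000
    read_length: int = 250
    leader_length: int = 30
    random_prefix_length: int = 4
    v_length_mean: float = 360.0
    v_length_sd: float = 25.0
    error_rate_r1: float = 0.0
    error_rate_r2: float = 0.0
    error_rate_i1: float = 0.0
    error_rate_i2: float = 0.0
    contaminant_fraction: float = 0.0
    base_quality: int = 37
    quality_decay: float = 0.0  # linear per-base 3' quality drop
    seed: int = 0
    sample_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for rate in (self.error_rate_r1, self.error_rate_r2,
                     self.error_rate_i1, self.error_rate_i2,
                     self.contaminant_fraction):
            if not 0.0 <= rate < 1.0:
                raise SimulationError(f"rate {rate} outside [0, 1)")
        for sample, mix in self.mixtures.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(
                    f"sample {sample!r}: subclass proportions sum to {total}, not 1"
                )


def mutate_read(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability `rate`.

    Substitutions are uniform over the three alternative bases; non-ACGT
    characters are left untouched. Deterministic under a fixed rng state.
    """
    if not 0.0 <= rate < 1.0:
        raise SimulationError(f"rate {rate} outside [0, 1)")
    if rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = np.full(len(arr), 255, dtype=np.uint8)
    for code, base in enumerate(b"ACGT"):
        idx[arr == base] = code
    hit = (rng.random(len(arr)) < rate) & (idx != 255)
    n_hit = int(hit.sum())
    if n_hit:
        shifts = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(idx[hit] + shifts) % 4]
    return arr.tobytes().decode("ascii")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _quality_string(length: int, config: SimConfig) -> str:
    quals = np.maximum(
        2, (config.base_quality - config.quality_decay * np.arange(length)).astype(int)
    )
    return (quals.astype(np.uint8) + 33).tobytes().decode("ascii")


def _pick_identifier(scheme: SubtypeScheme, subtype: str) -> str:
    cls = {"IgG2": "IgG24", "IgG4": "IgG24"}.get(subtype, subtype)
    seqs = scheme.identifiers.get(cls, ())
    if not seqs:
        raise SimulationError(f"scheme has no identifier for subtype {subtype!r}")
    return seqs[0]


def simulate_records(
    config: SimConfig, scheme: SubtypeScheme, sheet: SampleSheet
) -> Iterator[tuple[ReadQuad, TruthRecord]]:
    """Yield (ReadQuad, TruthRecord) per simulated cluster."""
    for sample, mix in config.mixtures.items():
        if sample not in sheet.samples:
            raise SimulationError(f"sample {sample!r} missing from the sample sheet")
        for subtype in mix:
            _pick_identifier(scheme, subtype)  # fail fast on absent subtypes

    rng = np.random.default_rng(config.seed)
    samples = list(config.mixtures)
    if config.sample_weights is not None:
        weights = np.array([config.sample_weights[s] for s in samples], dtype=float)
        weights = weights / weights.sum()
    else:
        weights = np.full(len(samples), 1.0 / len(samples))

    for n in range(config.n_clusters):
        cid = f"sim:{n:07d}"
        if rng.random() < config.contaminant_fraction:
            template = _random_seq(
                config.random_prefix_length + config.leader_length
                + max(1, int(round(rng.normal(config.v_length_mean, config.v_length_sd))))
                + 6,
                rng,
            )
            sample, subtype = "contaminant", ""
            i1_seq = _random_seq(scheme.identifier_length, rng)
            i2_seq = sheet.contaminant_index
        else:
            sample = samples[int(rng.choice(len(samples), p=weights))]
            mix = config.mixtures[sample]
            subtypes = list(mix)
            subtype = subtypes[int(rng.choice(len(subtypes), p=np.array(list(mix.values()))))]
            v_len = max(1, int(round(rng.normal(config.v_length_mean, config.v_length_sd))))
            template = (
                _random_seq(config.random_prefix_length, rng)
                + _random_seq(config.leader_length, rng)
                + _random_seq(v_len, rng)
                + CONSTANT_STUBS[subtype]
            )
            i1_seq = _pick_identifier(scheme, subtype)
            i2_seq = sheet.samples[sample]

        r1_seq = template[: config.read_length]
        r2_seq = reverse_complement(template[-config.read_length:])
        true_overlap = len(r1_seq) + len(r2_seq) - len(template)

        r1_seq = mutate_read(r1_seq, config.error_rate_r1, rng)
        r2_seq = mutate_read(r2_seq, config.error_rate_r2, rng)
        i1_seq = mutate_read(i1_seq, config.error_rate_i1, rng)
        i2_seq = mutate_read(i2_seq, config.error_rate_i2, rng)

        quad = ReadQuad(
            cid,
            FastqRecord(cid, r1_seq, _quality_string(len(r1_seq), config)),
            FastqRecord(cid, r2_seq, _quality_string(len(r2_seq), config)),
            FastqRecord(cid, i1_seq, _quality_string(len(i1_seq), config)),
            FastqRecord(cid, i2_seq, _quality_string(len(i2_seq), config)),
        )
        yield quad, TruthRecord(cid, sample, subtype, template, true_overlap)


def simulate_run(
    config: SimConfig,
    scheme: SubtypeScheme,
    sheet: SampleSheet,
    outdir: str | Path,
    gzip_output: bool = False,
) -> pd.DataFrame:
    """Write R1/R2/I1/I2 FASTQ files plus truth.tsv; return the truth table.

    Output is byte-identical for a fixed config (gzip members are written
    with a zeroed timestamp).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    streams = {name: [] for name in ("R1", "R2", "I1", "I2")}
    truth = []
    for quad, rec in simulate_records(config, scheme, sheet):
        streams["R1"].append(quad.r1)
        streams["R2"].append(quad.r2)
        streams["I1"].append(quad.i1)
        streams["I2"].append(quad.i2)
        truth.append(rec)
    for name, records in streams.items():
        write_fastq(outdir / f"{name.lower()}{suffix}", records)
    truth_frame = pd.DataFrame([vars(t) for t in truth])
    with open_text(outdir / "truth.tsv", "wt") as handle:
        truth_frame.to_csv(handle, sep="\t", index=False)
    return truth_frame
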