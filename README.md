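# igphase

Subtype-phased immunoglobulin repertoire sequencing analysis.

Antibody effector function depends on the constant-region isotype — for
human IgG, on the subclass IgG1–IgG4 — but a 2×250/2×300 paired-end
amplicon read over the variable region cannot reach the
subclass-determining positions of the CH1 domain when the HCDR3 is long.
`igphase` implements the analysis for a run design that solves this by
repurposing Illumina index read 1 as a short "third read" over the 5′ end
of CH1: a 12-nt identifier window there separates IgG1, IgG3 and the
merged IgG2/IgG4 pair, and one additional base near the start of read 2
(the complement of the third base of the first CH1 codon, GCC vs GCT)
resolves IgG2 from IgG4. Index read 2 keeps its usual role as the 8-nt
sample index. Light chains and other heavy-chain isotypes (the pooled
`klMA` category) carry a dedicated identifier engineered into their
reverse primer.

The package provides:

- **`igphase.scheme`** — the subclass-calling scheme: identifier sets with
  per-class mismatch tolerances (exact match for IgG classes, one
  mismatch for klMA), the read-2 discriminator rule, derivation of the
  scheme from CH1 reference sequences, and a Hamming-distance audit of
  identifier separation versus tolerances.
- **`igphase.demux`** — synchronized streaming of the four FASTQ files
  (R1/R2/I1/I2), sample assignment by index 2 with a reserved
  contaminant (PhiX-like) index, and routing of read pairs into
  per-(sample, category) buckets with conservation-checked tallies.
- **`igphase.merge`** — quality-aware 3′-overlap stitching of read pairs
  (minimum overlap 10 nt) into full-length variable regions, refusing
  ambiguous or high-mismatch junctions.
- **`igphase.report`** — subclass frequencies per sample
  (`100 · rearranged(c) / Σ_{c′∈IgG1..4} rearranged(c′)`), replicate
  aggregation (mean ± SD), run-level assignment/merge rates, and
  consensus collapse of identical variable regions by index-read
  majority vote.
- **`igphase.simulate`** — a seeded, ground-truthed four-read run
  simulator (amplicon structure, substitution errors, contaminant
  clusters) so the whole pipeline is testable without any download.
- **`igphase.cli` / `igphase.pipeline`** — `igphase
  {simulate,demux,merge,report,run}` plus `run_all()`, which chains the
  stages and emits a reproducible run manifest.

## Worked example

Simulate a small three-sample run and push it through the full pipeline:

```python
from igphase import SampleSheet, SimConfig, default_scheme, simulate_run, run_all

scheme = default_scheme()
sheet = SampleSheet(samples={"s1": "TATAGCCT", "s2": "ATAGAGGC", "s3": "CCTATCCT"})
mix = {"IgG1": 0.55, "IgG2": 0.28, "IgG3": 0.09, "IgG4": 0.03, "klMA": 0.05}
config = SimConfig(mixtures={"s1": mix, "s2": mix, "s3": mix},
                   n_clusters=10_000, contaminant_fraction=0.05,
                   error_rate_i1=0.002, seed=1)
simulate_run(config, scheme, sheet, "run/")
result = run_all("run/r1.fastq", "run/r2.fastq", "run/i1.fastq", "run/i2.fastq",
                 sheet, scheme)
print(result.frequencies)
```

prints the per-sample IgG subclass frequencies (percent of full-length
rearrangements; klMA excluded from the denominator):

```
    IgG1  IgG2  IgG3  IgG4
s1  57.7  29.2   9.9   3.2
s2  57.6  30.0   8.8   3.5
s3  58.1  29.2  10.2   2.5
```

— close to the configured IgG-internal mixture (57.9 / 29.5 / 9.5 / 3.2 %
after renormalising away the 5 % klMA fraction). With a 0.002 per-base
identifier error rate about 2–3 % of clusters fail the strict exact-match
rule and land in `undetermined` (here the assignment rate is 97.0 %);
the 5 % contaminant clusters are recognised by the reserved index.

The report stage can equally ingest externally produced counts. Running
it over the packaged benchmark table (`igphase/data/benchmark_counts.tsv`,
a published five-sample run: four replicate preparations of one healthy
donor plus one HIV-1 patient time point) gives IgG1 = 56.3 % for donor
prep 1, a four-prep aggregate of 56.1 ± 0.2 %, a run-level assignment
rate of 97.5 % and a merge rate of 96.7 %.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the benchmark-count report (per-sample
frequencies, replicate aggregate, run-level rates) and a seeded
10,000-cluster simulated run executed end to end through demultiplexing,
subclass calling, merging and reporting. Progress and the computed
summaries go to standard error; the target JSON is written to `--out`.
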