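# Methods

## The run design being analysed

Each sequenced cluster carries four reads: read 1 (forward, over the 4
random primer nucleotides, the leader and the 5′ part of the V region),
read 2 (reverse strand, from just upstream of the constant-region primer
back across the V region), index read 1 (12 cycles, repurposed as the
subclass identifier) and index read 2 (8 cycles, the sample index). The
identifier read is primed by a sequencing primer whose binding site ends
at CH1 position 45, so it reads CH1 positions 46–57 of the coding
strand. Read 2's primer binds CH1 positions 7 ff., so read-2 position
`k` is the complemented base of CH1 position `7 − k`; position 4 is the
complement of the third base of the first CH1 codon.

## Subclass-calling model

The default scheme (packaged as `data/default_scheme.yaml`) uses the
CH1 46–57 windows:

| class | identifier | distinguishing positions |
|-------|-----------|--------------------------|
| IgG1  | `AAGAGCACCTCT` | codon 16 AAG (K), codon 19 TCT |
| IgG3  | `AGGAGCACCTCT` | codon 16 AGG (R), codon 19 TCT |
| IgG2/4 | `AGGAGCACCTCC` | codon 19 TCC (shared window) |
| klMA  | `TTCTCGTGGAGA` | base-wise complement of the IgG1 identifier |

The IgG identifiers are mutually one to two nucleotides apart, so IgG
classes require a perfect identifier match (`igg_max_mismatch = 0`); the
klMA identifier is 12 nt from every IgG identifier, so one mismatch is
tolerated there (`klma_max_mismatch = 1`). Calling order is fixed —
IgG1, IgG3, IgG2/4, then klMA, then undetermined — so the looser klMA
ball can never shadow an exact IgG hit. The shared IgG2/4 window is
resolved by read-2 position 4: G → IgG2, A → IgG4; any other base
(including N, or a read 2 too short to cover the position) is
undetermined, because only those two bases are informative. `N` in a
compared position always counts as a mismatch. Input is uppercased and
U→T mapped.

`derive_scheme` reconstructs this scheme from CH1 references: it locates
the indexing-primer anchor (IUPAC-degenerate exact match) in each
allele, extracts the 12-nt window 3′ of it, groups identical windows,
and, when IgG2 and IgG4 windows coincide, searches the CH1 positions
upstream of the read-2 primer for a base that consistently separates the
two subclasses. A window shared by any other subclass combination is a
derivation error. Classes may hold several accepted identifiers (allele
variants); membership is "within tolerance of any accepted sequence".
The klMA identifier is engineered into the reverse primer rather than
encoded in CH1, so it is always supplied as explicit configuration.

The packaged CH1 FASTA (`data/ch1_refs_synthetic.fasta`) is a *synthetic
reconstruction* of the first 60 nt of the IGHG1–4 CH1 regions from the
known CH1 protein sequences and the documented subclass-determining
positions; it exists so that scheme derivation is testable offline and
is not a substitute for curated reference alleles.

`validate_scheme` reports the full pairwise Hamming matrix and flags a
scheme unsafe when any cross-class identifier pair sits within the sum
of the two classes' tolerances (overlapping tolerance balls). Scheme
construction itself rejects outright ambiguity (a klMA identifier within
`klma_max_mismatch` of an IgG identifier).

## Demultiplexing

Index 2 is matched against the sample sheet with `i2_max_mismatch`
tolerated mismatches (default 1 — vendor demultiplexers commonly default
to one; configurable down to 0). Sample indices must be pairwise more
than `2 · i2_max_mismatch` apart (guard optional via
`enforce_separation=False`); residual ties at the minimal distance are
undetermined. Clusters matching the reserved contaminant index — default
`TCTTTCCC`, the 8-mer an index-free universal-adaptor (PhiX-like)
cluster exposes at the index-2 position — are counted separately from
sample-undetermined clusters. The four streams are verified in lock-step
by cluster id; any disagreement is fatal and names the offending
records. Quality strings pass through untouched and the 4 random read-1
prefix nucleotides are retained by default (`trim_prefix` removes a
fixed-length prefix on request).

## Merging

Read 2 is reverse-complemented; candidate overlap lengths
`L ∈ [min_overlap, min(|r1|, |r2|)]` are scored by
`Σ s_i (q1_i + q2_i)/2`, with `s_i = +1` for a match and `−1` for a
mismatch (N is never a match). This separable objective is computed for
all L at once from per-base-channel convolutions, so merging is O(|r1|·|r2|)
in vectorised numpy per pair. The best-scoring candidate must be unique
(tied best scores → `ambiguous` failure: a guessed junction is never
emitted) and its mismatch fraction at most `max_mismatch_frac` (default
0.1 — permissive enough for 2×250 read tails, explicit and
configurable). Consensus inside the overlap takes the higher-quality
base (tie → read 1; a real base always beats N) with quality
`max(q1, q2)`, so consensus quality never drops below either input. The
default `min_overlap` of 10 nt reflects the analysed run design. The
scoring objective itself is this package's choice — the design only
fixes the minimum overlap — and gapped (indel-tolerant) alignment is out
of scope.

## Frequencies and aggregation

`freq(c) = 100 · rearranged(c) / Σ_{c′ ∈ IgG1..IgG4} rearranged(c′)`,
reported half-up to one decimal; klMA and undetermined are excluded from
both numerator and denominator. Replicate preparations aggregate as
arithmetic mean ± population SD (ddof = 0, recorded in the output
attrs; with typical four-replicate data both SD conventions round to
the same one-decimal value). Run-level rates: assignment rate =
assigned pairs (IgG1–4 + klMA) over sample-demultiplexed pairs; merge
rate = merged over assigned; contaminant and sample-undetermined shares
are fractions of all passing-filter pairs.

Whether a merged sequence is a *rearranged* full-length variable region
is an external annotator's decision; the pipeline ingests a cluster-id →
status TSV. Without one, a stand-in rule (merged and ≥ 250 nt) is
applied and labelled as such in the run manifest. A green test against
the stand-in establishes the pipeline's arithmetic, not annotation
accuracy.

Consensus collapse groups *identical* merged sequences and assigns the
plurality subclass among non-undetermined index calls; a tie at the top
or an all-undetermined group stays undetermined. Unanimous groups never
change label.

## Simulator: what it emulates and what it does not

Each cluster draws a sample (uniform by default), a subclass from the
configured per-sample mixture, and a template
`4 random nt + 30-nt leader stub + V-like random core + 6-nt CH1 stub`,
where the CH1 stub's third base encodes the IgG2/IgG4 discriminator.
The V core length is normal with mean 360 nt and SD 25 nt — matching
reported heavy-chain V-region lengths and placing the 2×250 read-pair
overlap near 100 nt. Reads are cut from the template ends (read 2
reverse-complemented), the identifier and sample index are attached, and
independent per-base substitution errors are injected per read.
Contaminant clusters carry fully random sequence, a random identifier
and the reserved index. Qualities are constant Q37 with an optional
linear 3′ decay (floor Q2). Output is byte-identical under a fixed seed
(gzip members are written with zeroed mtime).

Not emulated: indels (the pipeline's decision points — identifier match,
discriminator base, ungapped overlap — are substitution-sensitive),
somatic hypermutation and clonal structure, PCR chimeras, quality-
dependent error rates, real V-gene sequence composition (an optional
FASTA of real V genes can seed the cores). Green end-to-end tests
therefore establish decision-rule and bookkeeping correctness under the
stated error model, not robustness to indel-rich or chimeric data.

## Numerical and degenerate-input choices

- Rounding everywhere mirrors tabular presentation: decimal half-up to
  one decimal place.
- All-zero IgG rearranged counts, zero demultiplexed reads and empty
  replicate sets raise named errors instead of dividing by zero.
- A wrong-length identifier read flags the record
  (`identifier_wrong_length`) and routes it to undetermined rather than
  crashing a streaming run.
- Empty inputs demultiplex to empty outputs with a zero tally and exit
  success.
- Merge score ties are exact (integer-valued quality sums in float64),
  so the ambiguity test needs no epsilon.

## Known limitations

- The separation guard on sample sheets assumes a single global
  `i2_max_mismatch`; per-sample tolerances are not modelled.
- `run_all` holds per-bucket read pairs in memory; it is sized for
  simulator-scale runs (10^4–10^6 clusters), while the per-stage CLI
  subcommands stream to disk for larger inputs.
- The length stand-in for rearrangement status over-counts templates
  that merge but are not productive rearrangements; it exists to close
  the pipeline for testing.
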