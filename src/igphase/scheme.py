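"""IgG subclass calling scheme: identifier sets, discriminator rule, derivation.

The subclass of an IgG transcript is phased onto its variable region by
repurposing Illumina index read 1 as a short "third read" over the 5' end
of the CH1 constant domain. A 12-nt identifier window there separates
IgG1, IgG3 and the merged IgG2/IgG4 pair; IgG2 and IgG4 are then resolved
by a single discriminating base near the start of read 2 (the complement
of the third base of the first CH1 codon, GCC vs GCT). Light chains and
other heavy-chain isotypes (the pooled klMA category) carry a dedicated
identifier engineered into their reverse primer.

This module defines the scheme container, calls subclasses per read,
derives a scheme from CH1 reference sequences, and reports pairwise
identifier Hamming distances so that mismatch tolerances can be audited
against identifier separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

from importlib import resources

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC degenerate nucleotide codes and the plain bases they accept.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IGG_CLASSES = ("IgG1", "IgG3", "IgG24")
KLMA = "klMA"
UNDETERMINED = "undetermined"
#: The six per-sample categories a cluster can end up in.
CATEGORIES = ("IgG1", "IgG2", "IgG3", "IgG4", "klMA", "undetermined")


class SchemeError(ValueError):
    """Raised when a scheme violates its structural invariants."""


class SchemeDerivationError(ValueError):
    """Raised when a scheme cannot be derived from CH1 references."""


def normalize(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize(seq).translate(COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length sequences.

    An ``N`` on either side always counts as a mismatch; other IUPAC
    degeneracy in `a` (the reference side) is honoured.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    d = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            d += 1
        elif y not in IUPAC.get(x, x):
            d += 1
    return d


def _matches_degenerate(primer: str, window: str) -> bool:
    """Exact IUPAC-degenerate match of `primer` against a same-length window."""
    return len(primer) == len(window) and all(
        w in IUPAC.get(p, p) for p, w in zip(primer, window)
    )


def find_degenerate(primer: str, seq: str) -> int:
    """Return the 0-based start of the first IUPAC-degenerate occurrence, or -1."""
    primer = normalize(primer)
    seq = normalize(seq)
    for start in range(len(seq) - len(primer) + 1):
        if _matches_degenerate(primer, seq[start:start + len(primer)]):
            return start
    return -1


@dataclass(frozen=True)
class DiscriminatorRule:
    """Resolves the merged IgG2/IgG4 identifier class via one read-2 base.

    `position` is 1-based within the read named by `read`. Bases absent
    from `base_map` (including N) yield `fallback`.
    """

    read: str = "r2"
    position: int = 4
    base_map: Mapping[str, str] = field(
        default_factory=lambda: {"G": "IgG2", "A": "IgG4"}
    )
    fallback: str = UNDETERMINED

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SchemeError(f"discriminator position must be >= 1, got {self.position}")
        for base in self.base_map:
            if base not in "ACGT" or len(base) != 1:
                raise SchemeError(f"discriminator base_map key {base!r} is not a canonical base")

    def resolve(self, r2: str) -> str:
        r2 = normalize(r2)
        if len(r2) < self.position:
            return self.fallback
        return self.base_map.get(r2[self.position - 1], self.fallback)


@dataclass(frozen=True)
class SubtypeCall:
    """Outcome of calling one cluster's identifier read.

    `flag` records per-record rejection reasons (e.g. a wrong-length
    identifier read) without crashing a streaming run.
    """

    label: str
    matched_identifier: str = ""
    mismatches: int = 0
    flag: str | None = None


@dataclass(frozen=True)
class SubtypeScheme:
    """Identifier sets plus tolerances and the IgG2/4 discriminator.

    Each class may accept several identifier sequences (allele variants);
    membership is "within tolerance of any accepted sequence". IgG classes
    use `igg_max_mismatch` (default 0: a perfect match is required because
    inter-identifier Hamming distances are single nucleotides); the klMA
    class tolerates `klma_max_mismatch` (default 1, safe because its
    identifier is the complement of the IgG1 identifier and far from all
    IgG identifiers).
    """

    identifier_length: int = 12
    identifiers: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    igg_max_mismatch: int = 0
    klma_max_mismatch: int = 1
    discriminator: DiscriminatorRule = field(default_factory=DiscriminatorRule)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cls, seqs in self.identifiers.items():
            for s in seqs:
                if len(s) != self.identifier_length:
                    raise SchemeError(
                        f"identifier {s!r} of class {cls} has length {len(s)}, "
                        f"expected {self.identifier_length}"
                    )
                if s in seen and seen[s] != cls:
                    raise SchemeError(
                        f"identifier {s!r} shared between classes {seen[s]} and {cls}"
                    )
                seen[s] = cls
        # tolerance-ball guard: a klMA ball must not reach any IgG identifier
        for kseq in self.identifiers.get(KLMA, ()):
            for cls in IGG_CLASSES:
                for iseq in self.identifiers.get(cls, ()):
                    if hamming(iseq, kseq) <= self.klma_max_mismatch:
                        raise SchemeError(
                            f"klMA identifier {kseq!r} within klma_max_mismatch="
                            f"{self.klma_max_mismatch} of {cls} identifier {iseq!r}: "
                            "scheme is ambiguous"
                        )

    def tolerance(self, cls: str) -> int:
        return self.klma_max_mismatch if cls == KLMA else self.igg_max_mismatch

    def iter_identifiers(self) -> Iterator[tuple[str, str]]:
        for cls, seqs in self.identifiers.items():
            for s in seqs:
                yield cls, s

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "identifier_length": self.identifier_length,
            "identifiers": {cls: list(seqs) for cls, seqs in self.identifiers.items()},
            "igg_max_mismatch": self.igg_max_mismatch,
            "klma_max_mismatch": self.klma_max_mismatch,
            "discriminator": {
                "read": self.discriminator.read,
                "position": self.discriminator.position,
                "base_map": dict(self.discriminator.base_map),
                "fallback": self.discriminator.fallback,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubtypeScheme":
        disc = d.get("discriminator", {})
        return cls(
            identifier_length=int(d["identifier_length"]),
            identifiers={k: tuple(normalize(s) for s in v) for k, v in d["identifiers"].items()},
            igg_max_mismatch=int(d.get("igg_max_mismatch", 0)),
            klma_max_mismatch=int(d.get("klma_max_mismatch", 1)),
            discriminator=DiscriminatorRule(
                read=disc.get("read", "r2"),
                position=int(disc.get("position", 4)),
                base_map=dict(disc.get("base_map", {"G": "IgG2", "A": "IgG4"})),
                fallback=disc.get("fallback", UNDETERMINED),
            ),
        )


def save_scheme(scheme: SubtypeScheme, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(scheme.to_dict(), handle, sort_keys=False)


def load_scheme(path: str | Path) -> SubtypeScheme:
    with open(path) as handle:
        return SubtypeScheme.from_dict(yaml.safe_load(handle))


def default_scheme() -> SubtypeScheme:
    """The packaged default scheme (12-nt CH1 identifiers, read-2 discriminator)."""
    ref = resources.files("igphase.data") / "default_scheme.yaml"
    return SubtypeScheme.from_dict(yaml.safe_load(ref.read_text()))


# -- subclass calling ----------------------------------------------------


def call_subtype(i1: str, r2: str, scheme: SubtypeScheme) -> SubtypeCall:
    """Call the subclass category for one cluster.

    Evaluation order is fixed: exact-tolerance IgG classes first (IgG1,
    IgG3, then the merged IgG2/4 class resolved through the read-2
    discriminator), then klMA within its looser tolerance, otherwise
    undetermined. The order guarantees the klMA tolerance ball can never
    shadow an exact IgG match.
    """
    i1 = normalize(i1)
    if len(i1) != scheme.identifier_length:
        return SubtypeCall(UNDETERMINED, flag="identifier_wrong_length")
    for cls in IGG_CLASSES:
        for ident in scheme.identifiers.get(cls, ()):
            d = hamming(ident, i1)
            if d <= scheme.igg_max_mismatch:
                if cls == "IgG24":
                    return SubtypeCall(scheme.discriminator.resolve(r2), ident, d)
                return SubtypeCall(cls, ident, d)
    for ident in scheme.identifiers.get(KLMA, ()):
        d = hamming(ident, i1)
        if d <= scheme.klma_max_mismatch:
            return SubtypeCall(KLMA, ident, d)
    return SubtypeCall(UNDETERMINED)


# -- scheme derivation from CH1 references -------------------------------


@dataclass(frozen=True)
class Ch1Allele:
    name: str
    subclass: str
    sequence: str


@dataclass(frozen=True)
class Ch1Reference:
    """CH1 5' reference sequences plus the indexing-primer anchor.

    `anchor` is the index-read sequencing primer (IUPAC-degenerate); the
    identifier window starts immediately 3' of its 3' end.
    `read2_primer_start` is the 1-based CH1 position where the read-2
    sequencing primer's binding site begins; read 2 proceeds upstream of
    it on the reverse strand, so CH1 position p (< start) appears at
    read-2 position ``start - p`` as the complemented base.
    """

    alleles: tuple[Ch1Allele, ...]
    anchor: str
    read2_primer_start: int = 7

    @classmethod
    def from_fasta(cls, path: str | Path, anchor: str,
                   read2_primer_start: int = 7) -> "Ch1Reference":
        """Load alleles from FASTA; descriptions carry ``subclass=<label>``."""
        from Bio import SeqIO

        alleles = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = dict(
                kv.split("=", 1) for kv in rec.description.split() if "=" in kv
            )
            if "subclass" not in fields:
                raise SchemeDerivationError(
                    f"allele {rec.id!r}: no 'subclass=' tag in FASTA description"
                )
            alleles.append(Ch1Allele(rec.id, fields["subclass"], normalize(str(rec.seq))))
        return cls(tuple(alleles), normalize(anchor), read2_primer_start)


def derive_scheme(
    ref: Ch1Reference,
    identifier_length: int = 12,
    klma_identifier: str | None = None,
    igg_max_mismatch: int = 0,
    klma_max_mismatch: int = 1,
) -> SubtypeScheme:
    """Derive identifier sets and the discriminator from CH1 references.

    For each allele the `identifier_length`-nt window immediately 3' of
    the anchor primer is extracted; identical windows are grouped. A
    window shared by IgG2 and IgG4 alleles forms the merged IgG24 class
    and a discriminating CH1 position upstream of the read-2 primer is
    searched for; any other cross-subclass window collision is an error.
    The klMA identifier is engineered into the reverse primers, not
    encoded in CH1, so it is supplied explicitly.
    """
    windows: dict[str, set[str]] = {}
    by_subclass: dict[str, list[Ch1Allele]] = {}
    for allele in ref.alleles:
        pos = find_degenerate(ref.anchor, allele.sequence)
        if pos < 0:
            raise SchemeDerivationError(
                f"anchor primer not found in allele {allele.name!r} ({allele.subclass})"
            )
        start = pos + len(ref.anchor)
        window = allele.sequence[start:start + identifier_length]
        if len(window) < identifier_length:
            raise SchemeDerivationError(
                f"allele {allele.name!r}: only {len(window)} nt past the anchor, "
                f"need {identifier_length}"
            )
        windows.setdefault(window, set()).add(allele.subclass)
        by_subclass.setdefault(allele.subclass, []).append(allele)

    identifiers: dict[str, list[str]] = {}
    discriminator = DiscriminatorRule()
    for window, subclasses in windows.items():
        if len(subclasses) == 1:
            identifiers.setdefault(next(iter(subclasses)), []).append(window)
        elif subclasses == {"IgG2", "IgG4"}:
            identifiers.setdefault("IgG24", []).append(window)
            discriminator = _find_discriminator(ref, by_subclass)
        else:
            raise SchemeDerivationError(
                f"identifier window {window!r} merges subclasses "
                f"{sorted(subclasses)} and no discriminator rule is available"
            )
    if klma_identifier is not None:
        identifiers[KLMA] = [normalize(klma_identifier)]
    return SubtypeScheme(
        identifier_length=identifier_length,
        identifiers={k: tuple(v) for k, v in identifiers.items()},
        igg_max_mismatch=igg_max_mismatch,
        klma_max_mismatch=klma_max_mismatch,
        discriminator=discriminator,
    )


def _find_discriminator(
    ref: Ch1Reference, by_subclass: Mapping[str, Sequence[Ch1Allele]]
) -> DiscriminatorRule:
    """Find a CH1 position upstream of the read-2 primer separating IgG2/IgG4.

    Read 2 is reverse-complementary and starts immediately upstream of the
    primer binding site, so CH1 position p maps to read-2 position
    ``read2_primer_start - p`` with the base complemented.
    """
    for p in range(1, ref.read2_primer_start):  # 1-based CH1 position
        bases = {}
        for sub in ("IgG2", "IgG4"):
            vals = {a.sequence[p - 1] for a in by_subclass.get(sub, ())}
            if len(vals) != 1:
                break
            bases[sub] = next(iter(vals))
        if len(bases) == 2 and bases["IgG2"] != bases["IgG4"]:
            return DiscriminatorRule(
                read="r2",
                position=ref.read2_primer_start - p,
                base_map={
                    reverse_complement(bases["IgG2"]): "IgG2",
                    reverse_complement(bases["IgG4"]): "IgG4",
                },
            )
    raise SchemeDerivationError(
        "IgG2 and IgG4 share an identifier window but no consistent "
        "discriminating base exists upstream of the read-2 primer"
    )


# -- validation ----------------------------------------------------------


@dataclass(frozen=True)
class DistanceReport:
    """Pairwise Hamming distances between all identifiers of a scheme."""

    labels: tuple[tuple[str, str], ...]  # (class, identifier)
    matrix: np.ndarray
    safe: bool
    unsafe_pairs: tuple[tuple[str, str, int], ...]

    def min_distance(self, classes: Sequence[str] | None = None) -> int:
        """Minimum cross-class distance, optionally restricted to some classes.

        Returns -1 when no qualifying pair exists (e.g. single-class scheme).
        """
        best = -1
        for i, (ci, _) in enumerate(self.labels):
            for j, (cj, _) in enumerate(self.labels):
                if i >= j or ci == cj:
                    continue
                if classes is not None and (ci not in classes or cj not in classes):
                    continue
                d = int(self.matrix[i, j])
                best = d if best == -1 else min(best, d)
        return best


def validate_scheme(scheme: SubtypeScheme) -> DistanceReport:
    """Report pairwise identifier distances and tolerance safety.

    A scheme is safe when, for every pair of identifiers from distinct
    classes, the Hamming distance strictly exceeds the sum of the two
    classes' mismatch tolerances — i.e. no read can fall inside two
    classes' tolerance balls at once.
    """
    labels = tuple(scheme.iter_identifiers())
    n = len(labels)
    matrix = np.zeros((n, n), dtype=int)
    unsafe = []
    for i in range(n):
        for j in range(i + 1, n):
            d = hamming(labels[i][1], labels[j][1])
            matrix[i, j] = matrix[j, i] = d
            ci, cj = labels[i][0], labels[j][0]
            if ci != cj and d <= scheme.tolerance(ci) + scheme.tolerance(cj):
                unsafe.append((labels[i][1], labels[j][1], d))
    return DistanceReport(labels, matrix, safe=not unsafe, unsafe_pairs=tuple(unsafe))
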