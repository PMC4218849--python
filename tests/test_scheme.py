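"""Subclass-calling scheme: decision rules, derivation, distance auditing."""

import itertools

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st
from importlib import resources

from igphase import (
    SubtypeScheme,
    call_subtype,
    default_scheme,
    derive_scheme,
    validate_scheme,
)
from igphase.scheme import (
    Ch1Allele,
    Ch1Reference,
    DiscriminatorRule,
    SchemeDerivationError,
    SchemeError,
    hamming,
)

IGG1 = "AAGAGCACCTCT"
IGG3 = "AGGAGCACCTCT"
IGG24 = "AGGAGCACCTCC"
KLMA = "TTCTCGTGGAGA"
ANCHOR = "CCATCGGTCTTCCCCCTGGCRCCCTSCTCC"


class TestCallSubtype:
    @pytest.mark.parametrize(
        "i1, r2, expected",
        [
            (IGG1, "ACGT", "IgG1"),  # exact IgG1 identifier
            (IGG3, "ACGT", "IgG3"),
            (IGG24, "CTGG", "IgG2"),  # discriminator base 4 = G
            (IGG24, "CTGA", "IgG4"),  # discriminator base 4 = A
            (IGG24, "CTGT", "undetermined"),  # uninformative discriminator base
            (IGG24, "CTGN", "undetermined"),
            (IGG24, "", "undetermined"),  # empty read 2
            ("T" + IGG1[1:], "ACGT", "undetermined"),  # 1 mm from IgG1: IgG needs exact
            (KLMA[:-1] + "T", "ACGT", "klMA"),  # 1 mm tolerated for klMA
            ("ACACACACACAC", "ACGT", "undetermined"),  # far from everything
            (IGG1.lower(), "acgt", "IgG1"),  # case normalisation
            (IGG1.replace("T", "U"), "ACGT", "IgG1"),  # RNA alphabet
            ("N" + IGG1[1:], "ACGT", "undetermined"),  # N counts as mismatch
        ],
    )
    def test_decision_rules(self, scheme, i1, r2, expected):
        assert call_subtype(i1, r2, scheme).label == expected

    def test_wrong_length_flagged_not_crash(self, scheme):
        call = call_subtype(IGG1 + "A", "ACGT", scheme)
        assert call.label == "undetermined"
        assert call.flag == "identifier_wrong_length"

    def test_mismatch_count_reported(self, scheme):
        call = call_subtype(KLMA[:-1] + "T", "ACGT", scheme)
        assert call.mismatches == 1
        assert call.matched_identifier == KLMA

    def test_determinism(self, scheme):
        calls = {call_subtype(IGG24, "CTGA", scheme) for _ in range(5)}
        assert len(calls) == 1


def _oracle(i1, r2, scheme):
    """Brute-force nearest-identifier reference applying the same tolerances.

    Candidates within their class tolerance are ranked by distance; the
    fixed IgG-before-klMA order breaks any residual ties.
    """
    order = {"IgG1": 0, "IgG3": 1, "IgG24": 2, "klMA": 3}
    eligible = []
    for cls, ident in scheme.iter_identifiers():
        d = hamming(ident, i1)
        if d <= scheme.tolerance(cls):
            eligible.append((d, order[cls], cls))
    if not eligible:
        return "undetermined"
    _, _, cls = min(eligible)
    if cls == "IgG24":
        return scheme.discriminator.resolve(r2)
    return cls


class TestOracleAgreement:
    def test_exhaustive_distance_one(self, scheme):
        """All single-position perturbations of every identifier agree with
        the brute-force nearest-identifier oracle."""
        for _, ident in scheme.iter_identifiers():
            for pos in range(len(ident)):
                for base in "ACGTN":
                    read = ident[:pos] + base + ident[pos + 1:]
                    for r2 in ("CTGG", "CTGA", "CTGT"):
                        assert (
                            call_subtype(read, r2, scheme).label
                            == _oracle(read, r2, scheme)
                        ), (read, r2)

    def test_random_distance_two(self, scheme):
        import numpy as np

        rng = np.random.default_rng(42)
        idents = [s for _, s in scheme.iter_identifiers()]
        for _ in range(500):
            ident = idents[rng.integers(len(idents))]
            p1, p2 = rng.choice(len(ident), size=2, replace=False)
            read = list(ident)
            for p in (p1, p2):
                read[p] = "ACGT"[(("ACGT".index(read[p])) + rng.integers(1, 4)) % 4]
            read = "".join(read)
            assert call_subtype(read, "CTGG", scheme).label == _oracle(read, "CTGG", scheme)


class TestDeriveScheme:
    def test_packaged_ch1_references_yield_default_scheme(self, scheme):
        ref = Ch1Reference.from_fasta(
            resources.files("igphase.data") / "ch1_refs_synthetic.fasta", anchor=ANCHOR
        )
        derived = derive_scheme(ref, 12, klma_identifier=KLMA)
        assert {k: set(v) for k, v in derived.identifiers.items()} == {
            k: set(v) for k, v in scheme.identifiers.items()
        }
        assert derived.discriminator.position == 4
        assert derived.discriminator.base_map == {"G": "IgG2", "A": "IgG4"}

    def test_toy_four_allele_example(self):
        """Alleles differing only at the three determinant positions group
        into {IgG1}, {IgG3}, {IgG2,IgG4} with a read-2 discriminator."""
        base = list("GCCTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCACCCTCCTCCAAGAGCACCTCTGGG")
        seqs = {}
        for sub, (first3, p47, p57) in {
            "IgG1": ("C", "A", "T"),
            "IgG2": ("C", "G", "C"),
            "IgG3": ("T", "G", "T"),
            "IgG4": ("T", "G", "C"),
        }.items():
            s = base.copy()
            s[2], s[46], s[56] = first3, p47, p57
            seqs[sub] = "".join(s)
        ref = Ch1Reference(
            tuple(Ch1Allele(f"{s}*01", s, seq) for s, seq in seqs.items()), ANCHOR
        )
        derived = derive_scheme(ref, 12)
        assert set(derived.identifiers) == {"IgG1", "IgG3", "IgG24"}
        assert derived.discriminator.position == 4
        # GCC -> complement of third base C is G -> IgG2; GCT -> A -> IgG4
        assert derived.discriminator.base_map == {"G": "IgG2", "A": "IgG4"}

    def test_identical_windows_same_subclass_collapse(self):
        seq = "GCCTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCACCCTCCTCCAAGAGCACCTCTGGG"
        ref = Ch1Reference(
            (Ch1Allele("a*01", "IgG1", seq), Ch1Allele("a*02", "IgG1", seq)), ANCHOR
        )
        derived = derive_scheme(ref, 12)
        assert derived.identifiers == {"IgG1": ("AAGAGCACCTCT",)}

    def test_anchor_not_found_names_allele(self):
        ref = Ch1Reference((Ch1Allele("weird*01", "IgG1", "A" * 80),), ANCHOR)
        with pytest.raises(SchemeDerivationError, match="weird"):
            derive_scheme(ref, 12)

    def test_unresolvable_window_collision(self):
        seq = "GCCTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCACCCTCCTCCAAGAGCACCTCTGGG"
        ref = Ch1Reference(
            (Ch1Allele("g1", "IgG1", seq), Ch1Allele("g3", "IgG3", seq)), ANCHOR
        )
        with pytest.raises(SchemeDerivationError, match="merges subclasses"):
            derive_scheme(ref, 12)


class TestValidateScheme:
    def test_default_scheme_distances(self, scheme):
        report = validate_scheme(scheme)
        assert report.safe
        # adjacent IgG identifiers sit a single nucleotide apart
        assert report.min_distance(["IgG1", "IgG3", "IgG24"]) == 1
        assert report.min_distance(["IgG1", "klMA"]) == 12

    def test_ambiguous_klma_rejected_at_construction(self):
        with pytest.raises(SchemeError, match="ambiguous"):
            SubtypeScheme(
                identifier_length=12,
                identifiers={"IgG1": (IGG1,), "klMA": ("T" + IGG1[1:],)},
                klma_max_mismatch=1,
            )

    def test_overlapping_tolerance_balls_flagged_unsafe(self):
        # with 1 tolerated mismatch on IgG classes, distance-1 identifiers
        # admit reads inside two tolerance balls at once
        unsafe = SubtypeScheme(
            identifier_length=12,
            identifiers={"IgG1": (IGG1,), "IgG3": (IGG3,)},
            igg_max_mismatch=1,
        )
        report = validate_scheme(unsafe)
        assert not report.safe
        assert report.unsafe_pairs

    def test_single_class_scheme_safe(self):
        report = validate_scheme(
            SubtypeScheme(identifier_length=12, identifiers={"IgG1": (IGG1,)})
        )
        assert report.safe
        assert report.min_distance() == -1


class TestSchemeRoundTrip:
    def test_yaml_round_trip(self, scheme, tmp_path):
        from igphase import load_scheme, save_scheme

        path = tmp_path / "scheme.yaml"
        save_scheme(scheme, path)
        assert load_scheme(path) == scheme

    @given(
        length=st.integers(6, 16),
        igg_tol=st.integers(0, 1),
        data=st.data(),
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip_arbitrary(self, length, igg_tol, data):
        alphabet = "ACGT"
        ident = data.draw(
            st.text(alphabet=alphabet, min_size=length, max_size=length)
        )
        scheme = SubtypeScheme(
            identifier_length=length,
            identifiers={"IgG1": (ident,)},
            igg_max_mismatch=igg_tol,
            discriminator=DiscriminatorRule(position=data.draw(st.integers(1, 10))),
        )
        dumped = yaml.safe_dump(scheme.to_dict())
        assert SubtypeScheme.from_dict(yaml.safe_load(dumped)) == scheme


class TestSchemeInvariants:
    def test_wrong_length_identifier_rejected(self):
        with pytest.raises(SchemeError, match="length"):
            SubtypeScheme(identifier_length=12, identifiers={"IgG1": ("ACGT",)})

    def test_shared_identifier_rejected(self):
        with pytest.raises(SchemeError, match="shared"):
            SubtypeScheme(
                identifier_length=12,
                identifiers={"IgG1": (IGG1,), "IgG3": (IGG1,)},
            )
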