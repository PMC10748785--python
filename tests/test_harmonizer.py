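import random

import pytest
from hypothesis import given, settings, strategies as st

from vcbench.errors import NullVariantError, ReferenceMismatchError
from vcbench.harmonizer import (CanonicalVariant, canonical_to_vcf,
                                harmonize_callset, left_align,
                                split_multiallelic, to_canonical)
from vcbench.synthetic import (apply_canonical, apply_edit,
                               equivalent_indel_spellings)
from vcbench.vcf_io import DictReference, QualityParams, RawVcfRecord


def ref_of(seq):
    return DictReference({"c": seq})


class TestLeftAlign:
    def test_deletion_shifts_to_tract_start(self):
        # CAAAT: deleting any single A of the tract is the same haplotype
        assert left_align("c", 3, "AA", "A", ref_of("CAAAT")) == (1, "CA", "C")

    def test_snv_is_unchanged(self):
        assert left_align("c", 2, "C", "G", ref_of("ACGTA")) == (2, "C", "G")

    def test_insertion_shifts_to_tract_start(self):
        assert left_align("c", 5, "T", "TT", ref_of("ATTTTC")) == (1, "A", "AT")

    def test_padded_alleles_are_trimmed(self):
        # leading shared context trimmed while both alleles stay non-empty
        assert left_align("c", 1, "ACG", "ATG", ref_of("ACGTA")) == (2, "C", "T")

    def test_reference_mismatch_is_an_error(self):
        with pytest.raises(ReferenceMismatchError):
            left_align("c", 2, "T", "G", ref_of("ACGTA"))

    def test_contig_start_stops_instead_of_erroring(self):
        # deletion in a tract running to the contig edge cannot shift further
        pos, ref, alt = left_align("c", 1, "AA", "A", ref_of("AAAAT"))
        assert pos == 1
        assert apply_edit("AAAAT", pos, ref, alt) == "AAAT"


class TestToCanonical:
    def test_deletion(self):
        cv = to_canonical("c", 1, "CA", "C")
        assert (cv.start, cv.end, cv.ref, cv.alt, cv.vclass) == \
            (2, 2, "A", "-", "DEL")

    def test_insertion(self):
        cv = to_canonical("c", 1, "A", "AT")
        assert (cv.start, cv.end, cv.ref, cv.alt, cv.vclass) == \
            (1, 1, "-", "T", "INS")

    def test_snv(self):
        cv = to_canonical("c", 3, "C", "G")
        assert (cv.start, cv.end, cv.vclass) == (3, 3, "SNV")

    def test_mnv_spans_its_length(self):
        cv = to_canonical("c", 3, "CT", "GA")
        assert (cv.start, cv.end, cv.vclass) == (3, 4, "MNV")

    def test_null_variant_rejected(self):
        with pytest.raises(NullVariantError):
            to_canonical("c", 3, "C", "C")


def _rec(pos, ref, alts, qual=None, info=None, fmt=None):
    rec = RawVcfRecord("c", pos, None, ref, tuple(alts), qual, "PASS",
                       info or {}, fmt or {})
    return rec


class TestSplitMultiallelic:
    def test_zero_frequency_allele_dropped(self):
        rec = _rec(100, "A", ["G", "T"], info={"AF": (0.4, 0.0)})
        rec.params = (QualityParams(vaf=0.4), QualityParams(vaf=0.0))
        splits = split_multiallelic(rec)
        assert len(splits) == 1
        assert splits[0].alt == "G" and splits[0].params.vaf == 0.4

    def test_single_allele_identity(self):
        rec = _rec(100, "A", ["G"])
        rec.params = (QualityParams(),)
        (sp,) = split_multiallelic(rec)
        assert (sp.ref, sp.alt, sp.allele_index) == ("A", "G", 0)

    def test_number_r_arrays_sliced_per_allele(self):
        # AD=10,6,4: VAFs are per-allele counts over the AD sum
        from vcbench.vcf_io import CallerDialect, resolve_params
        rec = _rec(100, "A", ["G", "T"], fmt={"AD": (10, 6, 4)})
        rec.params = resolve_params(rec, CallerDialect("generic"))
        splits = split_multiallelic(rec)
        assert [sp.params.vaf for sp in splits] == \
            pytest.approx([6 / 20, 4 / 20])
        assert splits[0].per_allele_info["AD"] == (10, 6)
        assert splits[1].per_allele_info["AD"] == (10, 4)

    def test_mismatched_array_marked_missing(self):
        rec = _rec(100, "A", ["G", "T"], info={"AF": (0.4,)})  # wrong length
        rec.params = (QualityParams(), QualityParams())
        splits = split_multiallelic(rec)
        assert len(splits) == 2
        assert all(sp.per_allele_info["AF"] is None for sp in splits)


class TestHarmonizeCallset:
    def test_equivalent_records_collapse_keeping_highest_qual(self):
        seq = "GCAAAATC"
        a = _rec(3, "AA", ["A"], qual=10.0)
        a.params = (QualityParams(qual=10.0),)
        b = _rec(5, "AA", ["A"], qual=99.0)
        b.params = (QualityParams(qual=99.0),)
        out = harmonize_callset([a, b], ref_of(seq))
        assert len(out) == 1
        assert next(iter(out)).params.qual == 99.0

    def test_empty_input(self):
        assert harmonize_callset([], ref_of("ACGT")) == set()

    def test_multiallelic_with_two_live_alleles_gives_two_variants(self):
        rec = _rec(2, "C", ["G", "T"], info={"AF": (0.3, 0.2)})
        rec.params = (QualityParams(vaf=0.3), QualityParams(vaf=0.2))
        out = harmonize_callset([rec], ref_of("ACGTA"))
        assert {v.alt for v in out} == {"G", "T"}

    def test_reference_mismatch_skipped_not_fatal(self):
        good = _rec(2, "C", ["T"])
        good.params = (QualityParams(),)
        bad = _rec(4, "A", ["G"])      # reference has T at 4
        bad.params = (QualityParams(),)
        out = harmonize_callset([good, bad], ref_of("ACGTA"))
        assert len(out) == 1

    def test_idempotent_after_reexpression_as_vcf(self):
        seq = "GCAAAATCGGTTAACC"
        reference = ref_of(seq)
        recs = [_rec(3, "AA", ["A"]), _rec(8, "C", ["CGG"]),
                _rec(12, "T", ["A"])]
        for r in recs:
            r.params = (QualityParams(),)
        once = harmonize_callset(recs, reference)
        again_raw = []
        for cv in once:
            pos, ref, alt = canonical_to_vcf(cv, reference)
            rr = _rec(pos, ref, [alt])
            rr.params = (cv.params,)
            again_raw.append(rr)
        assert harmonize_callset(again_raw, reference) == once


def _random_variant(rng, seq):
    """A random raw (pos, ref, alt) edit inside seq, VCF-anchored."""
    kind = rng.choice(["snv", "ins", "del"])
    if kind == "snv":
        p0 = rng.randrange(2, len(seq) - 2)
        alt = rng.choice([b for b in "ACGT" if b != seq[p0]])
        return p0 + 1, seq[p0], alt
    if kind == "ins":
        p0 = rng.randrange(2, len(seq) - 2)
        ins = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 4)))
        return p0 + 1, seq[p0], seq[p0] + ins
    p0 = rng.randrange(2, len(seq) - 5)
    L = rng.randrange(1, 4)
    return p0 + 1, seq[p0:p0 + 1 + L], seq[p0]


class TestHaplotypeEquivalence:
    """The module's primary correctness property: the canonical edit applied
    to the reference reproduces exactly the haplotype of the raw edit."""

    def test_random_edits_preserve_haplotype(self):
        rng = random.Random(202)
        for _ in range(500):
            n = rng.randrange(20, 60)
            # repeat-rich sequences stress the left-aligner
            seq = "".join(rng.choice("AACCGT") for _ in range(n))
            pos, ref, alt = _random_variant(rng, seq)
            expected = apply_edit(seq, pos, ref, alt)
            reference = ref_of(seq)
            p, r, a = left_align("c", pos, ref, alt, reference)
            try:
                cv = to_canonical("c", p, r, a)
            except NullVariantError:
                assert expected == seq
                continue
            assert apply_canonical(seq, cv) == expected

    def test_all_equivalent_spellings_collapse_to_one_key(self):
        rng = random.Random(77)
        for _ in range(200):
            tract = rng.choice(["A", "T", "AG", "CT"]) * rng.randrange(3, 8)
            seq = "GC" + tract + "GATTACA"
            reference = ref_of(seq)
            unit = tract[:1] if len(set(tract)) == 1 else tract[:2]
            if rng.random() < 0.5:
                cv = CanonicalVariant("c", 4, 3 + len(unit),
                                      seq[3:3 + len(unit)], "-", "DEL")
                cv = to_canonical("c", *left_align(
                    "c", 3, seq[2:3 + len(unit)], seq[2], reference))
            else:
                cv = to_canonical("c", *left_align(
                    "c", 2, seq[1], seq[1] + unit, reference))
            spellings = equivalent_indel_spellings(seq, cv)
            assert len(spellings) >= 2   # a repeat tract admits shifts
            keys = set()
            for pos, ref, alt in spellings:
                p, r, a = left_align("c", pos, ref, alt, reference)
                keys.add(to_canonical("c", p, r, a).key)
            assert keys == {cv.key}

    @given(st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_left_alignment_is_minimal_and_equivalent(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=15, max_size=40))
        rng = random.Random(data.draw(st.integers(0, 2**20)))
        pos, ref, alt = _random_variant(rng, seq)
        reference = ref_of(seq)
        p, r, a = left_align("c", pos, ref, alt, reference)
        assert apply_edit(seq, p, r, a) == apply_edit(seq, pos, ref, alt)
        # no equivalent spelling exists at a smaller start
        try:
            cv = to_canonical("c", p, r, a)
        except NullVariantError:
            return
        if cv.vclass in ("INS", "DEL") and cv.start > 2:
            spellings = equivalent_indel_spellings(seq, cv)
            assert spellings[0][0] >= p
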