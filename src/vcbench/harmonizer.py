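"""Canonical variant representation: decomposition, left-alignment, parsimony.

Two callsets can spell the same edit differently — an indel shifted within a
repeat tract, padded alleles, or a multi-allelic record — and naive key
matching then reports a spurious ("symbolic") false negative.  This module
maps every raw VCF record to a single canonical form so that set comparison
becomes caller-independent.

The canonical form is the 5-column start/end/ref/alt convention with ``-``
for the absent allele:

* SNV:  start == end, single-base ref and alt
* DEL:  alt == "-", [start, end] are the deleted reference bases
* INS:  ref == "-", start == end is the base AFTER which the sequence is
  inserted
* MNV:  equal-length multi-base substitution (block substitutions with
  unequal lengths are carried under the same class)

Every canonical variant is left-aligned (no equivalent representation exists
at a smaller coordinate) and parsimonious (ref and alt share no leading or
trailing bases).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .errors import NullVariantError, ReferenceMismatchError
from .vcf_io import QualityParams, RawVcfRecord, ReferenceAccessor

log = logging.getLogger(__name__)

VCLASSES = ("SNV", "INS", "DEL", "MNV")


@dataclass(frozen=True)
class CanonicalVariant:
    """A normalized edit; equality and hashing use only the 5-column key."""

    chrom: str
    start: int      # 1-based inclusive
    end: int        # 1-based inclusive
    ref: str        # deleted/substituted bases, or "-" for insertions
    alt: str        # inserted/substituted bases, or "-" for deletions
    vclass: str = field(compare=False, default="SNV")
    params: QualityParams = field(compare=False, repr=False,
                                  default_factory=QualityParams)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.vclass in ("INS", "DEL")

    def positions(self) -> range:
        """1-based reference positions this call claims (insertion: anchor)."""
        return range(self.start, self.end + 1)


@dataclass
class AlleleSplit:
    """One alt allele sliced out of a (possibly multi-allelic) record."""

    parent: RawVcfRecord
    allele_index: int
    chrom: str
    pos: int
    ref: str
    alt: str
    params: QualityParams
    per_allele_info: dict = field(default_factory=dict)


# Number classes used when slicing per-allele INFO values for reporting.
_NUMBER_A = ("AF", "AO", "SAF", "SAR", "STB")
_NUMBER_R = ("AD", "ADF", "ADR")


def split_multiallelic(rec: RawVcfRecord) -> list[AlleleSplit]:
    """Decompose a record into per-allele splits, dropping zero-frequency alts.

    Number=A arrays are sliced to the matching allele and Number=R arrays to
    (ref, alt) pairs; scalar fields are duplicated.  An allele whose resolved
    VAF equals 0 is dropped (a decoy allele of a multi-allelic line); alleles
    with no frequency evidence at all are retained.
    """
    if not rec.alts:
        return []
    n = len(rec.alts)
    params = rec.params if len(rec.params) == n else tuple(
        QualityParams() for _ in range(n))
    out = []
    for i, alt in enumerate(rec.alts):
        p = params[i]
        if p.vaf is not None and p.vaf == 0:
            continue
        sliced = {}
        for src in (rec.info, rec.format_fields):
            for key, val in src.items():
                if key in _NUMBER_A and isinstance(val, (list, tuple)):
                    if len(val) == n:
                        sliced[key] = val[i]
                    else:
                        sliced[key] = None
                        log.warning("record %s:%d field %s: length %d != %d "
                                    "alts; marked missing", rec.chrom,
                                    rec.pos, key, len(val), n)
                elif key in _NUMBER_R and isinstance(val, (list, tuple)):
                    if len(val) == n + 1:
                        sliced[key] = (val[0], val[i + 1])
                    else:
                        sliced[key] = None
                        log.warning("record %s:%d field %s: length %d != %d "
                                    "alleles; marked missing", rec.chrom,
                                    rec.pos, key, len(val), n + 1)
                else:
                    sliced.setdefault(key, val)
        out.append(AlleleSplit(parent=rec, allele_index=i, chrom=rec.chrom,
                               pos=rec.pos, ref=rec.ref, alt=alt,
                               params=p, per_allele_info=sliced))
    return out


def left_align(chrom: str, pos: int, ref: str, alt: str,
               reference: ReferenceAccessor,
               check_ref: bool = True) -> tuple[int, str, str]:
    """Normalize a VCF-style allele pair: left-align and trim to parsimony.

    While ref and alt end with the same base, drop it; whenever either
    becomes empty, prepend the reference base at pos-1 and decrement pos;
    finally trim common leading bases while both lengths exceed 1.  The
    returned representation applied to the reference reproduces the same
    haplotype as the input, and no equivalent representation exists at a
    smaller position.

    At the contig start a further shift is impossible: normalization stops
    there with a warning rather than erroring.
    """
    ref, alt = ref.upper(), alt.upper()
    if check_ref:
        seen = reference.fetch(chrom, pos, pos + len(ref) - 1)
        if seen != ref:
            raise ReferenceMismatchError(
                f"{chrom}:{pos} REF {ref!r} != reference {seen!r}")
    if ref == alt:
        return pos, ref, alt   # null edit; caller raises at to_canonical
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            dropped = ref[-1]
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    # contig-start edge: cannot extend left, restore and stop
                    ref, alt = ref + dropped, alt + dropped
                    log.warning("%s:%d: left-alignment stopped at contig "
                                "start", chrom, pos)
                    break
                b = reference.fetch(chrom, pos - 1, pos - 1)
                ref, alt = b + ref, b + alt
                pos -= 1
            continue
        if not ref or not alt:
            # non-anchored input (e.g. ref="" insertion): anchor it
            if pos == 1:
                break
            b = reference.fetch(chrom, pos - 1, pos - 1)
            ref, alt = b + ref, b + alt
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def to_canonical(chrom: str, pos: int, ref: str, alt: str,
                 params: QualityParams | None = None) -> CanonicalVariant:
    """Convert a left-aligned, parsimony-trimmed allele pair to canonical form."""
    params = params or QualityParams()
    if ref == alt:
        raise NullVariantError(f"{chrom}:{pos} ref == alt ({ref!r})")
    if len(ref) == 1 and len(alt) == 1:
        return CanonicalVariant(chrom, pos, pos, ref, alt, "SNV", params)
    if len(ref) > len(alt) == 1 and ref[0] == alt:
        return CanonicalVariant(chrom, pos + 1, pos + len(ref) - 1,
                                ref[1:], "-", "DEL", params)
    if len(alt) > len(ref) == 1 and alt[0] == ref:
        return CanonicalVariant(chrom, pos, pos, "-", alt[1:], "INS", params)
    # equal-length MNV or unequal block substitution
    return CanonicalVariant(chrom, pos, pos + len(ref) - 1, ref, alt,
                            "MNV", params)


def canonical_to_vcf(cv: CanonicalVariant,
                     reference: ReferenceAccessor) -> tuple[int, str, str]:
    """Re-express a canonical variant as an anchored VCF (pos, ref, alt)."""
    if cv.vclass == "SNV" or cv.vclass == "MNV":
        return cv.start, cv.ref, cv.alt
    if cv.vclass == "DEL":
        if cv.start == 1:
            raise ValueError("deletion at contig start has no left anchor")
        anchor = reference.fetch(cv.chrom, cv.start - 1, cv.start - 1)
        return cv.start - 1, anchor + cv.ref, anchor
    if cv.vclass == "INS":
        anchor = reference.fetch(cv.chrom, cv.start, cv.start)
        return cv.start, anchor, anchor + cv.alt
    raise ValueError(f"unknown vclass {cv.vclass!r}")


def harmonize_callset(records: Iterable[RawVcfRecord],
                      reference: ReferenceAccessor) -> set[CanonicalVariant]:
    """Decompose, left-align and canonicalize a callset into a variant set.

    Duplicate canonical variants collapse to one, keeping the copy with the
    highest QUAL.  Reference-mismatching and null records are skipped with
    warnings, never aborts.
    """
    best: dict[tuple, CanonicalVariant] = {}
    for rec in records:
        for sp in split_multiallelic(rec):
            try:
                pos, ref, alt = left_align(sp.chrom, sp.pos, sp.ref, sp.alt,
                                           reference)
                cv = to_canonical(sp.chrom, pos, ref, alt, sp.params)
            except ReferenceMismatchError as e:
                log.warning("skipping record: %s", e)
                continue
            except NullVariantError as e:
                log.warning("dropping null variant: %s", e)
                continue
            old = best.get(cv.key)
            if old is None or _qual(cv) > _qual(old):
                best[cv.key] = cv
    return set(best.values())


def _qual(cv: CanonicalVariant) -> float:
    q = cv.params.qual
    return float("-inf") if q is None else q
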