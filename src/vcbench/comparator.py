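"""Callset matching inside high-confidence regions and accuracy metrics.

Matching is exact on the canonical key (chrom, start, end, ref, alt) —
genotype- and zygosity-blind, presence only.  True negatives are counted in
reference base pairs: every position of the high-confidence regions not
claimed by a positive call (TP or FP) is a true negative, which makes
specificity well defined for a callset benchmark.

Metric definitions (counts are variants, tn is base pairs):

    recall      = TP / (TP + FN)
    precision   = TP / (TP + FP)
    FDR         = FP / (TP + FP) = 1 - precision
    F1          = 2 * precision * recall / (precision + recall)
    specificity = TN / (TN + FP)
    recall_max  = (TP + b-FN) / (TP + FN)

recall_max is the maximum theoretical recall attainable by relaxing caller
filters: b-FNs (false negatives with supporting reads in the alignment)
could in principle be called, sequencing FNs cannot.  Any ratio with a zero
denominator is reported as null.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .harmonizer import CanonicalVariant
from .vcf_io import QualityParams, Region, total_bases

KLASSES = ("TP", "FP", "FN")
FN_SUBTYPES = ("b-FN", "seq-FN", "unchecked")


@dataclass
class ClassifiedCall:
    """A canonical variant tagged with its benchmark class.

    ``params`` come from the caller for TP/FP and from the pileup re-check
    for b-FN; ``fn_subtype`` stays "unchecked" until the re-check runs.
    """

    variant: CanonicalVariant
    klass: str
    fn_subtype: str = "unchecked"
    params: QualityParams = field(default_factory=QualityParams)

    @property
    def label(self) -> str:
        return self.klass if self.klass != "FN" else self.fn_subtype


def _ratio(num, den):
    return num / den if den else None


@dataclass
class MetricSet:
    """Accuracy metrics with the integer counts behind them."""

    tp: int
    fp: int
    fn: int
    bfn: int = 0
    tn_bases: int = 0
    rechecked: bool = False
    recall: float | None = None
    precision: float | None = None
    specificity: float | None = None
    f1: float | None = None
    fdr: float | None = None
    recall_max: float | None = None

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, bfn: int = 0,
                    tn_bases: int = 0, rechecked: bool = False) -> "MetricSet":
        m = cls(tp=tp, fp=fp, fn=fn, bfn=bfn, tn_bases=tn_bases,
                rechecked=rechecked)
        m.recall = _ratio(tp, tp + fn)
        m.precision = _ratio(tp, tp + fp)
        m.fdr = None if m.precision is None else 1.0 - m.precision
        if m.precision is not None and m.recall is not None and \
                (m.precision + m.recall) > 0:
            m.f1 = 2 * m.precision * m.recall / (m.precision + m.recall)
        m.specificity = _ratio(tn_bases, tn_bases + fp)
        if rechecked:
            m.recall_max = _ratio(tp + bfn, tp + fn)
        return m

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "bfn": self.bfn,
                "tn_bases": self.tn_bases, "recall": self.recall,
                "precision": self.precision, "specificity": self.specificity,
                "f1": self.f1, "fdr": self.fdr, "recall_max": self.recall_max}


def restrict_to_regions(calls: set[CanonicalVariant],
                        regions: Sequence[Region]) -> set[CanonicalVariant]:
    """Keep variants fully contained in one high-confidence region.

    Containment is full-containment of the variant's 1-based [start, end]
    interval (an insertion occupies only its anchor base): deletions hanging
    over a panel edge have ambiguous truth status and are excluded.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    kept = set()
    for v in calls:
        for r in by_chrom.get(v.chrom, ()):
            # region in 1-based inclusive coordinates: [start+1, end]
            if r.start + 1 <= v.start and v.end <= r.end:
                kept.add(v)
                break
    return kept


def match_callsets(query: set[CanonicalVariant],
                   truth: set[CanonicalVariant]) -> list[ClassifiedCall]:
    """Exact-key classification: TP = query∩truth, FP = query\\truth, FN = truth\\query.

    TP and FP carry the query record's params; FN params start absent.
    """
    truth_by_key = {v.key: v for v in truth}
    query_by_key = {v.key: v for v in query}
    calls = []
    for key, qv in query_by_key.items():
        if key in truth_by_key:
            calls.append(ClassifiedCall(qv, "TP", params=qv.params))
        else:
            calls.append(ClassifiedCall(qv, "FP", params=qv.params))
    for key, tv in truth_by_key.items():
        if key not in query_by_key:
            calls.append(ClassifiedCall(tv, "FN"))
    calls.sort(key=lambda c: c.variant.key)
    return calls


def count_tn_bases(regions: Sequence[Region],
                   calls: Iterable[ClassifiedCall]) -> int:
    """True-negative base pairs: region bases minus positions claimed by TP/FP.

    A deletion claims all deleted bases, an insertion its single anchor
    position; FN positions remain negative reference bases since specificity
    concerns the query's claims.
    """
    region_pos: dict[str, set] = {}
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    claimed: set[tuple[str, int]] = set()
    for c in calls:
        if c.klass not in ("TP", "FP"):
            continue
        v = c.variant
        for p in v.positions():
            for r in by_chrom.get(v.chrom, ()):
                if r.start + 1 <= p <= r.end:
                    claimed.add((v.chrom, p))
                    break
    return total_bases(regions) - len(claimed)


def compute_metrics(calls: Iterable[ClassifiedCall], tn_bases: int,
                    bfn_count: int | None = None) -> MetricSet:
    """Build the MetricSet from classified calls.

    ``bfn_count`` is None until the pileup re-check has run, in which case
    recall_max is not reported.
    """
    calls = list(calls)
    tp = sum(1 for c in calls if c.klass == "TP")
    fp = sum(1 for c in calls if c.klass == "FP")
    fn = sum(1 for c in calls if c.klass == "FN")
    if bfn_count is not None and bfn_count > fn:
        raise ValueError(f"bfn_count {bfn_count} exceeds FN count {fn}")
    return MetricSet.from_counts(
        tp=tp, fp=fp, fn=fn, bfn=bfn_count or 0, tn_bases=tn_bases,
        rechecked=bfn_count is not None)
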