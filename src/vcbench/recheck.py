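"""Re-evaluate false negatives in the read evidence.

A false negative can be a sequencing problem (no read supports the allele —
nothing a pipeline can do) or a bioinformatic one (supporting reads exist
but the caller filtered the variant out).  This module counts allele support
at each FN site, splits FNs into b-FN (bioinformatic) vs seq-FN
(sequencing), attaches caller-independent pileup parameters (VAF, DP, STB)
to the recovered b-FNs, and assembles the set of sequencing-positive
variants (SeqPos = TP + b-FN + FP) used by the optimizer.

Evidence can come from a SAM/BAM file (via pysam) or from a readcount-style
TSV.  The TSV dialect is: tab-separated columns

    chrom  pos  ref  depth  allele:count:fwd:rev  [allele:count:fwd:rev ...]

with 1-based ``pos`` at the pileup anchor (the variant base for SNVs, the
base after which the sequence is inserted for insertions, the base before
the deleted run for deletions), ``ref`` the reference base at the anchor,
and allele keys: the base itself for SNVs/reference, ``+SEQ`` for an
insertion of SEQ, ``-SEQ`` for a deletion of SEQ.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .comparator import ClassifiedCall
from .harmonizer import CanonicalVariant
from .vcf_io import QualityParams

log = logging.getLogger(__name__)


@dataclass
class RecheckPolicy:
    """Read-filtering thresholds for the pileup re-check.

    The b-FN criterion is existence of supporting reads, so ``min_alt_reads``
    defaults to 1; diagnostic users may prefer 2+.  Quality floors default to
    0 (count everything) and are exposed as flags.
    """

    min_alt_reads: int = 1
    min_base_quality: int = 0
    min_mapping_quality: int = 0

    def __post_init__(self):
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality floors must be non-negative")


@dataclass
class SiteReadcount:
    """Pileup evidence at one variant site, by strand."""

    variant: CanonicalVariant
    depth: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    ref_fwd: int = 0
    ref_rev: int = 0

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev


def derive_params(rc: SiteReadcount) -> tuple[float | None, int, float | None]:
    """Caller-independent (VAF, DP, STB) from a pileup.

    VAF = alt reads / depth (null at depth 0); STB = the larger strand's
    fraction of alt reads, in [0.5, 1] (null with no alt reads; 0.5 means
    perfectly balanced, 1 one-sided).
    """
    dp = rc.depth
    vaf = rc.alt_count / dp if dp > 0 else None
    stb = (max(rc.alt_fwd, rc.alt_rev) / rc.alt_count
           if rc.alt_count > 0 else None)
    return vaf, dp, stb


# ---------------------------------------------------------------------------
# evidence sources


def _anchor0(v: CanonicalVariant) -> int:
    """0-based pileup anchor position."""
    if v.vclass == "DEL":
        return v.start - 2
    return v.start - 1


class AlignmentPileupSource:
    """Allele-support counting over a SAM/BAM file.

    Reads are loaded once per contig into start-sorted arrays and queried by
    windowed scan, so plain SAM text and unsorted/unindexed BAMs work the
    same way.  Duplicate-marked, secondary, supplementary and unmapped
    alignments are excluded (standard pileup hygiene).
    """

    # generous bound on reference span of a single read at panel scale
    _MAX_SPAN = 2000

    def __init__(self, path):
        self.path = str(path)
        self._by_contig: dict[str, tuple[list[int], list]] = {}
        mode = "rb" if self.path.endswith(".bam") else "r"
        with pysam.AlignmentFile(self.path, mode, check_sq=False) as af:
            tmp: dict[str, list] = {}
            for read in af.fetch(until_eof=True):
                if (read.is_unmapped or read.is_secondary or
                        read.is_supplementary or read.is_duplicate):
                    continue
                tmp.setdefault(read.reference_name, []).append(read)
        for contig, reads in tmp.items():
            reads.sort(key=lambda r: r.reference_start)
            self._by_contig[contig] = ([r.reference_start for r in reads],
                                       reads)

    def has_contig(self, contig: str) -> bool:
        return contig in self._by_contig

    def reads_at(self, contig: str, pos0: int):
        if contig not in self._by_contig:
            return
        starts, reads = self._by_contig[contig]
        lo = bisect.bisect_left(starts, pos0 - self._MAX_SPAN)
        hi = bisect.bisect_right(starts, pos0)
        for i in range(lo, hi):
            r = reads[i]
            if r.reference_start <= pos0 < (r.reference_end or r.reference_start):
                yield r

    def site_counts(self, variant: CanonicalVariant,
                    policy: RecheckPolicy) -> SiteReadcount:
        rc = SiteReadcount(variant)
        a0 = _anchor0(variant)
        if not self.has_contig(variant.chrom):
            log.warning("contig %s absent from %s; site reported uncovered",
                        variant.chrom, self.path)
            return rc
        for read in self.reads_at(variant.chrom, a0):
            if read.mapping_quality < policy.min_mapping_quality:
                continue
            support = _classify_read(read, variant, policy)
            if support is None:
                continue
            rc.depth += 1
            if support == "alt":
                if read.is_reverse:
                    rc.alt_rev += 1
                else:
                    rc.alt_fwd += 1
            elif support == "ref":
                if read.is_reverse:
                    rc.ref_rev += 1
                else:
                    rc.ref_fwd += 1
        return rc


def _walk_cigar(read):
    """ref_pos -> query_pos map (None inside deletions), insertion map, deletions."""
    ref_map: dict[int, int | None] = {}
    insertions: dict[int, str] = {}   # keyed by ref position BEFORE the insertion
    deletions: set[tuple[int, int]] = set()
    rpos = read.reference_start
    qpos = 0
    seq = read.query_sequence or ""
    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8):           # M, =, X
            for k in range(ln):
                ref_map[rpos + k] = qpos + k
            rpos += ln
            qpos += ln
        elif op == 1:                 # I: insertion after rpos-1
            insertions[rpos - 1] = seq[qpos:qpos + ln]
            qpos += ln
        elif op == 2:                 # D
            deletions.add((rpos, ln))
            for k in range(ln):
                ref_map[rpos + k] = None
            rpos += ln
        elif op == 3:                 # N
            rpos += ln
        elif op == 4:                 # S
            qpos += ln
        # H/P consume nothing relevant
    return ref_map, insertions, deletions


def _classify_read(read, v: CanonicalVariant, policy: RecheckPolicy):
    """'alt' / 'ref' / 'other' support, or None if the read does not count.

    Indel support requires an exact match of the canonical edit in the read
    alignment (no fuzzy window), mirroring the comparator's exact-key match.
    """
    a0 = _anchor0(v)
    if not (read.reference_start <= a0 < (read.reference_end or 0)):
        return None
    ref_map, insertions, deletions = _walk_cigar(read)
    seq = read.query_sequence or ""
    quals = read.query_qualities

    if v.vclass in ("SNV", "MNV"):
        span = range(v.start - 1, v.end)
        if any(p not in ref_map for p in span):
            return "other"            # covers the anchor but not the full site
        qps = [ref_map[p] for p in span]
        if any(q is None for q in qps):
            return "other"            # site deleted in the read
        if v.vclass == "SNV" and quals is not None and \
                quals[qps[0]] < policy.min_base_quality:
            return None
        bases = "".join(seq[q] for q in qps)
        if bases == v.alt:
            return "alt"
        if bases == v.ref:
            return "ref"
        return "other"

    if v.vclass == "DEL":
        ds0, L = v.start - 1, v.end - v.start + 1
        if (ds0, L) in deletions:
            return "alt"
        if all(ref_map.get(p) is not None for p in range(ds0, ds0 + L)):
            return "ref"
        return "other"

    if v.vclass == "INS":
        ins = insertions.get(a0)
        if ins is not None:
            return "alt" if ins == v.alt else "other"
        nxt = a0 + 1
        if ref_map.get(a0) is not None and ref_map.get(nxt) is not None:
            return "ref"              # spans the junction with no insertion
        return "other"

    return "other"


class ReadcountTableSource:
    """Allele-support counting backed by a readcount-style TSV (see module doc)."""

    def __init__(self, path):
        self.path = str(path)
        self._rows: dict[tuple[str, int], tuple[str, int, dict]] = {}
        with open(self.path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 4:
                    raise ValueError(
                        f"{self.path} line {ln}: fewer than 4 columns")
                chrom, pos, ref_base, depth = (
                    cols[0], int(cols[1]), cols[2].upper(), int(cols[3]))
                alleles = {}
                for f in cols[4:]:
                    parts = f.split(":")
                    if len(parts) < 4:
                        raise ValueError(
                            f"{self.path} line {ln}: bad allele field {f!r}")
                    alleles[parts[0].upper()] = (
                        int(parts[1]), int(parts[2]), int(parts[3]))
                self._rows[(chrom, pos)] = (ref_base, depth, alleles)

    def site_counts(self, variant: CanonicalVariant,
                    policy: RecheckPolicy) -> SiteReadcount:
        v = variant
        rc = SiteReadcount(v)
        anchor = _anchor0(v) + 1   # 1-based
        row = self._rows.get((v.chrom, anchor))
        if row is None:
            return rc
        ref_base, depth, alleles = row
        rc.depth = depth
        if v.vclass in ("SNV", "MNV"):
            alt_key, ref_key = v.alt, v.ref
        elif v.vclass == "INS":
            alt_key, ref_key = "+" + v.alt, ref_base
        else:
            alt_key, ref_key = "-" + v.ref, ref_base
        if alt_key in alleles:
            _, rc.alt_fwd, rc.alt_rev = alleles[alt_key]
        if ref_key in alleles and ref_key != alt_key:
            _, rc.ref_fwd, rc.ref_rev = alleles[ref_key]
        return rc


def open_evidence(path) -> AlignmentPileupSource | ReadcountTableSource:
    """Open read evidence: .sam/.bam -> alignment source, .tsv -> table source."""
    s = str(path)
    if s.endswith((".sam", ".bam", ".cram")):
        return AlignmentPileupSource(s)
    return ReadcountTableSource(s)


# ---------------------------------------------------------------------------
# operations


def readcount_site(variant: CanonicalVariant, alignments,
                   policy: RecheckPolicy | None = None) -> SiteReadcount:
    """Count allele support at one site from either evidence source."""
    return alignments.site_counts(variant, policy or RecheckPolicy())


def classify_fns(fns: Sequence[ClassifiedCall], alignments,
                 policy: RecheckPolicy | None = None
                 ) -> tuple[list[ClassifiedCall], int | None]:
    """Split FNs into b-FN (>= min_alt_reads supporting reads) vs seq-FN.

    b-FNs get pileup-derived (VAF, DP, STB) as their params.  With no
    evidence source, every FN stays "unchecked" and None is returned so the
    caller knows recall_max cannot be reported.
    """
    policy = policy or RecheckPolicy()
    if alignments is None:
        return list(fns), None
    bfn = 0
    out = []
    for call in fns:
        if call.klass != "FN":
            raise ValueError("classify_fns expects only FN calls")
        rc = readcount_site(call.variant, alignments, policy)
        if rc.alt_count >= policy.min_alt_reads:
            vaf, dp, stb = derive_params(rc)
            call.fn_subtype = "b-FN"
            call.params = QualityParams(vaf=vaf, dp=float(dp), stb=stb)
            bfn += 1
        else:
            call.fn_subtype = "seq-FN"
            vaf, dp, stb = derive_params(rc)
            call.params = QualityParams(vaf=vaf, dp=float(dp), stb=stb)
        out.append(call)
    return out, bfn


def recheck_calls(calls: Sequence[ClassifiedCall], alignments,
                  policy: RecheckPolicy | None = None
                  ) -> tuple[list[ClassifiedCall], int | None]:
    """classify_fns over the FN subset of a full classified table."""
    fns = [c for c in calls if c.klass == "FN"]
    _, bfn = classify_fns(fns, alignments, policy)
    return list(calls), bfn


def build_seqpos(calls: Iterable[ClassifiedCall]) -> list:
    """Assemble the sequencing-positive set (TP + b-FN + FP).

    TPs and b-FNs are labelled 1 (positively callable), FPs 0 (should be
    called negative); sequencing FNs are excluded.  TP/FP rows carry caller
    parameters, b-FN rows the pileup parameters attached by classify_fns.
    """
    from .optimizer import SeqPosRecord, compute_qd

    out = []
    for c in calls:
        lab = c.label
        if lab in ("TP", "b-FN", "FP"):
            p = c.params
            qd = p.qd if p.qd is not None else compute_qd(p.qual, p.dp)
            out.append(SeqPosRecord(
                variant=c.variant, label=1 if lab in ("TP", "b-FN") else 0,
                vaf=p.vaf, dp=p.dp, stb=p.stb, qual=p.qual, qd=qd))
    return out
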