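"""Readers and writers for the formats the benchmarking suite touches.

VCF parsing is delegated to pysam and FASTA access to pyfaidx; this module's
job is coordinate bookkeeping (BED is 0-based half-open, VCF is 1-based —
conversions happen here and nowhere else) and resolving caller-specific
quality annotations into one uniform per-allele record, so downstream stages
never see caller dialect.

Supported dialects: ``gatk-hc``, ``tvc``, ``lofreq``, ``deepvariant`` and a
``generic`` fallback chain that covers all of them:

* VAF: FORMAT/AF -> INFO/AF -> FORMAT/VAF -> FORMAT/AD (alt over the AD sum)
  -> INFO/AO,RO as AO/(AO+RO)
* DP:  FORMAT/DP -> INFO/DP -> sum(AD)
* STB: INFO/STB -> strand counts (SAF/SAR, ADF/ADR, DP4) -> missing
* QUAL: the VCF QUAL column

Unresolvable parameters are ``None`` (missing), never silently zero.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pysam
from pyfaidx import Fasta

from .errors import BedParseError, ReferenceLookupError, VcfParseError

log = logging.getLogger(__name__)

DNA = frozenset("ACGTN")

DIALECTS = ("generic", "gatk-hc", "tvc", "lofreq", "deepvariant")


@dataclass
class QualityParams:
    """Uniform caller-independent quality annotations for one allele.

    ``None`` means the source record did not allow the value to be resolved.
    ``qd`` (quality by depth) is derived downstream by the optimizer.
    """

    vaf: float | None = None
    dp: float | None = None
    stb: float | None = None
    qual: float | None = None
    qd: float | None = None

    def as_dict(self) -> dict:
        return {"vaf": self.vaf, "dp": self.dp, "stb": self.stb,
                "qual": self.qual, "qd": self.qd}


@dataclass(frozen=True, order=True)
class Region:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise BedParseError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RawVcfRecord:
    """One VCF data line with per-allele quality parameters resolved."""

    chrom: str
    pos: int                      # 1-based
    id: str | None
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    filter: str                   # "PASS", "." or semicolon-joined filters
    info: dict
    format_fields: dict           # first sample only
    params: tuple[QualityParams, ...] = ()   # one entry per alt allele

    @property
    def is_pass(self) -> bool:
        return self.filter in ("PASS", ".")


@dataclass(frozen=True)
class CallerDialect:
    """Named lookup plan for caller-specific quality annotations."""

    name: str

    def __post_init__(self):
        if self.name not in DIALECTS:
            raise VcfParseError(
                f"unknown caller dialect {self.name!r}; known: {DIALECTS}")


# ---------------------------------------------------------------------------
# parameter resolution


def _as_float(v):
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def _tuple(v):
    if v is None:
        return None
    if isinstance(v, (list, tuple)):
        return tuple(v)
    return (v,)


def _number_a(values, i: int, n_alts: int):
    """Slice a Number=A array to allele i; None on length mismatch."""
    t = _tuple(values)
    if t is None or len(t) != n_alts:
        return None
    return t[i]


def _number_r(values, i: int, n_alts: int):
    """Slice a Number=R array to (ref, alt_i); None on length mismatch."""
    t = _tuple(values)
    if t is None or len(t) != n_alts + 1:
        return None
    return t[0], t[i + 1]


def _vaf_fmt_af(rec, i, n):
    return _as_float(_number_a(rec.format_fields.get("AF"), i, n))


def _vaf_info_af(rec, i, n):
    return _as_float(_number_a(rec.info.get("AF"), i, n))


def _vaf_fmt_vaf(rec, i, n):
    return _as_float(_number_a(rec.format_fields.get("VAF"), i, n))


def _vaf_fmt_ad(rec, i, n):
    ad = _tuple(rec.format_fields.get("AD"))
    if ad is None or len(ad) != n + 1:
        return None
    try:
        total = sum(ad)
        return ad[i + 1] / total if total > 0 else None
    except TypeError:
        return None


def _vaf_info_ao_ro(rec, i, n):
    ao = _as_float(_number_a(rec.info.get("AO"), i, n))
    ro = _as_float(rec.info.get("RO"))
    if ao is None or ro is None or ao + ro == 0:
        return None
    return ao / (ao + ro)


def _dp_fmt(rec, i, n):
    return _as_float(rec.format_fields.get("DP"))


def _dp_info(rec, i, n):
    return _as_float(rec.info.get("DP"))


def _dp_sum_ad(rec, i, n):
    ad = _tuple(rec.format_fields.get("AD"))
    if ad is None:
        return None
    try:
        return float(sum(ad))
    except TypeError:
        return None


def _stb_of(fwd, rev):
    fwd, rev = _as_float(fwd), _as_float(rev)
    if fwd is None or rev is None or fwd + rev == 0:
        return None
    return max(fwd, rev) / (fwd + rev)


def _stb_info(rec, i, n):
    return _as_float(_number_a(rec.info.get("STB"), i, n))


def _stb_saf_sar(rec, i, n):
    return _stb_of(_number_a(rec.info.get("SAF"), i, n),
                   _number_a(rec.info.get("SAR"), i, n))


def _stb_adf_adr(rec, i, n):
    f = _number_r(rec.format_fields.get("ADF"), i, n)
    r = _number_r(rec.format_fields.get("ADR"), i, n)
    if f is None or r is None:
        return None
    return _stb_of(f[1], r[1])


def _stb_dp4(rec, i, n):
    dp4 = _tuple(rec.info.get("DP4"))
    if dp4 is None or len(dp4) != 4:
        return None
    return _stb_of(dp4[2], dp4[3])


_GENERIC_VAF = (_vaf_fmt_af, _vaf_info_af, _vaf_fmt_vaf, _vaf_fmt_ad,
                _vaf_info_ao_ro)
_GENERIC_DP = (_dp_fmt, _dp_info, _dp_sum_ad)
_GENERIC_STB = (_stb_info, _stb_saf_sar, _stb_adf_adr, _stb_dp4)

# dialect-preferred sources, tried before the generic chain
_DIALECT_VAF = {
    "gatk-hc": (_vaf_fmt_af, _vaf_fmt_ad),
    "tvc": (_vaf_info_af,),
    "lofreq": (_vaf_info_af,),
    "deepvariant": (_vaf_fmt_vaf, _vaf_fmt_ad),
    "generic": (),
}
_DIALECT_DP = {
    "gatk-hc": (_dp_fmt,), "tvc": (_dp_info,), "lofreq": (_dp_info,),
    "deepvariant": (_dp_fmt,), "generic": (),
}
_DIALECT_STB = {
    "gatk-hc": (), "tvc": (_stb_info, _stb_saf_sar), "lofreq": (_stb_dp4,),
    "deepvariant": (), "generic": (),
}


def _resolve(chains, rec, i, n):
    for fn in chains:
        v = fn(rec, i, n)
        if v is not None:
            return v
    return None


def resolve_params(rec: RawVcfRecord, dialect: CallerDialect) -> tuple[QualityParams, ...]:
    """Resolve per-allele (VAF, DP, STB, QUAL) via the dialect's lookup plan.

    Deterministic: the same record and dialect always yield the same tuple.
    """
    n = len(rec.alts)
    out = []
    for i in range(n):
        vaf = _resolve(_DIALECT_VAF[dialect.name] + _GENERIC_VAF, rec, i, n)
        dp = _resolve(_DIALECT_DP[dialect.name] + _GENERIC_DP, rec, i, n)
        stb = _resolve(_DIALECT_STB[dialect.name] + _GENERIC_STB, rec, i, n)
        out.append(QualityParams(vaf=_as_float(vaf), dp=_as_float(dp),
                                 stb=_as_float(stb), qual=_as_float(rec.qual)))
    return tuple(out)


# ---------------------------------------------------------------------------
# VCF reading


@dataclass
class VcfReadResult:
    """Records plus counters destined for the run report."""

    records: list[RawVcfRecord] = field(default_factory=list)
    n_symbolic_skipped: int = 0
    n_filtered_out: int = 0
    n_no_alt: int = 0
    multi_sample: bool = False

    def __iter__(self) -> Iterator[RawVcfRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _is_symbolic(allele: str) -> bool:
    return not allele or not set(allele.upper()) <= DNA


def read_vcf(path, dialect: CallerDialect | str = "generic",
             pass_only: bool = False) -> VcfReadResult:
    """Read a VCF 4.x file (plain or bgzipped) into RawVcfRecords.

    Symbolic/breakend ALTs (``<DEL>``, ``N[chr2:321[`` ...) are skipped with a
    warning and counted in the result.  Multi-sample files use the first
    sample only (warned once).  With ``pass_only`` records whose FILTER is
    neither PASS nor ``.`` are dropped and counted.
    """
    if isinstance(dialect, str):
        dialect = CallerDialect(dialect)
    res = VcfReadResult()
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as e:
        raise VcfParseError(f"{path}: cannot open as VCF: {e}") from e
    n_header = str(vf.header).count("\n")
    with vf:
        if len(vf.header.samples) > 1:
            res.multi_sample = True
            log.warning("%s: %d samples; using the first only",
                        path, len(vf.header.samples))
        it = iter(vf)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as e:
                raise VcfParseError(
                    f"{path}: malformed VCF at line {n_header + i + 1}: {e}"
                ) from e
            i += 1
            alts = tuple(a for a in (rec.alts or ()))
            if not alts:
                res.n_no_alt += 1
                continue
            if any(_is_symbolic(a) for a in alts) or _is_symbolic(rec.ref):
                res.n_symbolic_skipped += 1
                log.warning("%s line %d: symbolic/breakend allele, skipped",
                            path, n_header + i)
                continue
            filters = list(rec.filter.keys())
            filt = ";".join(filters) if filters else "."
            raw = RawVcfRecord(
                chrom=rec.chrom, pos=rec.pos, id=rec.id,
                ref=rec.ref.upper(), alts=tuple(a.upper() for a in alts),
                qual=_as_float(rec.qual), filter=filt,
                info=dict(rec.info),
                format_fields=(dict(rec.samples[0]) if rec.samples else {}),
            )
            if pass_only and not raw.is_pass:
                res.n_filtered_out += 1
                continue
            raw.params = resolve_params(raw, dialect)
            res.records.append(raw)
    return res


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[Region]:
    """Read a BED3+ file, returning per-chromosome merged regions.

    Overlapping and adjacent intervals are unioned so total_bases() is
    well defined.
    """
    raw: list[Region] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if (not line or line.startswith(("#", "track", "browser"))):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path} line {ln}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as e:
                raise BedParseError(f"{path} line {ln}: {e}") from e
            if start >= end:
                raise BedParseError(
                    f"{path} line {ln}: start {start} >= end {end}")
            raw.append(Region(cols[0], start, end))
    return merge_regions(raw)


def merge_regions(regions: Sequence[Region]) -> list[Region]:
    """Union overlapping/adjacent intervals; sorted by (chrom, start)."""
    out: list[Region] = []
    for r in sorted(regions):
        if out and out[-1].chrom == r.chrom and r.start <= out[-1].end:
            if r.end > out[-1].end:
                out[-1] = Region(r.chrom, out[-1].start, r.end)
        else:
            out.append(Region(r.chrom, r.start, r.end))
    return out


def total_bases(regions: Sequence[Region]) -> int:
    return sum(r.length for r in regions)


# ---------------------------------------------------------------------------
# reference access


class ReferenceAccessor:
    """1-based inclusive fetches of uppercase reference sequence."""

    def fetch(self, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError

    def contig_length(self, chrom: str) -> int:
        raise NotImplementedError


class DictReference(ReferenceAccessor):
    """In-memory reference, for tests and the synthetic generator."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {k: v.upper() for k, v in contigs.items()}

    def fetch(self, chrom, start, end):
        if chrom not in self._contigs:
            raise ReferenceLookupError(f"contig {chrom!r} not in reference")
        seq = self._contigs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ReferenceLookupError(
                f"{chrom}:{start}-{end} out of range (length {len(seq)})")
        return seq[start - 1:end]

    def contig_length(self, chrom):
        if chrom not in self._contigs:
            raise ReferenceLookupError(f"contig {chrom!r} not in reference")
        return len(self._contigs[chrom])


class FastaReference(ReferenceAccessor):
    """FASTA-backed reference (indexed on first open by pyfaidx)."""

    def __init__(self, path):
        self._fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom, start, end):
        if chrom not in self._fa:
            raise ReferenceLookupError(f"contig {chrom!r} not in reference")
        if start < 1 or end > len(self._fa[chrom]) or start > end:
            raise ReferenceLookupError(
                f"{chrom}:{start}-{end} out of range "
                f"(length {len(self._fa[chrom])})")
        return str(self._fa[chrom][start - 1:end])

    def contig_length(self, chrom):
        if chrom not in self._fa:
            raise ReferenceLookupError(f"contig {chrom!r} not in reference")
        return len(self._fa[chrom])


def read_reference(path) -> FastaReference:
    return FastaReference(path)


# ---------------------------------------------------------------------------
# reports

_TSV_COLS = ("chrom", "start", "end", "ref", "alt", "vclass",
             "vaf", "dp", "stb", "qual", "qd", "class")


def _call_row(call) -> dict:
    v, p = call.variant, call.params
    klass = call.klass if call.klass != "FN" else call.fn_subtype
    return {"chrom": v.chrom, "start": v.start, "end": v.end,
            "ref": v.ref, "alt": v.alt, "vclass": v.vclass,
            "vaf": p.vaf, "dp": p.dp, "stb": p.stb, "qual": p.qual,
            "qd": p.qd, "class": klass}


def write_report(metrics, calls, out_dir, run_info: dict | None = None) -> dict:
    """Write the metrics JSON and per-class TSVs.

    Files: ``metrics.json``, ``tp.tsv``, ``fp.tsv``, ``bfn.tsv``,
    ``seqfn.tsv`` (the variants with no supporting reads in the alignment —
    not found in the BAM) and ``fn_unchecked.tsv`` when the re-check stage
    did not run.  Returns the path map.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = metrics.to_dict()
    if run_info:
        payload["run_info"] = run_info
    (out / "metrics.json").write_text(json.dumps(payload, indent=2) + "\n")
    groups = {"tp.tsv": [], "fp.tsv": [], "bfn.tsv": [], "seqfn.tsv": [],
              "fn_unchecked.tsv": []}
    name = {"TP": "tp.tsv", "FP": "fp.tsv", "b-FN": "bfn.tsv",
            "seq-FN": "seqfn.tsv", "unchecked": "fn_unchecked.tsv"}
    for c in calls:
        key = name[c.klass if c.klass != "FN" else c.fn_subtype]
        groups[key].append(_call_row(c))
    paths = {"metrics": out / "metrics.json"}
    for fname, rows in groups.items():
        df = pd.DataFrame(rows, columns=_TSV_COLS)
        df = df.sort_values(["chrom", "start", "end", "ref", "alt"]) if len(df) else df
        df.to_csv(out / fname, sep="\t", index=False)
        paths[fname.removesuffix(".tsv")] = out / fname
    return paths
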