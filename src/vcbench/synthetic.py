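"""Deterministic, seedable generator of complete benchmark fixtures.

The generator emulates a targeted deep-sequencing benchmark: a reference
contig with embedded homopolymer and dinucleotide repeat tracts, a ground
truth of SNVs and small indels, a degraded query callset, and read evidence
(SAM text plus a readcount TSV) — together with a per-variant ledger that
records every intended class and read count, so the whole suite can be
tested end to end with no downloads, using the ledger as the oracle.

Three error classes are injected into the query:

* b-FN (bioinformatic): omitted from the query, but the reads support it —
  recoverable by relaxing caller filters;
* seq-FN (sequencing): omitted and unsupported (allelic dropout / no
  coverage) — unrecoverable;
* FP: called but absent from the truth, with artifact-like parameters
  (low VAF, shallower depth, strand bias, lower QUAL).

On top of that, a configurable fraction of true positives is deliberately
re-spelled in the query (shifted within a repeat tract, padded alleles, or
buried in a multi-allelic line with a zero-frequency decoy): these
"symbolic" mismatches must disappear under harmonization, so the ledger's
confusion matrix is invariant to them.

All randomness flows from one seed through named sub-streams; fixtures are
byte-identical across runs with the same configuration.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .harmonizer import CanonicalVariant
from .vcf_io import DictReference

BASES = ("A", "C", "G", "T")

ROLES = ("TP", "bFN", "seqFN", "FP")
SPELLINGS = ("canonical", "shifted", "padded", "multiallelic")


@dataclass
class SimConfig:
    """Study conditions for one synthetic benchmark.

    Depth defaults follow deep targeted amplicon sequencing (mean coverage
    995, SD ~674, i.e. negative-binomial dispersion ~2.2); ~100 variants per
    dataset; the effect size separating true-call from artifact parameter
    distributions defaults to 2 SD.
    """

    seed: int = 0
    contig: str = "sim1"
    region_length: int = 25_000
    n_snv: int = 60
    n_ins: int = 20
    n_del: int = 20
    homopolymer_fraction: float = 0.5
    depth_mean: float = 995.0
    depth_dispersion: float = 2.2
    vaf_rule: tuple = ("beta", 20.0, 20.0)      # callable variants (~het)
    fp_vaf_rule: tuple = ("beta", 1.5, 28.5)    # artifact-like low VAF
    strand_balance: float = 0.5
    fp_strand_balance: float = 0.9              # artifact strand bias
    fp_rate: float = 0.10
    bfn_rate: float = 0.10
    seqfn_rate: float = 0.05
    symbolic_rate: float = 0.30
    separation: float = 2.0                     # SD units, QUAL and DP shift
    qual_mean: float = 60.0
    qual_sd: float = 15.0
    read_length: int = 60

    def __post_init__(self):
        for name in ("homopolymer_fraction", "fp_rate", "bfn_rate",
                     "seqfn_rate", "symbolic_rate", "strand_balance",
                     "fp_strand_balance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.bfn_rate + self.seqfn_rate > 1:
            raise ConfigError("bfn_rate + seqfn_rate must be <= 1")
        if self.region_length < 200:
            raise ConfigError("region_length must be >= 200")
        if self.n_truth == 0:
            raise ConfigError("at least one truth variant required")
        spacing = self._spacing
        need = 2 * self.n_truth * spacing + 2 * self.read_length
        if need > self.region_length:
            raise ConfigError(
                f"region_length {self.region_length} too small for "
                f"{self.n_truth} variants (+FP slots); need >= {need}")

    @property
    def n_truth(self) -> int:
        return self.n_snv + self.n_ins + self.n_del

    @property
    def _spacing(self) -> int:
        # sites far enough apart that no read overlaps two of them
        return self.read_length + 40


@dataclass
class Tract:
    """A repeat tract implanted in the reference."""

    start0: int       # 0-based start
    length: int
    unit: str         # repeated unit ("A" homopolymer, "AG" dinucleotide)
    kind: str         # "homopolymer" | "dinucleotide"


@dataclass
class SimEntry:
    """Ledger row: one emitted variant with its intended fate."""

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    vclass: str
    role: str                     # TP | bFN | seqFN | FP
    spelling: str = "canonical"   # spelling used in the query VCF
    in_tract: bool = False
    depth: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    ref_fwd: int = 0
    ref_rev: int = 0
    vaf_drawn: float | None = None
    qual: float | None = None

    @property
    def key(self):
        return (self.chrom, self.start, self.end, self.ref, self.alt)

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def vaf_realized(self) -> float | None:
        return self.alt_count / self.depth if self.depth else None

    def canonical(self) -> CanonicalVariant:
        return CanonicalVariant(self.chrom, self.start, self.end,
                                self.ref, self.alt, self.vclass)


@dataclass
class SimTruth:
    """The generator's ledger — the oracle for every downstream stage."""

    config: SimConfig
    entries: list[SimEntry] = field(default_factory=list)

    def count(self, role: str) -> int:
        return sum(1 for e in self.entries if e.role == role)

    @property
    def expected_counts(self) -> dict:
        return {"tp": self.count("TP"), "fp": self.count("FP"),
                "bfn": self.count("bFN"), "seqfn": self.count("seqFN"),
                "fn": self.count("bFN") + self.count("seqFN")}

    @property
    def expected_recall_max(self) -> float:
        c = self.expected_counts
        return (c["tp"] + c["bfn"]) / (c["tp"] + c["fn"])

    def to_json(self) -> str:
        return json.dumps({"config": asdict(self.config),
                           "expected_counts": self.expected_counts,
                           "entries": [asdict(e) for e in self.entries]},
                          indent=1)


# ---------------------------------------------------------------------------
# edit semantics helpers (shared with the test-suite oracles)


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a VCF-style edit (1-based pos) to a contig string."""
    i = pos - 1
    if seq[i:i + len(ref)] != ref:
        raise ValueError(f"ref {ref!r} does not match sequence at {pos}")
    return seq[:i] + alt + seq[i + len(ref):]


def apply_canonical(seq: str, cv: CanonicalVariant) -> str:
    """Apply a canonical (start/end/ref/alt, '-') edit to a contig string."""
    if cv.vclass == "INS":
        a0 = cv.start      # insert after 1-based start == after index start-1
        return seq[:a0] + cv.alt + seq[a0:]
    s0, e0 = cv.start - 1, cv.end - 1
    if seq[s0:e0 + 1] != cv.ref:
        raise ValueError("canonical ref does not match sequence")
    repl = "" if cv.alt == "-" else cv.alt
    return seq[:s0] + repl + seq[e0 + 1:]


def vcf_spelling(seq: str, cv: CanonicalVariant) -> tuple[int, str, str]:
    """Anchored VCF (pos, ref, alt) for a canonical variant."""
    if cv.vclass in ("SNV", "MNV"):
        return cv.start, cv.ref, cv.alt
    if cv.vclass == "DEL":
        anchor = seq[cv.start - 2]
        return cv.start - 1, anchor + cv.ref, anchor
    anchor = seq[cv.start - 1]
    return cv.start, anchor, anchor + cv.alt


def equivalent_indel_spellings(seq: str, cv: CanonicalVariant,
                               max_shift: int = 30) -> list[tuple[int, str, str]]:
    """All anchored VCF spellings of an indel equivalent to the canonical one.

    Works from edit semantics alone (string equality of the resulting
    haplotypes), independently of the harmonizer's normalization loop, so it
    doubles as a test oracle.  Spellings are returned sorted by position;
    the first is the left-most (canonical) one.
    """
    out = []
    if cv.vclass == "DEL":
        L = cv.end - cv.start + 1
        s0 = cv.start - 1
        for d0 in range(max(1, s0 - max_shift), min(len(seq) - L, s0 + max_shift) + 1):
            lo, hi = min(d0, s0), max(d0, s0)
            if seq[lo:hi] == seq[lo + L:hi + L]:
                out.append((d0, seq[d0 - 1:d0 + L], seq[d0 - 1]))
    elif cv.vclass == "INS":
        S = cv.alt
        L = len(S)
        a0 = cv.start - 1          # 0-based anchor index
        for b0 in range(max(0, a0 - max_shift), min(len(seq) - 2, a0 + max_shift) + 1):
            if b0 <= a0:
                gap = seq[b0 + 1:a0 + 1]
                t = (gap + S)[:L]
                ok = t + gap == gap + S
            else:
                gap = seq[a0 + 1:b0 + 1]
                t = (S + gap)[-L:]
                ok = gap + t == S + gap
            if ok:
                out.append((b0 + 1, seq[b0], seq[b0] + t))
    else:
        raise ValueError("only indels have shifted spellings")
    return sorted(set(out))


# ---------------------------------------------------------------------------
# reference generation


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _slots(cfg: SimConfig) -> list[int]:
    """0-based site centers: truth slots first, then FP slots."""
    spacing = cfg._spacing
    first = cfg.read_length
    return [first + i * spacing for i in range(2 * cfg.n_truth)]


def generate_reference(cfg: SimConfig) -> tuple[str, list[Tract]]:
    """Random contig with repeat tracts implanted at every indel site slot.

    Homopolymer tracts are 5-15 bp, dinucleotide tracts 3-7 unit repeats;
    tract boundaries are sealed with non-unit bases so an edit of one unit
    at the tract start is left-aligned by construction.  Deterministic for
    a given seed.
    """
    rng = _rng(cfg, 0)
    seq = rng.choice(BASES, size=cfg.region_length).tolist()
    slots = _slots(cfg)
    tracts: list[Tract] = []
    for si in range(cfg.n_snv, cfg.n_truth):
        c = slots[si]
        if rng.random() < 0.6:
            unit = str(rng.choice(BASES))
            length = int(rng.integers(5, 16))
            fill = unit * length
            kind = "homopolymer"
        else:
            x, y = rng.choice(BASES, size=2, replace=False)
            reps = int(rng.integers(3, 8))
            unit = str(x) + str(y)
            length = 2 * reps
            fill = unit * reps
            kind = "dinucleotide"
        seq[c:c + length] = list(fill)
        others = [b for b in BASES if b not in unit]
        seq[c - 1] = str(rng.choice(others))
        seq[c + length] = str(rng.choice(others))
        tracts.append(Tract(start0=c, length=length, unit=unit, kind=kind))
    return "".join(seq), tracts


# ---------------------------------------------------------------------------
# variant construction


def _draw(rng, rule) -> float:
    kind = rule[0]
    if kind == "fixed":
        return float(rule[1])
    if kind == "beta":
        return float(rng.beta(rule[1], rule[2]))
    if kind == "uniform":
        return float(rng.uniform(rule[1], rule[2]))
    raise ConfigError(f"unknown sampling rule {rule!r}")


def _negbin(rng, mean: float, dispersion: float) -> int:
    # var = mean + mean^2/dispersion
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _make_snv(seq, rng, pos0: int) -> tuple[int, int, str, str, str]:
    ref = seq[pos0]
    alt = str(rng.choice([b for b in BASES if b != ref]))
    return pos0 + 1, pos0 + 1, ref, alt, "SNV"


def _make_del(seq, rng, pos0: int) -> tuple[int, int, str, str, str]:
    """Canonical (left-aligned) deletion near pos0 in plain sequence."""
    L = int(rng.integers(1, 4))
    for s0 in range(pos0, pos0 + 12):
        d = seq[s0:s0 + L]
        if seq[s0 - 1] != d[-1]:          # no equivalent one base left
            return s0 + 1, s0 + L, d, "-", "DEL"
    raise RuntimeError("could not place deletion")   # pragma: no cover


def _make_ins(seq, rng, pos0: int) -> tuple[int, int, str, str, str]:
    """Canonical insertion after pos0 (1-based anchor pos0+1... pos0)."""
    L = int(rng.integers(1, 4))
    s = "".join(rng.choice(BASES, size=L))
    anchor_base = seq[pos0]
    if s[-1] == anchor_base:
        s = s[:-1] + str(rng.choice([b for b in BASES if b != anchor_base]))
    return pos0 + 1, pos0 + 1, "-", s, "INS"


def _tract_indel(tract: Tract, want_del: bool) -> tuple[int, int, str, str, str]:
    """One repeat-unit indel at the tract start (canonical by construction)."""
    t0, u = tract.start0, tract.unit
    if want_del:
        return t0 + 1, t0 + len(u), u, "-", "DEL"
    return t0, t0, "-", u, "INS"      # insertion after 1-based position t0


def generate_truth_and_query(cfg: SimConfig,
                             reference: tuple[str, list[Tract]] | None = None
                             ) -> tuple[str, str, SimTruth]:
    """Truth VCF text, query VCF text and the ledger.

    The truth VCF holds every expected variant in canonical spelling.  The
    query holds the TPs (a ``symbolic_rate`` fraction of them deliberately
    re-spelled) plus the injected FPs, each with caller-style annotations
    (AF/DP/strand counts in INFO, QUAL column) whose distributions separate
    true calls from artifacts by ``cfg.separation``.  b-FN and seq-FN
    variants are omitted from the query.
    """
    if reference is None:
        reference = generate_reference(cfg)
    seq, tracts = reference
    rng = _rng(cfg, 1)
    slots = _slots(cfg)
    truth = SimTruth(config=cfg)
    used_keys: set = set()

    kinds = (["SNV"] * cfg.n_snv + ["INS"] * cfg.n_ins + ["DEL"] * cfg.n_del)
    tract_by_slot = {t.start0: t for t in tracts}
    for si, kind in enumerate(kinds):
        c = slots[si]
        if kind == "SNV":
            start, end, ref, alt, vclass = _make_snv(seq, rng, c)
            in_tract = False
        else:
            tract = tract_by_slot.get(c)
            use_tract = tract is not None and rng.random() < cfg.homopolymer_fraction
            if use_tract:
                start, end, ref, alt, vclass = _tract_indel(
                    tract, want_del=(kind == "DEL"))
                in_tract = True
            else:
                off = c + (tract.length if tract else 0) + 10
                maker = _make_del if kind == "DEL" else _make_ins
                start, end, ref, alt, vclass = maker(seq, rng, off)
                in_tract = False
        entry = SimEntry(cfg.contig, start, end, ref, alt, vclass, role="TP",
                         in_tract=in_tract)
        if entry.key in used_keys:       # slots are disjoint; belt and braces
            continue
        used_keys.add(entry.key)
        u = rng.random()
        if u < cfg.bfn_rate:
            entry.role = "bFN"
        elif u < cfg.bfn_rate + cfg.seqfn_rate:
            entry.role = "seqFN"
        truth.entries.append(entry)

    # FP injection: per-variant probability, at the reserved FP slots
    fp_slot = cfg.n_truth
    for _ in range(len(truth.entries)):
        if rng.random() >= cfg.fp_rate:
            continue
        c = slots[fp_slot]
        fp_slot += 1
        r = rng.random()
        if r < 0.7:
            start, end, ref, alt, vclass = _make_snv(seq, rng, c)
        elif r < 0.85:
            start, end, ref, alt, vclass = _make_del(seq, rng, c)
        else:
            start, end, ref, alt, vclass = _make_ins(seq, rng, c)
        entry = SimEntry(cfg.contig, start, end, ref, alt, vclass, role="FP")
        if entry.key in used_keys:
            continue
        used_keys.add(entry.key)
        truth.entries.append(entry)

    _assign_evidence(cfg, rng, truth)
    _assign_spellings(cfg, rng, seq, truth)

    truth_vcf = _truth_vcf(cfg, seq, truth)
    query_vcf = _query_vcf(cfg, seq, truth, rng)
    return truth_vcf, query_vcf, truth


def _assign_evidence(cfg: SimConfig, rng, truth: SimTruth) -> None:
    """Draw read counts and caller QUAL for every ledger entry."""
    fp_depth_mean = cfg.depth_mean / (1.0 + 0.25 * cfg.separation)
    fp_qual_mean = cfg.qual_mean - cfg.separation * cfg.qual_sd
    for e in truth.entries:
        if e.role == "seqFN":
            depth = 0 if rng.random() < 0.5 else max(
                1, _negbin(rng, cfg.depth_mean, cfg.depth_dispersion))
            e.depth = depth
            e.ref_fwd = int(rng.binomial(depth, cfg.strand_balance))
            e.ref_rev = depth - e.ref_fwd
            continue
        is_fp = e.role == "FP"
        mean = fp_depth_mean if is_fp else cfg.depth_mean
        depth = max(2, _negbin(rng, mean, cfg.depth_dispersion))
        vaf = _draw(rng, cfg.fp_vaf_rule if is_fp else cfg.vaf_rule)
        alt = min(depth, max(1, round(vaf * depth)))
        sb = cfg.fp_strand_balance if is_fp else cfg.strand_balance
        e.depth = depth
        e.vaf_drawn = vaf
        e.alt_fwd = int(rng.binomial(alt, sb))
        e.alt_rev = alt - e.alt_fwd
        ref = depth - alt
        e.ref_fwd = int(rng.binomial(ref, cfg.strand_balance))
        e.ref_rev = ref - e.ref_fwd
        if e.role in ("TP", "FP"):
            qmean = fp_qual_mean if is_fp else cfg.qual_mean
            e.qual = round(max(1.0, float(rng.normal(qmean, cfg.qual_sd))), 1)


def _assign_spellings(cfg: SimConfig, rng, seq: str, truth: SimTruth) -> None:
    for e in truth.entries:
        if e.role != "TP" or rng.random() >= cfg.symbolic_rate:
            continue
        choices = ["padded", "multiallelic"]
        if e.vclass in ("INS", "DEL"):
            choices.append("shifted")
        e.spelling = str(rng.choice(choices))


# ---------------------------------------------------------------------------
# VCF emission

_TRUTH_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_QUERY_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alt reads on forward strand">
##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alt reads on reverse strand">
##INFO=<ID=SRF,Number=1,Type=Integer,Description="Ref reads on forward strand">
##INFO=<ID=SRR,Number=1,Type=Integer,Description="Ref reads on reverse strand">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _fmt_af(v: float) -> str:
    return f"{v:.6g}"


def _truth_vcf(cfg: SimConfig, seq: str, truth: SimTruth) -> str:
    lines = []
    for e in truth.entries:
        if e.role == "FP":
            continue
        pos, ref, alt = vcf_spelling(seq, e.canonical())
        lines.append((pos, f"{cfg.contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t."))
    lines.sort(key=lambda t: t[0])
    return _TRUTH_HEADER.format(contig=cfg.contig, length=len(seq)) + \
        "".join(l + "\n" for _, l in lines)


def _decoy_alt(rng, ref: str, alt: str) -> str:
    bad = {ref[0], alt[0] if alt else ref[0]}
    base = str(rng.choice([b for b in BASES if b not in bad]))
    decoy = base + ref[1:]
    return decoy


def _query_vcf(cfg: SimConfig, seq: str, truth: SimTruth, rng) -> str:
    lines = []
    for e in truth.entries:
        if e.role not in ("TP", "FP"):
            continue
        pos, ref, alt = vcf_spelling(seq, e.canonical())
        # the caller-style AF annotation is the latent allele fraction; the
        # pileup VAF (alt/depth) is its finite-depth realization
        af = e.vaf_drawn
        spelling = e.spelling
        if spelling == "shifted":
            alts = equivalent_indel_spellings(seq, e.canonical())
            others = [s for s in alts if s[0] != pos]
            if others:
                pos, ref, alt = others[-1]     # right-most spelling
            else:
                spelling = "padded"
        if spelling == "padded":
            k = int(rng.integers(1, 3))
            k = min(k, pos - 1)
            ctx = seq[pos - 1 - k:pos - 1]
            pos, ref, alt = pos - k, ctx + ref, ctx + alt
        if spelling == "multiallelic":
            decoy = _decoy_alt(rng, ref, alt)
            info = (f"AF={_fmt_af(af)},0;DP={e.depth};"
                    f"SAF={e.alt_fwd},0;SAR={e.alt_rev},0;"
                    f"SRF={e.ref_fwd};SRR={e.ref_rev}")
            line = (f"{cfg.contig}\t{pos}\t.\t{ref}\t{alt},{decoy}\t"
                    f"{e.qual}\tPASS\t{info}")
        else:
            info = (f"AF={_fmt_af(af)};DP={e.depth};"
                    f"SAF={e.alt_fwd};SAR={e.alt_rev};"
                    f"SRF={e.ref_fwd};SRR={e.ref_rev}")
            line = (f"{cfg.contig}\t{pos}\t.\t{ref}\t{alt}\t"
                    f"{e.qual}\tPASS\t{info}")
        e.spelling = spelling
        lines.append((pos, line))
    lines.sort(key=lambda t: t[0])
    return _QUERY_HEADER.format(contig=cfg.contig, length=len(seq)) + \
        "".join(l + "\n" for _, l in lines)


# ---------------------------------------------------------------------------
# reads


def _anchor0_of(e: SimEntry) -> int:
    return e.start - 2 if e.vclass == "DEL" else e.start - 1


def generate_reads(cfg: SimConfig, truth: SimTruth, seq: str
                   ) -> tuple[str, str]:
    """Error-free reads realizing the ledger's counts exactly.

    Returns (SAM text, readcount TSV text).  Reads are perfect copies of the
    reference or of the alt haplotype around each site (CIGAR I/D for
    indels), placed so that no read spans two sites; per-strand counts match
    the ledger by construction.  Same seed, same bytes.
    """
    rng = _rng(cfg, 2)
    rl = cfg.read_length
    sam_rows = []
    ridx = 0

    def read_start(a0: int, extra: int) -> int:
        jit = int(rng.integers(-8, 9))
        st = a0 - rl // 2 + jit
        return max(0, min(st, len(seq) - rl - extra))

    for e in truth.entries:
        if e.depth == 0:
            continue
        a0 = _anchor0_of(e)
        reads = ([("alt", False)] * e.alt_fwd + [("alt", True)] * e.alt_rev +
                 [("ref", False)] * e.ref_fwd + [("ref", True)] * e.ref_rev)
        for support, is_rev in reads:
            if support == "ref" or e.vclass == "SNV":
                st = read_start(a0, 0)
                bases = seq[st:st + rl]
                if support == "alt":      # SNV substitution
                    k = (e.start - 1) - st
                    bases = bases[:k] + e.alt + bases[k + 1:]
                cigar = f"{rl}M"
            elif e.vclass == "DEL":
                L = e.end - e.start + 1
                ds0 = e.start - 1
                st = read_start(a0, L)
                left = ds0 - st
                bases = seq[st:ds0] + seq[ds0 + L:ds0 + L + (rl - left)]
                cigar = f"{left}M{L}D{rl - left}M"
            else:                         # INS
                L = len(e.alt)
                st = read_start(a0, L)
                left = a0 - st + 1
                right = rl - left - L
                bases = seq[st:a0 + 1] + e.alt + seq[a0 + 1:a0 + 1 + right]
                cigar = f"{left}M{L}I{right}M"
            flag = 16 if is_rev else 0
            sam_rows.append((st + 1,
                             f"r{ridx}\t{flag}\t{cfg.contig}\t{st + 1}\t60\t"
                             f"{cigar}\t*\t0\t0\t{bases}\t{'I' * len(bases)}"))
            ridx += 1
    sam_rows.sort(key=lambda t: t[0])
    sam = (f"@HD\tVN:1.6\tSO:coordinate\n"
           f"@SQ\tSN:{cfg.contig}\tLN:{len(seq)}\n" +
           "".join(r + "\n" for _, r in sam_rows))
    return sam, readcount_tsv(cfg, truth, seq)


def readcount_tsv(cfg: SimConfig, truth: SimTruth, seq: str) -> str:
    """Readcount TSV straight from the ledger's per-site counts."""
    tsv_rows = []
    for e in truth.entries:
        a0 = _anchor0_of(e)
        ref_base = seq[a0]
        if e.vclass == "SNV" or e.vclass == "MNV":
            alt_key = e.alt
        elif e.vclass == "INS":
            alt_key = "+" + e.alt
        else:
            alt_key = "-" + e.ref
        fields = [cfg.contig, str(a0 + 1), ref_base, str(e.depth),
                  f"{ref_base}:{e.ref_fwd + e.ref_rev}:{e.ref_fwd}:{e.ref_rev}"]
        if e.alt_count > 0:
            fields.append(f"{alt_key}:{e.alt_count}:{e.alt_fwd}:{e.alt_rev}")
        tsv_rows.append((a0 + 1, "\t".join(fields)))
    tsv_rows.sort(key=lambda t: t[0])
    return "#chrom\tpos\tref\tdepth\tallele:count:fwd:rev...\n" + \
        "".join(r + "\n" for _, r in tsv_rows)


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SimDataset:
    """Paths of an emitted fixture set plus the in-memory ledger."""

    truth: SimTruth
    reference: Path
    truth_vcf: Path
    query_vcf: Path
    bed: Path
    sam: Path
    readcounts: Path
    ledger: Path


def write_fasta(seq: str, contig: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")


def generate_dataset(cfg: SimConfig, out_dir, write_sam: bool = True
                     ) -> SimDataset:
    """Emit a complete fixture set (FASTA, VCFs, BED, SAM, TSV, ledger JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq, tracts = generate_reference(cfg)
    truth_vcf, query_vcf, truth = generate_truth_and_query(cfg, (seq, tracts))
    if write_sam:
        sam, tsv = generate_reads(cfg, truth, seq)
    else:
        sam, tsv = None, readcount_tsv(cfg, truth, seq)
    paths = SimDataset(
        truth=truth,
        reference=out / "reference.fa",
        truth_vcf=out / "truth.vcf",
        query_vcf=out / "query.vcf",
        bed=out / "regions.bed",
        sam=out / "reads.sam",
        readcounts=out / "readcounts.tsv",
        ledger=out / "ledger.json",
    )
    write_fasta(seq, cfg.contig, paths.reference)
    paths.truth_vcf.write_text(truth_vcf)
    paths.query_vcf.write_text(query_vcf)
    paths.bed.write_text(f"{cfg.contig}\t0\t{cfg.region_length}\n")
    if write_sam:
        paths.sam.write_text(sam)
    paths.readcounts.write_text(tsv)
    paths.ledger.write_text(truth.to_json())
    return paths


def reference_accessor(seq: str, contig: str) -> DictReference:
    return DictReference({contig: seq})
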