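# Methods

## Problem setting

Benchmarking a variant-calling pipeline means comparing its callset
(query) with a trusted callset (truth) inside high-confidence regions.
Three complications dominate in practice: the same edit can be spelled
many ways in VCF; specificity needs a notion of true negatives on a
reference where almost every base is negative; and a false negative can
have three distinct causes (never sequenced, sequenced but filtered out,
or merely spelled differently) that call for entirely different remedies.
vcbench addresses all three: harmonization, base-level TN accounting, and
a pileup re-check that splits FNs into sequencing (seq-FN) and
bioinformatic (b-FN) classes.

## Canonical variant representation

Every raw record is decomposed into single-allele edits, left-aligned and
parsimony-trimmed, then stored as `(chrom, start, end, ref, alt)` with `-`
for the absent allele:

* SNV: `start == end`, one base each side.
* DEL: `alt == "-"`, `[start, end]` are the deleted bases.
* INS: `ref == "-"`, `start == end` is the base *after* which the sequence
  is inserted.
* MNV: multi-base substitution (unequal-length block substitutions are
  carried under the same class; they are matched exactly, never
  re-decomposed).

The normalization loop is the standard one: repeatedly drop shared
trailing bases (re-anchoring on the previous reference base whenever an
allele would empty), then trim shared leading bases while both alleles
stay longer than one. Correctness is defined semantically — applying the
canonical edit to the reference must reproduce the exact haplotype of the
raw edit — and the test suite checks that property against a string-splice
oracle on tens of thousands of generated spellings, including
homopolymer-shifted, padded and multi-allelic ones.

Degenerate inputs: a deletion/insertion pinned at position 1 stops
shifting with a warning instead of erroring; `ref == alt` after trimming
is a null edit and the record is dropped with a warning; a REF that
disagrees with the reference sequence skips the record (warning), never
aborts the run. Duplicate canonical variants collapse keeping the copy
with the highest QUAL — the copy most likely to survive downstream
thresholds. `N` is treated as a literal base: exact matching is the
conservative choice for benchmarking.

## Matching and metrics

Matching is exact on the canonical key — presence only, genotype- and
zygosity-blind, no haplotype reconstruction. Region restriction is
full-containment of the variant's `[start, end]` interval (insertions:
the anchor base): a deletion hanging over a panel edge has ambiguous
truth status and is excluded from both sides.

Counts: `TP = |query ∩ truth|`, `FP = |query \ truth|`,
`FN = |truth \ query|`. True negatives are base pairs: region bases not
claimed by any positive call, where a deletion claims all deleted bases
and an insertion its anchor. FN positions stay negative — specificity
concerns the query's claims, and an uncalled position is a negative call.
All ratios with zero denominators are reported as null, never NaN.

## Pileup re-check and recall_max

Each FN site is counted in the alignment: a read supports an SNV if its
aligned base at the site equals the alt; a deletion if its alignment
deletes exactly the canonical interval; an insertion if it inserts exactly
the canonical sequence after the anchor (no fuzzy windows — mirroring the
exact-key matching). Duplicate-marked, secondary, supplementary and
unmapped reads are excluded; mapping- and base-quality floors default to 0
and are exposed as options. An FN with at least `min_alt_reads`
(default 1 — the criterion is *existence* of support; diagnostic users may
prefer 2) supporting reads is a b-FN, otherwise a seq-FN, and

```
recall_max = (TP + b-FN) / (TP + FN)
```

is the recall attainable if every supported variant were called. b-FNs
carry pileup-derived parameters: `VAF = alt/depth`,
`STB = max(alt_fwd, alt_rev) / (alt_fwd + alt_rev)` ∈ [0.5, 1] (0.5
balanced, 1 one-sided — the convention of reporting bias toward one
strand). Evidence can also come from a readcount-style TSV (documented in
the README); both paths return identical counts on the synthetic suite.
Alignments are loaded per contig into memory and scanned by window, so
plain SAM text and unindexed BAMs work; this targets panel-scale data,
not whole genomes.

## Parameter analysis

SeqPos = TP + b-FN (label 1) + FP (label 0); seq-FNs are excluded since no
parameter change can call them. TPs and FPs contribute their caller
parameters, b-FNs their pileup parameters — the only ones each has.

* **Distribution tests**: two-sided Mann–Whitney U at α = 0.05 for TP vs
  FP and TP vs b-FN per parameter; exact enumeration when both groups have
  ≤ 8 tie-free observations (keeps small-sample p-values exact), otherwise
  the normal approximation with tie and continuity corrections. Raw
  p-values, no multiplicity correction — parameters are screened
  marginally.
* **ROC**: thresholds at midpoints between consecutive distinct observed
  values plus ±∞ sentinels; AUROC by trapezoid, verified at every call
  against the pairwise-concordance statistic `U/(n1·n0)` with ties counted
  half (the two are equal exactly, ties included; the library asserts it).
  Directions: VAF, DP, QUAL, QD greater-is-positive; STB
  smaller-is-positive (high bias suggests artifact); configurable.
* **Cutpoints**: maximize Youden's `J = sens + spec − 1`; ties break
  toward the threshold retaining more positives (lower threshold for
  greater-is-positive), so a worthless parameter falls back to the −∞
  sentinel rather than discarding calls.
* **QD**: some callers do not report quality-by-depth; it is derived as
  `QD = 4·QUAL/DP` (null at DP = 0), kept deliberately in one swappable
  function.
* **Threshold simulation**: each TP/FP/b-FN is re-judged on its own
  parameters. Failing TPs become FNs, failing FPs are removed, passing
  b-FNs are recovered as TPs, seq-FNs stay FN. A null parameter passes any
  constraint — a threshold on a metric a caller never reports must not
  annihilate its callset. Positions of calls that are no longer positive
  (failing TPs and FPs) return to the TN base count, consistent with the
  TN definition above; overlapping calls could double-count a position
  here, which is negligible at panel scale. With empty thresholds every
  b-FN is recovered, so simulated recall equals recall_max — a useful
  sanity identity. The simulated MetricSet's own `recall_max` counts
  every read-supported variant (failing TPs and unrecovered b-FNs) and is
  therefore invariant under thresholds.

## Synthetic data generator

The generator emulates a deep targeted amplicon panel benchmarked against
a germline-like truth set. Defaults (chosen once as the study conditions):

| parameter | default | rationale |
|---|---|---|
| variants per dataset | 60 SNV + 20 INS + 20 DEL | panel-scale callset |
| depth | negative binomial, mean 995, dispersion 2.2 (SD ≈ 674) | deep amplicon coverage with realistic overdispersion |
| VAF, callable | Beta(20, 20) | heterozygous-like cluster at 0.5 |
| VAF, artifact | Beta(1.5, 28.5) | low-frequency noise, mean 0.05 |
| QUAL | Normal(60, 15), artifacts shifted down by `separation`·SD | |
| separation | 2 SD | effect size separating real calls from artifacts |
| artifact strand balance | 0.9 forward | strand-biased artifacts |
| fp / bfn / seqfn / symbolic rates | 0.10 / 0.10 / 0.05 / 0.30 | all error classes present but TP-dominated |
| homopolymer fraction | 0.5 | half the indels inside repeat tracts |

Sites are placed on disjoint slots (spacing > read length) so no read
spans two sites and the ledger's per-site counts are exact on the SAM
path. Repeat tracts (homopolymers 5–15 bp, dinucleotide repeats 3–7
units) are implanted at indel slots with sealed borders, making the
intended edit left-aligned by construction; the "shifted" query spelling
is drawn from an independent enumeration of haplotype-equivalent
spellings. Reads are error-free, locally placed copies of the reference
or alt haplotype (CIGAR I/D for indels) — sufficient to exercise the
pileup logic without simulating an aligner. The caller-style `AF`
annotation is the latent allele fraction; the pileup VAF is its
finite-depth realization (they agree to within 1/depth). seq-FN sites
have zero alt reads and, half the time, zero coverage (allelic dropout
vs. total dropout). All randomness flows from one seed through named
sub-streams; outputs are byte-identical per seed.

What passing tests on this generator do **not** show: robustness to
sequencing errors, quality-score miscalibration, alignment artifacts
around indels, overlapping/nearby variants, contamination or somatic
subclonality. Those are properties of real data the generator
deliberately omits; the generator validates the bookkeeping and the
statistics, not the biology.

## Design choices that were genuinely open

* Records with FILTER ≠ PASS are kept (and flagged) by default, with a
  `--pass-only` switch: filter policy is the benchmark user's tradeoff.
* Multi-sample VCFs use the first sample, with a warning.
* The VAF fallback chain resolves, in order: FORMAT/AF, INFO/AF,
  FORMAT/VAF, FORMAT/AD (alt over the AD sum), INFO/AO,RO; DP:
  FORMAT/DP, INFO/DP, sum(AD); STB: INFO/STB, SAF/SAR, ADF/ADR, DP4.
  Missing stays missing — never silently zero.
* Zero-frequency alleles of multi-allelic records (resolved VAF = 0) are
  dropped at decomposition; alleles with no frequency evidence are kept.

## Problem sizes and runtime

The shipped test suite runs ~140 tests in well under a minute on one
core: 10,000+ harmonization spellings, 100 generator seeds of ~100
variants each for the confusion-matrix oracle (readcount path), 1,000
random sets for the AUROC identity, full Mann–Whitney enumeration to
n = 6 per group, and 100 seeds of a 500-variant cutpoint-recovery study
(generative VAF boundary at 0.07; the recovered cutpoint must land within
the local observed-value spacing in ≥ 95 seeds). `scripts/acceptance.py`
runs the default study end to end, SAM path included, in a few seconds.

## Known limitations

* No haplotype/diplotype-aware matching and no genotype comparison: a
  het/hom mismatch at the same allele is a TP here.
* Complex variants are matched as exact blocks, not re-decomposed into
  constituent simple edits.
* Marginal (per-parameter) threshold analysis only; no joint
  optimization.
* In-memory alignment access targets panels; whole-genome BAMs would want
  indexed iteration.
* gVCF blocks, structural variants, breakends and phasing fields are out
  of scope; symbolic ALT records are skipped and counted.
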