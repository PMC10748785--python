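# vcbench

Benchmarking small-variant calling pipelines against a ground truth —
with an answer to the question standard benchmarkers leave open: *when a
variant is missed, whose fault is it?*

A false negative can be a **sequencing** failure (no read supports the
allele; only a redesigned assay can fix it) or a **bioinformatic** one (the
reads support it, the caller filtered it out; recoverable by retuning
parameters) — or merely **symbolic**, an artifact of two files spelling the
same edit differently. vcbench eliminates the symbolic class by
harmonization, separates the other two by re-checking every FN in the read
evidence, and reports the *maximum theoretical recall*

```
recall_max = (TP + b-FN) / (TP + FN)
```

the recall a pipeline could reach on this data by relaxing its filters,
where b-FN counts the FNs with supporting reads. It then treats the
sequencing-positive variants (SeqPos = TP + b-FN labelled 1, FP labelled 0)
as a classification problem: per-parameter ROC curves over caller quality
metrics (VAF, DP, strand bias, QUAL, QD = 4·QUAL/DP), AUROC, optimal
cutpoints by Youden's J, Mann–Whitney tests between call classes, and
what-if simulation of new thresholds without re-running the caller.

Intended users: people validating or tuning NGS/TGS panels and variant
callers (GATK-HC, TVC, LoFreq, DeepVariant-style dialects are recognized;
a generic fallback chain covers the rest), especially in diagnostic
settings where recall is the priority and every missed variant needs an
explanation.

## What it does

1. **Harmonization** — multi-allelic decomposition (keeping per-allele
   quality values, dropping zero-frequency decoy alleles), left-alignment
   and parsimony trimming into a canonical start/end/ref/alt form with `-`
   for the absent allele. Two spellings of one edit always collapse to one
   key.
2. **Accuracy** — exact-key matching inside the high-confidence BED
   regions; recall, precision, FDR, F1, and base-level specificity (true
   negatives counted in reference base pairs not claimed by any positive
   call).
3. **Re-check** — every FN is looked up in the BAM/SAM (or a readcount
   TSV); caller-independent pileup parameters (VAF, DP, STB) are attached
   to the recoverable ones, giving `recall_max`.
4. **Optimization** — distribution tests, ROC/AUROC, optimal cutpoints,
   and threshold simulation on the SeqPos set.

A deterministic synthetic-data generator (`vcbench.synthetic`) produces
complete fixture sets — reference with homopolymer/dinucleotide tracts,
truth and degraded query VCFs, reads, readcounts — with a ledger recording
every variant's intended fate, so the whole pipeline is testable offline.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/03_recheck_maximum_recall.py` (seed 7: 100 truth
variants, 85 called, plus 13 artifact calls):

```
before re-check: recall = 0.850, recall_max unknown
after re-check : 15 FN = 9 b-FN + 6 seq-FN
recall_max = 0.940  (recall 0.850 could rise to this by relaxing caller filters)

  recoverable SNV sim1:761 T>C  pileup VAF=0.432 DP=1874 STB=0.52
  ...
  recoverable DEL sim1:8387 AC>-  pileup VAF=0.487 DP=942 STB=0.51
```

Of the 15 missed variants, 9 are sitting in the reads waiting for a better
filter setting and 6 were never sequenced; 0.94 is the ceiling any tuning
can reach. `examples/04_optimize_thresholds.py` then finds the VAF
cutpoint that realizes the ceiling:

```
parameter  AUROC   optimal cutpoint  (direction)
  vaf      1.000         0.2421   (greater-is-positive)
  stb      1.000         0.6438   (smaller-is-positive)
  qual     0.967             46   (greater-is-positive)

replaying the callset with min VAF = 0.242:
  recall    0.850 -> 0.940 (ceiling recall_max = 0.940)
  precision 0.867 -> 1.000
```

## Command line

The same stages as shell commands, each writing a metrics JSON, per-class
TSV tables (TP/FP/b-FN/seq-FN), and a run manifest:

```bash
vcbench simulate-data --seed 7 --out data/
vcbench benchmark --query q.vcf --truth t.vcf --bed hc.bed --ref ref.fa --out out/
vcbench recheck   ... --bam sample.bam --out out/      # adds recall_max
vcbench optimize  ... --bam sample.bam --min-vaf 0.05 --out out/
```

`--bam` accepts a SAM/BAM alignment or a readcount TSV
(`chrom  pos  ref  depth  allele:count:fwd:rev ...`, with `+SEQ`/`-SEQ`
keys for indels at their anchor base). A YAML/JSON `--config` file can
supply any option (flags override it; the run manifest records the
resolved values). Exit codes: 0 success, 2 usage/input error, 3 data
error.

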