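"""Split false negatives by their cause and compute the maximum recall.

Every FN is re-evaluated in the read alignment: if supporting reads exist
it is a bioinformatic FN (the caller filtered it; recoverable), otherwise a
sequencing FN (nothing to recover).  recall_max = (TP + b-FN) / (TP + FN)
is the best recall any parameter tuning could reach on this data.
"""
import tempfile

from vcbench import pipeline
from vcbench.synthetic import SimConfig, generate_dataset

ds = generate_dataset(SimConfig(seed=7), tempfile.mkdtemp())
res = pipeline.run_benchmark(ds.query_vcf, ds.truth_vcf, ds.bed,
                             ds.reference)
print(f"before re-check: recall = {res.metrics.recall:.3f}, "
      f"recall_max unknown")

res = pipeline.run_recheck(res, ds.sam)          # or ds.readcounts (TSV)
m = res.metrics
seqfn = sum(1 for c in res.calls if c.label == "seq-FN")
print(f"after re-check : {m.fn} FN = {m.bfn} b-FN + {seqfn} seq-FN")
print(f"recall_max = {m.recall_max:.3f}  (recall {m.recall:.3f} could rise "
      f"to this by relaxing caller filters)")
print()
for c in res.calls:
    if c.label == "b-FN":
        v, p = c.variant, c.params
        print(f"  recoverable {v.vclass:>3} {v.chrom}:{v.start} "
              f"{v.ref}>{v.alt}  pileup VAF={p.vaf:.3f} DP={p.dp:.0f} "
              f"STB={p.stb:.2f}")
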