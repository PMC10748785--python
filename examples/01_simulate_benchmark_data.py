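"""Simulate a complete benchmark fixture set with a known answer.

Builds a reference contig with repeat tracts, a ground-truth callset, a
degraded query callset (false positives, two flavors of false negatives,
deliberately re-spelled true positives) and matching read evidence, then
prints the ledger's expected confusion matrix — the numbers every later
stage must reproduce.
"""
import tempfile
from pathlib import Path

from vcbench.synthetic import SimConfig, generate_dataset

cfg = SimConfig(seed=7)
out = Path(tempfile.mkdtemp(prefix="vcbench-demo-"))
ds = generate_dataset(cfg, out)

print(f"wrote fixture set to {out}:")
for name in ("reference", "truth_vcf", "query_vcf", "bed", "sam",
             "readcounts", "ledger"):
    print(f"  {getattr(ds, name).name}")
print()
c = ds.truth.expected_counts
print(f"expected confusion matrix: TP={c['tp']}  FP={c['fp']}  "
      f"b-FN={c['bfn']}  seq-FN={c['seqfn']}")
print(f"expected recall_max     : {ds.truth.expected_recall_max:.3f}")
print()
print("TP+b-FN+seq-FN is the truth-set size; b-FNs have supporting reads")
print("(recoverable by relaxing caller filters), seq-FNs do not.")
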