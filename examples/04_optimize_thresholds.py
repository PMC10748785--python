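"""Score caller quality parameters and simulate new filter thresholds.

The sequencing-positive set (TP + b-FN labelled 1, FP labelled 0) is the
material for per-parameter ROC curves: the AUROC says how well each metric
separates real calls from artifacts, and the optimal cutpoint (Youden's J)
suggests a filter threshold.  simulate_thresholds then replays the callset
under candidate thresholds without re-running the caller.
"""
import tempfile

from vcbench import pipeline
from vcbench.optimizer import ThresholdSet, simulate_thresholds
from vcbench.synthetic import SimConfig, generate_dataset

ds = generate_dataset(SimConfig(seed=7), tempfile.mkdtemp())
res = pipeline.run_recheck(
    pipeline.run_benchmark(ds.query_vcf, ds.truth_vcf, ds.bed, ds.reference),
    ds.readcounts)
opt = pipeline.run_optimize(res)

print(f"SeqPos: {len(res.seqpos)} records "
      f"({sum(r.label for r in res.seqpos)} callable, rest artifacts)")
print()
print("parameter  AUROC   optimal cutpoint  (direction)")
for p, c in opt.cutpoints.items():
    print(f"  {p:<7} {c['auroc']:6.3f}   {c['cutpoint']:>12.4g}   "
          f"({c['direction']}-is-positive)")

t = opt.tests[0]["TP_vs_FP"]
print(f"\nMann-Whitney VAF TP vs FP: U={t['u']:.0f}, p={t['p_value']:.2e} "
      f"({'significant' if t['significant'] else 'not significant'} at 0.05)")

cut = opt.cutpoints["vaf"]["cutpoint"]
m0 = res.metrics
m = simulate_thresholds(res.calls, ThresholdSet(min_vaf=cut), res.tn_bases)
print(f"\nreplaying the callset with min VAF = {cut:.3f}:")
print(f"  recall    {m0.recall:.3f} -> {m.recall:.3f} "
      f"(ceiling recall_max = {m0.recall_max:.3f})")
print(f"  precision {m0.precision:.3f} -> {m.precision:.3f}")
print("a threshold below every b-FN VAF recovers them as TPs while")
print("discarding artifact calls; recall can exceed the original.")
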