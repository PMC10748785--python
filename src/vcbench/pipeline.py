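"""End-to-end orchestration: harmonize -> restrict -> match -> metrics,
then the optional pileup re-check and parameter-analysis stages.

These functions are the library's top-level entry points; the CLI is a thin
wrapper around them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from . import comparator, harmonizer, optimizer, recheck, vcf_io

log = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    """Classified calls and metrics for one query-vs-truth comparison."""

    calls: list[comparator.ClassifiedCall]
    metrics: comparator.MetricSet
    tn_bases: int
    regions: list[vcf_io.Region]
    n_query: int
    n_truth: int
    query_stats: dict = field(default_factory=dict)
    bfn_count: int | None = None
    seqpos: list = field(default_factory=list)


def run_benchmark(query_vcf, truth_vcf, bed, fasta_or_ref,
                  dialect: str = "generic",
                  pass_only: bool = False) -> BenchmarkResult:
    """Stages 1-2: harmonization and accuracy quantification.

    ``fasta_or_ref`` is a FASTA path or an already-open ReferenceAccessor.
    """
    reference = (fasta_or_ref if isinstance(fasta_or_ref, vcf_io.ReferenceAccessor)
                 else vcf_io.read_reference(fasta_or_ref))
    regions = vcf_io.read_bed(bed)
    qres = vcf_io.read_vcf(query_vcf, dialect=dialect, pass_only=pass_only)
    tres = vcf_io.read_vcf(truth_vcf, dialect="generic")
    query = harmonizer.harmonize_callset(qres, reference)
    truth = harmonizer.harmonize_callset(tres, reference)
    query = comparator.restrict_to_regions(query, regions)
    truth = comparator.restrict_to_regions(truth, regions)
    if not truth:
        log.warning("zero truth variants inside the high-confidence regions; "
                    "metrics will be null")
    # attach derived QD to caller params
    for v in query:
        v.params.qd = optimizer.compute_qd(v.params.qual, v.params.dp)
    calls = comparator.match_callsets(query, truth)
    tn = comparator.count_tn_bases(regions, calls)
    metrics = comparator.compute_metrics(calls, tn)
    return BenchmarkResult(
        calls=calls, metrics=metrics, tn_bases=tn, regions=regions,
        n_query=len(query), n_truth=len(truth),
        query_stats={"symbolic_skipped": qres.n_symbolic_skipped,
                     "filtered_out": qres.n_filtered_out,
                     "no_alt": qres.n_no_alt})


def run_recheck(result: BenchmarkResult, evidence_path,
                policy: recheck.RecheckPolicy | None = None
                ) -> BenchmarkResult:
    """Stage 3: FN re-evaluation in the read evidence (BAM/SAM or TSV).

    Splits FNs into b-FN / seq-FN, attaches pileup parameters, recomputes
    the metrics with recall_max, and builds the SeqPos set.
    """
    source = recheck.open_evidence(evidence_path)
    result.calls, bfn = recheck.recheck_calls(result.calls, source, policy)
    result.bfn_count = bfn
    result.metrics = comparator.compute_metrics(
        result.calls, result.tn_bases, bfn_count=bfn)
    result.seqpos = recheck.build_seqpos(result.calls)
    return result


@dataclass
class OptimizeResult:
    tests: list[dict]
    rocs: dict
    cutpoints: dict
    simulated: comparator.MetricSet | None = None
    skipped: dict = field(default_factory=dict)


def run_optimize(result: BenchmarkResult,
                 parameters: Sequence[str] = ("vaf", "dp", "stb", "qual", "qd"),
                 thresholds: optimizer.ThresholdSet | dict | None = None,
                 directions: dict | None = None) -> OptimizeResult:
    """Stage 4: distribution tests, per-parameter ROC/cutpoints, simulation.

    Requires the re-check stage (SeqPos and b-FN parameters).  Parameters
    whose ROC is undefined (single class, all null) are skipped with a
    notice rather than erroring.
    """
    if result.bfn_count is None:
        from .errors import DataError
        raise DataError(
            "run_recheck must run before run_optimize (SeqPos needs b-FNs)")
    directions = {**optimizer.DEFAULT_DIRECTIONS, **(directions or {})}
    tests = [optimizer.compare_distributions(result.calls, p)
             for p in parameters]
    rocs, cutpoints, skipped = {}, {}, {}
    for p in parameters:
        try:
            roc = optimizer.roc_curve(result.seqpos, p, directions[p])
        except Exception as e:  # single-class or all-null input
            skipped[p] = str(e)
            continue
        optimizer.optimal_cutpoint(roc)
        rocs[p] = roc
        cutpoints[p] = {"cutpoint": roc.optimal_cutpoint,
                        "youden_j": roc.optimal_j, "auroc": roc.auroc,
                        "direction": roc.direction}
    ths = thresholds if thresholds is not None else optimizer.ThresholdSet()
    if not isinstance(ths, optimizer.ThresholdSet):
        ths = optimizer.ThresholdSet.from_dict(dict(ths))
    simulated = optimizer.simulate_thresholds(result.calls, ths,
                                              result.tn_bases)
    return OptimizeResult(tests=tests, rocs=rocs, cutpoints=cutpoints,
                          simulated=simulated, skipped=skipped)
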