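import itertools
import math
import random

import numpy as np
import pytest

from vcbench.comparator import ClassifiedCall
from vcbench.errors import ConfigError, DataError
from vcbench.harmonizer import CanonicalVariant
from vcbench.optimizer import (SeqPosRecord, ThresholdSet,
                               compare_distributions, compute_qd,
                               mann_whitney, optimal_cutpoint, roc_curve,
                               simulate_thresholds)
from vcbench.vcf_io import QualityParams

CV = CanonicalVariant("c", 1, 1, "A", "G", "SNV")


def recs(pos, neg, param="vaf"):
    return ([SeqPosRecord(CV, 1, **{param: float(v)}) for v in pos] +
            [SeqPosRecord(CV, 0, **{param: float(v)}) for v in neg])


def exact_two_sided_p(x, y):
    """Full-enumeration two-sided Mann-Whitney p (tie-free data)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    center = n1 * (len(y)) / 2.0
    dev = abs(u_obs - center)
    total = hits = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = sum(1 for a in xs for b in ys if a > b)
        total += 1
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_disjoint_small_groups_exact(self):
        # 20 arrangements, the observed split is one of the 2 extremes
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1)
        assert not r.significant

    def test_identical_groups_not_significant(self):
        r = mann_whitney([1, 2], [1, 2])
        assert r.p_value > 0.05 and not r.significant

    def test_matches_enumeration_oracle(self):
        rng = random.Random(9)
        for n1, n2 in [(2, 3), (3, 3), (4, 2), (5, 4), (6, 6)]:
            vals = rng.sample(range(1000), n1 + n2)
            x, y = vals[:n1], vals[n1:]
            r = mann_whitney(x, y)
            assert r.p_value == pytest.approx(exact_two_sided_p(x, y))

    def test_separated_distributions_detected(self):
        # effect size 2 SD at n=200 per group: significant for any seed tried
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.5, 0.1, 200)
            b = rng.normal(0.3, 0.1, 200)
            r = mann_whitney(a, b)
            assert r.method == "asymptotic" and r.significant

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            mann_whitney([], [1.0])


class TestCompareDistributions:
    def _calls(self):
        def c(klass, sub, vaf):
            return ClassifiedCall(CV, klass, fn_subtype=sub,
                                  params=QualityParams(vaf=vaf))
        return ([c("TP", "unchecked", v) for v in (0.4, 0.5, 0.6)] +
                [c("FP", "unchecked", v) for v in (0.1, 0.2, 0.3)] +
                [c("FN", "b-FN", v) for v in (0.35, 0.45)])

    def test_both_comparisons_reported(self):
        out = compare_distributions(self._calls(), "vaf")
        assert out["TP_vs_FP"]["u"] == 9.0
        assert out["TP_vs_FP"]["p_value"] == pytest.approx(0.1)
        assert not out["TP_vs_b-FN"]["skipped"]

    def test_all_null_parameter_skipped(self):
        out = compare_distributions(self._calls(), "stb")
        assert out["TP_vs_FP"]["skipped"]
        assert "reason" in out["TP_vs_FP"]

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigError):
            compare_distributions(self._calls(), "gc_content")


class TestRocCurve:
    def test_perfect_separation(self):
        assert roc_curve(recs([0.4, 0.5], [0.1, 0.2]), "vaf").auroc == 1.0

    def test_one_concordant_pair_of_four(self):
        assert roc_curve(recs([0.1, 0.3], [0.2, 0.4]), "vaf").auroc == 0.25

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(17)
        vals = rng.uniform(0, 1, 1000)
        labels = rng.integers(0, 2, 1000)
        records = [SeqPosRecord(CV, int(l), vaf=float(v))
                   for l, v in zip(labels, vals)]
        assert abs(roc_curve(records, "vaf").auroc - 0.5) < 0.05

    def test_trapezoid_equals_concordance_with_ties(self):
        # grid-valued scores force heavy ties; the identity is asserted
        # inside roc_curve itself, so surviving the call is the check
        rng = np.random.default_rng(3)
        for _ in range(300):
            n1, n0 = rng.integers(2, 30, 2)
            pos = rng.integers(0, 6, n1) / 5
            neg = rng.integers(0, 6, n0) / 5
            roc_curve(recs(pos, neg), "vaf")

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        for _ in range(50):
            n1, n0 = rng.integers(3, 40, 2)
            pos = rng.integers(0, 8, n1) / 7
            neg = rng.integers(0, 8, n0) / 7
            ours = roc_curve(recs(pos, neg), "vaf").auroc
            skl = roc_auc_score([1] * n1 + [0] * n0,
                                np.concatenate([pos, neg]))
            assert ours == pytest.approx(skl, abs=1e-12)

    def test_smaller_is_positive_direction(self):
        # low strand bias marks real calls
        roc = roc_curve(recs([0.5, 0.55], [0.9, 1.0], param="stb"), "stb")
        assert roc.direction == "smaller" and roc.auroc == 1.0

    def test_single_class_is_an_error(self):
        with pytest.raises(DataError):
            roc_curve(recs([0.4], []), "vaf")

    def test_null_values_excluded_and_counted(self):
        records = recs([0.4, 0.5], [0.1]) + [SeqPosRecord(CV, 0)]
        roc = roc_curve(records, "vaf")
        assert roc.n_excluded == 1 and (roc.n_pos, roc.n_neg) == (2, 1)


class TestOptimalCutpoint:
    def test_midpoint_between_classes(self):
        roc = roc_curve(recs([0.3, 0.4, 0.5], [0.05, 0.1]), "vaf")
        assert optimal_cutpoint(roc) == pytest.approx(0.2)
        assert roc.optimal_j == pytest.approx(1.0)

    def test_interleaved_values_fall_back_to_sentinel(self):
        # alternating classes: J=0 everywhere; the tie-break keeps every
        # positive, i.e. the -inf sentinel for greater-is-positive
        roc = roc_curve(recs([0.1, 0.3], [0.2, 0.4]), "vaf")
        t = optimal_cutpoint(roc)
        assert t == -math.inf and roc.optimal_j == pytest.approx(0.0)

    def test_smaller_direction_tie_break_keeps_positives(self):
        roc = roc_curve(recs([0.5, 0.9], [0.6, 1.0], param="stb"), "stb")
        t = optimal_cutpoint(roc)
        sens = [p[1] for p in roc.points if p[0] == t][0]
        assert sens == 1.0 or t == math.inf


class TestSimulateThresholds:
    def _calls(self):
        def c(klass, sub="unchecked", **kw):
            return ClassifiedCall(CV, klass, fn_subtype=sub,
                                  params=QualityParams(**kw))
        return [c("TP", vaf=0.4), c("TP", vaf=0.03), c("FP", vaf=0.02),
                c("FN", "b-FN", vaf=0.1)]

    def test_min_vaf_reshuffles_classes(self):
        m = simulate_thresholds(self._calls(), ThresholdSet(min_vaf=0.05), 100)
        assert (m.tp, m.fp, m.fn) == (2, 0, 1)
        assert m.recall == pytest.approx(2 / 3)
        assert m.precision == 1.0

    def test_empty_thresholds_recover_all_bfns(self):
        m = simulate_thresholds(self._calls(), ThresholdSet(), 100)
        assert (m.tp, m.fp, m.fn) == (3, 1, 0)
        assert m.recall == 1.0           # recall_max of the input
        assert m.fp == 1                 # FP count unchanged

    def test_impossible_threshold_fails_everything(self):
        m = simulate_thresholds(self._calls(), ThresholdSet(min_vaf=1.1), 100)
        assert m.tp == 0 and m.fp == 0

    def test_null_parameter_never_fails_a_call(self):
        calls = [ClassifiedCall(CV, "TP", params=QualityParams(vaf=None))]
        m = simulate_thresholds(calls, ThresholdSet(min_vaf=0.9), 10)
        assert m.tp == 1

    def test_failing_positions_return_to_tn(self):
        m = simulate_thresholds(self._calls(), ThresholdSet(min_vaf=0.05), 100)
        assert m.tn_bases == 102         # failing TP + failing FP, 1 bp each

    def test_unknown_threshold_parameter_rejected(self):
        with pytest.raises(ConfigError):
            ThresholdSet.from_dict({"min_gc": 0.5})

    def test_monotone_recall_under_tightening(self):
        rng = random.Random(5)
        calls = []
        for _ in range(120):
            r = rng.random()
            if r < 0.55:
                calls.append(ClassifiedCall(CV, "TP", params=QualityParams(
                    vaf=rng.uniform(0.05, 0.9))))
            elif r < 0.75:
                calls.append(ClassifiedCall(CV, "FP", params=QualityParams(
                    vaf=rng.uniform(0.0, 0.2))))
            elif r < 0.9:
                calls.append(ClassifiedCall(CV, "FN", "b-FN",
                                            params=QualityParams(
                                                vaf=rng.uniform(0.02, 0.4))))
            else:
                calls.append(ClassifiedCall(CV, "FN", "seq-FN"))
        n_truth = sum(1 for c in calls if c.klass in ("TP", "FN"))
        n_fp = sum(1 for c in calls if c.klass == "FP")
        prev = 1.1
        for t in np.linspace(0, 1, 21):
            m = simulate_thresholds(calls, ThresholdSet(min_vaf=float(t)), 1000)
            assert m.recall <= prev + 1e-12
            # truth variants are conserved; FPs can only be removed
            assert m.tp + m.fn == n_truth
            assert m.fp <= n_fp
            prev = m.recall


class TestComputeQd:
    def test_formula(self):
        assert compute_qd(100.0, 50.0) == pytest.approx(8.0)

    def test_zero_quality(self):
        assert compute_qd(0.0, 50.0) == 0.0

    def test_zero_or_missing_depth_is_null(self):
        assert compute_qd(10.0, 0) is None
        assert compute_qd(None, 50.0) is None
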