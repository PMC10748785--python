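"""Quality-parameter analysis: distribution tests, ROC/AUROC, cutpoints,
and what-if threshold simulation.

The set of sequencing-positive variants (SeqPos = TP + b-FN + FP) carries a
binary "callability" label: TPs and b-FNs are positively callable (1), FPs
should be called negative (0).  Each quality parameter (VAF, DP, STB, QUAL,
QD) is scored as a classifier of that label: a ROC curve with thresholds at
midpoints between consecutive distinct observed values, AUROC by trapezoid
(which equals the pairwise-concordance statistic U/(n1*n0) with ties counted
half — checked internally), and an optimal cutpoint maximizing Youden's
J = sensitivity + specificity - 1.

Distribution differences between classes (TP vs FP, TP vs b-FN) are tested
with the two-sided Mann-Whitney U test at alpha = 0.05: exact enumeration
for small tie-free groups (both n <= 8), normal approximation with tie and
continuity corrections otherwise.

``simulate_thresholds`` re-evaluates every TP/FP/b-FN against a candidate
threshold set and recomputes the metrics: failing TPs become FNs, failing
FPs are removed (their positions return to true-negative bases), passing
b-FNs are recovered as TPs, and sequencing FNs always stay FN.  A null
parameter passes any constraint — a threshold on a metric a caller never
reports must not annihilate its callset.  With an empty threshold set every
b-FN is recovered, so the simulated recall equals recall_max.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .comparator import ClassifiedCall, MetricSet
from .errors import ConfigError, DataError
from .harmonizer import CanonicalVariant

ALPHA = 0.05

#: ROC direction per parameter: high VAF/DP/QUAL/QD favor a real call,
#: high strand bias (STB -> 1) suggests an artifact.
DEFAULT_DIRECTIONS = {"vaf": "greater", "dp": "greater", "stb": "smaller",
                      "qual": "greater", "qd": "greater"}

PARAMETERS = tuple(DEFAULT_DIRECTIONS)


@dataclass
class SeqPosRecord:
    """One sequencing-positive variant with its callability label."""

    variant: CanonicalVariant
    label: int                    # 1 = TP or b-FN, 0 = FP
    vaf: float | None = None
    dp: float | None = None
    stb: float | None = None
    qual: float | None = None
    qd: float | None = None

    def value(self, parameter: str) -> float | None:
        if parameter not in PARAMETERS:
            raise ConfigError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)


@dataclass
class RocResult:
    """ROC curve for one parameter on the SeqPos set."""

    parameter: str
    direction: str                          # greater- or smaller-is-positive
    points: list[tuple[float, float, float]]  # (threshold, sens, spec)
    auroc: float
    n_pos: int
    n_neg: int
    n_excluded: int = 0                     # records with null parameter
    optimal_cutpoint: float | None = None
    optimal_j: float | None = None


@dataclass
class ThresholdSet:
    """Candidate caller thresholds; absent (None) means no constraint."""

    min_vaf: float | None = None
    min_dp: float | None = None
    max_stb: float | None = None
    min_qual: float | None = None
    min_qd: float | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        allowed = {f.name for f in fields(cls)}
        bad = set(d) - allowed
        if bad:
            raise ConfigError(f"unknown threshold parameter(s): {sorted(bad)}")
        return cls(**d)

    def passes(self, p) -> bool:
        """True iff params satisfy every set constraint; nulls always pass."""
        if self.min_vaf is not None and p.vaf is not None and p.vaf < self.min_vaf:
            return False
        if self.min_dp is not None and p.dp is not None and p.dp < self.min_dp:
            return False
        if self.max_stb is not None and p.stb is not None and p.stb > self.max_stb:
            return False
        if self.min_qual is not None and p.qual is not None and p.qual < self.min_qual:
            return False
        if self.min_qd is not None and p.qd is not None and p.qd < self.min_qd:
            return False
        return True


def compute_qd(qual: float | None, dp: float | None) -> float | None:
    """Quality by depth, QD = 4 * QUAL / DP (null when DP is 0 or missing).

    Kept as a single swappable function: the scaling follows the TVC-style
    quality-by-depth convention this suite adapts for callers that do not
    report QD themselves.
    """
    if qual is None or dp is None or dp == 0:
        return None
    return 4.0 * qual / dp


# ---------------------------------------------------------------------------
# distribution tests


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    significant: bool
    n1: int
    n2: int
    method: str


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have <= 8 observations and the pooled
    data is tie-free; otherwise the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups need at least one observation")
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(res.pvalue)
    return MannWhitneyResult(u=float(res.statistic), p_value=p,
                             significant=p < ALPHA, n1=len(x), n2=len(y),
                             method=method)


def compare_distributions(calls: Iterable[ClassifiedCall],
                          parameter: str) -> dict:
    """Mann-Whitney tests of one parameter: TP vs FP and TP vs b-FN.

    A comparison with an empty (all-null) group is skipped and reported as
    not computable.
    """
    if parameter not in PARAMETERS:
        raise ConfigError(f"unknown parameter {parameter!r}")
    groups: dict[str, list[float]] = {"TP": [], "FP": [], "b-FN": []}
    for c in calls:
        lab = c.label
        if lab in groups:
            v = getattr(c.params, parameter)
            if v is not None:
                groups[lab].append(float(v))
    out: dict[str, dict] = {"parameter": parameter}
    for other in ("FP", "b-FN"):
        key = f"TP_vs_{other}"
        if not groups["TP"] or not groups[other]:
            out[key] = {"skipped": True,
                        "reason": f"no non-null {parameter} values in "
                                  f"{'TP' if not groups['TP'] else other}"}
            continue
        r = mann_whitney(groups["TP"], groups[other])
        out[key] = {"skipped": False, "u": r.u, "p_value": r.p_value,
                    "significant": r.significant, "n_tp": r.n1,
                    "n_other": r.n2, "method": r.method}
    return out


# ---------------------------------------------------------------------------
# ROC / cutpoints


def _concordance(pos: np.ndarray, neg: np.ndarray) -> float:
    """Pairwise concordance P(pos > neg) with ties counted half (exact)."""
    all_v = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_v)
    r1 = ranks[:len(pos)].sum()
    n1, n0 = len(pos), len(neg)
    u = r1 - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def roc_curve(records: Sequence[SeqPosRecord], parameter: str,
              direction: str | None = None) -> RocResult:
    """ROC of one quality parameter as a predictor of callability.

    Records with a null parameter are excluded (and counted); thresholds are
    the midpoints between consecutive distinct observed values plus -inf and
    +inf sentinels, in the parameter's original units.  For
    smaller-is-positive parameters (STB) a record is predicted positive when
    its value is <= the threshold.
    """
    if direction is None:
        direction = DEFAULT_DIRECTIONS.get(parameter, "greater")
    if direction not in ("greater", "smaller"):
        raise ConfigError(f"bad direction {direction!r}")
    pos, neg, n_excl = [], [], 0
    for r in records:
        v = r.value(parameter)
        if v is None:
            n_excl += 1
            continue
        (pos if r.label == 1 else neg).append(float(v))
    if not pos or not neg:
        raise DataError(
            f"ROC undefined for {parameter!r}: needs both labels with "
            f"non-null values (n_pos={len(pos)}, n_neg={len(neg)})")
    pos_a, neg_a = np.array(pos), np.array(neg)
    sign = 1.0 if direction == "greater" else -1.0
    sp, sn = sign * pos_a, sign * neg_a
    distinct = np.unique(np.concatenate([sp, sn]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else \
        np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    points = []
    for t in thresholds:
        sens = float((sp >= t).mean())
        spec = float((sn < t).mean())
        points.append((float(sign * t), sens, spec))
    points.sort(key=lambda p: p[0])
    auroc = _concordance(sp, sn)
    # internal cross-check: trapezoid over the (1-spec, sens) polyline must
    # agree with the concordance statistic
    fpr = np.array([1 - p[2] for p in points])
    tpr = np.array([p[1] for p in points])
    order = np.lexsort((tpr, fpr))   # staircase: ties in FPR rise in TPR
    trap = float(np.trapezoid(tpr[order], fpr[order]))
    if not math.isclose(trap, auroc, rel_tol=0, abs_tol=1e-9):
        raise AssertionError(
            f"AUROC identity violated: trapezoid {trap} vs concordance {auroc}")
    return RocResult(parameter=parameter, direction=direction, points=points,
                     auroc=float(auroc), n_pos=len(pos), n_neg=len(neg),
                     n_excluded=n_excl)


def optimal_cutpoint(roc: RocResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the threshold retaining more positives: the
    lowest threshold for greater-is-positive parameters, the highest for
    smaller-is-positive.  The result is recorded on the RocResult as well.
    """
    best_t, best_j = None, -np.inf
    pts = roc.points if roc.direction == "greater" else list(reversed(roc.points))
    # iterate from the positive-retaining end so the first maximum wins
    for t, sens, spec in pts:
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    roc.optimal_cutpoint = float(best_t)
    roc.optimal_j = float(best_j)
    return float(best_t)


# ---------------------------------------------------------------------------
# threshold simulation


def _span(v: CanonicalVariant) -> int:
    return 1 if v.vclass == "INS" else v.end - v.start + 1


def simulate_thresholds(calls: Iterable[ClassifiedCall],
                        thresholds: ThresholdSet,
                        tn_bases: int) -> MetricSet:
    """Recompute the metrics as if the caller had applied ``thresholds``.

    TPs and FPs are judged on their caller parameters, b-FNs on their pileup
    parameters; sequencing FNs stay FN.  Positions of calls that are no
    longer positive (failing TPs and FPs) return to the true-negative base
    count, mirroring how TN bases are defined on the original callset.
    """
    if not isinstance(thresholds, ThresholdSet):
        thresholds = ThresholdSet.from_dict(dict(thresholds))
    tp = fp = fn = bfn_remaining = 0
    tn = tn_bases
    for c in calls:
        if c.klass == "TP":
            if thresholds.passes(c.params):
                tp += 1
            else:
                fn += 1
                bfn_remaining += 1   # was called, so reads support it
                tn += _span(c.variant)
        elif c.klass == "FP":
            if thresholds.passes(c.params):
                fp += 1
            else:
                tn += _span(c.variant)
        elif c.klass == "FN":
            if c.fn_subtype == "b-FN" and thresholds.passes(c.params):
                tp += 1
            else:
                fn += 1
                if c.fn_subtype == "b-FN":
                    bfn_remaining += 1   # still has read support
        else:
            raise ConfigError(f"unknown class {c.klass!r}")
    return MetricSet.from_counts(tp=tp, fp=fp, fn=fn, bfn=bfn_remaining,
                                 tn_bases=tn, rechecked=True)
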