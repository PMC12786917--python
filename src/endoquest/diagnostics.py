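"""Diagnostic-accuracy statistics for 2x2 tables and group comparisons.

Conventions (fixed throughout the package):

* A :class:`ContingencyTable` is oriented rows = condition (control /
  case), columns = test result (negative / positive): cells
  ``(tn, fp, fn, tp)``.
* Fisher's exact two-sided p uses the point-probability rule — the sum
  of probabilities of all tables (at fixed margins) whose hypergeometric
  point probability does not exceed the observed one, with a relative
  guard of 1e-7 against floating-point ties.  This matches the common
  statistical software definition.
* Proportion confidence intervals are Wilson score intervals; ratio
  intervals (odds ratio, relative risk, likelihood ratios) use the log
  (Woolf-type) normal approximation.
* When any cell is zero, ratio measures are computed on
  Haldane-Anscombe corrected cells (+0.5 everywhere) and the summary is
  flagged as corrected; proportions are never corrected.
* The relative risk is the risk of disease given a positive versus a
  negative test, i.e. PPV / (1 - NPV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .model import ITEM_IDS, Label

__all__ = [
    "ContingencyTable", "Metric", "DiagnosticSummary", "TestResult",
    "RocResult", "Alternative", "fisher_exact", "diagnostic_summary",
    "mann_whitney", "roc_cutoff", "contingency_from_indicator",
    "IndicatorContingency",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts, rows = condition NO_EMS/EMS, columns = test neg/pos."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=np.int64)

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(tn=self.tn, fp=self.fn, fn=self.fp, tp=self.tp)


@dataclass(frozen=True)
class Metric:
    estimate: float
    ci_low: float
    ci_high: float

    def __iter__(self):
        return iter((self.estimate, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0,1]")


class Alternative(str, Enum):
    TWO_SIDED = "TWO_SIDED"
    LESS = "LESS"
    GREATER = "GREATER"


def fisher_exact(table: ContingencyTable,
                 alternative: Alternative = Alternative.TWO_SIDED) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The statistic is the sample odds ratio (NaN when undefined).  With a
    zero margin every table consistent with the margins is the observed
    one, so p = 1 (noted in ``method``).
    """
    a, b, c, d = table.tn, table.fp, table.fn, table.tp
    n = table.total
    row1, col1 = a + b, a + c
    odds = (a * d) / (b * c) if b * c > 0 else math.nan

    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return TestResult(odds, 1.0, "fisher exact (degenerate margin, p := 1)")

    # X = top-left cell ~ Hypergeometric(n, row1, col1)
    dist = stats.hypergeom(n, row1, col1)
    if alternative is Alternative.LESS:
        p = float(dist.cdf(a))
        method = "fisher exact, one-sided (less)"
    elif alternative is Alternative.GREATER:
        p = float(dist.sf(a - 1))
        method = "fisher exact, one-sided (greater)"
    else:
        support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
        pmf = dist.pmf(support)
        p_obs = dist.pmf(a)
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
        method = "fisher exact, two-sided (point probability)"
    return TestResult(odds, min(1.0, p), method)


_Z95 = stats.norm.ppf(0.975)


def _wilson(count: int, nobs: int) -> Metric:
    est = count / nobs
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return Metric(est, float(lo), float(hi))


def _log_ci(estimate: float, se_log: float) -> tuple[float, float]:
    if not math.isfinite(estimate) or estimate <= 0:
        return (math.nan, math.nan)
    return (estimate * math.exp(-_Z95 * se_log),
            estimate * math.exp(_Z95 * se_log))


@dataclass(frozen=True)
class DiagnosticSummary:
    """Full accuracy panel with 95% CIs for a 2x2 table.

    ``continuity_corrected`` flags that ratio measures were computed on
    Haldane-Anscombe corrected cells because some cell was zero.
    """

    table: ContingencyTable
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    accuracy: Metric
    odds_ratio: Metric          # diagnostic odds ratio
    relative_risk: Metric       # PPV / (1 - NPV)
    lr_pos: Metric
    lr_neg: Metric
    continuity_corrected: bool = False


def diagnostic_summary(table: ContingencyTable) -> DiagnosticSummary:
    """Compute the accuracy-metric panel for a 2x2 table."""
    if table.total == 0:
        raise ValueError("empty table")
    tn, fp, fn, tp = table.tn, table.fp, table.fn, table.tp

    sens = _wilson(tp, tp + fn) if tp + fn else Metric(math.nan, math.nan, math.nan)
    spec = _wilson(tn, tn + fp) if tn + fp else Metric(math.nan, math.nan, math.nan)
    ppv = _wilson(tp, tp + fp) if tp + fp else Metric(math.nan, math.nan, math.nan)
    npv = _wilson(tn, tn + fn) if tn + fn else Metric(math.nan, math.nan, math.nan)
    acc = _wilson(tp + tn, table.total)

    corrected = 0 in (tn, fp, fn, tp)
    if corrected:
        tn_, fp_, fn_, tp_ = (tn + 0.5, fp + 0.5, fn + 0.5, tp + 0.5)
    else:
        tn_, fp_, fn_, tp_ = float(tn), float(fp), float(fn), float(tp)

    sens_ = tp_ / (tp_ + fn_)
    spec_ = tn_ / (tn_ + fp_)
    lr_pos_est = sens_ / (1 - spec_)
    lr_neg_est = (1 - sens_) / spec_
    dor_est = (tp_ * tn_) / (fp_ * fn_)
    rr_est = (tp_ / (tp_ + fp_)) / (fn_ / (fn_ + tn_))

    se_or = math.sqrt(1 / tp_ + 1 / fp_ + 1 / fn_ + 1 / tn_)
    se_rr = math.sqrt(1 / tp_ - 1 / (tp_ + fp_) + 1 / fn_ - 1 / (fn_ + tn_))
    se_lrp = math.sqrt(1 / tp_ - 1 / (tp_ + fn_) + 1 / fp_ - 1 / (fp_ + tn_))
    se_lrn = math.sqrt(1 / fn_ - 1 / (tp_ + fn_) + 1 / tn_ - 1 / (fp_ + tn_))

    return DiagnosticSummary(
        table=table,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, accuracy=acc,
        odds_ratio=Metric(dor_est, *_log_ci(dor_est, se_or)),
        relative_risk=Metric(rr_est, *_log_ci(rr_est, se_rr)),
        lr_pos=Metric(lr_pos_est, *_log_ci(lr_pos_est, se_lrp)),
        lr_neg=Metric(lr_neg_est, *_log_ci(lr_neg_est, se_lrn)),
        continuity_corrected=corrected,
    )


def mann_whitney(group_a: Sequence[float],
                 group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have n <= 8 and no ties occur;
    otherwise the tie-corrected normal approximation.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = a.size <= 8 and b.size <= 8 and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    method = ("mann-whitney, exact" if exact
              else "mann-whitney, tie-corrected normal approximation")
    return TestResult(float(res.statistic), min(1.0, float(res.pvalue)), method)


@dataclass(frozen=True)
class RocResult:
    auc: Metric              # Hanley-McNeil 95% CI
    best_cutoff: float       # midpoint between adjacent observed values
    youden_j: float
    sensitivity_at_best: float
    specificity_at_best: float


def roc_cutoff(scores: Sequence[float], labels: Sequence[Label]) -> RocResult:
    """ROC AUC (rank formula) and the Youden-optimal cut-off.

    Higher scores are taken to indicate disease.  The cut-off is
    reported as the midpoint between adjacent distinct observed score
    values ("score > cutoff" is positive); ties in Youden's J are broken
    toward higher specificity (the larger cut-off).
    """
    s = np.asarray(scores, float)
    y = np.asarray([1 if l is Label.EMS or l == "EMS" else 0 for l in labels])
    if s.size != y.size:
        raise ValueError("scores and labels differ in length")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present")

    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    # Hanley & McNeil (1982) standard error
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    auc_m = Metric(float(auc), max(0.0, auc - _Z95 * se),
                   min(1.0, auc + _Z95 * se))

    uniq = np.unique(s)
    cutoffs = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else uniq
    best = None
    for c in cutoffs:  # ascending: later (larger) cutoffs win ties -> higher spec
        pos = s > c
        sens = (pos & (y == 1)).sum() / n1
        spec = (~pos & (y == 0)).sum() / n0
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or abs(j - best[0]) <= 1e-12:
            best = (j, float(c), float(sens), float(spec))
    j, c, sens, spec = best
    return RocResult(auc=auc_m, best_cutoff=c, youden_j=j,
                     sensitivity_at_best=sens, specificity_at_best=spec)


@dataclass(frozen=True)
class IndicatorContingency:
    """Counts of an indicator per group, with missing-data counts."""

    table: ContingencyTable
    missing_ems: int
    missing_no_ems: int


def contingency_from_indicator(cohort, indicator) -> IndicatorContingency:
    """Build the per-item 2x2 table of an indicator over a labeled cohort.

    ``indicator`` may be an SP id (int), a codebook item id (str, true
    means positive) or a :class:`~endoquest.tree.Predicate`.  A missing
    answer counts as indicator-false (the scoring convention) and is
    also reported in the missing-data counts.
    """
    from .model import get_item_value
    from .scoring import DEFAULT_SP_REGISTRY, score_record
    from .tree import Predicate

    if not cohort:
        raise ValueError("empty cohort")

    if isinstance(indicator, int):
        rules = {r.sp_id: r for r in DEFAULT_SP_REGISTRY}
        if indicator not in rules:
            raise KeyError(f"unknown sp_id: {indicator}")
        rule = rules[indicator]

        def value(rec):
            scores = score_record(rec)
            return rule.evaluate(rec, scores.sum_vas), _rule_missing(rule, rec)
    elif isinstance(indicator, str):
        if indicator not in ITEM_IDS:
            raise KeyError(f"unknown item_id: {indicator!r}")

        def value(rec):
            v = get_item_value(rec, indicator)
            return v is True, v is None
    elif isinstance(indicator, Predicate):
        def value(rec):
            scores = score_record(rec)
            missing = (indicator.source.value == "ITEM"
                       and get_item_value(rec, indicator.item_id) is None)
            return indicator.evaluate(rec, scores), missing
    else:
        raise TypeError("indicator must be an sp_id, item_id or Predicate")

    tn = fp = fn = tp = 0
    missing_ems = missing_no_ems = 0
    for rec in cohort:
        if rec.label is None:
            raise ValueError(f"patient {rec.patient_id}: missing label")
        v, miss = value(rec)
        if rec.label is Label.EMS:
            tp += v
            fn += not v
            missing_ems += miss
        else:
            fp += v
            tn += not v
            missing_no_ems += miss
    return IndicatorContingency(
        ContingencyTable(tn=tn, fp=fp, fn=fn, tp=tp),
        missing_ems=missing_ems, missing_no_ems=missing_no_ems)


def _rule_missing(rule, rec) -> bool:
    from .model import get_item_value
    if rule.kind in ("item_true", "nrs_gt"):
        return get_item_value(rec, rule.params[0]) is None
    if rule.kind == "conjunction":
        return any(get_item_value(rec, it) is None for it in rule.params)
    if rule.kind == "pattern_eq":
        return rec.course_pattern is None
    return False
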