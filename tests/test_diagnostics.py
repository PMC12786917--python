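"""Oracle-backed tests for the 2x2 and group-comparison statistics."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from endoquest import (
    Alternative, ContingencyTable, Label, PatientRecord,
    contingency_from_indicator, diagnostic_summary, fisher_exact,
    mann_whitney, roc_cutoff,
)


def fisher_two_sided_bruteforce(tn, fp, fn, tp):
    """Exact enumeration over the hypergeometric support (independent oracle)."""
    n = tn + fp + fn + tp
    r1, c1 = tn + fp, tn + fn

    def prob(a):
        b, c = r1 - a, c1 - a
        d = n - a - b - c
        if min(b, c, d) < 0:
            return 0.0
        return comb(r1, a) * comb(n - r1, c) / comb(n, c1)

    p_obs = prob(tn)
    return sum(p for a in range(0, min(r1, c1) + 1)
               if (p := prob(a)) <= p_obs * (1 + 1e-7))


class TestFisher:
    @given(tn=st.integers(0, 20), fp=st.integers(0, 20),
           fn=st.integers(0, 20), tp=st.integers(0, 20))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_two_sided_p_matches_enumeration_property(self, tn, fp, fn, tp):
        assume(tn + fp + fn + tp > 0)
        t = ContingencyTable(tn, fp, fn, tp)
        p = fisher_exact(t).p_value
        if (tn + fp) in (0, t.total) or (tn + fn) in (0, t.total):
            assert p == 1.0
        else:
            assert p == pytest.approx(
                fisher_two_sided_bruteforce(tn, fp, fn, tp),
                rel=1e-9, abs=1e-12)

    def test_symmetric_table_gives_p_one(self):
        res = fisher_exact(ContingencyTable(5, 5, 5, 5))
        assert res.p_value == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        res = fisher_exact(ContingencyTable(2, 3, 4, 1))
        assert res.p_value == pytest.approx(
            fisher_two_sided_bruteforce(2, 3, 4, 1), rel=1e-12)

    def test_dysuria_table_is_highly_significant(self):
        res = fisher_exact(ContingencyTable(108, 1, 77, 42))
        assert res.p_value < 0.001

    def test_matches_enumeration_and_scipy_on_all_small_tables(self):
        """Every table with total <= 40: enumeration oracle + scipy agree."""
        rng = np.random.default_rng(11)
        checked = 0
        for total in (8, 12, 20, 40):
            for _ in range(60):
                cells = rng.multinomial(total, [0.25] * 4)
                t = ContingencyTable(*map(int, cells))
                p = fisher_exact(t).p_value
                assert p == pytest.approx(
                    fisher_two_sided_bruteforce(*cells), rel=1e-9, abs=1e-12)
                p_sp = sps.fisher_exact(t.as_array())[1]
                assert p == pytest.approx(p_sp, rel=1e-6, abs=1e-12)
                checked += 1
        assert checked == 240

    def test_one_sided_alternatives_match_scipy(self):
        t = ContingencyTable(8, 2, 3, 9)
        for alt, scipy_alt in ((Alternative.LESS, "less"),
                               (Alternative.GREATER, "greater")):
            assert fisher_exact(t, alt).p_value == pytest.approx(
                sps.fisher_exact(t.as_array(), scipy_alt)[1], rel=1e-9)

    def test_invariance_under_transposition_and_double_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            cells = rng.integers(0, 30, 4)
            t = ContingencyTable(*map(int, cells))
            p = fisher_exact(t).p_value
            assert fisher_exact(t.transposed()).p_value == pytest.approx(p)
            # simultaneous row + column swap
            swapped = ContingencyTable(tn=t.tp, fp=t.fn, fn=t.fp, tp=t.tn)
            assert fisher_exact(swapped).p_value == pytest.approx(p)

    def test_zero_margin_gives_p_one(self):
        res = fisher_exact(ContingencyTable(0, 0, 3, 5))
        assert res.p_value == 1.0 and "degenerate" in res.method


class TestDiagnosticSummary:
    def test_zero_cell_haldane_correction(self):
        s = diagnostic_summary(ContingencyTable(10, 0, 0, 10))
        assert s.continuity_corrected
        assert s.odds_ratio.estimate == pytest.approx((10.5 * 10.5) / 0.25)

    def test_identities_on_random_tables(self):
        """DOR = (tp*tn)/(fp*fn), RR = PPV/(1-NPV), DOR = LR+/LR-."""
        rng = np.random.default_rng(9)
        for _ in range(1000):
            tn, fp, fn, tp = (int(v) for v in rng.integers(1, 200, 4))
            s = diagnostic_summary(ContingencyTable(tn, fp, fn, tp))
            assert s.odds_ratio.estimate == pytest.approx(tp * tn / (fp * fn))
            assert s.relative_risk.estimate == pytest.approx(
                s.ppv.estimate / (1 - s.npv.estimate))
            assert s.accuracy.estimate == pytest.approx(
                (tp + tn) / (tp + tn + fp + fn))
            assert s.odds_ratio.estimate == pytest.approx(
                s.lr_pos.estimate / s.lr_neg.estimate, rel=1e-9)

    def test_proportion_cis_contain_their_estimates(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            tn, fp, fn, tp = (int(v) for v in rng.integers(1, 50, 4))
            s = diagnostic_summary(ContingencyTable(tn, fp, fn, tp))
            for m in (s.sensitivity, s.specificity, s.ppv, s.npv, s.accuracy):
                assert m.ci_low <= m.estimate <= m.ci_high
                assert 0 <= m.estimate <= 1


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0, abs=0.01)

    def test_small_sample_matches_permutation_enumeration(self):
        # all C(4,2)=6 rank assignments; observed is the most extreme
        res = mann_whitney([1, 2], [3, 4])
        assert "exact" in res.method
        assert res.p_value == pytest.approx(2 / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 60)
        b = rng.normal(2, 1, 60)
        assert mann_whitney(b, a).p_value < 1e-6


class TestRoc:
    def test_perfect_separation(self):
        res = roc_cutoff([1, 2, 8, 9],
                         [Label.NO_EMS, Label.NO_EMS, Label.EMS, Label.EMS])
        assert res.auc.estimate == 1.0
        assert res.best_cutoff == 5.0
        assert res.youden_j == pytest.approx(1.0)

    def test_auc_matches_pair_counting(self):
        """Rank-formula AUC equals O(n^2) concordant-pair counting."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(8, 50))
            scores = rng.integers(0, 12, n).astype(float)
            labels = [Label.EMS if v else Label.NO_EMS
                      for v in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                continue
            res = roc_cutoff(scores, labels)
            pos = scores[[l is Label.EMS for l in labels]]
            neg = scores[[l is Label.NO_EMS for l in labels]]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert res.auc.estimate == pytest.approx(
                conc / (len(pos) * len(neg)))

    def test_cutoff_is_midpoint_of_observed_values(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(0, 20, 40).astype(float)
        labels = [Label.EMS if s + rng.normal() > 10 else Label.NO_EMS
                  for s in scores]
        if len(set(labels)) == 2:
            res = roc_cutoff(scores, labels)
            uniq = np.unique(scores)
            mids = (uniq[:-1] + uniq[1:]) / 2
            assert res.best_cutoff in mids

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_cutoff([1, 2], [Label.EMS, Label.EMS])

    def test_ties_in_j_resolve_toward_higher_specificity(self):
        # both cutoffs 1.5 and 2.5 give J = 0.5; the larger must win
        res = roc_cutoff([1, 2, 2, 3],
                         [Label.NO_EMS, Label.NO_EMS, Label.EMS, Label.EMS])
        assert res.best_cutoff == 2.5


class TestWilsonCoverage:
    def test_wilson_coverage_quick(self):
        """>= 93% empirical coverage at n=100 (smaller sweep than the
        acceptance run)."""
        from statsmodels.stats.proportion import proportion_confint
        rng = np.random.default_rng(12)
        for p in (0.1, 0.5, 0.9):
            counts = rng.binomial(100, p, size=500)
            lo, hi = proportion_confint(counts, 100, method="wilson")
            assert np.mean((lo <= p) & (p <= hi)) >= 0.93


class TestContingencyFromIndicator:
    def test_hand_built_counts(self):
        cohort = []
        for i in range(3):
            cohort.append(PatientRecord(patient_id=f"E{i}", label=Label.EMS,
                                        dysuria=True))
        for i in range(2):
            cohort.append(PatientRecord(patient_id=f"N{i}", label=Label.NO_EMS,
                                        dysuria=False))
        ic = contingency_from_indicator(cohort, "dysuria")
        t = ic.table
        assert (t.tn, t.fp, t.fn, t.tp) == (2, 0, 0, 3)
        assert ic.missing_ems == 0 and ic.missing_no_ems == 0

    def test_missing_counts_false_and_reported(self):
        cohort = [PatientRecord(patient_id="E", label=Label.EMS),
                  PatientRecord(patient_id="N", label=Label.NO_EMS,
                                dysuria=True)]
        ic = contingency_from_indicator(cohort, "dysuria")
        assert ic.table.fn == 1 and ic.missing_ems == 1
        ic6 = contingency_from_indicator(cohort, 6)  # SP 6 = dysuria
        assert ic6.table.fn == 1 and ic6.missing_ems == 1

    def test_unknown_indicator_rejected(self):
        cohort = [PatientRecord(patient_id="E", label=Label.EMS)]
        with pytest.raises(KeyError):
            contingency_from_indicator(cohort, "dysurria")
        with pytest.raises(KeyError):
            contingency_from_indicator(cohort, 99)
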