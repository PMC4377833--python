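"""Confusion statistics, exact binomial CIs and cohort reclassification."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

from msiamp import (OverallStatus, clopper_pearson, cohort_summary,
                    locus_vs_locus, locus_vs_overall, series1_matrix,
                    series2_matrix)
from msiamp.evaluate import (CallMatrix, ConfusionSummary,
                             NotComparableError, evaluation_report,
                             round_half_up)


@pytest.fixture(scope="module")
def series1():
    return series1_matrix()


@pytest.fixture(scope="module")
def series2():
    return series2_matrix()


def _cp_oracle(k, n, confidence=0.95):
    """Independent Clopper-Pearson oracle: root-find the binomial tails.

    lower solves P(X >= k | p) = alpha/2; upper solves P(X <= k | p) =
    alpha/2 — no beta quantiles involved.
    """
    alpha = 1 - confidence
    lo = 0.0 if k == 0 else brentq(
        lambda p: binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
        xtol=1e-12)
    hi = 1.0 if k == n else brentq(
        lambda p: binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
        xtol=1e-12)
    return 100 * lo, 100 * hi


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (20, 20, 83.2, 100.0),
        (30, 30, 88.4, 100.0),
        (27, 27, 87.2, 100.0),
        (13, 17, 50.1, 93.2),
        (6, 9, 29.9, 92.5),
        (33, 35, 80.8, 99.3),
        (10, 17, 32.9, 81.6),
        (26, 27, 81.0, 99.9),
        (8, 17, 23.0, 72.2),
        (3, 3, 29.2, 100.0),
    ])
    def test_reproduces_published_interval_bounds(self, k, n, lo, hi):
        got = clopper_pearson(k, n)
        assert round_half_up(got[0]) == lo
        assert round_half_up(got[1]) == hi

    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = clopper_pearson(0, 12)
        assert lo == 0.0 and 0 < hi < 100

    def test_agrees_with_binomial_tail_oracle(self):
        """Beta-quantile form equals direct tail root-finding to 4
        decimals for every (k, n) with n <= 30."""
        for n in range(1, 31):
            for k in range(n + 1):
                got = clopper_pearson(k, n)
                want = _cp_oracle(k, n)
                assert got == pytest.approx(want, abs=1e-4)

    def test_wider_confidence_widens_interval(self):
        lo95, hi95 = clopper_pearson(13, 17, 0.95)
        lo99, hi99 = clopper_pearson(13, 17, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson(k, n)
            assert lo <= 100 * k / n <= hi

    def test_zero_trials_errors(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)


class TestLocusVsLocus:
    def test_dinucleotide_marker_confusion(self, series1):
        cs = locus_vs_locus(series1, "D5S346")
        assert (cs.tp, cs.fp, cs.tn, cs.fn) == (6, 2, 33, 3)
        assert round_half_up(cs.sensitivity) == 66.7
        assert round_half_up(cs.specificity) == 94.3
        assert cs.n == len(series1)

    @pytest.mark.parametrize("locus", ["BAT25", "BAT26"])
    def test_mononucleotide_markers_fully_concordant(self, series1, locus):
        cs = locus_vs_locus(series1, locus)
        assert cs.sensitivity == 100.0 and cs.specificity == 100.0
        assert cs.fp == cs.fn == 0

    def test_locus_without_pcr_calls_not_comparable(self, series1):
        with pytest.raises(NotComparableError):
            locus_vs_locus(series1, "BAT34c4")
        with pytest.raises(NotComparableError):
            locus_vs_locus(series1, "D18S55")

    def test_all_stable_matrix_sensitivity_not_applicable(self):
        m = CallMatrix(name="toy", cases=("1", "2"), loci=("L",),
                       ngs={"L": (False, False)},
                       pcr={"L": (False, False)},
                       ngs_status=(OverallStatus.MSS,) * 2,
                       pcr_status=(OverallStatus.MSS,) * 2)
        cs = locus_vs_locus(m, "L")
        assert cs.tp == cs.fn == 0
        assert cs.sensitivity is None and cs.sens_ci is None
        assert cs.specificity == 100.0


class TestLocusVsOverall:
    @pytest.mark.parametrize("locus", ["BAT25", "BAT26"])
    def test_quasimonomorphic_markers_pooled(self, series1, series2, locus):
        cs = locus_vs_overall([series1, series2], locus)
        assert cs.sensitivity == 100.0 and cs.specificity == 100.0
        assert cs.tp + cs.fn == 20 and cs.tn + cs.fp == 30
        assert round_half_up(cs.sens_ci[0]) == 83.2
        assert round_half_up(cs.spec_ci[0]) == 88.4

    @pytest.mark.parametrize("locus,sens,spec", [
        ("BAT34c4", 76.5, 100.0),
        ("D18S55", 58.8, 96.3),
        ("D5S346", 47.1, 100.0),
    ])
    def test_remaining_markers(self, series1, locus, sens, spec):
        cs = locus_vs_overall(series1, locus)
        assert round_half_up(cs.sensitivity) == sens
        assert round_half_up(cs.specificity) == spec

    def test_interval_bounds_for_weak_markers(self, series1):
        cs = locus_vs_overall(series1, "D18S55")
        assert [round_half_up(x) for x in cs.sens_ci] == [32.9, 81.6]
        assert [round_half_up(x) for x in cs.spec_ci] == [81.0, 99.9]

    def test_single_row_matrix(self):
        m = CallMatrix(name="toy", cases=("1",), loci=("L",),
                       ngs={"L": (True,)}, pcr={"L": (True,)},
                       ngs_status=(OverallStatus.MSI_H,),
                       pcr_status=(OverallStatus.MSI_H,))
        cs = locus_vs_overall(m, "L")
        assert cs.sensitivity == 100.0 and cs.specificity is None

    def test_counts_conserved(self, series1, series2):
        for matrices, locus in [([series1], "D18S55"),
                                ([series1, series2], "BAT25")]:
            cs = locus_vs_overall(matrices, locus)
            assert cs.n == sum(len(m) for m in matrices)


class TestCohortSummary:
    def test_series1_reclassification(self, series1):
        summary = cohort_summary(series1)
        assert summary.counts == {OverallStatus.MSS: 26,
                                  OverallStatus.MSI_L: 1,
                                  OverallStatus.MSI_H: 17}
        assert summary.discrepancies == ()
        assert summary.recomputed == series1.ngs_status

    def test_series2_reclassification(self, series2):
        summary = cohort_summary(series2)
        assert summary.counts[OverallStatus.MSI_H] == 3
        assert summary.counts[OverallStatus.MSS] == 3
        assert summary.discrepancies == ()

    def test_empty_matrix(self):
        m = CallMatrix(name="empty", cases=(), loci=("L",),
                       ngs={"L": ()}, pcr={"L": ()},
                       ngs_status=(), pcr_status=())
        summary = cohort_summary(m)
        assert all(n == 0 for n in summary.counts.values())


def test_evaluation_report_layout(series1, series2):
    report = evaluation_report({"series1": series1, "series2": series2})
    pooled = report[report.comparison == "pooled:locus-vs-overall"]
    assert set(pooled.locus) == {"BAT25", "BAT26"}
    row = report[(report.comparison == "series1:ngs-vs-pcr")
                 & (report.locus == "D5S346")].iloc[0]
    assert (row.fn, row.fp) == (3, 2)
    assert row.sens == 66.7 and row.spec == 94.3
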