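"""Confusion tables, exact intervals, kappa, reconstruction, sample size,
logistic regression — each cross-checked against an independent route."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from eyescreen.stats import (
    AgreementBand,
    ConfusionTable,
    ReconstructionError,
    SeparationError,
    UndefinedMetricError,
    accuracy_summary,
    achieved_half_width,
    build_confusion,
    cohen_kappa,
    exact_binomial_ci,
    fit_logistic,
    odds_ratio_2x2,
    percent_agreement,
    reconstruct_2x2,
    round_half_up,
    sample_size_sensitivity,
)

tables = st.builds(ConfusionTable, tp=st.integers(0, 200), fn=st.integers(0, 200),
                   fp=st.integers(0, 200), tn=st.integers(0, 200))


# -- independent oracle: invert the binomial tails by bisection ------------

def cp_interval_by_bisection(k: int, n: int, level: float = 0.95,
                             tol: float = 1e-10) -> tuple[float, float]:
    """Clopper-Pearson bounds found by bisecting the binomial tail sums."""
    alpha = 1 - level

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    if k == 0:
        low = 0.0
    else:
        # smallest p with P(X >= k | p) >= alpha/2
        low = bisect(lambda p: sum(sps.binom.pmf(x, n, p) for x in range(k, n + 1))
                     - alpha / 2, 0.0, 1.0)
    if k == n:
        high = 1.0
    else:
        # largest p with P(X <= k | p) >= alpha/2
        high = bisect(lambda p: alpha / 2
                      - sum(sps.binom.pmf(x, n, p) for x in range(0, k + 1)),
                      0.0, 1.0)
    return low, high


class TestConfusionTable:
    def test_build_single_concordant_pair(self):
        t = build_confusion([True], [True])
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 0, 0, 0)

    def test_degenerate_index_never_refers(self):
        t = build_confusion([False] * 5, [True, True, False, False, False])
        assert t.tp == 0 and t.fp == 0 and (t.fn, t.tn) == (2, 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            build_confusion([True], [True, False])

    def test_missing_decision_names_position(self):
        with pytest.raises(ValueError, match="position 1"):
            build_confusion([True, None], [True, False])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(1, -1, 0, 0)

    @given(t=tables)
    def test_margins_partition_the_total(self, t):
        assert t.reference_positives + t.reference_negatives == t.total
        assert t.index_positives + t.index_negatives == t.total


class TestAccuracySummary:
    def test_final_round_metrics(self):
        s = accuracy_summary(ConfusionTable(344, 34, 43, 153))
        assert round_half_up(s.sensitivity.point, 3) == 0.910
        assert round_half_up(s.specificity.point, 3) == 0.781
        assert round_half_up(s.ppv.point, 3) == 0.889
        assert round_half_up(s.npv.point, 3) == 0.818

    def test_mandatory_va_round_metrics(self):
        s = accuracy_summary(ConfusionTable(110, 3, 74, 16))
        assert s.sensitivity.percent == 97.3
        assert s.specificity.percent == 17.8

    def test_perfect_classifier(self):
        s = accuracy_summary(ConfusionTable(7, 0, 0, 9))
        assert all(getattr(s, m).point == 1.0
                   for m in ("sensitivity", "specificity", "ppv", "npv"))

    def test_zero_denominator_flagged_undefined(self):
        s = accuracy_summary(ConfusionTable(0, 0, 3, 5))
        assert s.sensitivity is None and s.ppv is not None
        s2 = accuracy_summary(ConfusionTable(5, 2, 0, 0))
        assert s2.specificity is None and s2.npv is not None


class TestClopperPearson:
    def test_final_round_sensitivity_bounds(self):
        low, high = exact_binomial_ci(344, 378)
        assert (round_half_up(100 * low, 1), round_half_up(100 * high, 1)) == (87.7, 93.7)

    @pytest.mark.parametrize("k,n", [(0, 10), (10, 10)])
    def test_degenerate_endpoints(self, k, n):
        low, high = exact_binomial_ci(k, n)
        assert low == 0.0 if k == 0 else high == 1.0

    @pytest.mark.parametrize("k,n", [(3, 12), (0, 7), (7, 7), (1, 50), (25, 60)])
    def test_matches_tail_inversion_oracle(self, k, n):
        got = exact_binomial_ci(k, n)
        want = cp_interval_by_bisection(k, n)
        assert got == pytest.approx(want, abs=1e-8)

    @pytest.mark.parametrize("n", [5, 17])
    def test_endpoints_monotone_in_k(self, n):
        bounds = [exact_binomial_ci(k, n) for k in range(n + 1)]
        lows, highs = zip(*bounds)
        assert list(lows) == sorted(lows)
        assert list(highs) == sorted(highs)

    @pytest.mark.parametrize("bad", [(-1, 5, 0.95), (6, 5, 0.95), (2, 0, 0.95),
                                     (2, 5, 0.0), (2, 5, 1.0)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            exact_binomial_ci(*bad)

    def test_coverage_at_least_nominal_small_n(self):
        """Exhaustive binomial enumeration: CP coverage >= 95% everywhere."""
        level = 0.95
        for n in range(1, 26):
            intervals = [exact_binomial_ci(k, n, level) for k in range(n + 1)]
            for p in np.linspace(0.005, 0.995, 199):
                pmf = sps.binom.pmf(np.arange(n + 1), n, p)
                coverage = sum(w for (lo, hi), w in zip(intervals, pmf)
                               if lo - 1e-12 <= p <= hi + 1e-12)
                assert coverage >= level - 1e-9, (n, p, coverage)


class TestAgreement:
    def test_trainee_one_kappa_is_moderate(self):
        t = ConfusionTable(42, 2, 7, 8)
        res = cohen_kappa(t)
        assert round_half_up(res.kappa, 2) == 0.55
        assert res.band is AgreementBand.MODERATE

    def test_perfect_diagonal_kappa_one(self):
        res = cohen_kappa(ConfusionTable(12, 0, 0, 30))
        assert res.kappa == pytest.approx(1.0)
        assert res.band is AgreementBand.GOOD

    def test_chance_level_kappa_zero(self):
        assert cohen_kappa(ConfusionTable(25, 25, 25, 25)).kappa == pytest.approx(0.0)

    def test_degenerate_marginals_flagged(self):
        with pytest.raises(UndefinedMetricError):
            cohen_kappa(ConfusionTable(10, 0, 0, 0))

    @given(t=tables)
    def test_kappa_matches_sklearn_and_is_bounded(self, t):
        from sklearn.metrics import cohen_kappa_score

        if t.total == 0:
            return
        pe = (t.reference_positives * t.index_positives
              + t.reference_negatives * t.index_negatives) / t.total ** 2
        if pe >= 1.0:
            return
        res = cohen_kappa(t)
        assert -1.0 - 1e-9 <= res.kappa <= 1.0 + 1e-9
        ref = [1] * (t.tp + t.fn) + [0] * (t.fp + t.tn)
        idx = [1] * t.tp + [0] * t.fn + [1] * t.fp + [0] * t.tn
        assert res.kappa == pytest.approx(cohen_kappa_score(ref, idx), abs=1e-9)
        assert cohen_kappa(t.transpose()).kappa == pytest.approx(res.kappa)
        if t.fn == 0 and t.fp == 0:
            assert res.kappa == pytest.approx(1.0)

    def test_percent_agreement(self):
        assert percent_agreement(ConfusionTable(42, 2, 7, 8)) == pytest.approx(50 / 59)
        assert percent_agreement(ConfusionTable(3, 0, 0, 4)) == 1.0
        assert percent_agreement(ConfusionTable(0, 2, 3, 0)) == 0.0


class TestReconstruct2x2:
    def test_trainee_one_reconstruction(self):
        t = reconstruct_2x2(59, 44, 49, 0.848)
        assert (t.tp, t.fn, t.fp, t.tn) == (42, 2, 7, 8)

    def test_full_agreement(self):
        t = reconstruct_2x2(10, 10, 10, 1.0)
        assert (t.tp, t.fn, t.fp, t.tn) == (10, 0, 0, 0)

    def test_zero_agreement_with_complementary_marginals(self):
        t = reconstruct_2x2(10, 5, 5, 0.0)
        assert (t.tp, t.fn, t.fp, t.tn) == (0, 5, 5, 0)
        # cross-check: enumerate all tables with these marginals
        matches = [
            (a, 5 - a, 5 - a, a) for a in range(6)
            if (a + a) / 10 == 0.0
        ]
        assert matches == [(0, 5, 5, 0)]

    @pytest.mark.parametrize("args", [(10, 9, 9, 0.0),   # negative tn
                                      (59, 44, 49, 0.80)])  # parity violation
    def test_inconsistent_inputs_rejected(self, args):
        with pytest.raises(ReconstructionError):
            reconstruct_2x2(*args)

    @given(t=tables.filter(lambda t: t.total > 0))
    def test_round_trip_from_any_table(self, t):
        """Marginals + agreement of a real table always reconstruct it."""
        got = reconstruct_2x2(t.total, t.reference_positives, t.index_positives,
                              percent_agreement(t))
        assert got == t


class TestSampleSize:
    def test_precision_design(self):
        cases, n = sample_size_sensitivity(0.90, 0.05, 0.30)
        assert (cases, n) == (139, 464)

    def test_achieved_half_width_with_observed_cases(self):
        # the final round accrued 155 expected cases; precision ~ +/-4.7%
        assert achieved_half_width(0.90, 155) == pytest.approx(0.0472, abs=5e-4)

    def test_monotone_decreasing_in_half_width(self):
        ns = [sample_size_sensitivity(0.9, hw, 0.3)[1]
              for hw in (0.10, 0.05, 0.02, 0.01)]
        assert ns == sorted(ns) and ns[0] < ns[-1]

    @pytest.mark.parametrize("bad", [(0.0, 0.05, 0.3), (0.9, 0.0, 0.3),
                                     (0.9, 0.05, 1.0)])
    def test_invalid_proportions_rejected(self, bad):
        with pytest.raises(ValueError):
            sample_size_sensitivity(*bad)


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(y, np.zeros((100, 0)))
        assert fit.params[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-6)

    def test_parameter_recovery_on_synthetic_data(self):
        rng = np.random.default_rng(7)
        n, beta = 5000, np.array([-1.0, 0.8])
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(beta[0] + beta[1] * x)))
        y = (rng.random(n) < p).astype(int)
        fit = fit_logistic(y, x)
        assert np.all(np.abs(fit.params - beta) < 3 * fit.std_errors)

    def test_single_binary_covariate_or_equals_cross_product(self):
        # outcome-by-exposure table (20, 10, 5, 10) -> OR 4.0
        y = [1] * 20 + [0] * 10 + [1] * 5 + [0] * 10
        x = [1] * 30 + [0] * 15
        fit = fit_logistic(y, x)
        direct = odds_ratio_2x2(20, 10, 5, 10)
        assert direct.odds_ratio == pytest.approx(4.0)
        assert fit.odds_ratios[1] == pytest.approx(direct.odds_ratio, abs=1e-6)
        assert fit.or_ci_low[1] == pytest.approx(direct.ci_low, rel=1e-4)

    def test_complete_separation_raises(self):
        y = [0] * 20 + [1] * 20
        x = list(range(40))
        with pytest.raises(SeparationError):
            fit_logistic(y, x)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic([0, 1, 2], [1.0, 2.0, 3.0])


class TestOddsRatio:
    def test_null_and_known_tables(self):
        assert odds_ratio_2x2(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)
        assert odds_ratio_2x2(20, 10, 5, 10).odds_ratio == pytest.approx(4.0)

    def test_zero_cell_gets_continuity_correction(self):
        res = odds_ratio_2x2(5, 0, 3, 7)
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))
        assert not odds_ratio_2x2(5, 1, 3, 7).continuity_corrected


class TestDisplayRounding:
    @pytest.mark.parametrize("x, nd, want", [(0.8185, 3, 0.819), (91.05, 1, 91.1),
                                             (0.545, 2, 0.55), (66.04, 1, 66.0)])
    def test_round_half_up(self, x, nd, want):
        assert round_half_up(x, nd) == want
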