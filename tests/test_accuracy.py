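"""Accuracy panel, binomial intervals, rounding and sample-size planning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from standing_triage import (
    CIMethod,
    ConfusionTable,
    Diagnosis,
    UndefinedMetricError,
    ValidationError,
    build_confusion,
    diagnostic_metrics,
    proportion_ci,
    round_half_away,
    sample_size,
)


class TestBuildConfusion:
    def test_table2_replay(self):
        """40 central of whom 38 worrisome; 312 others of whom 42 worrisome."""
        records = (
            [(True, Diagnosis.CENTRAL)] * 38
            + [(False, Diagnosis.CENTRAL)] * 2
            + [(True, Diagnosis.OTHER)] * 42
            + [(False, Diagnosis.OTHER)] * 270
        )
        t = build_confusion(records)
        assert (t.tp, t.fn, t.fp, t.tn) == (38, 2, 42, 270)

    def test_single_cell(self):
        t = build_confusion([(True, "CENTRAL")] * 10)
        assert (t.tp, t.fn, t.fp, t.tn) == (10, 0, 0, 0)

    def test_matches_independent_tally(self):
        rng = np.random.default_rng(7)
        preds = rng.random(1000) < 0.3
        truths = np.where(rng.random(1000) < 0.2, "CENTRAL", "OTHER")
        t = build_confusion(zip(preds.tolist(), truths.tolist()))
        # brute-force recount
        tp = sum(1 for p, d in zip(preds, truths) if p and d == "CENTRAL")
        fn = sum(1 for p, d in zip(preds, truths) if not p and d == "CENTRAL")
        fp = sum(1 for p, d in zip(preds, truths) if p and d == "OTHER")
        tn = sum(1 for p, d in zip(preds, truths) if not p and d == "OTHER")
        assert (t.tp, t.fn, t.fp, t.tn) == (tp, fn, fp, tn)
        assert t.total == 1000

    def test_rejects_empty_and_unknown(self):
        with pytest.raises(ValidationError):
            build_confusion([])
        with pytest.raises(ValidationError):
            build_confusion([(True, Diagnosis.UNKNOWN)])


class TestDiagnosticMetrics:
    def test_published_panel(self, table2_confusion):
        """The validation cohort's panel: 95/87/48/99/88 at integer rounding."""
        panel = diagnostic_metrics(table2_confusion, percent_decimals=0)
        assert panel.sensitivity.value == 95
        assert panel.specificity.value == 87
        assert panel.ppv.value == 48
        assert panel.npv.value == 99
        assert panel.accuracy.value == 88

    def test_perfect_test(self):
        panel = diagnostic_metrics(ConfusionTable(tp=5, fn=0, fp=0, tn=9))
        assert all(m.value == 100 for m in panel.as_dict().values())

    def test_sens_spec_exchange_under_cell_swap(self):
        a = ConfusionTable(tp=13, fn=5, fp=8, tn=21)
        b = ConfusionTable(tp=21, fn=8, fp=5, tn=13)  # tp<->tn, fp<->fn
        pa = diagnostic_metrics(a, percent_decimals=3)
        pb = diagnostic_metrics(b, percent_decimals=3)
        assert pa.sensitivity.value == pb.specificity.value
        assert pa.specificity.value == pb.sensitivity.value

    @given(
        tp=hst.integers(0, 200), fp=hst.integers(0, 200),
        fn=hst.integers(0, 200), tn=hst.integers(0, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_formulas(self, tp, fp, fn, tn):
        """Unrounded metrics equal the textbook fractions."""
        if tp + fp + fn + tn == 0:
            return
        panel = diagnostic_metrics(ConfusionTable(tp, fp, fn, tn), percent_decimals=6)
        expected = {
            "sensitivity": (tp, tp + fn),
            "specificity": (tn, tn + fp),
            "ppv": (tp, tp + fp),
            "npv": (tn, tn + fn),
            "accuracy": (tp + tn, tp + fp + fn + tn),
        }
        for name, (num, den) in expected.items():
            got = panel.as_dict()[name]
            if den == 0:
                assert got.value is None
            else:
                assert got.value == pytest.approx(100 * num / den, abs=1e-5)
                assert got.ci_low <= got.value <= got.ci_high

    def test_zero_denominator_reported_missing(self):
        panel = diagnostic_metrics(ConfusionTable(tp=0, fn=0, fp=3, tn=7))
        assert panel.sensitivity.value is None
        assert panel.specificity.value is not None


class TestProportionCI:
    def test_boundaries(self):
        assert proportion_ci(40, 40)[1] == 100
        assert proportion_ci(0, 40)[0] == 0

    @pytest.mark.parametrize(
        "successes, n, expected_rounded",
        [
            (38, 40, (83, 99)),   # the published sensitivity CI
            (270, 272, (97, 100)),  # the published NPV CI
        ],
    )
    def test_clopper_pearson_matches_beta_oracle(self, successes, n, expected_rounded):
        low, high = proportion_ci(successes, n, CIMethod.CLOPPER_PEARSON)
        # independent beta-quantile oracle
        olow = 100 * stats.beta.ppf(0.025, successes, n - successes + 1)
        ohigh = 100 * stats.beta.ppf(0.975, successes + 1, n - successes)
        if successes == n:
            ohigh = 100.0
        assert low == pytest.approx(olow, abs=1e-9)
        assert high == pytest.approx(ohigh, abs=1e-9)
        assert (round_half_away(low), round_half_away(high)) == expected_rounded

    @given(successes=hst.integers(0, 50), n=hst.integers(1, 50))
    @settings(max_examples=80, deadline=None)
    def test_both_methods_bracket_the_point_estimate(self, successes, n):
        if successes > n:
            return
        p = 100 * successes / n
        for method in CIMethod:
            low, high = proportion_ci(successes, n, method)
            assert low - 1e-9 <= p <= high + 1e-9

    def test_exact_interval_contains_wilson_midpoint_estimate(self):
        for s, n in [(3, 17), (10, 20), (38, 40)]:
            cp = proportion_ci(s, n, CIMethod.CLOPPER_PEARSON)
            w = proportion_ci(s, n, CIMethod.WILSON)
            assert cp[0] <= (w[0] + w[1]) / 2 <= cp[1]

    def test_simulated_coverage(self):
        """Exact-interval empirical coverage >= 95% at n = 50."""
        rng = np.random.default_rng(11)
        n, draws = 50, 10_000
        intervals = [proportion_ci(x, n, CIMethod.CLOPPER_PEARSON) for x in range(n + 1)]
        lows = np.array([iv[0] for iv in intervals])
        highs = np.array([iv[1] for iv in intervals])
        for p in (0.1, 0.5, 0.9):
            xs = rng.binomial(n, p, size=draws)
            covered = np.mean((lows[xs] <= 100 * p) & (100 * p <= highs[xs]))
            assert covered >= 0.95 - 3 * math.sqrt(0.05 * 0.95 / draws)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            proportion_ci(1, 0)
        with pytest.raises(ValidationError):
            proportion_ci(5, 4)


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(47.5, 48), (37.5, 38), (87.5, 88), (82.5, 83), (-2.5, -3), (2.4, 2)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_one_decimal_and_float_ties(self):
        assert round_half_away(100 * 40 / 352, 1) == 11.4
        assert round_half_away(100 * 33 / 40) == 83  # 82.5 stored imprecisely


class TestSampleSize:
    def test_standard_formula_values(self):
        """z^2 S(1-S)/d^2 -> 73 diseased, 730 total, 812 after 10% dropout.

        The standard precision formula does not yield the historically
        quoted 330 for these inputs; the package implements the formula.
        """
        assert sample_size(0.10, 0.95, 0.05, dropout_fraction=0.0) == 730
        assert sample_size(0.10, 0.95, 0.05, dropout_fraction=0.10) == 812
        # diseased-only requirement
        z = stats.norm.ppf(0.975)
        assert math.ceil(z * z * 0.95 * 0.05 / 0.05**2) == 73

    def test_limit_and_monotonicity(self):
        assert sample_size(0.5, 0.5, 1000.0, 0.0) == 2
        widths = [0.02, 0.05, 0.10]
        sizes = [sample_size(0.1, 0.9, w, 0.0) for w in widths]
        assert sizes == sorted(sizes, reverse=True)
        assert sample_size(0.1, 0.9, 0.05, 0.2) >= sample_size(0.1, 0.9, 0.05, 0.0)

    def test_invalid(self):
        with pytest.raises(ValidationError):
            sample_size(0.0, 0.9, 0.05)
        with pytest.raises(ValidationError):
            sample_size(0.1, 0.9, 0.05, dropout_fraction=1.0)


def test_empty_table_is_an_error():
    with pytest.raises((UndefinedMetricError, ValidationError)):
        diagnostic_metrics(ConfusionTable(0, 0, 0, 0))
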