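"""Diagnostic-accuracy panel for a binary triage rule.

Builds 2x2 confusion tables of the worrisome-STANDING conclusion against
the central-vertigo reference standard and computes sensitivity,
specificity, predictive values and accuracy with binomial confidence
intervals, plus the prospective sample-size calculator used to plan a
sensitivity-driven accuracy study.

Percentages are rounded *half away from zero*, the convention needed to
reproduce report-style integer tables (82.5 -> 83, 37.5 -> 38), which
differs from Python's built-in banker's rounding.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .algorithm import Diagnosis
from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "CIMethod",
    "ConfusionTable",
    "MetricWithCI",
    "DiagnosticMetrics",
    "build_confusion",
    "diagnostic_metrics",
    "proportion_ci",
    "sample_size",
    "round_half_away",
]


class CIMethod(str, enum.Enum):
    CLOPPER_PEARSON = "CLOPPER_PEARSON"
    WILSON = "WILSON"


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (82.5 -> 83, -2.5 -> -3)."""
    factor = 10.0**decimals
    # snap to 9 decimals first so ties stored imprecisely (82.4999999999)
    # still round away from zero
    scaled = round(x * factor, 9)
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / factor


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts; test = worrisome STANDING, truth = central vertigo."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValidationError("counts must be non-negative integers", field=name)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def non_diseased(self) -> int:
        return self.fp + self.tn


class MetricWithCI(NamedTuple):
    value: float | None
    ci_low: float | None
    ci_high: float | None


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five-metric panel, as percentages with 95% CIs.

    A metric whose denominator is zero is reported as ``None`` (missing),
    never silently as 0 or 100.
    """

    sensitivity: MetricWithCI
    specificity: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    accuracy: MetricWithCI
    ci_method: CIMethod
    percent_decimals: int

    def as_dict(self) -> dict[str, MetricWithCI]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def build_confusion(records: Iterable[tuple[bool, Diagnosis | str]]) -> ConfusionTable:
    """Tally (predicted_worrisome, truth) pairs into a 2x2 table.

    Truth must be CENTRAL or OTHER for every record; UNKNOWN labels and
    empty input are rejected so that a table is never silently biased.
    """
    tp = fp = fn = tn = 0
    n = 0
    for i, (worrisome, truth) in enumerate(records):
        truth = Diagnosis(truth)
        if truth is Diagnosis.UNKNOWN:
            raise ValidationError("UNKNOWN truth not allowed", field="truth", row=i)
        n += 1
        if truth is Diagnosis.CENTRAL:
            if worrisome:
                tp += 1
            else:
                fn += 1
        else:
            if worrisome:
                fp += 1
            else:
                tn += 1
    if n == 0:
        raise ValidationError("no records to tally")
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def proportion_ci(
    successes: int,
    n: int,
    method: CIMethod = CIMethod.CLOPPER_PEARSON,
    level: float = 0.95,
) -> tuple[float, float]:
    """Two-sided binomial confidence interval, as percentages.

    CLOPPER_PEARSON is the exact interval from beta-distribution
    quantiles; WILSON is the score interval.  ``successes == 0`` pins the
    lower bound at 0 and ``successes == n`` pins the upper bound at 100.
    """
    if n <= 0:
        raise ValidationError("n must be positive", field="n")
    if not 0 <= successes <= n:
        raise ValidationError("successes must lie in [0, n]", field="successes")
    sm_method = "beta" if method is CIMethod.CLOPPER_PEARSON else "wilson"
    low, high = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    # statsmodels returns nan for the beta bound at the boundary
    if successes == 0:
        low = 0.0
    if successes == n:
        high = 1.0
    return 100.0 * float(low), 100.0 * float(high)


def _metric(
    successes: int, n: int, method: CIMethod, decimals: int
) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(None, None, None)
    point = round_half_away(100.0 * successes / n, decimals)
    low, high = proportion_ci(successes, n, method)
    return MetricWithCI(
        point, round_half_away(low, decimals), round_half_away(high, decimals)
    )


def diagnostic_metrics(
    table: ConfusionTable,
    ci_method: CIMethod = CIMethod.CLOPPER_PEARSON,
    percent_decimals: int = 0,
) -> DiagnosticMetrics:
    """Compute the five-metric accuracy panel from a confusion table."""
    if table.total == 0:
        raise UndefinedMetricError("empty confusion table")
    return DiagnosticMetrics(
        sensitivity=_metric(table.tp, table.diseased, ci_method, percent_decimals),
        specificity=_metric(table.tn, table.non_diseased, ci_method, percent_decimals),
        ppv=_metric(table.tp, table.tp + table.fp, ci_method, percent_decimals),
        npv=_metric(table.tn, table.tn + table.fn, ci_method, percent_decimals),
        accuracy=_metric(table.tp + table.tn, table.total, ci_method, percent_decimals),
        ci_method=ci_method,
        percent_decimals=percent_decimals,
    )


def sample_size(
    prevalence: float,
    expected_sensitivity: float,
    half_width: float,
    dropout_fraction: float = 0.0,
    level: float = 0.95,
) -> int:
    """Patients needed to estimate sensitivity to a CI half-width.

    Uses the normal-approximation precision formula: the number of
    *diseased* subjects is ``ceil(z^2 S(1-S) / d^2)`` for expected
    sensitivity ``S`` and half-width ``d``; dividing by the disease
    prevalence gives the total cohort, inflated for anticipated dropout.

    Note the standard formula with 10% prevalence, S = 0.95, d = 0.05 and
    10% dropout yields 812 patients, not the 330 sometimes quoted for this
    design; no textbook variant reproduces 330 from those inputs.
    """
    for name, v in (
        ("prevalence", prevalence),
        ("expected_sensitivity", expected_sensitivity),
    ):
        if not 0 < v < 1:
            raise ValidationError("must lie in (0, 1)", field=name)
    if half_width <= 0:
        raise ValidationError("must be positive", field="half_width")
    if not 0 <= dropout_fraction < 1:
        raise ValidationError("must lie in [0, 1)", field="dropout_fraction")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    s = expected_sensitivity
    diseased_needed = math.ceil(z * z * s * (1 - s) / half_width**2)
    total = math.ceil(diseased_needed / prevalence)
    return math.ceil(total / (1 - dropout_fraction))
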