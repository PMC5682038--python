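"""Added-diagnostic-value analysis via backward stepwise logistic regression.

The question this answers: once the ordinary clinical picture is accounted
for (hypertension, continuous vertigo, headache, neurological signs), does
a worrisome triage result still carry independent information about a
central cause?  The tool is a logit-link binomial model fitted by maximum
likelihood, with backward elimination of the weakest predictor (largest
Wald p-value >= 0.05) until every retained predictor is significant.

Fits go through statsmodels' Logit; this module adds the elimination
loop, odds-ratio reporting and an explicit separation check: a predictor
that (quasi-)separates the outcome drives the MLE to infinity, and the
fit must fail loudly rather than return silently diverged estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import SeparationError, ValidationError

__all__ = ["ModelFit", "fit_logit", "backward_stepwise"]

# |coefficient| beyond this (odds ratio > 5e8) is treated as numerically
# diverged, the signature of quasi-separation that slips past statsmodels
_DIVERGENCE_BOUND = 20.0


@dataclass(frozen=True)
class ModelFit:
    """Coefficient table of a fitted logit model, with odds ratios."""

    params: pd.DataFrame  # index: predictor; columns: coef, se, wald_z, p_value, or_, or_low, or_high
    log_likelihood: float
    retained: tuple[str, ...]
    removal_order: tuple[str, ...] = ()
    intercept_only: bool = False

    def odds_ratio(self, predictor: str) -> tuple[float, float, float]:
        row = self.params.loc[predictor]
        return float(row["or_"]), float(row["or_low"]), float(row["or_high"])


def _check_inputs(outcome: np.ndarray, predictors: pd.DataFrame) -> None:
    if predictors.shape[1] < 1:
        raise ValidationError("need at least one predictor", field="predictors")
    if len(outcome) != len(predictors):
        raise ValidationError("outcome and predictors differ in length", field="outcome")
    uniq = np.unique(outcome)
    if not np.isin(uniq, [0, 1]).all() or len(uniq) < 2:
        raise ValidationError(
            "outcome must be binary with both classes present", field="outcome"
        )


def fit_logit(
    outcome,
    predictors: pd.DataFrame,
    tol: float = 1e-8,
    level: float = 0.95,
) -> ModelFit:
    """Maximum-likelihood logit fit with Wald tests and OR intervals.

    Raises :class:`SeparationError` on complete or quasi-complete
    separation instead of returning diverged estimates.
    """
    outcome = np.asarray(outcome, dtype=float)
    predictors = pd.DataFrame(predictors).astype(float)
    _check_inputs(outcome, predictors)
    design = sm.add_constant(predictors, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(outcome, design).fit(disp=0, tol=tol, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"separation detected during fit: {exc}") from exc
    coefs = res.params.drop(labels=["const"], errors="ignore")
    if (coefs.abs() > _DIVERGENCE_BOUND).any():
        offenders = list(coefs.index[coefs.abs() > _DIVERGENCE_BOUND])
        raise SeparationError(f"quasi-separation: diverged coefficients for {offenders}")
    z = norm.ppf(1 - (1 - level) / 2)
    table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "wald_z": res.tvalues,
            "p_value": res.pvalues,
        }
    )
    table["or_"] = np.exp(table["coef"])
    table["or_low"] = np.exp(table["coef"] - z * table["se"])
    table["or_high"] = np.exp(table["coef"] + z * table["se"])
    return ModelFit(
        params=table,
        log_likelihood=float(res.llf),
        retained=tuple(c for c in predictors.columns),
    )


def backward_stepwise(
    outcome,
    candidate_predictors: pd.DataFrame,
    alpha_retain: float = 0.05,
) -> ModelFit:
    """Backward elimination at the given retention threshold.

    Repeatedly removes the predictor with the largest Wald p-value at or
    above ``alpha_retain`` and refits, until every retained predictor is
    below the threshold.  Ties on the maximal p-value are broken by
    removing the lexicographically last name, so the procedure is
    deterministic and invariant to column order.  If every candidate is
    eliminated, an intercept-only fit is returned with
    ``intercept_only=True``.
    """
    candidate_predictors = pd.DataFrame(candidate_predictors)
    current = list(candidate_predictors.columns)
    removed: list[str] = []
    while current:
        fit = fit_logit(outcome, candidate_predictors[current])
        pvals = fit.params.loc[current, "p_value"]
        worst = pvals.max()
        if worst < alpha_retain:
            return ModelFit(
                params=fit.params,
                log_likelihood=fit.log_likelihood,
                retained=tuple(current),
                removal_order=tuple(removed),
            )
        ties = sorted(pvals.index[pvals == worst])
        drop = ties[-1]
        removed.append(drop)
        current.remove(drop)
    # intercept-only fallback
    outcome = np.asarray(outcome, dtype=float)
    res = sm.Logit(outcome, np.ones((len(outcome), 1))).fit(disp=0)
    table = pd.DataFrame(
        {
            "coef": [float(res.params[0])],
            "se": [float(res.bse[0])],
            "wald_z": [float(res.tvalues[0])],
            "p_value": [float(res.pvalues[0])],
        },
        index=["const"],
    )
    table["or_"] = np.exp(table["coef"])
    table["or_low"] = np.exp(table["coef"] - 1.959963984540054 * table["se"])
    table["or_high"] = np.exp(table["coef"] + 1.959963984540054 * table["se"])
    return ModelFit(
        params=table,
        log_likelihood=float(res.llf),
        retained=(),
        removal_order=tuple(removed),
        intercept_only=True,
    )
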