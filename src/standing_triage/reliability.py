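"""Multi-rater agreement for the triage algorithm and its individual steps.

The study design has each patient examined by 2 of a pool of 6 physicians,
with the pair varying from patient to patient.  Because rater identity is
not fixed across subjects, the appropriate chance-corrected agreement
statistic is Fleiss' kappa (raters anonymous, m ratings per subject)
rather than Cohen's kappa, even though m = 2.

For an n-subjects x k-categories count matrix with every row summing to m:

    P_i    = (sum_j n_ij^2 - m) / (m (m - 1))        per-subject agreement
    p_j    = sum_i n_ij / (n m)                      category prevalence
    kappa  = (mean_i P_i - sum_j p_j^2) / (1 - sum_j p_j^2)

Steps 2 and 3 of the algorithm are conditional: a rater only judges
nystagmus direction if they saw spontaneous nystagmus, and only performs
the head-impulse test inside the unidirectional branch.  Step-level kappas
are therefore computed on the subjects *both* raters routed to that step —
the only definition that never fabricates a rating.

Confidence intervals are percentile bootstrap over subjects (the rating
rows), since no closed-form interval is standard for this design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import UndefinedKappaError, ValidationError

__all__ = [
    "RatingMatrix",
    "fleiss_kappa",
    "kappa_ci_bootstrap",
    "stepwise_kappas",
    "STEP_CATEGORIES",
]

# category vocabularies for per-step rating matrices
STEP_CATEGORIES: dict[str, tuple[str, ...]] = {
    "step1": ("SPONTANEOUS", "POSITIONAL", "NONE"),
    "step2": ("UNIDIRECTIONAL", "MULTIDIRECTIONAL_OR_VERTICAL"),
    "step3": ("POSITIVE", "NEGATIVE"),
    "step4": ("ABLE", "UNABLE"),
    "overall": ("WORRISOME", "BENIGN"),
}


@dataclass(frozen=True)
class RatingMatrix:
    """Subjects x categories count matrix with m ratings per subject."""

    counts: np.ndarray
    m: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 2:
            raise ValidationError("counts must be n x k with n >= 1, k >= 2", field="counts")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative", field="counts")
        if self.m < 2:
            raise ValidationError("need at least two ratings per subject", field="m")
        if (counts.sum(axis=1) != self.m).any():
            raise ValidationError("every row must sum to m", field="counts")

    @property
    def n_subjects(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_categories(self) -> int:
        return int(self.counts.shape[1])


def fleiss_kappa(ratings: RatingMatrix) -> float:
    """Fleiss' chance-corrected agreement; in [-1, 1].

    Raises :class:`UndefinedKappaError` when all ratings fall in a single
    category (expected chance agreement is 1 and the statistic is 0/0).
    """
    counts = ratings.counts
    m = ratings.m
    p_i = (np.square(counts).sum(axis=1) - m) / (m * (m - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (ratings.n_subjects * m)
    p_e = float(np.square(p_j).sum())
    if 1.0 - p_e < 1e-12:
        raise UndefinedKappaError("all ratings in one category; kappa undefined")
    return float((p_bar - p_e) / (1.0 - p_e))


def kappa_ci_bootstrap(
    ratings: RatingMatrix,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Percentile bootstrap CI for kappa, resampling subjects.

    Resamples with undefined kappa (all mass in one category) are redrawn
    up to ``max_redraws`` times in total before giving up.
    """
    if n_boot < 100:
        raise ValidationError("need at least 100 bootstrap resamples", field="n_boot")
    rng = np.random.default_rng(seed)
    n = ratings.n_subjects
    stats: list[float] = []
    redraws = 0
    while len(stats) < n_boot:
        idx = rng.integers(0, n, size=n)
        resampled = RatingMatrix(ratings.counts[idx], ratings.m)
        try:
            stats.append(fleiss_kappa(resampled))
        except UndefinedKappaError:
            redraws += 1
            if redraws > max_redraws:
                raise UndefinedKappaError(
                    "too many degenerate bootstrap resamples; matrix nearly unanimous"
                )
    alpha = 1 - level
    low, high = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def _matrix_from_pairs(
    pairs: Sequence[tuple[str, str]], categories: Sequence[str]
) -> RatingMatrix:
    index = {c: j for j, c in enumerate(categories)}
    counts = np.zeros((len(pairs), len(categories)), dtype=int)
    for i, (a, b) in enumerate(pairs):
        counts[i, index[a]] += 1
        counts[i, index[b]] += 1
    return RatingMatrix(counts, m=2)


def stepwise_kappas(
    paired_step_ratings: Sequence[Mapping[str, tuple[str | None, str | None]]],
    categories: Mapping[str, Sequence[str]] = STEP_CATEGORIES,
) -> dict[str, float | None]:
    """Kappa per algorithm step from paired rater observations.

    ``paired_step_ratings`` holds, per subject, a mapping from step name to
    the two raters' categories (``None`` where a rater never reached that
    step).  For each step, only subjects with both ratings present enter
    that step's matrix; a step with fewer than two eligible subjects, or
    with undefined kappa, is reported as ``None`` (not estimable).
    """
    out: dict[str, float | None] = {}
    for step, cats in categories.items():
        pairs = [
            (r[step][0], r[step][1])
            for r in paired_step_ratings
            if step in r and r[step][0] is not None and r[step][1] is not None
        ]
        if len(pairs) < 2:
            out[step] = None
            continue
        try:
            out[step] = fleiss_kappa(_matrix_from_pairs(pairs, cats))
        except UndefinedKappaError:
            out[step] = None
    return out
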