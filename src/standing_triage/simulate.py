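"""Latent-class synthetic cohorts with the validation study's structure.

No patient-level data accompany the study, so every downstream stage —
classification, accuracy panels, reliability, regression — is exercised on
cohorts drawn from a two-class generative model:

* a latent diagnosis class (central vertigo vs other) with prevalence
  40/352 ~ 11.4% at the published calibration;
* a class-conditional categorical finding profile over the six mutually
  exclusive step-1/step-2 presentations (no nystagmus, three positional
  types, unidirectional or multidirectional spontaneous nystagmus);
* a class-conditional probability of a negative head-impulse test, drawn
  only inside the unidirectional branch;
* a class-conditional probability of being unable to stand and walk.

Gait is sampled conditionally on the class only — independent of the
nystagmus category given class — because only marginal frequencies were
published.  Simulated cohorts therefore approximate, but do not exactly
replay, the published joint accuracy; exact replay uses the packaged
aggregate counts in :mod:`standing_triage.tables`.

A rater-error model layers on top for reliability studies: two anonymous
raters observe each patient's true step outcomes, each step's category is
flipped to a uniformly random other category with a per-step probability,
and each rater's observed findings are re-routed through the classifier so
that disagreement propagates downstream exactly as it would at the
bedside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .algorithm import (
    ClassifierConfig,
    Criterion,
    Diagnosis,
    HitPolicy,
    HitResult,
    NystagmusMode,
    PatientFindings,
    PositionalType,
    SpontaneousDirection,
    classify,
)
from .errors import ValidationError
from .tables import N_CENTRAL, N_OTHER, N_TOTAL, TableFixture, table_fixture

__all__ = [
    "FINDING_CATEGORIES",
    "CohortParameters",
    "calibrate_from_table2",
    "generate",
    "generate_paired_ratings",
    "table_fixture",
    "TableFixture",
]

# mutually exclusive presentation categories (steps 1-2 combined)
FINDING_CATEGORIES = (
    "NONE",
    "POSITIONAL_TYPICAL_LATERAL",
    "POSITIONAL_TYPICAL_POSTERIOR",
    "POSITIONAL_ATYPICAL",
    "SPONT_UNIDIRECTIONAL",
    "SPONT_MULTIDIRECTIONAL",
)

_SIMULATION_CONFIG = ClassifierConfig(hit_policy=HitPolicy.ASSUME_NEGATIVE)


@dataclass(frozen=True)
class CohortParameters:
    """Generative model for a synthetic vertigo cohort."""

    prevalence_central: float
    finding_profile: Mapping[str, Mapping[str, float]]
    p_hit_negative_given_unidirectional: Mapping[str, float]
    p_unable_to_stand: Mapping[str, float]
    n: int = N_TOTAL
    seed: int = 0
    provenance: tuple[str, ...] = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence_central <= 1:
            raise ValidationError("must lie in [0, 1]", field="prevalence_central")
        if self.n < 1:
            raise ValidationError("must be positive", field="n")
        for cls in ("CENTRAL", "OTHER"):
            profile = self.finding_profile[cls]
            probs = [profile[c] for c in FINDING_CATEGORIES]
            if any(p < 0 or p > 1 for p in probs):
                raise ValidationError(
                    f"{cls} profile has probabilities outside [0, 1]",
                    field="finding_profile",
                )
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(
                    f"{cls} profile must sum to 1", field="finding_profile"
                )
            for name in ("p_hit_negative_given_unidirectional", "p_unable_to_stand"):
                p = getattr(self, name)[cls]
                if not 0 <= p <= 1:
                    raise ValidationError("must lie in [0, 1]", field=name)


def calibrate_from_table2(n: int = N_TOTAL, seed: int = 0) -> CohortParameters:
    """Parameters matching the published class-conditional frequencies.

    The published central column is inconsistent as a joint table (modes
    sum to 41 of 40; head-impulse results sum to 5 of 3 unidirectional
    patients), so each branch is renormalized independently: the six-way
    finding profile over its own sum, and the HIT split over the sum of
    the printed positive and negative counts.  The renormalizations
    applied are recorded in the returned object's provenance notes.
    """
    rows = table_fixture(TableFixture.TABLE2_BY_ROW)
    profile: dict[str, dict[str, float]] = {}
    p_hit: dict[str, float] = {}
    p_unable: dict[str, float] = {}
    notes: list[str] = []
    for cls, col in (("CENTRAL", "central"), ("OTHER", "other")):
        counts = {
            "NONE": rows["no_nystagmus"][col],
            "POSITIONAL_TYPICAL_LATERAL": rows["positional_lateral_canal"][col],
            "POSITIONAL_TYPICAL_POSTERIOR": rows["positional_posterior_canal"][col],
            "POSITIONAL_ATYPICAL": rows["positional_nystagmus"][col]
            - rows["positional_lateral_canal"][col]
            - rows["positional_posterior_canal"][col],
            "SPONT_UNIDIRECTIONAL": rows["spontaneous_unidirectional"][col],
            "SPONT_MULTIDIRECTIONAL": rows["spontaneous_multidirectional_vertical"][col],
        }
        total = sum(counts.values())
        class_n = N_CENTRAL if cls == "CENTRAL" else N_OTHER
        if total != class_n:
            notes.append(
                f"{cls}: finding categories sum to {total}, not {class_n}; "
                f"profile renormalized over {total}"
            )
        profile[cls] = {k: v / total for k, v in counts.items()}
        hit_neg, hit_pos = rows["hit_negative"][col], rows["hit_positive"][col]
        uni = rows["spontaneous_unidirectional"][col]
        if hit_neg + hit_pos != uni:
            notes.append(
                f"{cls}: HIT counts sum to {hit_neg + hit_pos}, not the {uni} "
                f"unidirectional patients; split renormalized over {hit_neg + hit_pos}"
            )
        p_hit[cls] = hit_neg / (hit_neg + hit_pos)
        p_unable[cls] = rows["unable_to_stand_or_walk"][col] / class_n
    return CohortParameters(
        prevalence_central=N_CENTRAL / N_TOTAL,
        finding_profile=profile,
        p_hit_negative_given_unidirectional=p_hit,
        p_unable_to_stand=p_unable,
        n=n,
        seed=seed,
        provenance=tuple(notes),
    )


def _findings_from_category(
    category: str, hit_negative: bool, unable: bool, diagnosis: Diagnosis
) -> PatientFindings:
    mode = NystagmusMode.NONE
    direction = None
    ptype = None
    hit = HitResult.NOT_PERFORMED
    if category.startswith("POSITIONAL"):
        mode = NystagmusMode.POSITIONAL
        ptype = {
            "POSITIONAL_TYPICAL_LATERAL": PositionalType.TYPICAL_LATERAL_CANAL,
            "POSITIONAL_TYPICAL_POSTERIOR": PositionalType.TYPICAL_POSTERIOR_CANAL,
            "POSITIONAL_ATYPICAL": PositionalType.ATYPICAL,
        }[category]
    elif category == "SPONT_UNIDIRECTIONAL":
        mode = NystagmusMode.SPONTANEOUS
        direction = SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
        hit = HitResult.NEGATIVE if hit_negative else HitResult.POSITIVE_SACCADE
    elif category == "SPONT_MULTIDIRECTIONAL":
        mode = NystagmusMode.SPONTANEOUS
        direction = SpontaneousDirection.MULTIDIRECTIONAL_OR_VERTICAL
    return PatientFindings(
        nystagmus_mode=mode,
        spontaneous_direction=direction,
        positional_type=ptype,
        hit_result=hit,
        can_stand_walk_unassisted=not unable,
        true_diagnosis=diagnosis,
    )


def generate(params: CohortParameters) -> list[PatientFindings]:
    """Draw a cohort of ``params.n`` patients; reproducible given the seed.

    Sampling is hierarchical: diagnosis class, then the finding category
    from the class profile, then a head-impulse result (unidirectional
    branch only) and gait from the class-conditional marginals.
    """
    rng = np.random.default_rng(params.seed)
    cats = np.array(FINDING_CATEGORIES)
    out: list[PatientFindings] = []
    is_central = rng.random(params.n) < params.prevalence_central
    for central in is_central:
        cls = "CENTRAL" if central else "OTHER"
        probs = [params.finding_profile[cls][c] for c in FINDING_CATEGORIES]
        category = str(rng.choice(cats, p=probs))
        hit_negative = bool(
            rng.random() < params.p_hit_negative_given_unidirectional[cls]
        )
        unable = bool(rng.random() < params.p_unable_to_stand[cls])
        out.append(
            _findings_from_category(
                category,
                hit_negative,
                unable,
                Diagnosis.CENTRAL if central else Diagnosis.OTHER,
            )
        )
    return out


# --- rater-error model -------------------------------------------------

_STEP1_CATS = ("SPONTANEOUS", "POSITIONAL", "NONE")
_STEP2_CATS = ("UNIDIRECTIONAL", "MULTIDIRECTIONAL_OR_VERTICAL")
_STEP3_CATS = ("POSITIVE", "NEGATIVE")
_STEP4_CATS = ("ABLE", "UNABLE")


def _maybe_flip(value: str, cats: tuple[str, ...], p: float, rng: np.random.Generator) -> str:
    if p > 0 and rng.random() < p:
        others = [c for c in cats if c != value]
        return str(rng.choice(others))
    return value


def _observe(
    patient: PatientFindings,
    flip: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, str | None]:
    """One rater's noisy per-step observations of a patient."""
    true_step1 = patient.nystagmus_mode.value
    if true_step1 == "NONE":
        true_step1 = "NONE"
    step1 = _maybe_flip(
        {"NONE": "NONE", "SPONTANEOUS": "SPONTANEOUS", "POSITIONAL": "POSITIONAL"}[
            true_step1
        ],
        _STEP1_CATS,
        flip.get("step1", 0.0),
        rng,
    )
    step2 = step3 = None
    if step1 == "SPONTANEOUS":
        if patient.spontaneous_direction is not None:
            true_step2 = (
                "UNIDIRECTIONAL"
                if patient.spontaneous_direction
                is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
                else "MULTIDIRECTIONAL_OR_VERTICAL"
            )
        else:  # misperceived mode: no true direction exists, observe at random
            true_step2 = str(rng.choice(_STEP2_CATS))
        step2 = _maybe_flip(true_step2, _STEP2_CATS, flip.get("step2", 0.0), rng)
        if step2 == "UNIDIRECTIONAL":
            if patient.hit_result is HitResult.NEGATIVE:
                true_step3 = "NEGATIVE"
            elif patient.hit_result is HitResult.POSITIVE_SACCADE:
                true_step3 = "POSITIVE"
            else:
                true_step3 = str(rng.choice(_STEP3_CATS))
            step3 = _maybe_flip(true_step3, _STEP3_CATS, flip.get("step3", 0.0), rng)
    true_step4 = "ABLE" if patient.can_stand_walk_unassisted else "UNABLE"
    step4 = _maybe_flip(true_step4, _STEP4_CATS, flip.get("step4", 0.0), rng)
    return {"step1": step1, "step2": step2, "step3": step3, "step4": step4}


def _route(obs: Mapping[str, str | None], rng: np.random.Generator) -> str:
    """Re-run the decision rule on a rater's observed findings."""
    mode = NystagmusMode(obs["step1"])
    direction = ptype = None
    hit = HitResult.NOT_PERFORMED
    if mode is NystagmusMode.SPONTANEOUS:
        direction = (
            SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
            if obs["step2"] == "UNIDIRECTIONAL"
            else SpontaneousDirection.MULTIDIRECTIONAL_OR_VERTICAL
        )
        if obs["step3"] is not None:
            hit = (
                HitResult.NEGATIVE
                if obs["step3"] == "NEGATIVE"
                else HitResult.POSITIVE_SACCADE
            )
    elif mode is NystagmusMode.POSITIONAL:
        # positional subtype is not a rated step; any typical type routes
        # identically through the worrisome criteria
        ptype = PositionalType.TYPICAL_POSTERIOR_CANAL
    result = classify(
        PatientFindings(
            nystagmus_mode=mode,
            spontaneous_direction=direction,
            positional_type=ptype,
            hit_result=hit,
            can_stand_walk_unassisted=obs["step4"] == "ABLE",
        ),
        _SIMULATION_CONFIG,
    )
    return "WORRISOME" if result.worrisome else "BENIGN"


def generate_paired_ratings(
    cohort: list[PatientFindings],
    flip_probability_per_step: Mapping[str, float],
    seed: int = 0,
) -> list[dict[str, tuple[str | None, str | None]]]:
    """Two independent noisy raters per patient, for reliability analysis.

    Each rater observes the true step outcomes with per-step flip
    probabilities (a flip replaces the category by a uniformly random
    other one), then the observed findings are re-routed through the
    classifier so downstream steps and the overall conclusion reflect that
    rater's path.  An ``overall`` flip probability, when given, is applied
    to the routed worrisome/benign conclusion directly.

    Returns, per subject, ``{step: (rater1_category, rater2_category)}``
    with ``None`` where a rater never reached the step — the input
    expected by :func:`standing_triage.reliability.stepwise_kappas`.
    """
    for step, p in flip_probability_per_step.items():
        if not 0 <= p <= 0.5:
            raise ValidationError("flip probabilities must lie in [0, 0.5]", field=step)
    rng = np.random.default_rng(seed)
    out: list[dict[str, tuple[str | None, str | None]]] = []
    for patient in cohort:
        obs1 = _observe(patient, flip_probability_per_step, rng)
        obs2 = _observe(patient, flip_probability_per_step, rng)
        overall1 = _maybe_flip(
            _route(obs1, rng), ("WORRISOME", "BENIGN"),
            flip_probability_per_step.get("overall", 0.0), rng,
        )
        overall2 = _maybe_flip(
            _route(obs2, rng), ("WORRISOME", "BENIGN"),
            flip_probability_per_step.get("overall", 0.0), rng,
        )
        record: dict[str, tuple[str | None, str | None]] = {
            "step1": (obs1["step1"], obs2["step1"]),
            "step2": (obs1["step2"], obs2["step2"]),
            "step3": (obs1["step3"], obs2["step3"]),
            "step4": (obs1["step4"], obs2["step4"]),
            "overall": (overall1, overall2),
        }
        out.append(record)
    return out
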