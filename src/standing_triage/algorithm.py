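"""The STANDING four-step bedside triage rule for acute vertigo/unsteadiness.

STANDING condenses the bedside work-up of an acutely vertiginous patient
into four sequential observations:

1. *SponTAneous vs positional* — is nystagmus present, and if so is it
   spontaneous (present at rest) or provoked by positioning maneuvers?
2. *Nystagmus Direction* — spontaneous nystagmus that is multidirectional
   (gaze-evoked, direction-changing) or vertical is a central sign.
3. *head Impulse test* — within the horizontal-unidirectional branch, the
   absence of a corrective saccade (a "negative" HIT) points to a central
   lesion, while a catch-up saccade indicates an acute peripheral
   vestibulopathy.
4. *staNdinG* — every patient is finally asked to stand and walk;
   inability to do so unassisted is worrisome.

The rule concludes "worrisome" (suspected central vertigo) when at least
one of three criteria holds: (a) multidirectional/vertical spontaneous
nystagmus, (b) unidirectional spontaneous nystagmus with a negative HIT,
(c) inability to stand and walk without assistance.  Otherwise it emits a
specific benign label: typical positional nystagmus maps to posterior- or
lateral-canal BPPV, unidirectional nystagmus with a positive HIT to acute
peripheral vestibulopathy (APV), anything else to an unspecific benign
conclusion.

This module is a *total, deterministic* encoding of that decision tree:
every invariant-satisfying findings record maps to exactly one result, and
the full (finite) findings space can be enumerated for exhaustive testing.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace

from .errors import HitRequiredError, ValidationError

__all__ = [
    "NystagmusMode",
    "SpontaneousDirection",
    "PositionalType",
    "HitResult",
    "Diagnosis",
    "Label",
    "Criterion",
    "Step",
    "HitPolicy",
    "PatientFindings",
    "ClassifierConfig",
    "StandingResult",
    "classify",
    "enumerate_findings_space",
]


class NystagmusMode(str, enum.Enum):
    NONE = "NONE"
    SPONTANEOUS = "SPONTANEOUS"
    POSITIONAL = "POSITIONAL"


class SpontaneousDirection(str, enum.Enum):
    HORIZONTAL_UNIDIRECTIONAL = "HORIZONTAL_UNIDIRECTIONAL"
    MULTIDIRECTIONAL_OR_VERTICAL = "MULTIDIRECTIONAL_OR_VERTICAL"


class PositionalType(str, enum.Enum):
    TYPICAL_POSTERIOR_CANAL = "TYPICAL_POSTERIOR_CANAL"
    TYPICAL_LATERAL_CANAL = "TYPICAL_LATERAL_CANAL"
    ATYPICAL = "ATYPICAL"


class HitResult(str, enum.Enum):
    POSITIVE_SACCADE = "POSITIVE_SACCADE"
    NEGATIVE = "NEGATIVE"
    NOT_PERFORMED = "NOT_PERFORMED"


class Diagnosis(str, enum.Enum):
    """Reference-standard final diagnosis (central vs everything else)."""

    CENTRAL = "CENTRAL"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class Label(str, enum.Enum):
    CENTRAL = "CENTRAL"
    BPPV_POSTERIOR = "BPPV_POSTERIOR"
    BPPV_LATERAL = "BPPV_LATERAL"
    APV = "APV"
    BENIGN_OTHER = "BENIGN_OTHER"


class Criterion(str, enum.Enum):
    """Which worrisome rule fired (first match in evaluation order)."""

    MULTIDIRECTIONAL_OR_VERTICAL_NYSTAGMUS = "MULTIDIRECTIONAL_OR_VERTICAL_NYSTAGMUS"
    UNIDIRECTIONAL_HIT_NEGATIVE = "UNIDIRECTIONAL_HIT_NEGATIVE"
    UNABLE_TO_STAND = "UNABLE_TO_STAND"
    # only reachable under ClassifierConfig.atypical_positional_is_worrisome
    ATYPICAL_POSITIONAL_NYSTAGMUS = "ATYPICAL_POSITIONAL_NYSTAGMUS"
    NONE = "NONE"


class Step(str, enum.Enum):
    STEP1_NYSTAGMUS_TYPE = "STEP1_NYSTAGMUS_TYPE"
    STEP2_DIRECTION = "STEP2_DIRECTION"
    STEP3_HIT = "STEP3_HIT"
    STEP4_GAIT = "STEP4_GAIT"


class HitPolicy(str, enum.Enum):
    """What to do with a missing HIT in the unidirectional branch."""

    ERROR = "ERROR"
    ASSUME_NEGATIVE = "ASSUME_NEGATIVE"  # conservative: missing HIT flags central


@dataclass(frozen=True)
class PatientFindings:
    """One examinee's coded STANDING observations.

    ``spontaneous_direction`` must be present exactly when the nystagmus is
    spontaneous, ``positional_type`` exactly when it is positional, and the
    head-impulse test is only defined inside the horizontal-unidirectional
    branch (``hit_result`` must read ``NOT_PERFORMED`` everywhere else).
    """

    nystagmus_mode: NystagmusMode
    spontaneous_direction: SpontaneousDirection | None = None
    positional_type: PositionalType | None = None
    hit_result: HitResult = HitResult.NOT_PERFORMED
    can_stand_walk_unassisted: bool = True
    true_diagnosis: Diagnosis = Diagnosis.UNKNOWN

    def __post_init__(self) -> None:
        # coerce bare strings to their enums so records read from files or
        # built by hand validate identically
        coercions = (
            ("nystagmus_mode", NystagmusMode, False),
            ("spontaneous_direction", SpontaneousDirection, True),
            ("positional_type", PositionalType, True),
            ("hit_result", HitResult, False),
            ("true_diagnosis", Diagnosis, False),
        )
        for name, enum_cls, optional in coercions:
            value = getattr(self, name)
            if optional and value is None:
                continue
            if not isinstance(value, enum_cls):
                try:
                    object.__setattr__(self, name, enum_cls(value))
                except ValueError:
                    raise ValidationError(
                        f"'{value}' is not one of {[e.value for e in enum_cls]}",
                        field=name,
                    ) from None
        self.validate()

    def validate(self) -> None:
        spont = self.nystagmus_mode is NystagmusMode.SPONTANEOUS
        if spont and self.spontaneous_direction is None:
            raise ValidationError(
                "spontaneous nystagmus requires a direction",
                field="spontaneous_direction",
            )
        if not spont and self.spontaneous_direction is not None:
            raise ValidationError(
                "direction only meaningful for spontaneous nystagmus",
                field="spontaneous_direction",
            )
        positional = self.nystagmus_mode is NystagmusMode.POSITIONAL
        if positional and self.positional_type is None:
            raise ValidationError(
                "positional nystagmus requires a positional type",
                field="positional_type",
            )
        if not positional and self.positional_type is not None:
            raise ValidationError(
                "positional type only meaningful for positional nystagmus",
                field="positional_type",
            )
        unidirectional = (
            self.spontaneous_direction is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
        )
        if not unidirectional and self.hit_result is not HitResult.NOT_PERFORMED:
            raise ValidationError(
                "HIT is only defined in the horizontal-unidirectional branch",
                field="hit_result",
            )


@dataclass(frozen=True)
class ClassifierConfig:
    """Switches covering the decision rule's two textual ambiguities.

    gait_only_when_no_nystagmus
        The gait criterion reads "particularly when no nystagmus was
        found"; by default inability to stand is worrisome in every branch
        (the criteria form a plain disjunction).  Setting this restricts it
        to patients without any nystagmus, for sensitivity analysis.
    atypical_positional_is_worrisome
        Atypical positional nystagmus is not covered by the three worrisome
        criteria; by default such patients are routed through the gait
        step.  Setting this forces them to a central conclusion.
    hit_policy
        Whether a missing HIT in the unidirectional branch is an error
        (default) or is conservatively treated as negative.
    """

    gait_only_when_no_nystagmus: bool = False
    atypical_positional_is_worrisome: bool = False
    hit_policy: HitPolicy = HitPolicy.ERROR


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class StandingResult:
    worrisome: bool
    label: Label
    criterion: Criterion
    steps_traversed: tuple[Step, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.worrisome != (self.label is Label.CENTRAL):
            raise ValidationError("worrisome iff label CENTRAL", field="worrisome")
        if (not self.worrisome) != (self.criterion is Criterion.NONE):
            raise ValidationError("criterion NONE iff benign", field="criterion")


def classify(
    findings: PatientFindings, config: ClassifierConfig = DEFAULT_CONFIG
) -> StandingResult:
    """Run the four-step rule on one findings record.

    Returns exactly one :class:`StandingResult`; raises
    :class:`HitRequiredError` when the HIT is missing in the
    unidirectional branch under the default policy, and
    :class:`ValidationError` if the record violates its invariants.
    """
    findings.validate()
    steps: list[Step] = [Step.STEP1_NYSTAGMUS_TYPE]
    mode = findings.nystagmus_mode

    hit = findings.hit_result
    if mode is NystagmusMode.SPONTANEOUS:
        steps.append(Step.STEP2_DIRECTION)
        if findings.spontaneous_direction is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL:
            steps.append(Step.STEP3_HIT)
            if hit is HitResult.NOT_PERFORMED:
                if config.hit_policy is HitPolicy.ERROR:
                    raise HitRequiredError(
                        "HIT required in the unidirectional spontaneous branch"
                    )
                hit = HitResult.NEGATIVE
    # gait is evaluated in all patients
    steps.append(Step.STEP4_GAIT)

    # worrisome criteria, evaluated in their published order; first match wins
    criterion = Criterion.NONE
    if findings.spontaneous_direction is SpontaneousDirection.MULTIDIRECTIONAL_OR_VERTICAL:
        criterion = Criterion.MULTIDIRECTIONAL_OR_VERTICAL_NYSTAGMUS
    elif (
        findings.spontaneous_direction is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
        and hit is HitResult.NEGATIVE
    ):
        criterion = Criterion.UNIDIRECTIONAL_HIT_NEGATIVE
    elif not findings.can_stand_walk_unassisted and (
        not config.gait_only_when_no_nystagmus or mode is NystagmusMode.NONE
    ):
        criterion = Criterion.UNABLE_TO_STAND
    elif (
        config.atypical_positional_is_worrisome
        and findings.positional_type is PositionalType.ATYPICAL
    ):
        criterion = Criterion.ATYPICAL_POSITIONAL_NYSTAGMUS

    if criterion is not Criterion.NONE:
        return StandingResult(True, Label.CENTRAL, criterion, tuple(steps))

    if findings.positional_type is PositionalType.TYPICAL_POSTERIOR_CANAL:
        label = Label.BPPV_POSTERIOR
    elif findings.positional_type is PositionalType.TYPICAL_LATERAL_CANAL:
        label = Label.BPPV_LATERAL
    elif (
        findings.spontaneous_direction is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
        and hit is HitResult.POSITIVE_SACCADE
    ):
        label = Label.APV
    else:
        label = Label.BENIGN_OTHER
    return StandingResult(False, label, Criterion.NONE, tuple(steps))


def enumerate_findings_space(include_diagnosis: bool = False) -> list[PatientFindings]:
    """Every invariant-satisfying combination of the findings enums.

    The space is small (16 combinations ignoring the diagnosis label),
    which makes exhaustive totality and determinism checks cheap.  With
    ``include_diagnosis`` each combination is repeated for CENTRAL and
    OTHER truth labels.
    """
    out: list[PatientFindings] = []
    for mode in NystagmusMode:
        if mode is NystagmusMode.SPONTANEOUS:
            branch = [
                (SpontaneousDirection.MULTIDIRECTIONAL_OR_VERTICAL, None, [HitResult.NOT_PERFORMED]),
                (SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL, None, list(HitResult)),
            ]
        elif mode is NystagmusMode.POSITIONAL:
            branch = [(None, pt, [HitResult.NOT_PERFORMED]) for pt in PositionalType]
        else:
            branch = [(None, None, [HitResult.NOT_PERFORMED])]
        for direction, ptype, hits in branch:
            for hit, gait in itertools.product(hits, (True, False)):
                out.append(
                    PatientFindings(
                        nystagmus_mode=mode,
                        spontaneous_direction=direction,
                        positional_type=ptype,
                        hit_result=hit,
                        can_stand_walk_unassisted=gait,
                    )
                )
    if include_diagnosis:
        out = [
            replace(f, true_diagnosis=dx)
            for f in out
            for dx in (Diagnosis.CENTRAL, Diagnosis.OTHER)
        ]
    return out
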