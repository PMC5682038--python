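"""The four-step decision rule: published branch behavior and invariants."""

import itertools

import pytest
from dataclasses import replace

from standing_triage import (
    ClassifierConfig,
    Criterion,
    HitPolicy,
    HitRequiredError,
    HitResult,
    Label,
    NystagmusMode,
    PatientFindings,
    PositionalType,
    SpontaneousDirection,
    Step,
    ValidationError,
    classify,
    enumerate_findings_space,
)

from conftest import findings

TOTALITY_CONFIG = ClassifierConfig(hit_policy=HitPolicy.ASSUME_NEGATIVE)


@pytest.mark.parametrize(
    "kwargs, worrisome, label, criterion",
    [
        # multidirectional/vertical spontaneous nystagmus is a central sign,
        # whatever the gait
        (
            dict(mode="SPONTANEOUS", direction="MULTIDIRECTIONAL_OR_VERTICAL"),
            True, Label.CENTRAL, Criterion.MULTIDIRECTIONAL_OR_VERTICAL_NYSTAGMUS,
        ),
        (
            dict(mode="SPONTANEOUS", direction="MULTIDIRECTIONAL_OR_VERTICAL", can_stand=False),
            True, Label.CENTRAL, Criterion.MULTIDIRECTIONAL_OR_VERTICAL_NYSTAGMUS,
        ),
        # unidirectional + negative HIT -> central
        (
            dict(mode="SPONTANEOUS", direction="HORIZONTAL_UNIDIRECTIONAL", hit="NEGATIVE"),
            True, Label.CENTRAL, Criterion.UNIDIRECTIONAL_HIT_NEGATIVE,
        ),
        # unidirectional + catch-up saccade -> acute peripheral vestibulopathy
        (
            dict(mode="SPONTANEOUS", direction="HORIZONTAL_UNIDIRECTIONAL", hit="POSITIVE_SACCADE"),
            False, Label.APV, Criterion.NONE,
        ),
        # typical positional nystagmus -> canal-specific BPPV
        (
            dict(mode="POSITIONAL", positional="TYPICAL_POSTERIOR_CANAL"),
            False, Label.BPPV_POSTERIOR, Criterion.NONE,
        ),
        (
            dict(mode="POSITIONAL", positional="TYPICAL_LATERAL_CANAL"),
            False, Label.BPPV_LATERAL, Criterion.NONE,
        ),
        # no nystagmus: gait decides
        (dict(mode="NONE", can_stand=False), True, Label.CENTRAL, Criterion.UNABLE_TO_STAND),
        (dict(mode="NONE", can_stand=True), False, Label.BENIGN_OTHER, Criterion.NONE),
        # atypical positional with preserved gait routes benign by default
        (
            dict(mode="POSITIONAL", positional="ATYPICAL"),
            False, Label.BENIGN_OTHER, Criterion.NONE,
        ),
    ],
)
def test_published_branches(kwargs, worrisome, label, criterion):
    result = classify(findings(**kwargs))
    assert result.worrisome is worrisome
    assert result.label is label
    assert result.criterion is criterion


def test_steps_traversed_always_include_nystagmus_and_gait():
    """Every patient is assessed for nystagmus first and gait last."""
    for f in enumerate_findings_space():
        steps = classify(f, TOTALITY_CONFIG).steps_traversed
        assert steps[0] is Step.STEP1_NYSTAGMUS_TYPE
        assert steps[-1] is Step.STEP4_GAIT
        # direction only examined for spontaneous nystagmus; HIT only in
        # the unidirectional branch
        assert (Step.STEP2_DIRECTION in steps) == (
            f.nystagmus_mode is NystagmusMode.SPONTANEOUS
        )
        assert (Step.STEP3_HIT in steps) == (
            f.spontaneous_direction is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
        )


def test_totality_and_determinism():
    """Exactly one result for every point of the findings space, twice."""
    space = enumerate_findings_space()
    first = [classify(f, TOTALITY_CONFIG) for f in space]
    second = [classify(f, TOTALITY_CONFIG) for f in space]
    assert first == second
    assert len(first) == len(space)


def test_enumeration_matches_brute_force():
    """Independent cross-product-and-filter oracle for the findings space."""
    oracle = []
    for mode, direction, ptype, hit, gait in itertools.product(
        NystagmusMode,
        list(SpontaneousDirection) + [None],
        list(PositionalType) + [None],
        HitResult,
        (True, False),
    ):
        spont = mode is NystagmusMode.SPONTANEOUS
        positional = mode is NystagmusMode.POSITIONAL
        if (direction is not None) != spont:
            continue
        if (ptype is not None) != positional:
            continue
        uni = direction is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
        if not uni and hit is not HitResult.NOT_PERFORMED:
            continue
        oracle.append((mode, direction, ptype, hit, gait))
    space = enumerate_findings_space()
    assert len(space) == len(oracle) == 16
    keys = {
        (f.nystagmus_mode, f.spontaneous_direction, f.positional_type,
         f.hit_result, f.can_stand_walk_unassisted)
        for f in space
    }
    assert keys == set(oracle)
    # degenerate no-nystagmus branch present in both gait states
    assert findings(mode="NONE", can_stand=True) in space
    assert findings(mode="NONE", can_stand=False) in space


def test_monotone_alarm_on_gait():
    """Losing the ability to stand can never downgrade the conclusion."""
    for f in enumerate_findings_space():
        if not f.can_stand_walk_unassisted:
            continue
        fell = replace(f, can_stand_walk_unassisted=False)
        assert classify(fell, TOTALITY_CONFIG).worrisome >= classify(
            f, TOTALITY_CONFIG
        ).worrisome


def test_criterion_soundness():
    """The reported criterion's defining predicate holds on the input."""
    for f in enumerate_findings_space():
        r = classify(f, TOTALITY_CONFIG)
        if r.criterion is Criterion.MULTIDIRECTIONAL_OR_VERTICAL_NYSTAGMUS:
            assert f.spontaneous_direction is SpontaneousDirection.MULTIDIRECTIONAL_OR_VERTICAL
        elif r.criterion is Criterion.UNIDIRECTIONAL_HIT_NEGATIVE:
            assert f.spontaneous_direction is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
            # under the conservative policy a missing HIT counts as negative
            assert f.hit_result in (HitResult.NEGATIVE, HitResult.NOT_PERFORMED)
        elif r.criterion is Criterion.UNABLE_TO_STAND:
            assert not f.can_stand_walk_unassisted
        else:
            assert r.criterion is Criterion.NONE and not r.worrisome


def test_branch_exclusivity():
    """BPPV labels only from positional mode; APV only from uni + saccade."""
    for f in enumerate_findings_space():
        r = classify(f, TOTALITY_CONFIG)
        if r.label in (Label.BPPV_POSTERIOR, Label.BPPV_LATERAL):
            assert f.nystagmus_mode is NystagmusMode.POSITIONAL
        if r.label is Label.APV:
            assert f.spontaneous_direction is SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL
            assert f.hit_result is HitResult.POSITIVE_SACCADE


def test_hit_policy():
    """Missing HIT in the unidirectional branch: error or conservative flag."""
    f = findings(mode="SPONTANEOUS", direction="HORIZONTAL_UNIDIRECTIONAL", hit="NOT_PERFORMED")
    with pytest.raises(HitRequiredError):
        classify(f)
    r = classify(f, ClassifierConfig(hit_policy=HitPolicy.ASSUME_NEGATIVE))
    assert r.worrisome and r.criterion is Criterion.UNIDIRECTIONAL_HIT_NEGATIVE


def test_gait_only_when_no_nystagmus_flag():
    """Sensitivity-analysis flag restricts the gait criterion to the
    no-nystagmus branch."""
    restricted = ClassifierConfig(gait_only_when_no_nystagmus=True)
    bppv_fallen = findings(
        mode="POSITIONAL", positional="TYPICAL_POSTERIOR_CANAL", can_stand=False
    )
    assert classify(bppv_fallen).worrisome  # default: disjunction applies everywhere
    assert not classify(bppv_fallen, restricted).worrisome
    no_nyst_fallen = findings(mode="NONE", can_stand=False)
    assert classify(no_nyst_fallen, restricted).worrisome


def test_atypical_positional_flag():
    atypical = findings(mode="POSITIONAL", positional="ATYPICAL")
    assert not classify(atypical).worrisome
    forced = classify(atypical, ClassifierConfig(atypical_positional_is_worrisome=True))
    assert forced.worrisome
    assert forced.criterion is Criterion.ATYPICAL_POSITIONAL_NYSTAGMUS


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(nystagmus_mode=NystagmusMode.SPONTANEOUS), "spontaneous_direction"),
        (dict(nystagmus_mode=NystagmusMode.POSITIONAL), "positional_type"),
        (
            dict(
                nystagmus_mode=NystagmusMode.NONE,
                spontaneous_direction=SpontaneousDirection.HORIZONTAL_UNIDIRECTIONAL,
            ),
            "spontaneous_direction",
        ),
        (
            dict(nystagmus_mode=NystagmusMode.NONE, hit_result=HitResult.NEGATIVE),
            "hit_result",
        ),
        (
            dict(
                nystagmus_mode=NystagmusMode.SPONTANEOUS,
                spontaneous_direction=SpontaneousDirection.MULTIDIRECTIONAL_OR_VERTICAL,
                hit_result=HitResult.POSITIVE_SACCADE,
            ),
            "hit_result",
        ),
    ],
)
def test_invariant_violations_name_the_field(kwargs, field):
    with pytest.raises(ValidationError) as exc:
        PatientFindings(**kwargs)
    assert exc.value.field == field
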