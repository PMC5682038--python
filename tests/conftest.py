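import pytest

from standing_triage import (
    ConfusionTable,
    HitResult,
    NystagmusMode,
    PatientFindings,
    PositionalType,
    SpontaneousDirection,
    calibrate_from_table2,
)


def findings(
    mode="NONE",
    direction=None,
    positional=None,
    hit="NOT_PERFORMED",
    can_stand=True,
    diagnosis="UNKNOWN",
) -> PatientFindings:
    """Terse builder for findings records in tests."""
    return PatientFindings(
        nystagmus_mode=NystagmusMode(mode),
        spontaneous_direction=SpontaneousDirection(direction) if direction else None,
        positional_type=PositionalType(positional) if positional else None,
        hit_result=HitResult(hit),
        can_stand_walk_unassisted=can_stand,
        true_diagnosis=diagnosis,
    )


@pytest.fixture(scope="session")
def table2_confusion() -> ConfusionTable:
    """The published final-row confusion matrix: 38/2/42/270."""
    return ConfusionTable(tp=38, fn=2, fp=42, tn=270)


@pytest.fixture(scope="session")
def calibrated_params():
    return calibrate_from_table2()
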