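"""Published aggregate counts from the 352-patient validation cohort.

The study released no patient-level data; what it printed are aggregate
contingency rows — bedside findings by final-diagnosis class, the final
worrisome-vs-truth margin, and the diagnosis mix.  These counts are
packaged verbatim for exact replay of the headline accuracy numbers.

The findings-by-class rows are known to be internally inconsistent as a
joint table (the central column's modes sum to 41 of 40 patients, and the
head-impulse counts exceed the unidirectional count), so ``TABLE2_BY_ROW``
exposes each row independently and no patient-level reconstruction is
asserted.  Calibration of the generative model renormalizes per branch
(see :mod:`standing_triage.simulate`).
"""

from __future__ import annotations

import enum
from types import MappingProxyType
from typing import Any

from .errors import ValidationError

__all__ = ["TableFixture", "table_fixture", "N_TOTAL", "N_CENTRAL", "N_OTHER"]

N_TOTAL = 352
N_CENTRAL = 40
N_OTHER = 312


class TableFixture(str, enum.Enum):
    TABLE2_FINAL_ROW = "TABLE2_FINAL_ROW"
    TABLE2_BY_ROW = "TABLE2_BY_ROW"
    TABLE3_DIAGNOSES = "TABLE3_DIAGNOSES"


# final margin: worrisome conclusions by truth class
_TABLE2_FINAL_ROW = {
    "central": {"worrisome": 38, "total": N_CENTRAL},
    "other": {"worrisome": 42, "total": N_OTHER},
}

# per-finding rows, each (central count, other count); rows are independent
# margins, not a consistent joint table
_TABLE2_BY_ROW = {
    "positional_nystagmus": {"central": 3, "other": 185},
    "positional_lateral_canal": {"central": 1, "other": 70},
    "positional_posterior_canal": {"central": 2, "other": 115},
    "spontaneous_nystagmus": {"central": 18, "other": 70},
    "spontaneous_unidirectional": {"central": 3, "other": 61},
    "spontaneous_multidirectional_vertical": {"central": 15, "other": 9},
    "hit_positive": {"central": 2, "other": 50},
    "hit_negative": {"central": 3, "other": 9},
    "no_nystagmus": {"central": 20, "other": 56},
    "unable_to_stand_or_walk": {"central": 33, "other": 36},
    "conclusion_central": {"central": 38, "other": 42},
}

# final diagnoses; counts within each truth class
_TABLE3_DIAGNOSES = {
    "central": {
        "ischemic_stroke": 27,
        "hemorrhagic_stroke": 1,
        "cerebral_tumors": 10,
        "hydrocephalus": 1,
        "demyelinating_disease": 1,
    },
    "other": {
        "bppv": 176,
        "acute_peripheral_vestibulopathy": 56,
        "migraine": 19,
        "vertebro_basilar_insufficiency": 19,
        "menieres_disease": 4,
        "miscellaneous": 14,
        "undetermined": 24,
    },
}


def _freeze(obj: Any) -> Any:
    if isinstance(obj, dict):
        return MappingProxyType({k: _freeze(v) for k, v in obj.items()})
    return obj


_FIXTURES = {
    TableFixture.TABLE2_FINAL_ROW: _freeze(_TABLE2_FINAL_ROW),
    TableFixture.TABLE2_BY_ROW: _freeze(_TABLE2_BY_ROW),
    TableFixture.TABLE3_DIAGNOSES: _freeze(_TABLE3_DIAGNOSES),
}


def table_fixture(name: TableFixture | str) -> Any:
    """Return the named published-count fixture (read-only mapping)."""
    try:
        name = TableFixture(name)
    except ValueError:
        raise ValidationError(f"unknown fixture '{name}'", field="name") from None
    return _FIXTURES[name]
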