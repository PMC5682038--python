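"""Write a simulated cohort to CSV, read it back, and validate every row.

The cohort CSV dialect is deliberately rigid: comma-delimited, UTF-8,
fixed header, upper-snake-case enum strings, booleans as true/false.
Malformed rows are rejected with the row number and offending field.
"""

import tempfile
from dataclasses import replace
from pathlib import Path

from standing_triage import (
    ValidationError,
    calibrate_from_table2,
    generate,
    read_cohort,
    write_cohort,
)

cohort = generate(replace(calibrate_from_table2(), n=20, seed=5))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cohort.csv"
    write_cohort(cohort, path)
    print(path.read_text().splitlines()[0])        # the canonical header
    back = read_cohort(path)
    print(f"round-trip: {len(back.records)} records, identical={back.records == cohort}")

    bad = Path(tmp) / "bad.csv"
    text = path.read_text().splitlines()
    text[3] = text[3].replace("NONE", "SPONTANEOUS", 1)  # direction now missing
    bad.write_text("\n".join(text) + "\n")
    try:
        read_cohort(bad)
    except ValidationError as exc:
        print(f"rejected as expected -> {exc}")
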