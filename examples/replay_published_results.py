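"""Exact replay of the validation study's headline numbers.

The packaged aggregate counts (the findings-by-class rows, the final
worrisome-vs-truth margin, and the diagnosis mix of the 352-patient
cohort) are fed through confusion-table construction and the accuracy
panel, then compared with the published figures after integer rounding.
A few published cells are known to be irreproducible from the published
counts; they are reported as "paper-discrepant" rather than failed.
"""

from standing_triage import reproduce_paper, sample_size

report = reproduce_paper()
print(report.summary())

planned = sample_size(
    prevalence=0.10, expected_sensitivity=0.95, half_width=0.05, dropout_fraction=0.10
)
print(
    f"\nsample size by the standard precision formula "
    f"(10% prevalence, S=0.95, +/-5%, 10% dropout): {planned} patients"
)
print(
    "Note: the formula requires far more patients than the 330 the study "
    "planned; no standard\nvariant reproduces that figure from the stated "
    "inputs."
)
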