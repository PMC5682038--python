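"""Classify a handful of bedside findings records with the four-step rule.

Each patient is a coded set of observations: nystagmus mode (none /
spontaneous / positional), direction or canal type where applicable, the
head-impulse test result inside the unidirectional branch, and whether the
patient can stand and walk unassisted.  The classifier prints a worrisome
flag (suspected central vertigo), a specific benign label otherwise, and
which rule fired.
"""

from standing_triage import PatientFindings, classify

patients = {
    "vertical nystagmus, steady": PatientFindings(
        nystagmus_mode="SPONTANEOUS",
        spontaneous_direction="MULTIDIRECTIONAL_OR_VERTICAL",
    ),
    "unidirectional, HIT saccade": PatientFindings(
        nystagmus_mode="SPONTANEOUS",
        spontaneous_direction="HORIZONTAL_UNIDIRECTIONAL",
        hit_result="POSITIVE_SACCADE",
    ),
    "unidirectional, HIT negative": PatientFindings(
        nystagmus_mode="SPONTANEOUS",
        spontaneous_direction="HORIZONTAL_UNIDIRECTIONAL",
        hit_result="NEGATIVE",
    ),
    "posterior-canal positional": PatientFindings(
        nystagmus_mode="POSITIONAL", positional_type="TYPICAL_POSTERIOR_CANAL"
    ),
    "no nystagmus, cannot stand": PatientFindings(
        nystagmus_mode="NONE", can_stand_walk_unassisted=False
    ),
}

for description, findings in patients.items():
    result = classify(findings)
    flag = "WORRISOME" if result.worrisome else "benign   "
    print(f"{description:30s} -> {flag}  {result.label.value:15s} ({result.criterion.value})")

print(
    "\nWORRISOME means the rule suspects a central cause (stroke, tumor, "
    "demyelination)\nand the patient should get neuroimaging; benign labels "
    "name the likely inner-ear diagnosis."
)
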