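"""Simulate a 352-patient cohort, classify it, and compute the accuracy panel.

The generator draws a latent diagnosis class (central vertigo at ~11.4%
prevalence) and class-conditional bedside findings calibrated to the
published validation cohort, then the classifier's worrisome flag is
scored against the true class.  Because gait and nystagmus are sampled
independently given the class, the simulated panel approximates (rather
than replays) the published one — see examples/replay_published_results.py
for the exact replay.
"""

from dataclasses import replace

from standing_triage import (
    ClassifierConfig,
    HitPolicy,
    build_confusion,
    calibrate_from_table2,
    classify,
    diagnostic_metrics,
    generate,
)

params = replace(calibrate_from_table2(), n=352, seed=42)
cohort = generate(params)
config = ClassifierConfig(hit_policy=HitPolicy.ASSUME_NEGATIVE)

table = build_confusion(
    (classify(p, config).worrisome, p.true_diagnosis) for p in cohort
)
print(f"confusion table: TP={table.tp} FP={table.fp} FN={table.fn} TN={table.tn}")

panel = diagnostic_metrics(table, percent_decimals=0)
for name, m in panel.as_dict().items():
    print(f"{name:12s} {m.value:5.0f}%  (95% CI {m.ci_low:.0f}-{m.ci_high:.0f})")

print(
    "\nSensitivity is the share of central-vertigo patients flagged "
    "worrisome; the high NPV is\nwhat lets a benign result rule out a "
    "central cause at the bedside. Intervals are exact\n(Clopper-Pearson)."
)
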