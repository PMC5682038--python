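# standing-triage

Vertigo is one of the most treacherous presenting complaints in the
emergency department: the overwhelming majority of cases are benign inner-ear
disease, but a posterior-circulation stroke can present with vertigo alone —
and it is the symptom most often associated with a missed stroke diagnosis.
The STANDING algorithm is a four-step bedside decision rule that lets a
trained non-sub-specialist sort acutely vertiginous patients into "worrisome"
(suspected central cause, image the brain) and specific benign diagnoses:

1. **S**pon**TA**neous vs positional — is nystagmus present, spontaneous, or
   provoked by positioning maneuvers? Typical paroxysmal positional nystagmus
   on a canal plane means benign paroxysmal positional vertigo (BPPV).
2. **N**ystagmus **D**irection — multidirectional (gaze-evoked,
   direction-changing) or vertical spontaneous nystagmus is a central sign.
3. head **I**mpulse test (HIT) — within the horizontal-unidirectional branch,
   a corrective catch-up saccade indicates an acute peripheral
   vestibulopathy; its *absence* (negative HIT) indicates a central lesion.
4. sta**N**din**G** — every patient is asked to stand and walk; inability to
   do so unassisted is worrisome.

The conclusion is worrisome when at least one of three criteria holds:
multidirectional/vertical nystagmus, unidirectional nystagmus with negative
HIT, or inability to stand and walk.

This package is both the rule and the validation machinery around it:

- `standing_triage.algorithm` — a total, deterministic classifier over coded
  bedside findings, with an exhaustively enumerable input space and explicit
  configuration for the rule's textual ambiguities;
- `standing_triage.accuracy` — 2×2 confusion tables against the
  central-vertigo reference standard; sensitivity, specificity, PPV, NPV and
  accuracy with exact (Clopper–Pearson) or Wilson score intervals; the
  sample-size calculator for sensitivity-driven accuracy studies;
- `standing_triage.reliability` — Fleiss' multi-rater kappa (m ratings per
  subject, raters anonymous), per-step kappas on conditionally reached steps,
  and subject-level bootstrap intervals;
- `standing_triage.simulate` — a latent-class synthetic-cohort generator
  calibrated to the published 352-patient validation cohort (11.4% central
  prevalence), plus a rater-error model for reliability studies;
- `standing_triage.regression` — backward stepwise logistic regression for
  the added-diagnostic-value question;
- `standing_triage.replication` — exact replay of the published headline
  numbers from packaged aggregate counts;
- `standing_triage.io` — validated CSV/JSON cohort files and YAML classifier
  config.

## Worked example

```python
from standing_triage import PatientFindings, classify

result = classify(PatientFindings(
    nystagmus_mode="SPONTANEOUS",
    spontaneous_direction="HORIZONTAL_UNIDIRECTIONAL",
    hit_result="NEGATIVE",
))
print(result.worrisome, result.label.value, result.criterion.value)
# True CENTRAL UNIDIRECTIONAL_HIT_NEGATIVE
```

Simulating a full validation study (`examples/evaluate_accuracy.py`) draws a
352-patient cohort at the published calibration, classifies it, and scores
the worrisome flag against the latent truth:

```
confusion table: TP=36 FP=58 FN=3 TN=255
sensitivity     92%  (95% CI 79-98)
specificity     81%  (95% CI 77-86)
ppv             38%  (95% CI 28-49)
npv             99%  (95% CI 97-100)
accuracy        83%  (95% CI 78-86)
```

Sensitivity is the share of true central-vertigo patients flagged worrisome;
the very high negative predictive value is what makes a benign conclusion
safe grounds for withholding urgent neuroimaging. (The simulated panel
approximates the published one because gait and nystagmus are sampled
independently given the diagnosis class; the exact published panel —
sensitivity 95%, specificity 87%, PPV 48%, NPV 99%, accuracy 88% — is
replayed from the packaged counts by `examples/replay_published_results.py`.)

The other examples each demonstrate one capability: `classify_patients.py`
(the rule on individual records), `interrater_reliability.py` (per-step
Fleiss kappas under a rater-error model), `added_value.py` (backward
stepwise logistic regression retaining the triage flag with a large odds
ratio), `cohort_files.py` (validated cohort CSV round-trips), and
`replay_published_results.py` (the replication report and sample-size
formula).

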