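# Methods

## The decision rule

The classifier is a literal encoding of the four-step bedside sequence as a
total function over coded findings. A findings record has a nystagmus mode
(none / spontaneous / positional), a direction for spontaneous nystagmus
(horizontal-unidirectional vs multidirectional-or-vertical), a canal type for
positional nystagmus (typical posterior, typical lateral, atypical), a
head-impulse result defined only inside the unidirectional branch, and a
gait flag. Invariants tie the optional fields to the mode, so the reachable
input space is finite (16 combinations) and the classifier is tested
exhaustively for totality, determinism, criterion soundness and branch
exclusivity.

The worrisome criteria are evaluated as a disjunction in the rule's own
order — (a) multidirectional/vertical nystagmus, (b) unidirectional
nystagmus with negative HIT, (c) unable to stand and walk — and the first
matching criterion is reported for the audit trail; the order affects only
the report, never the flag.

Three points in the rule's published description are genuinely ambiguous,
and each is an explicit configuration switch rather than a silent choice:

- **Gait scope** (`gait_only_when_no_nystagmus`, default off). The gait
  criterion is phrased "particularly when no nystagmus was found", which
  could be read as restricting it to the no-nystagmus branch. The default
  applies it in every branch, matching the plain "at least one of the
  following" disjunction; the switch enables the restricted reading for
  sensitivity analysis.
- **Atypical positional nystagmus** (`atypical_positional_is_worrisome`,
  default off). Atypical positional nystagmus is covered by none of the
  three criteria. The default routes such patients through the gait step,
  consistent with the observation that the validation study's two false
  negatives were positional cases (had atypicality been auto-worrisome, at
  least some would likely have been flagged). The switch forces a central
  conclusion instead, and then reports a dedicated criterion value
  (`ATYPICAL_POSITIONAL_NYSTAGMUS`), a deliberate extension of the criterion
  vocabulary reachable only under this non-default flag.
- **Missing HIT** (`hit_policy`, default `ERROR`). A missing head-impulse
  test inside the unidirectional branch is an error by default (the rule
  cannot proceed); `ASSUME_NEGATIVE` is the conservative alternative that
  treats the missing maneuver as a central sign. Simulation pipelines use
  `ASSUME_NEGATIVE` so the classifier is total.

Multi-canal positional disease cannot be encoded: the schema forces one
positional type per record, so such patients must be coded as the treated
canal.

## Accuracy statistics

Sensitivity, specificity, predictive values and accuracy are the textbook
fractions of the 2×2 table of worrisome conclusion against the
central-vertigo reference standard. A metric with a zero denominator is
reported as missing, never as 0 or 100 — in small simulated cohorts an empty
margin is common and silently substituting a number would bias summaries.

Binomial confidence intervals default to Clopper–Pearson (exact
beta-quantile); Wilson score intervals are selectable. The published
intervals state no method and are mutually inconsistent — the sensitivity
(83–99 for 38/40) and NPV (97–100 for 270/272) intervals match
Clopper–Pearson exactly, while the published specificity and PPV intervals
match neither the exact nor the score interval — so interval method is a
user choice and only point estimates are replayed.

Percentages are rounded **half away from zero** (82.5 → 83, 37.5 → 38,
47.5 → 48), zero decimals for panel tables and one decimal for prevalence;
this is the only convention that reproduces the published integers from the
underlying fractions, and it differs from Python's default banker's
rounding.

The sample-size calculator is the standard precision formula: diseased
subjects needed = ⌈z²·S(1−S)/d²⌉ for expected sensitivity S and CI
half-width d, divided by prevalence and inflated for dropout. With 10%
prevalence, S = 0.95, d = 0.05 and 10% dropout this gives 73 diseased → 730
total → 812 after dropout. The 330 quoted for this design is not
reproducible from any standard variant of the formula with those inputs; the
package implements the formula and documents the discrepancy rather than
matching the quoted number.

## Reliability

Fleiss' kappa is computed from an n×k count matrix with m ratings per
subject. With rotating anonymous rater pairs (2 of 6 physicians), the Fleiss
formulation is the correct one despite m = 2 inviting Cohen's kappa, which
assumes two fixed identified raters. When every rating falls in one category
the chance agreement is 1 and kappa is undefined; this raises an error
rather than returning NaN.

Per-step kappas use only subjects that **both** raters routed to the step
(direction is only rated if the rater saw spontaneous nystagmus; the HIT
only inside the rater's unidirectional branch). This is the only inclusion
rule that never fabricates a rating; it does mean conditional steps are
estimated on smaller, rater-dependent subsets. A step with fewer than two
doubly-rated subjects, or with undefined kappa, is reported as not
estimable.

Kappa intervals are percentile bootstrap over subjects (default 2000
resamples, seeded); degenerate resamples are redrawn with a cap. Published
step kappas (overall 0.83, steps 0.95/0.74/0.81/0.83) rest on unpublished
rater-level data and serve only as plausibility anchors for the simulation,
not as targets.

## The synthetic cohort

The generator is a two-class latent-class model: diagnosis class (central
vs other) at prevalence 40/352 ≈ 11.4%, then a class-conditional categorical
over six mutually exclusive presentations (no nystagmus; lateral-canal,
posterior-canal or atypical positional; unidirectional or
multidirectional/vertical spontaneous), a class-conditional probability of a
negative HIT inside the unidirectional branch, and a class-conditional
probability of being unable to stand.

Calibration takes the published class-conditional counts as they stand. Two
published inconsistencies force per-branch renormalization: the central
column's presentation counts sum to 41 of 40 patients, and its HIT results
sum to 5 against 3 unidirectional patients. Each class profile is therefore
normalized over its own sum and the HIT split over the printed
positive+negative total; the renormalizations applied are recorded in the
returned parameters' provenance notes. The replay fixtures keep every
printed row untouched. The atypical-positional category receives probability
0 in both classes because the published canal counts exhaust the positional
total.

Gait is drawn independently of the presentation **given the class**, because
only marginal frequencies were published. Consequence: simulated cohorts
reproduce the class-conditional marginals (verified to 3 binomial standard
errors at n = 100,000) and an accuracy panel close to, but not exactly, the
published one — the implied sensitivity is ≈ 90% rather than 95% because in
the real cohort inability to stand was concentrated in the central patients
whose nystagmus findings were unrevealing. A green simulation test therefore
establishes the generator's own self-consistency and the pipeline's
correctness, not exact agreement with the published panel; exact agreement
is established separately by replaying the packaged counts.

The rater-error model gives each of two raters an independent noisy
observation of every step (flip to a uniformly random other category with a
per-step probability in [0, 0.5]), re-routes each rater's observed findings
through the classifier so that a step-1 error propagates to which downstream
steps exist for that rater, and optionally flips the routed overall
conclusion. When a rater misperceives the mode (e.g. sees spontaneous
nystagmus where the truth is positional) downstream truths do not exist and
the affected observation is drawn uniformly; positional subtype is not a
rated step, so a rater's positional observation is routed as a typical type,
which is conclusion-equivalent under the default configuration. Seeds are
explicit everywhere; identical seeds give identical cohorts and ratings.

## Added-value regression

Logit-link binomial fits by maximum likelihood (IRLS via statsmodels), Wald
z tests, and Wald intervals on odds ratios. Backward elimination removes the
predictor with the largest Wald p ≥ 0.05 (the conventional retention
threshold) and refits until all retained predictors are significant; ties on
the maximal p-value remove the lexicographically last name, making the
procedure deterministic and column-order invariant. If everything is
eliminated an intercept-only fit is returned with a status flag. Wald rather
than likelihood-ratio tests are used for elimination, matching common
practice for this design.

Complete or quasi-complete separation raises an explicit error: statsmodels'
separation signal is escalated, and any fitted |coefficient| above 20 (odds
ratio beyond ~5·10⁸) is treated as numerical divergence. The published
added-value odds ratio (OR 122, CI 15–943) suggests near-separation in the
original data and cannot be reproduced without the unpublished patient-level
covariates; it is not a target.

## Replay of published numbers and known discrepancies

The replication report expands the packaged final margin (38/2/42/270) into
records, tallies and scores them, does the same for each step as a
standalone test from the findings-by-class rows, and computes the diagnosis
shares. All headline values — sensitivity 95, specificity 87, PPV 48, NPV
99, accuracy 88, prevalence 11.4, step-level sensitivities 45/38/83,
ischemic-stroke share 67.5, BPPV share 56.4 — reproduce exactly under the
documented rounding.

Cells that do not reproduce are flagged `expected_discrepant` and reported
without being asserted: the published step-1 specificity (77 vs computed
78), step-4 specificity (89 vs 88) and step-4 NPV (97 vs 98) differ by one
point from any value derivable from the published counts, and the entire
published "negative head impulse test" row (sensitivity 95, specificity 18)
cannot be derived from the published HIT counts under any direct standalone
reading of that step — its computation basis is unstated. Honest reporting
with a flag was chosen over either asserting irreproducible numbers or
dropping the row.

## Numerical choices

- Rounding: half away from zero, snapped at 9 decimals first so ties stored
  imprecisely in binary still round up.
- Clopper–Pearson boundary cases pinned: 0 successes → lower bound 0;
  n successes → upper bound 100.
- Kappa undefined threshold: chance agreement within 1e-12 of 1.
- Logit convergence: statsmodels defaults with tol 1e-8, 200 iterations.
- One root seed per operation; numpy `default_rng` throughout.

## Limitations

- The generator emulates class-conditional marginals only; joint
  gait-by-finding structure within class is unpublished and not modeled.
- Truth labels are generated directly; imaging, follow-up and adjudication
  are outside scope, as are comparator rules (HINTS, ABCD₂) and the
  TIA-reclassification sensitivity analysis.
- Reliability simulations are plausibility checks; published kappas are not
  reproducible without rater-level data.
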