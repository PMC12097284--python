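# Methods

This note documents the models, conventions and design choices behind
`rwpfs`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical details a
user reproducing or extending the analyses should know.

## Text annotation

The reference annotator is deterministic and rule-based.  Candidate
sentences are proposed by a case-insensitive regular-expression lexicon
(`AnnotatorConfig.progression_patterns`); a parallel lexicon
(`disease_patterns`) drives positive disease-confirmation sentences used
for cohort attrition.  Labels follow the cue-scope heuristics of the
NegEx/ConText family:

- **certainty** — NO when a negation cue ("no evidence of", "without",
  "negative for", ...) occurs to the *left* of the pattern match within
  the same sentence (scope runs to the end of the sentence by default;
  `negation_scope_tokens` can bound it), MAYBE when a hedge cue
  ("possible", "suspicious for", "cannot exclude", ...) co-occurs, else
  YES;
- **subject** — FAMILY when a family cue ("mother", "sister", "family
  history", ...) co-occurs, else PATIENT;
- **temporality** — HISTORY when a history cue ("history of",
  "previously", "status post", ...) co-occurs, else CURRENT.

The reference implementation emits confidence 1.0 for every decided
label.  The downstream relevance threshold (`min_confidence`, default
0.9) is therefore only exercised by model-backed annotators or simulated
confidences; it is kept in the contract because the selection rule is
defined on (label, confidence) pairs, not labels alone.  The FUTURE and
OTHER label values exist for contract completeness; the reference rules
never emit them.

Section headers are detected from colon-terminated lines, all-caps lines,
or a configurable lexicon; text before the first header forms a
"preamble" section.  Sentences are split on terminal punctuation with an
abbreviation guard.  All lexicons are repo conventions, overridable in a
YAML/JSON config; none is a claim about any proprietary configuration.

## Selection conditions

A mention becomes a progression capture when it is (1) relevant —
YES/PATIENT/CURRENT at confidence ≥ 0.9; (2) not filed under an excluded
section (defaults: "past history", "past medical history", "past surgical
history" — the latter two are conservative synonyms of the first); and
(3) the first chronological instance of its normalized sentence for that
patient.  Normalization lowercases, collapses whitespace and strips edge
punctuation, so copy-forwarded text that differs only in formatting
deduplicates.  Date ties break on the smallest note id; deduplication is
per patient across note types.  Mentions with no identifiable section are
retained, since the exclusion is defined only for identified sections.
Each condition can be skipped independently, which is exactly how the
ablation analysis is implemented; skipping a condition can only enlarge
the capture set.

## Structured events

ICD matching is prefix-based on the dot-stripped, uppercased code, so
"C50.9" matches prefix "C50" (the children-code convention).  NLP disease
evidence requires strictly more than 4 positive disease sentences; the
evidence date is the day the count first exceeds the threshold, and the
earlier of the code route and the sentence route wins.

The index date is the start of *concurrent* exposure: each regimen drug
contributes its first order strictly after the metastasis date; if all
first orders fall within a 30-day concurrency window, the latest of them
is the index.  The window is an artifact parameter — the anchoring
convention is "first structured order of the combination" and the
30-day window is the conservative reading of "combination".

Line advancement is the earliest order of a *new* second-line candidate
drug at least 60 days (washout) after the index, where "new" means the
drug has no order at any earlier date.  Drug names are matched exactly on
a lowercase canonical form after a small synonym map; no RxNorm dependency
at this scale.

ECOG eligibility takes the record nearest the index within ±60 days
(equidistant ties resolve to the earlier record) and requires score < 3.
Patients with no in-window record are excluded.  Age uses birth year only
(the deidentified-data convention), evaluated at the index date.

## Survival definitions

- rwPFS event: the earlier of the first capture dated more than 30 days
  after the index (earlier captures are dropped, not the patient) and the
  line-advancement date.  A progression/advancement same-day tie counts as
  progression; an event on the censor date counts as an event.
- rwPFS censoring: the earliest of death, last encounter and study end,
  with tie priority death > last encounter > end of study.  Death is a
  censoring reason by default; the sensitivity analysis flips it to an
  event.
- rwOS: index to death; censoring at last encounter or study end.
- Durations convert days to months by 30.4375 (mean Gregorian month),
  defined once in `rwpfs.survival.MONTH_DAYS`.

Curves come from lifelines' product-limit estimator.  The curve object
carries the Greenwood variance Var[S(t)] = S(t)² Σ dᵢ/(nᵢ(nᵢ−dᵢ)); the
median is the first event time with S(t) ≤ 0.5 and its 95% CI intersects
the log(−log) (Kalbfleisch-Prentice) pointwise bands with 0.5 — the same
convention lifelines uses, cross-checked against it in the tests.  A
median or bound that never crosses is reported as "not reached" (None).
The log-rank test is the standard two-group chi-square with 1 df.

## Validation metrics

Patient-level validation is temporality-aware over each patient's single
first capture: TP within ±30 days of the manual date; FP when there is no
manual event or the capture is more than 30 days early; FN when the
manual event is missed or captured more than 30 days late; TN when
neither source has an event.  Metrics with zero denominators are reported
as undefined, never zero.

`recover_confusion_matrices` inverts rounded printed metrics to the
integer matrices consistent with them, using exact rational arithmetic
and half-up rounding at the printed precision.  It enumerates the
positives split and prunes with the sensitivity/specificity windows, so
n = 1000 recovers in milliseconds.  This is the oracle used to check
metric bookkeeping against published validation tables; where a table's
base metrics admit several matrices, only joint consistency (a nonempty
solution set under all printed values) is asserted.

## PHQ-8 statistics

Peak reduction is the largest decrease over *all* ordered chronological
score pairs (i < j), floored at zero; cumulative decline is the sum of
positive decreases over the same pairs.  "All pairs" is the literal
reading of the definition; a consecutive-pairs mode is available via
`consecutive_only=True`.  Patients need ≥ 2 in-window scores.  Groups are
compared with the pooled (Student) two-sample t test — the published
df = n₁ + n₂ − 2 identifies the pooled rather than Welch variant.  The
closed-form t computed from rounded group summaries differs slightly from
a t computed on unrounded data; the package asserts its own closed form.

## Synthetic cohort generator

The generator emulates the study conditions the workflow assumes:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 316 | cohort size |
| `true_median_pfs_months` | 20 | median of the true PFS distribution |
| `pfs_distribution` | exponential | rate = ln 2 / median; Weibull optional |
| `median_os_months` | 84 | death times (median OS beyond follow-up) |
| `median_dropout_months` | 60 | loss to follow-up |
| `enrollment` | 2015-01 – 2016-12 | metastasis dates; study ends 2021-12 |
| `encounter_interval_days` | 45 | routine visit cadence |
| `copy_forward_probability` | 0.3 | verbatim repeat of the progression sentence |
| `redocumentation_probability` | 0.5 | re-described progression, new wording |
| `negated_sentence_rate` | 0.15 | "no evidence of progression" per pre-event note |
| `hedged_rate` | 0.05 | hedged progression sentences |
| `family_history_rate` | 0.05 | family-subject progression sentences |
| `past_history_rate` | 0.05 | history-cue sentences and Past-History sections |
| `radiology_coverage` | 0.55 | progressions with an in-network radiology report |
| `doc_delay_probability` | 0.2 | clinical documentation delayed 30–75 days |
| `second_line_probability` | 0.5 | second-line drug order after progression |
| `phq8_visit_rate` | 0.3 | patients with a PHQ-8 series |

Design notes:

- OS and drop-out medians are set so that roughly 63% of patients
  progress before censoring, the regime the workflow is meant to operate
  in, and so that median overall survival is not reached within typical
  follow-up.
- Documentation lags truth by a uniform 0–14 days (30–75 with probability
  `doc_delay_probability`, emulating outside imaging documented late), so
  the ±30-day validation window is meaningfully exercised and a realistic
  share of first captures is more than 30 days late (honest false
  negatives at default settings).
- Radiology reports cover 55% of progressions with a short lag, so pooled
  captures draw on both sources and source-stratified medians diverge.
- Re-documentation matters: clinicians re-describe a progression in later
  notes with new wording, not only verbatim copy-forwarding.  Without it,
  the 30-day early-exclusion rule would permanently delete the events of
  early progressors, which real notes would not do.
- Deceased patients get a terminal encounter on the death date, so death
  (rather than an earlier routine visit) is their censoring reason, as a
  real cohort's censoring breakdown reports it.
- Encounters continue up to 180 days past the analytic study end for
  active patients, so end-of-study censoring is distinguishable from loss
  to follow-up.
- Randomness: every draw comes from a per-patient, per-record-type
  `numpy` generator seeded by (seed, patient index, stream), so output is
  bit-reproducible and adding patients never perturbs earlier patients.

What the generator does **not** emulate: realistic clinical prose,
inter-annotator disagreement, graded model confidences (all simulated
sentences are labeled at confidence 1.0 by the reference annotator),
coding errors in structured data, and sentence-level label noise.
Passing tests therefore demonstrate that the workflow's logic is correct
under its stated assumptions — not that any particular accuracy would be
achieved on real clinical text, where the annotator's lexicons would need
tuning and a model-backed engine would supply calibrated confidences.

## Problem sizes and seeds

The test suite and acceptance script run the full workflow at the study
size (n = 316); parameter-recovery checks use 20 seeded replicates, and
sensitivity analyses use 20 repetitions per missingness fraction.
Smaller cohorts (25–200 patients) back the structural and ablation tests.
All stochastic tests fix their seeds.

## Known limitations

- The rule-based annotator is a reference implementation of the
  annotation contract, not a clinical-grade NLP engine; its cue lists are
  deliberately small.
- Negation scope is a left-cue heuristic; scoped constructions ("no
  change in the known progressive disease") can mislabel.
- The censoring rule takes the earliest of death, last encounter and
  study end; a death recorded after a long documentation gap therefore
  censors at the last encounter, which undercounts death censoring in
  cohorts with ragged follow-up.
- Drug matching is exact-name after a small synonym map; free-text or
  compound medication entries are out of scope.
- Subgroup and source-stratified analyses refit on partitions of one
  cohort; no covariate adjustment or matching is provided.
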