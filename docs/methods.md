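# Methods

`prodrome` implements an end-to-end analysis of longitudinal electronic
health records for depression: rule-based cohort phenotyping, prediction of
a future depression diagnosis from horizon-truncated histories, assessment
of baseline severity, prediction of treatment response, and a screen for
treatment moderators. Because the clinical datasets such analyses run on
are proprietary, the package ships first-class synthetic-data generators
that reproduce the statistical structure each stage assumes; every claim in
the test suite is a property of that generative design, not of any real
patient population.

## Phenotyping model

A patient is a depression **case** when the record contains all three of:

1. a depression ICD-9 code — the 296.2x / 296.3x major-depressive families
   (fifth digit ignored), 296.82, 298.0, 300.4, or 311;
2. a depression disorder term in clinical text, neither negated nor
   attributed to family history;
3. a mention of a depression-specific antidepressant ingredient.

The term set is built by expanding a small seed set of disorder concepts
two rounds down an is-a ontology (round count configurable; the expansion
is monotone and idempotent once the reachable set is exhausted), then
filtering a curated blocklist. Ingredients come from a drug-indication
table: ingredients of depression-indicated drugs minus any ingredient that
also appears in a drug with a different primary indication. Both
terminologies ship as small toy stand-ins for the licensed vocabularies
(UMLS, RxNorm, Medi-Span) a deployment would substitute.

The **index date** is the earliest date by which both a qualifying code and
a qualifying ingredient mention have occurred (the later of the two first
occurrences). Cases need ≥ 548 days (1.5 years) of visits before the
index and ≤ 100 days between the first code and the first ingredient
mention; the gap is unsigned. **Controls** carry no depression code and no
depression term mention at all — we adopt the strict reading under which
even a negated mention disqualifies. Each case is matched to six controls
drawn uniformly without replacement from the pool with identical integer
age at the case's index date and identical 183-day history-length bin;
cases with insufficient stratum candidates are reported, never silently
dropped. Matching without replacement across the whole cohort prevents a
control from serving two cases.

## Features and truncation

Histories become binary indicator matrices: one column per ICD-9 code and
per usable (non-negated, non-family-history) text concept, a one-hot
visit-rate bin, gender, and — for the treated cohort — age and optionally
the baseline PHQ-9 score as numeric columns. Visit rate is visits per day
of history times 365 (a single-visit record divides by one day), binned
into [0,2), [2,4), …, [18,∞) visits/year. Everything that defines the
phenotype is removed from the matrix and logged, as is any PHQ-9-derived
column in the severity task.

Truncation cutoffs (0, −183, −365 days relative to the index) simulate
early prediction. Training uses the cutoff-0 matrix: cases truncated at
their index, controls with full history. Test matrices apply the offset to
cases *and* to controls relative to their end of history — the sources do
not say whether control test histories were truncated; we truncate so that
truncated case and control histories stay comparable, which also keeps the
no-signal configuration genuinely null. Per patient, indicator sets nest
across cutoffs by construction.

For the treated cohort, events in the 10-day window before the first
treatment start (and everything after it) are hidden, so the models see
pre-treatment history only.

## Models

All classifiers are L1-penalised (LASSO) logistic regressions. Columns are
scaled to unit variance without centring (preserving sparsity); the penalty
is chosen by 10-fold stratified cross-validation over a log-spaced path
from the critical penalty (all coefficients zero) downward, with the
one-standard-error rule. The path search stops three grid points past the
deviance minimum — the dense tail is never the 1-SE choice. Fits use
liblinear with `intercept_scaling=100`, because liblinear L1-penalises its
intercept and, at strong penalties, dense uncentred columns would otherwise
impersonate it and corrupt the path. Reported coefficients are mapped back
to the original scale; feature *ranking* uses standardised magnitudes so
binary indicators and numeric columns compare fairly.

Discrimination is summarised by the empirical ROC curve, trapezoidal AUC,
a 95% DeLong confidence interval (cross-checked against R pROC in the test
suite; a percentile bootstrap is available), and sensitivity at requested
specificities by linear interpolation. Ties in scores receive half credit,
the Mann–Whitney convention.

Three experiments: **diagnosis** (one model, one shared 80/20 stratified
patient partition, evaluated on the three per-cutoff test matrices),
**response** (per modality — medication or psychotherapy — predicting a
≥ 5-point PHQ-9 drop from baseline to the ~90-day follow-up; patients
starting both modalities the same day are excluded), and **severity**
(severe, PHQ-9 > 19, versus minimal/mild, ≤ 9; moderate groups excluded;
the baseline score itself is excluded and a leakage guard errors if any
PHQ-9-derived column reaches the design matrix).

## Outcomes

PHQ-9 totals (0–27) map to minimal (0–4), mild (5–9), moderate (10–14),
moderately severe (15–19) and severe (20–27). Improvement is a decrease of
at least five points. Note a 5-point drop need not change severity level
(27 → 22 stays severe); the 5-point rule is primary. Only the first
treatment per patient counts; two modalities starting the same day collapse
to `both`.

## Moderator screen

Candidate moderators are ranked by information gain — the reduction in
outcome entropy conditional on the feature, base-2, with 0·log 0 = 0 —
against a binary outcome: by default |change| ≥ 5 points in either
direction, optionally the one-sided improvement label. The top k = 100
(ties broken by feature id; near-constant columns outside [2%, 98%]
prevalence are dropped first) enter a logistic model with a boolean
treatment vector (1 = medication) and feature × treatment products; Wald
p-values on the interactions are reported raw and Benjamini–Hochberg
adjusted, with significance called at BH 0.05. Baseline PHQ-9 stays in the
model as a main-effect covariate — it is the strongest outcome predictor
and would head any screened list. Two model forms are provided: the single
joint model, and per-feature models (intercept, feature, treatment,
product), the stable choice when the 2k+2-parameter joint design is too
collinear for trustworthy Wald intervals at the available sample size.
Non-estimable interactions (separation, exploding standard errors) are
flagged, not dropped. With the one-sided improvement outcome, patients
whose baseline is below 5 are excluded as structural zeros: they cannot
drop five points, and keeping them biases every coefficient toward null.

## Synthetic populations

**Primary-care mode.** Follow-up spans are exponential with an 8-year
mean; visits are a homogeneous Poisson process at 4.2 visits/year, with
Poisson numbers of coded diagnoses (mean 2.0/visit) and annotated text
terms (1.9/visit) drawn from a Zipf-like rank distribution over synthetic
vocabularies; term mentions are negated with probability 0.05 and
family-history-flagged with probability 0.03. A deterministic
round(prevalence × n) patients are cases (prevalence 1/7 by default, so the
14.3% depressed fraction is exact). Cases carry the three phenotype
markers clustered within ≤ 30 days of a latent index date (so the 100-day
gap rule always passes and the recovered index equals the latent one) and
accumulate 20 prodromal signal features whose per-visit presence odds are
multiplied by `signal_strength` (default 4) inside a 400-day pre-index
window; base presence rate 0.02 per visit per feature. Signal mentions are
drawn as a thinned Poisson mention process whose per-visit, per-feature
presence probability is exactly the configured Bernoulli rate — duplicates
are repeat mentions, and all downstream features are presence-based. Ages
are uniform 18–85; dates are integer day offsets from a fixed epoch.

Two placement choices are load-bearing. The index falls 0–90 days before
the end of a case's record: with history-length-matched controls, an index
deep inside the record would make truncated case histories systematically
shorter than control histories, leaking case status through background
feature prevalence — with this placement (plus symmetric control
truncation), the no-signal configuration yields AUC ≈ 0.5. And in matched
mode each control copies the age and 183-day history bin of a template
case, so 1:6 matching always succeeds — mirroring a fully matched design.

**Treated-cohort mode.** Baseline PHQ-9 scores follow the five-bin
severity mix of a large treated cohort (bin weights 267 : 747 : 1294 :
1652 : 1301 — these printed bin counts sum to 5261 although the cohort is
quoted as 5651 patients; we use the proportions and leave the discrepancy
documented rather than resolved), uniform within bin. First-treatment
modality is medication / psychotherapy / both with the printed proportions
(2472 : 2401 : 778 of 5651); `both` patients emit two same-day treatment
rows and are excluded from single-modality models. Improvement follows a
logistic model in baseline score and modality:

    logit P(improve) = 1.8512 − 0.15·baseline + 1.372·medication
                       [+ β·feature·medication for a planted moderator]

The slope, intercept and modality effect are the package's calibration:
with the default severity mix they reproduce marginal improvement rates of
63.8% (medication) and 36.9% (psychotherapy) exactly, accounting for the
floor effect — a baseline below 5 cannot drop five points, so those draws
can never manifest as improvement. The floor also dictates the slope
magnitude: at mild slopes the forced non-improvement of minimal-severity
patients (who sit at extreme leverage) almost exactly cancels the linear
baseline–outcome association, leaving baseline undetectable to a linear
model; −0.15/point keeps baseline severity the dominant, recoverable
signal, as the design intends. The follow-up score is baseline − Δ with
Δ = 5 + Poisson(3) when the improvement draw fires and uniform on
{−8, …, 4} otherwise, clipped to [0, 27]; Δ beyond the threshold is noise
and not identified. Twenty history features carry severity-linked signal
(per-visit presence odds × e^0.08 per baseline point above 13.5), making
pre-treatment history informative about severity. An optional planted
moderator is a per-patient feature (prevalence 0.3, 1–3 pre-blackout
mentions) whose interaction log-odds apply under medication only.

### What the generators do not emulate

No comorbidity or temporal correlation structure beyond the planted
signals; no clinical note text (term events arrive pre-annotated and
pre-flagged); no care-seeking feedback between illness and visit rate; no
misdiagnosis or chart-review error. Passing tests therefore demonstrate
that the pipeline's logic and statistics behave as specified under a known
generative model — not that comparable accuracy would be achieved on real
records.

## Problem sizes and test design

The statistical suite runs the full chain at the sizes the properties are
stated for: horizon decay and null calibration on 7000-patient populations
over five seeds; moderator type-I error on 200 replicate 2000-patient
cohorts (raw rejection in [0.03, 0.07]); moderator power on 50 replicate
5000-patient cohorts with a planted interaction odds ratio of 2 (BH
detection ≥ 80%); baseline-severity dominance on five treated cohorts at
the default 5651 patients. Exact oracles (all-pairs concordance for AUC,
direct entropy arithmetic for information gain, depth-limited graph
traversal for term expansion) agree to 1e-12. `scripts/acceptance.py`
regenerates the 35 000-patient cohort (5000 cases), re-runs phenotyping
and matching from scratch, and reports the depressed percentage of the
assembled cohort.

## Known limitations

Liblinear's coordinate descent makes very dense path segments slow; the
early-stopped path avoids them but means the reported CV curve covers only
the explored prefix. The per-feature moderator models ignore correlation
between screened features; the joint model accounts for it at the cost of
wider intervals. The moderator power property sits near its threshold by
design (the planted effect is deliberately modest), so individual replicate
batches can land within a few detections of the 80% line. DeLong intervals
are asymptotic and can undercover for AUCs very near 1 with few positives.
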