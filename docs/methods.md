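# Methods

## The screening problem

Infantile atopic dermatitis (AD) — chronic, itchy, relapsing eczema in
children under two years — is common (around 30% prevalence in the
populations this toolkit targets) but frequently undiagnosed, because
caregivers do not connect the skin findings to a treatable disease.
Web-based questionnaires can reach community populations that never see a
dermatologist, provided the identification rule applied to the answers is
validated against clinical diagnosis. This package implements that whole
workflow: the rules, their validation, the survey planning, and the data
cleaning, together with a synthetic-cohort generator that stands in for the
(undeposited) respondent-level data.

## Identification rules

An answer vector is seven strict booleans Q1–Q7 (family history, red rash,
dry skin, itching, sites within a week, sites within six months, previous
diagnosis). Rules are data, not code:

- **Boolean rules** are AND/OR trees over question atoms. The three
  built-ins are `Q2&Q4&Q5` (rule 1, the week-window rule), `Q2&Q4&Q6`
  (rule 2, the six-month window), and
  `(Q2&(Q4|(Q1&Q3))&Q6)|Q7` (rule 3, which lets family history plus dry
  skin substitute for itching and lets a previous diagnosis override the
  symptom logic). Negation is deliberately unsupported: all rules are
  monotone (flipping any answer no→yes can only keep or gain a positive),
  which is both clinically sensible and a property the tests exploit.
- **The logistic rule** (rule 4) computes
  p = 1/(1+exp(−(b0 + Σ bᵢQᵢ))) with coefficients
  {Q1: 1.484, Q2: 2.415, Q3: 1.367, Q4: 2.749, Q6: 1.448} and classifies
  positive when p strictly exceeds the ROC-derived cutoff 0.849, or when
  Q7 is yes (the override disjunct — Q7 has no model coefficient). Q5 is
  not in the model (its predictive value is dominated by Q6).

Two intercepts circulate for the same fitted model: −4.483 (the
full-precision regression equation) and −4.84 (the coefficient table,
printed at two decimals). Both exponentiate to an odds ratio that rounds
to 0.01, so neither can be ruled out from the published numbers alone. We
default to −4.483, matching the three-decimal precision of the slope
coefficients, and ship −4.84 as the named preset `rule4_table_intercept`.
Exhaustive enumeration shows the two variants disagree on exactly two of
the 128 answer patterns (Q2,Q3,Q4 yes; Q1,Q6,Q7 no; Q5 free), whose score
straddles the cutoff. The strict `>` comparison at the cutoff follows the
published rule statement; a non-strict variant is a constructor flag since
boundary patterns exist.

Every rule — logistic included — is a deterministic function of seven
booleans, so its full truth table (128 entries) is cheap. The truth table
is both the vectorised evaluation path for cohorts (a single indexed
lookup) and the oracle the tests compare pointwise evaluation against.

## Diagnostic accuracy

Metrics are the standard 2×2 quantities: Se = TP/(TP+FN),
Sp = TN/(TN+FP), PPV, NPV, Cohen's κ from the table margins, and — for a
binary rule — AUC = (Se+Sp)/2, the trapezoid area under the one-point ROC.
A degenerate margin (no diseased, no positive calls, …) yields NaN plus an
entry in the report's `undefined` list, never a silent 0/0. Reports print
at the conventional precision: percentages to one decimal, κ/AUC to two.

**Confusion-matrix reconstruction.** Published validation tables usually
print n, the case count, and Se/Sp but not the 2×2 table. With
TP = round(Se·n_diseased) and TN = round(Sp·n_healthy) (half-up — the
convention under which all reconstructed cells recover their printed Se/Sp
consistently), the remaining cells follow by complement and every derived
metric can be recomputed. Round-tripping is exact to within half a count
of each margin.

**ROC cutoff.** Candidate cutoffs are midpoints between consecutive
distinct scores (plus one below the minimum), evaluated under the strict
`score > cutoff` convention the logistic rule uses; the Youden index
Se+Sp−1 picks the winner, with ties broken toward the lowest cutoff
(favouring sensitivity — the natural choice for a screening instrument,
and unstated in the sources this mirrors). ROC points and AUC come from
scikit-learn.

**Agreement.** κ between two rules reuses the same two-category Cohen
formula with one rule treated as the reference; it is symmetric and
relabel-invariant, and cross-checked against scikit-learn in the tests.
When expected agreement is exactly 1 (both raters constant and equal,
forcing observed agreement 1) κ is defined as 1.

## Sample-size formulas

For validating a screening test at confidence z, tolerance d, in a
population with disease prevalence p:

    n_Se = z²·Se(1−Se)/(d²·p),    n_Sp = z²·Sp(1−Sp)/(d²·(1−p))

— the one-proportion formula inflated so the diseased (resp. healthy)
subgroup alone reaches the precision target. For a prevalence survey with
design effect D (variance inflation for non-ideal sampling):

    n = D·z²·p(1−p)/d².

All results round up (186.03→187, 54.1→55, 651.2→652 under the default
designs). The recruitment target divides the required analysed n by
(1−unqualified)·(1−nonresponse), applied to the rounded n — the more
conservative of the two defensible orderings (inflating the unrounded
651.2 instead gives 1371, one recruit less).

## Cleaning flow

Exclusions apply in a fixed order so each record lands in exactly one
bucket: structurally unparseable → exact duplicates (device id, network
address, *and* basic demographics all equal; first submission kept;
partial matches are flagged but retained) → reliability failures (the
twice-asked check question disagreeing, self-evaluated poor quality, or
any missing answer) → age at response ≥ 24.0 months (the limit itself is
excluded; "younger than two years" is read strictly) → excluded medical
conditions. The order is a package choice — the sources give the checks
but not their sequence — and cleaning is idempotent by construction.

## Synthetic cohorts and calibration

The generator draws a latent disease state at the configured prevalence
and answers from one of two models:

- **Conditional independence** given disease state (seven per-state
  probabilities), with the logical implication Q5 → Q6 enforced — sites
  affected within a week were affected within six months — by drawing Q5
  only when Q6 is yes, at rate min(1, p5/p6).
- **Pattern tables** — explicit distributions over the 128 answer patterns
  per state, used when exact calibration is needed.

Operating characteristics under either model are computed analytically
(pattern probabilities dotted with the rule truth table), never by
sampling. `calibrate` finds pattern tables hitting rule-level Se/Sp
targets and overall answer marginals simultaneously: all targets are
linear in the two pattern distributions, so the fit is a bounded linear
least-squares over the product of two simplices (heavily weighted
sum-to-one rows, then renormalisation), with residuals checked at
tolerance 0.01 per target and an explicit infeasibility report otherwise.

Calibration does **not** enforce the Q5 → Q6 implication. That is
deliberate: under the implication a week-window conjunction is a subset of
its six-month counterpart, forcing Sp(week rule) ≥ Sp(six-month rule) —
yet real cohorts show the opposite (the week rule collects *more* false
positives), because respondents do tick "within a week" without "within
six months". Honouring observed answer behaviour beats honouring logic the
respondents themselves violate.

The caregiver-awareness flag is drawn at rate 0.061 among diseased
children (matching the observed awareness level among undiagnosed
identified cases); ages are uniform on [0, 24) months, rounded to 0.1 and
clipped below the age limit. What the generator does *not* emulate: the
true inter-question dependence structure (only rule-level characteristics
and marginals are matched, not the full joint distribution), free-text
answers, response timestamps, or any demographic structure beyond age and
sex. Passing tests therefore show the *methods* behave correctly under
controlled conditions, not that any particular field cohort satisfies the
calibrated model.

## Problem sizes and determinism

Default study sizes mirror the workflow the toolkit models: a 195-record
validation cohort with 148 cases, an 837-record implementation survey, and
10,000-record synthetic cohorts for Monte-Carlo recovery (binomial noise
on a recovered sensitivity at that size is ~0.5 points, comfortably inside
the 2-point recovery tolerance); the marginal-convergence check uses
100,000 records against a 3-standard-error band. Every random draw flows
from an explicit `numpy.random.default_rng` seed: same seed, byte-identical
cohort. End-to-end report bundles embed the seed and a hash of the
canonical configuration.

## Known limitations

- Reconstruction recovers the 2×2 table only up to the rounding of the
  published Se/Sp; a κ printed from unrounded software output can differ
  in the last digit from the κ of the reconstructed table (the week-window
  rule reconstructs to κ = 0.565).
- Wald intervals recomputed from coefficients and standard errors printed
  at 2 decimals carry ~1% relative uncertainty in the bounds.
- The 0.849 cutoff is an input; without respondent-level scores it cannot
  be re-derived, and whether it is the Youden optimum of its source ROC is
  unknowable from the published material.
- Confidence intervals for Se/Sp/PPV/NPV and DeLong AUC comparisons are
  out of scope.
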