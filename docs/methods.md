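# Methods

## Model structure

Each gestational-age week (34, 35, 36) gets its own two-arm decision tree:
administer antenatal corticosteroids (ACS) or not, to a singleton pregnancy
presenting and delivering in that week.  Outcomes are neonatal acute
respiratory disease (ARD, i.e. respiratory distress syndrome), and the
long-term childhood states chronic respiratory disease (CRD, modelled as
persistent asthma), neurodevelopmental delay (cerebral palsy-like), death,
and health.  Maternal outcomes are out of scope.

The joint outcome distribution factorises as
`P(path) = P(ARD) · P(long-term state) · P(CRD | survivor)`, with the CRD
branch suppressed on death paths: 10 terminal paths per arm.  The published
sources give per-arm marginal probabilities, not a joint structure; treating
the three branch families as independent is the simplest tree consistent
with them.  Whether the original model conditioned chronic outcomes on
acute disease is unknown; this is an assumption.

## QALY accrual

A path's QALYs are
`U_acute · (w/52) + U_long · A(T_long − w/52, r)` where

* `w` = latency from delivery to 40 weeks (6/5/4 weeks at 34/35/36 weeks);
  during this window the ARD utility (0.87) substitutes for the healthy
  utility when the path has ARD.  Chronic-state utilities do not
  additionally multiply the acute window.
* `U_long` = product of the applicable long-term utilities (healthy 1.0,
  delay 0.76, death 0.01, × 0.88 if CRD), utilities treated as independent
  and multiplicative.
* `T_long` = 78.2 years (2009 US life expectancy) for health, CRD and the
  death state; 17 years for delay (cerebral-palsy life expectancy), with no
  accrual of QALYs or costs afterward.
* `A(T, r)` = annuity factor: year 0 undiscounted, year *t* weighted
  `(1+r)^−t`, final fractional year prorated linearly.  `A(78.2, 0.03) =
  30.930`.

Two deliberately literal choices: death is carried as a *state* with
utility 0.01 over 78.2 years (as the source tables print it), not as zero
utility; and QALYs are discounted at the same 3% annual rate as costs.
The sources mention discounting only for costs, but undiscounted QALYs give
an incremental effect near 0.16 QALY, irreconcilable with the published
incremental effect of 0.112, while discounting gives 0.118.  Both choices
are configurable (`EconomicSettings.discount_qalys`; the death utility is an
ordinary parameter).

## Costs

2011 US dollars, single-payer perspective.  Delivery cost per arm ($8,449
without ACS; $16,277 with, reflecting the ~48-hour inpatient steroid
admission), ARD cost ($2,505/$1,081/$863 by week) and the childhood-death
cost ($56,500) are one-time, year-0, undiscounted.  CRD ($56,641 lifetime)
and delay ($270,790 lifetime) costs are spread uniformly over the state
duration and discounted, accruing only over years lived (a CRD case on a
delay path accrues CRD costs for 17 years, not 78.2).  One-time chronic
costs were considered and rejected: they understate the incremental cost
(~$6.7K vs the published ~$7.1K).

## Base case, partial course, cohort

Base case evaluates all point estimates; reconstruction gives IC
$7,138/$7,272/$7,295, IE 0.1177/0.1171/0.1168 and ICER
$60,660/$62,117/$62,464 at 34/35/36 weeks (published: IC ~7.1-7.2K, IE
0.112, ICER $62,888/$64,426/$64,794 from an unpublished commercial-software
rollup; the published per-strategy "utiles" of ~155.8-155.9 are not
derivable from any stated convention and are not targeted).

The partial course models delivery before regimen completion: every
ACS-arm probability is replaced by `p_noACS − 0.5·(p_noACS − p_ACS)` (half
the absolute risk reduction, applied to point/low/high alike), delivery
costs unchanged — the "50% reduction in hospital costs" the scenario is
paired with in the source emerges automatically as the halved downstream
cost offsets; literally halving the ACS delivery cost would make the
partial course dominant, contradicting the published partial-course ICERs
of ~2× the full course.  Reconstruction: $127,239-$129,545/QALY.

Cohort projection applies the per-arm marginal probabilities to an annual
US cohort of 331,500 late-preterm singletons, split equally (110,500) per
week for the week-specific acute outcome.  Counts use round-half-away-from-
zero on the unrounded product, and "prevented" rounds the unrounded
probability difference × n, which reproduces every published count except
the 816 delay cases (815.49 by this rule; a source rounding inconsistency).
The `cost_delta` column is this package's internally consistent figure —
unrounded prevented cases × unit cost, minus (acute outcome only) the
cohort-wide incremental delivery cost; the source's "cost saved" dollar
columns are not derivable from its printed unit costs and are not targeted.

## One-way sensitivity

Each of the 18 `Estimate` inputs is swept across its plausible [low, high]
range (default 21 points) with the rest at base case; threshold finding
bisects on the accept/reject *decision* at the willingness-to-pay threshold
(robust to the ICER discontinuity at zero incremental effect), to a final
bracket of 1e-4 of the initial width.

Reconstruction: no acute-disease input flips the decision anywhere in its
range, at any week, and the CRD inputs dominate the tornado — both in
agreement with the published analysis.  The decision flips at an ACS-arm
CRD probability of 7.20% (published 6.45%) and a no-ACS-arm probability of
5.81% (published 6.60%); the CRD-utility sweep does *not* flip the decision
in this reconstruction (even at utility 1.0 the ICER is ~$89K/QALY, because
the non-CRD incremental effect — dominated by the 0.063-QALY childhood-death
term — alone keeps ACS under the threshold), whereas the published flip
point is a utility of 0.94.  The published thresholds depend on the same
unpublished rollup as the absolute "utiles" and could not be reproduced at
that precision; the qualitative conclusion (the decision is sensitive only
to chronic-respiratory-disease inputs) is unchanged.

## Probabilistic sensitivity analysis

Second-order Monte Carlo, default 10,000 iterations.  Probabilities get
method-of-moments beta distributions with mean = point and sd = range/3.92
(the plausible range read as a central 95% interval — a conventional choice;
the source does not state its variance mapping); if the implied variance is
infeasible the sd shrinks to 0.95 of the feasible maximum.  Utilities and
costs get normals with the same moment rule, truncated to [0,1] and
[0,∞).  Zero-width ranges become point masses.  Per-arm probabilities are
drawn independently (the sources attach distributions to probabilities, not
relative risks), so draws can reverse the effect direction — precisely what
drives full-scope acceptability toward equivocal values.

Reproducibility: a master seed spawns one substream per iteration
(`SeedSequence(seed, spawn_key=(i,))`), and every input is drawn in a fixed
canonical order whether or not it is in scope, so scope changes do not
shift unrelated draws.  Structural coherence (death + delay ≤ 1 per arm) is
enforced by rejection-resampling the offending pair (cap 10,000/iteration).
The 95%-confidence WTP threshold is computed exactly from the per-iteration
critical WTP values (the order statistic the refined-grid definition
converges to).

At seed 1: acute-only scope is acceptable at $100K/QALY in 100% of
iterations at all weeks with 95%-confidence WTP ≈ $63.1K/$62.8K/$62.8K
(published: 100%, >$64.7-65.8K); full scope is acceptable in 62-64% with no
WTP reaching 95% confidence (published: ~47%, likewise no threshold — the
published percentage depends on the unpublished variance mapping and is not
a quantitative target).

## Synthetic parameter sets

`acs_cea.synthetic` generates random valid parameter sets mirroring the
real ones structurally: bounded per-arm probabilities with plausible ranges
(capped at 0.5, and 0.25 for death/delay, so the healthy remainder never
needs rejection), utilities in [0,1], nonnegative costs, and a controllable
effect direction/magnitude and delivery-cost premium.  They exercise every
pipeline stage; they do not emulate the *correlations* of real
literature-derived estimates (each input is drawn independently), so
passing property tests demonstrates structural correctness, not calibration
to any real population.  `known_answer_fixture` isolates a single
chronic-respiratory risk with zero chronic cost, making incremental cost
and effect available in closed form for oracle tests.

## Numerical notes and limitations

* All tree quantities are exact expectations (no first-order simulation);
  path probabilities are validated to sum to 1 within 1e-9.
* Degenerate inputs: zero-width ranges sweep to a constant; identical arms
  give IC = IE = 0 and an undefined ICER, classified as indifferent
  (acceptable); ICER is reported as `None` whenever IE = 0.
* Bisection is decision-based and capped at 60 iterations (ample for 1e-6
  relative tolerance).
* The model is a one-shot cohort expectation: no Markov cycling, no
  within-cycle correction beyond linear proration, no patient-level
  heterogeneity, and all deliveries occur in the presenting week.
* Problem sizes used by the shipped analyses: 10,000 PSA iterations per
  scope/week and 10^6 draws in the Monte Carlo cross-check of the tree
  expectation — the same sizes the published analysis reports.
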