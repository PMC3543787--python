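# acs-cea

Decision-analytic and cost-effectiveness model of **antenatal corticosteroids
(ACS) for late-preterm delivery** (34, 35 and 36 completed weeks of
gestation).  ACS accelerate fetal lung maturation and are standard of care
before 34 weeks; this package evaluates, from a single-payer perspective in
2011 US dollars, whether extending them to the late-preterm window is good
value.  It is written for perinatal health-services researchers and health
economists who want a scriptable, testable, fully reproducible version of
this class of model.

## The model

For each gestational-age week a decision tree compares two strategies,
giving or withholding ACS.  Each newborn may experience acute respiratory
disease (probability `p_ARD`, per arm), and independently one of three
long-term states — childhood death (`p_death`), neurodevelopmental delay
(`p_delay`) or health (`1 − p_death − p_delay`) — with chronic respiratory
disease (`p_CRD`) branching for survivors, giving 10 terminal paths per
strategy.  Each path accrues

* **QALYs**: `U_ARD · (w/52) + U_long · A(T_long − w/52, r)`, where `w` is
  the latency-to-term window in weeks, `U_long` the product of the
  applicable state utilities, `T_long` the state duration (78.2 years for
  health, chronic respiratory disease and death-as-modelled; 17 years for
  delay) and `A(T, r)` the discounted annuity factor at annual rate
  `r = 3%` (year 0 undiscounted, final fractional year prorated);
* **costs**: delivery cost per strategy plus one-time acute/death costs at
  year 0, plus lifetime chronic costs spread uniformly over the state
  duration and discounted over the years actually lived.

Strategies are compared by the incremental cost-effectiveness ratio
`ICER = (C_ACS − C_noACS) / (Q_ACS − Q_noACS)` against a willingness-to-pay
threshold of $100,000/QALY, with standard dominance classification.  On top
of the base case the package provides a partial-course scenario (half the
absolute risk reduction for every outcome), an annual-cohort impact
projection, one-way sensitivity sweeps with bisection threshold finding,
and a seeded 10,000-iteration second-order Monte Carlo probabilistic
sensitivity analysis (method-of-moments beta distributions for
probabilities, truncated normals for utilities and costs, ranges read as
95% intervals) with cost-effectiveness acceptability curves.

## Worked example

```python
from acs_cea import builtin_parameter_set, compare, to_partial_course

r = compare(builtin_parameter_set(34))
print(f"IC ${r.incremental_cost:,.2f}  IE {r.incremental_effect:.4f} QALY  "
      f"ICER ${r.icer:,.2f}/QALY  {r.classification}")
p = compare(to_partial_course(builtin_parameter_set(34)))
print(f"partial course ICER ${p.icer:,.2f}/QALY  {p.classification}")
```

prints

```
IC $7,137.89  IE 0.1177 QALY  ICER $60,659.76/QALY  acs_cost_effective
partial course ICER $127,238.63/QALY  acs_not_cost_effective
```

i.e. a full steroid course at 34 weeks costs $7,138 more per delivery
(mostly the ~48-hour admission), buys 0.118 discounted QALYs (mostly
averted chronic respiratory disease and childhood death), and at
$60,660/QALY is cost-effective at the $100K/QALY threshold — while a
course interrupted by delivery, retaining half the risk reduction at full
delivery cost, is not.

The same analyses are scripted end to end under `analysis/`
(`01_basecase.py` … `05_psa.py`, writing tables to `results/`) and exposed
on the command line:

```sh
acs-cea basecase --ga 34
acs-cea cohort --ga 34 --n-cohort 110500
acs-cea psa --ga 34 --iterations 10000 --seed 1 --scope acute
```

Custom parameter files (YAML/JSON, schema in
`acs_cea.parameters.parameter_set_to_dict`) can replace the built-in
estimates everywhere via `--params`.

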