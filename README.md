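# disattrib

Attribution of disability prevalence to chronic diseases, and
decomposition of the educational gap in disability, via a **binomial
additive hazard model** — the "attribution method" used in
population-health studies of disabling chronic conditions.

## Who this is for

Epidemiologists and health-inequality researchers who have
individual-level survey data (disability indicator such as the GALI,
a checklist of chronic conditions, demographics, sampling weights) and
want to answer two questions:

1. How much of the disability prevalence in a population group is
   attributable to each chronic condition, allowing for multimorbidity
   and for disability with no reported disease ("background")?
2. Is a disability gap between groups (here: education levels) driven
   by differences in *disease prevalence* or in the *disabling impact*
   of diseases?

## The model

For respondent *i* with age band *a*, education *e* and disease
indicators X<sub>di</sub>,

    Y_i ~ Bernoulli(pi_i)
    pi_i = 1 - exp(-eta_i)
    eta_i = alpha_ae + sum_d beta_cde * X_di

where eta is a cumulative disability rate, alpha the background rate,
and the age(*c*)-by-disease-by-education impacts are reduced to rank
one, beta_cde = gamma_c * delta_de (gamma fixed to 1 in the youngest
rank band). All parameters are constrained non-negative, so diseases
act as additive competing causes. Each respondent's pi is partitioned
proportionally to the hazard terms:

    contribution of disease d = pi * beta_cde X_di / eta
    background part           = pi * alpha_ae / eta

Survey-weighted means of these shares give an exactly additive
partition of the (model-predicted) disability prevalence; direct age
standardization with a standard population keeps it additive. Two
counterfactual scenarios re-compute a group's attribution with another
group's age-specific disease prevalences (`swap_prevalence`, exact
expectation over all 2^13 disease states under independence) or with
its disabling impacts (`swap_impact`), decomposing the gap. Bootstrap
resampling (default 1000 replicates) gives confidence intervals.

The model is fitted separately for men and women by weighted maximum
likelihood under box constraints (block-alternating bounded
quasi-Newton with a joint polish step, multi-start).

Because survey microdata of this kind are not redistributable, the
package ships a synthetic-cohort generator with known ground-truth
parameters (education-graded disease prevalences, age gradients,
non-uniform weights) so every stage is testable end to end.

## Worked example

```python
from disattrib import run_full_analysis

report = run_full_analysis({"n": 23_348, "seed": 1})
male = report.per_sex["male"]
print(f"baseline gap          {100 * male.gap.baseline_gap:.1f} pp")
print(f"gap, equal prevalence {100 * male.gap.remaining_gap_equal_prevalence:.1f} pp")
print(f"gap, equal impact     {100 * male.gap.remaining_gap_equal_impact:.1f} pp")
print(male.table2.round(1).iloc[[1, -2, -1]])
```

prints (synthetic cohort from the built-in ground-truth fixture):

```
baseline gap          20.6 pp
gap, equal prevalence 10.7 pp
gap, equal impact     14.0 pp
                       recipient (1)  donor (2)  cf prevalence of donor (3)  cf impact of donor (4)  baseline gap (1-2)  gap, equal prevalence (3-2)  gap, equal impact (4-2)
cause
arthritis                        6.1        4.3                         3.7                     6.8                 1.8                         -0.6                      2.5
Background                       9.1        4.7                        10.6                    10.2                 4.4                          5.8                      5.5
Disability prevalence           44.8       24.3                        35.0                    38.3                20.6                         10.7                     14.0
```

Read: low-educated men have 20.6 percentage points more disability
than high-educated men; giving them the high-educated group's disease
prevalences would leave 10.7 pp (the part due to disabling impact),
giving them its disabling impacts would leave 14.0 pp (the part due to
prevalence). Each column is additive: causes + background = prevalence.

The same analysis is available from the shell:

```
disattrib synth --n 23348 --seed 1 --out cohort.csv
disattrib fit --cohort cohort.csv --sex male --out params.json
disattrib report --config analysis.yaml --out-dir results/
```

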