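# weighttte

Target trial emulation when the exposure is a **change** — here, weight
change in overweight adults (BMI 25–29.9 kg/m²) and its effect on
cardiovascular disease over 20 years of follow-up with visits every two
years.

Estimating the effect of weight change from observational data raises two
questions a randomised trial never faces: *where is time zero?* (enrolment,
or the first follow-up when the change can finally be measured?) and
*which confounder measurements should be adjusted for?* (enrolment,
follow-up, or both?).  Three strategies circulate in the applied
literature, and they disagree. This package implements all three so their
biases can be measured, not argued about:

| | time zero | exclusions | adjustment |
|---|---|---|---|
| method 1 | enrolment | none | enrolment covariates |
| method 2 | first follow-up | first-interval events | follow-up covariates |
| method 3 (recommended) | enrolment (2-year zero-risk baseline period) | first-interval events | covariates at **both** waves |

The core model is discrete-time survival via pooled logistic regression on
person-period records,

    logit P(Y_it = 1 | at risk) = α_t + β_L·loss_i + β_G·gain_i + γ'X_i ,

whose exposure coefficients β read as log hazard ratios in the rare-event
regime.  Around it sit: an exactly-counted 40-subject worked example; a
cohort simulator with known confounding and true conditional effects
(log HR 0 for loss vs maintenance, 0.3 for gain); stabilized-IPW
Kaplan–Meier and parametric g-formula incidence curves; and a replication
harness reporting bias, empirical SD and 95%-CI coverage per method and
contrast.  See `docs/methods.md` for the model, the generator's causal
structure and its limitations.

## Worked example

The 40-subject toy trial needs no modelling — risks are exact counts:

```sh
$ weighttte toy
Trial risks by randomised arm:
  a_low_caloric: 3/20 = 15.0%
  b_standard_caloric: 3/20 = 15.0%
method1:
  loss: 4/22 = 18.2%
  maintain: 2/18 = 11.1%
  risk difference (loss - maintain): 7.1%
method2:
  loss: 2/18 = 11.1%
  maintain: 2/18 = 11.1%
  risk difference (loss - maintain): 0.0%
method3:
  loss: 2/18 = 11.1%
  maintain: 2/18 = 11.1%
  risk difference (loss - maintain): 0.0%
```

The randomised trial finds identical 15% risk in both arms — weight loss
does nothing.  Method 1, grouping by observed weight change with no
exclusions, manufactures a 7.1-point excess risk for weight loss: the four
subjects whose loss was caused by an emerging chronic disease (and who
carry its excess risk) all land in the loss group.  Methods 2 and 3
exclude them and recover the null exactly.

The same comparison with modelling, on simulated cohorts:

```python
from weighttte import default_params, run_replications, summarize_report

report = run_replications(default_params(), n_reps=500, master_seed=1)
print(summarize_report(report))
```

```
Replication study: 500 replicates, seed 1, params 62d156a09ebb

contrast                   method1                       method2                       method3
                  estimate      bias     cover  estimate      bias     cover  estimate      bias     cover
loss_vs_maint        0.107     0.107     0.444     0.076     0.076     0.700     0.000     0.000     0.964
gain_vs_maint        0.241    -0.059     0.808     0.266    -0.034     0.890     0.300    -0.000     0.946

method1: mean n after exclusions = 10000.0, failed replicates = 0
method2: mean n after exclusions = 9728.4, failed replicates = 0
method3: mean n after exclusions = 9728.4, failed replicates = 0
```

Method 3 recovers both true effects (0 and 0.3) with ~95% coverage;
method 2 is biased by the unadjusted enrolment confounders; method 1 is
worst — biased upward for loss (reverse causation) and downward for gain —
and its confidence intervals cover the truth far below nominal rate.
Equivalent CLI: `weighttte replicate --reps 500 --n 10000 --seed 1`.

Marginal incidence curves from a single cohort:

```sh
weighttte simulate --n 10000 --seed 1 --out cohort.csv
weighttte curves --estimator gformula --method 3 --cohort cohort.csv
weighttte curves --estimator ipw-km  --method 3 --cohort cohort.csv --plot km.png
```

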