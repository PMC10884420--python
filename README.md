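# psmcr

Propensity-score updating of right-censored observations in two-cause
competing-risks survival models, with the cause-specific Cox machinery,
Weibull simulator, cumulative-incidence estimation and Monte-Carlo study
built around it.

## The problem

In cancer follow-up cohorts, a subject under loco-regional control may
progress (first, then distant progression) and die, or die directly without
progression. Death after progression and direct death are mutually
exclusive **competing risks** (causes 1 and 2). A large share of subjects
is right-censored: their death status is simply unknown at last follow-up,
and some of them will in reality have died of either cause. This package
implements a matching-style procedure that *updates* the status of the
censored subjects judged most at risk, reassigning them to one of the two
competing causes before the cause-specific analysis is run.

## The method

The cause-specific hazard of cause k is modelled with a Cox proportional
hazards model,

    h_k(t | z) = h_{k0}(t) exp(beta_k' z),    k = 1, 2,

fitted by Newton-Raphson on the Breslow partial likelihood (events of the
other cause are censored at their times); the cumulative baseline hazard
H_{k0}(t) is the Nelson-Aalen / Breslow step estimator. Cumulative
incidence F_k(t) = P(T <= t, D = k) is estimated by the Aalen-Johansen
formula F_k(t) = sum_{t_j <= t} S(t_j-) d_{kj} / n_j, which avoids the
upward bias of one-minus-Kaplan-Meier per cause.

The censoring update works per cause k:

1. **Coefficient signs.** Fit the cause-k Cox model (maximum partial
   likelihood, or its Bayesian counterpart via random-walk Metropolis under
   a flat prior) and keep only sign(beta_l).
2. **Reference point.** Build the minimum-hazard corner X_min over all n
   subjects: coordinate l is the column minimum if beta_l > 0 and the
   column maximum if beta_l <= 0.
3. **Propensity score.** For each censored subject r compute the weighted
   squared Euclidean distance Delta_r = sum_v w_v (x_{v,min} - x_{vr})^2,
   with w_v = 1/s_v^2 by default.
4. **Threshold rule.** Flip subject r from censored (status 0) to dead of
   cause k iff the empirical CDF of Delta_r among censored subjects
   strictly exceeds the threshold probability p (default 0.9) — the top
   (1 - p) fraction of censored subjects farthest from the low-risk corner.
   Observed times are never changed; tau_0k counts the flips.

A joint variant runs both causes on the original censored set and resolves
double flags by the larger empirical-CDF rank. A Monte-Carlo driver
simulates Weibull competing-risks data (cumulative-hazard inversion,
H(t) = lambda t^gamma) and tabulates mean/bias/MSE of the cause-specific
coefficients before and after the update.

## Worked example

```python
import numpy as np
from psmcr import (SimulationConfig, simulate_dataset, fit_cause_specific_cox,
                   psm_update_joint, aalen_johansen_cif)

config = SimulationConfig(n=200, seed=11)      # Weibull competing-risks design
data = simulate_dataset(config)
print("status counts (censored, cause 1, cause 2):",
      np.bincount(data.statuses, minlength=3))

fit = fit_cause_specific_cox(data, cause=1)
print(fit.summary().round(3))

updated, updates = psm_update_joint(data, p=0.9)
print("updated censored subjects: tau_01 =", updates[1].n_updated,
      " tau_02 =", updates[2].n_updated)

refit = fit_cause_specific_cox(updated, cause=1)
cif = aalen_johansen_cif(updated)
print("F1(5) = %.3f, F2(5) = %.3f" % (cif.cif_at(1, 5.0), cif.cif_at(2, 5.0)))
```

prints

```
status counts (censored, cause 1, cause 2): [19 93 88]
     beta  exp(beta)  se(beta)      z      p
x1 -0.547      0.579     0.116 -4.704  0.000
x2 -0.151      0.860     0.112 -1.345  0.179
x3 -0.044      0.957     0.120 -0.368  0.713
updated censored subjects: tau_01 = 2  tau_02 = 2
F1(5) = 0.475, F2(5) = 0.450
```

The cause-1 fit recovers the generating coefficient beta_1 = -0.5 well
within one standard error; 19 of 200 subjects are censored at the 5-year
cutoff, and the joint update at p = 0.9 reassigns two of them to each
cause. The two cumulative incidences at 5 years sum with the survivors to
one.

A command-line interface mirrors the library:
`psmcr simulate`, `psmcr fit`, `psmcr psm-update`, `psmcr cif`,
`psmcr study` (see `psmcr --help`).

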