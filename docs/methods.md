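# Methods

## Model and scope

The package models a four-state forward-only process — loco-regional
control (1), first progression (2), distant progression (3), death (4) —
whose absorbing state splits into two competing causes: death after
progression (cause 1) and direct death without progression (cause 2). Two
levels of analysis are supported:

* **Flat competing risks.** One row per subject: observed time, status in
  {0 censored, 1, 2}, covariates. Cause-specific Cox models treat the other
  cause as censoring; the Aalen-Johansen estimator gives the cumulative
  incidence of each cause.
* **Multistate (long format).** One row per at-risk transition
  (mstate-style). The joint partial likelihood factorises by transition,
  so each of the five allowed transitions is fitted as its own Cox model on
  sojourn durations (clock reset at state entry). Left truncation,
  interval censoring and time-varying covariates are out of scope.

## Cause-specific Cox fitting

Newton-Raphson on the Breslow log partial likelihood, started at beta = 0,
with step-halving whenever a full step fails to improve the likelihood.
Convergence is declared when the score max-norm falls below `tol`
(default 1e-8, `max_iter` 100). Ties are handled by the Breslow
convention: each event at a tied time uses the full risk set, which is
exact for the plug-in form of the likelihood and is measure-zero territory
for the continuous simulations anyway. No intercept is included (not
identifiable in a partial likelihood). Standard errors come from the
inverse observed information; Wald z and two-sided normal p-values are
reported. Monotone likelihood (perfect separation) is detected as either
non-convergence or a coefficient magnitude above 15 on the working scale,
and is flagged rather than silently returned; the study driver counts and
excludes such replicates and aborts if they exceed 10%. If the risk-set
sum underflows at an extreme trial point, the log-likelihood is reported
as -inf so line searches and the MCMC sampler reject the point.

The cumulative baseline hazard is the Nelson-Aalen / Breslow step function
H_0(t) = sum_{t_j <= t} d_j / sum_{l in R(t_j)} exp(beta' z_l),
right-continuous and zero before the first event.

## Bayesian variant

Only the *signs* of the coefficients enter the downstream reference point,
so posterior location is all that matters. The sampler is random-walk
Metropolis on the Breslow partial likelihood under a flat improper prior —
a standard Bayesian treatment of Cox regression. Defaults: 2000
iterations, 500 burn-in, per-coordinate proposal SD 2.5 se(beta_hat)/sqrt(m)
(scaled from the Newton-Raphson fit), seed required. Signs are taken from
the posterior mean, with exactly zero mapped to the non-positive branch.
The `mple` fast path takes signs of the point estimate directly; it gives
identical signs in practice and keeps the 100-replicate study fast, so it
is the study default. A chain with zero acceptances in its first 500
proposals raises a tuning error instead of returning a degenerate
posterior. Fitting "on the censored subjects" alone is impossible (no
events), so the model is always fitted on the full dataset for the given
cause and the censored subjects are only *scored*.

## The censoring update

For cause k: reference point X_min over all n subjects (column minimum
where beta_l > 0, column maximum where beta_l <= 0 — the minimum-hazard
corner); scores Delta_r = sum_v w_v (x_{v,min} - x_{vr})^2 for censored
subjects only, with w_v = 1/s_v^2 (sample SD over all n subjects,
`standardize=False` gives w_v = 1). The score is deliberately the
*squared* weighted distance: only its ranks are used, so the square root
is immaterial. Subject r is flipped to cause k iff the empirical CDF of
Delta_r among censored subjects strictly exceeds p (default 0.9). With
distinct scores this flips the top (1-p) fraction; the reported
delta-quantile is the inverted-CDF empirical quantile. Flipped subjects
keep their observed (censoring) time as the event time — no later death
time is imputed. Statuses only ever change 0 -> k; the updated sets are
nested as p grows; p = 1 is a no-op and p = 0 flips every censored
subject.

The printed threshold rule in the source material is not well-formed and
its accompanying direction sentence contradicts both the construction of
X_min and the real-data update magnitudes; the strict empirical-CDF rule
above is the package's documented resolution. In the joint update both
causes score the original censored set; a subject flagged twice goes to
the cause with the larger empirical-CDF rank, ties to cause 1.

## Simulator

Latent times per cause are drawn by cumulative-hazard inversion of the
Weibull proportional-hazards model, t = [-log u / (lambda e^{x beta})]^{1/gamma}
with H(t) = lambda t^gamma. Defaults are the reference design: n = 200
subjects, m = 3 i.i.d. standard-normal baseline covariates,
beta^(1) = (-0.5, 0.01, 0.02), beta^(2) = (-0.5, 0.43, 0.03), gamma = 1.5,
lambda = 0.1, administrative censoring at c = 5 years, 100 replicates.
The two latent times use independent uniforms (their dependence is not
specified by the design; independence is the documented choice). The
earlier latent time wins; exact ties (probability zero) go to cause 1.
Replicate r uses seed + r, so any replicate is reproducible in isolation.
Under these defaults roughly 90% of subjects experience an event before
c = 5, leaving ~20 censored subjects per replicate; at p = 0.9 the update
therefore flips ~2 subjects per cause. Passing tests under this design
says nothing about informative censoring: the generator censors
administratively, i.e. independently of covariates, which real cohorts
need not obey.

The cohort analog (`simulate_chemo_analog`) emulates the *shape* of a
536-subject chemoradiotherapy cohort: semi-Markov Weibull sojourn hazards
over the four-state topology, six baseline labs on clinically plausible
scales plus gender acting proportionally on every transition, and
administrative censoring uniform on 3-6 years (staggered accrual with a
fixed study end). Its transition rates are configuration, calibrated once
so that the mean event counts (about 155 cause-1 deaths, 79 direct deaths,
302 censored) match the order of magnitude of such a cohort; they are not
estimates of any real dataset, and no numeric claims are attached to this
fixture.

## Monte-Carlo study

Per replicate: simulate, fit both cause-specific models (the "without"
condition), apply the update per cause at threshold p with `mple` signs,
refit (the "with" condition). Bias is mean minus truth; MSE is the mean
squared deviation from truth; the identity MSE = bias^2 + variance holds
to 1e-12 by construction. The per-replicate coefficient archive is kept so
Monte-Carlo standard errors (SD/sqrt(reps)) can be computed for any cell.
The per-cause (rather than jointly allocated) update is used in the study,
matching the described before/after protocol; the joint path is available.

Problem sizes used by the test suite: the full study (100 x 200) runs in
about a second; the large-sample consistency check uses 20 replicates of
n = 5000; oracle comparisons use 20 datasets of n = 50.

## Known limitations

* The update assumes larger covariate distance from the minimum-hazard
  corner means higher death risk; with strongly non-monotone covariate
  effects the reference-point construction is not meaningful.
* Updated subjects keep the censoring time as event time, which
  understates their true survival and attenuates hazard contrasts when
  many subjects are flipped.
* Under the reference simulation design the without-update estimator is
  already consistent (censoring is independent), and the experiment here
  accordingly shows the update *adding* small bias rather than removing
  it; the published improvement claim does not reproduce under a faithful
  implementation of the stated design. See the acceptance test for the
  exact comparisons.
* Covariates must be numeric; categorical inputs need prior encoding.
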