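# Methods

`omtrial` analyses double-blind placebo-controlled *crossover* cohorts
performing the "What was where?" Oxford Memory Task (OMT), a touch-screen
test of object-location memory binding used in dementia trials. This note
documents the models, the synthetic-data generator that stands in for the
(undeposited) trial data, the numerical choices, and the limits of what the
test suite demonstrates.

## Trial structure

Participants are randomized 1:1 (restricted block) to receive active drug or
placebo first and cross over after washout. Assessments fall at weeks 0, 8,
12 and 20; weeks 0/8 form session (arm) 1 and weeks 12/20 session 2, week 0
and week 12 being each arm's own baseline (pre-titration / post-washout).
Each OMT assessment presents 20 trials, by default 10 one-item and 10
two-item displays (the per-session condition mix is configurable; the split
is not prescribed anywhere, so an even split is the default). Pharmacology is
deliberately out of scope: a session carries only a binary drug label.

## Task metrics

Per trial the task yields identification correctness, identification and
localization times (canonically milliseconds — regression coefficients on
these outcomes are only interpretable at ms magnitudes), and the absolute
localization error: the Euclidean distance in screen pixels between the
studied location and the response. Screen coordinates are 0-based pixels,
origin top-left, y downward, on a default 1024x768 px display with a 100 px
item-free margin. Pixels are a convention here, not a calibrated physical
unit; nothing downstream depends on the choice.

## Spatial mixture model

Two-item localization responses are decomposed with a mixture model in the
tradition of analogue-report working-memory modelling, transplanted from 1-D
circular feature space to the 2-D screen:

    f(r) = p_T g(r; x_T, sigma) + p_N g(r; x_N, sigma) + p_U / A

* `p_T` (target detection): mass of responses distributed around the true
  target location `x_T`;
* `p_N` (misbinding / swap errors): responses around the *non-target*
  location `x_N` — the item was remembered, its binding to location was not;
* `p_U` (guessing): uniform over the screen area `A`;
* `sigma` (imprecision, px): one shared isotropic spread for the target and
  non-target components, matching the single imprecision metric reported for
  this task.

`g` is an isotropic bivariate normal truncated to the screen rectangle and
renormalized there (the generator truncates by redraw, never by clipping, so
model and simulator describe the same distribution). Because misbinding is
defined for *correctly identified* items, the default fitting frame is
two-item, correct-identification trials; a switch admits all trials.
Identification accuracy itself is a separate per-subject Bernoulli parameter,
not part of the spatial mixture.

### Fitting

Maximum likelihood by EM over the three component responsibilities.
Weights update in closed form. Because the truncated-normal normalizer
depends on `sigma`, the `sigma` update uses the closed-form untruncated
solution and keeps it only when it improves the expected complete-data
log-likelihood, otherwise falling back to a bounded 1-D search (and, failing
that, retaining the current value). This is a generalized EM, so the
observed-data log-likelihood is non-decreasing at every iteration — asserted
in the tests on the recorded iteration history.

Numerical choices: initial responsibilities from nearest-center assignment
with a 10% uniform floor and equal split on ties; 5 restarts with
log-normal jitter on the initial responsibilities; relative log-likelihood
tolerance 1e-6; at most 500 iterations; `sigma` floored at 1 px (degenerate
all-on-target data converge to `p_T -> 1`, `sigma ->` floor); minimum 10
trials per fit, refused below that. One-item trials (no non-target) simply
lose the swap component; a fit with no non-targets anywhere reduces exactly
to a two-component target+uniform model with `p_N = 0`.

### Permutation null for misbinding

The swap component is identified only relative to the observed pairing of
targets and non-targets, and a finite-sigma component near a random location
absorbs weight even from pure noise. Chance-level misbinding is therefore
calibrated by permutation: non-target locations are shuffled across trials
(targets and responses fixed), the model refitted (warm-started at the
observed fit, single restart), and the observed `p_N` compared with the
permutation distribution. The p-value uses the add-one estimator
`(1 + #{null >= observed}) / (B + 1)`, exact under exchangeability; at least
19 permutations are required to resolve p < 0.05. A chance-corrected weight
`max(0, observed - mean(null))` is reported alongside.

Two caveats are intrinsic. First, the exact permutation scheme used in the
trial's own analysis is not recoverable from public sources; shuffling
non-target locations is this package's documented reconstruction, following
the task family's precedent. Second, the minimum item-separation constraint
couples targets and non-targets, so permuted pairings are not perfectly
exchangeable with the observed one; empirically the rejection region is
calibrated (5% nominal, within binomial 99% bounds over 200 null datasets)
although the null p-value distribution is compressed away from 1.

## Synthetic cohorts

The generator emulates the study conditions so that every downstream stage is
testable with known ground truth: 8 subjects allocated 5:3
(active-first : placebo-first), 20 trials per assessment at weeks 0/8/12/20,
items uniform on the margin-inset rectangle with >= 150 px separation
(rejection sampling, capped at 10,000 draws), responses from the mixture
above, identification Bernoulli, and:

* response times: log-normal (median 6 s identification / 4 s localization,
  within-subject log-SD 0.4, between-subject log-SD 0.25 on the median) —
  strictly positive and right-skewed, as reaction times are; chosen to sit at
  the magnitudes the trial's own coefficient tables exhibit. Session, drug
  and session-by-drug effects are additive on the whole time distribution
  (hence on its median), following the linear predictor
  `b1*s + b2*d + b3*s*d` with session coded 1/2 and drug 0/1 — exactly the
  mixed model's coding, so recovery is bias-free by construction;
* drug effects on the mixture act additively on logit `p_T`, logit `p_N`,
  logit identification accuracy and log `sigma`, clipped back to the simplex;
* drug effects appear only at the end-of-arm assessments (weeks 8/20) of
  sessions labelled active; weeks 0/12 precede titration or follow washout
  and are generated drug-free. All defaults are zero — the default cohort is
  the null;
* questionnaires (MMSE, BADLS, DSRS, NPI, EQ5D patient/caregiver/proxy, QoL
  patient/caregiver): subject baseline + white measurement noise + optional
  additive drug effect at on-drug assessments;
* adverse events: per subject-arm Poisson totals (default mean 2.2 per arm,
  matching the reported overall reporting rate) multinomially spread over a
  small term vocabulary;
* demographics: age ~ N(68.4, 9.2^2) truncated above 50, P(female) = 0.625,
  baseline MMSE taken from the week-0 MMSE record.

Reproducibility: one RNG stream per subject, spawned from the master seed, so
cohorts are identical regardless of generation order. Every latent quantity —
per-subject parameters and per-trial mixture component labels — is emitted in
a ground-truth ledger beside the data; nothing is simulated that the ledger
does not record. All float fields are rounded to 6 decimals at creation so
the CSV round trip is exact.

What the generator does **not** emulate: learning/practice drifts across
trials, dropouts (the study had none; an optional missing-session mask
exists), carryover pharmacology, non-stationary adverse-event reporting, or
subject-level overdispersion of adverse events. Passing tests therefore
demonstrate correctness of the machinery under a faithful but idealized data
law, not robustness to every failure mode of real cohorts.

## Statistical plan

* **Change scores**: end-of-arm minus own-arm baseline (week 8 − week 0;
  week 20 − week 12), one delta per subject x instrument x respondent x
  session, drug label from the assignment. Missing weeks are listed as
  exclusions, never dropped silently.
* **Questionnaires**: within-subject active-vs-placebo comparison of deltas;
  paired t (with 95% CI) when the Shapiro-Wilk gate (alpha 0.05) accepts
  normality of the paired differences, Wilcoxon signed-rank otherwise;
  constant differences route to the rank branch with a note; all-zero
  differences return the degenerate null result.
* **Baseline comparisons**: Welch two-sample t or Mann-Whitney U by the same
  gate; Pearson chi-square (no continuity correction) for categorical
  tables.
* **Task metrics**: trial-level random-intercept model
  `value ~ 1 + session*drug + (1|subject)` on the end-of-arm assessments
  (one week per session; session 1/2, drug 0/1). Per-trial correctness is
  modelled 0/1 as a linear probability model, matching how linear
  coefficients for proportion correct are conventionally tabulated for this
  task; a logistic treatment is a possible extension, not the default.
  Estimation via statsmodels MixedLM (REML default, ML switch), with the
  outcome standardized internally for optimizer conditioning and mapped back
  exactly.
* **Adverse events**: totals by arm and term; paired t on per-subject
  (active − placebo) counts with 95% CI, zeros filled from the crossover
  roster.
* **Multiplicity**: Bonferroni by default (Holm available) over an explicit
  family — all fitted task outcomes x the three non-intercept terms. The
  family is configuration, not doctrine.

### Inference for the mixed model: why not a plain normal reference

`wald_summary` (t = coefficient/SE, p from the standard normal) reproduces
published coefficient-table arithmetic and is exposed as such. As the
*default inference* for the fitted model, however, the normal reference is
untenable at this trial's size: the drug and session-by-drug contrasts carry
between-subject information with roughly `n_subjects − 2` degrees of
freedom, and simulation under the generator's null shows ~14% rejection at
nominal 5% with 8 subjects even for a perfectly specified homoskedastic
model. Three references are provided:

* `"normal"` — the coefficient-table convention;
* `"satterthwaite"` — model-based Satterthwaite df for the random-intercept
  structure (computed in-package from the variance-component Fisher
  information); with REML this is nearly calibrated but remains sensitive to
  subject-level heteroskedasticity (slower subjects are noisier — true of
  log-normal times and of binary outcomes alike);
* `"cr2"` (pipeline default) — Bell-McCaffrey CR2 cluster-robust standard
  errors with Satterthwaite df, computed in the GLS-whitened space where the
  random-intercept fit is an OLS problem. This absorbs per-subject variance
  differences and, in 200-cohort null simulations, holds every pipeline
  test's type-I error within binomial 99% bounds of 5%.

ML remains available (`reml=False`) for likelihood comparisons across fixed-
effect structures; REML is the estimation default because ML variance
components are biased low with few subjects and inference inherits the bias.

## Problem sizes used in the automated checks

Simulation-based checks run at sizes chosen to make their Monte-Carlo noise
small relative to the tolerances they assert: mixture recovery at 2,000
trials (weights within ±0.03, sigma within ±5%); permutation-null
calibration over 200 datasets of 150 trials with 99 permutations; pipeline
type-I calibration over 200 study-sized cohorts; effect recovery over 200
cohorts of 30 subjects. The injected time effects for recovery are at the
magnitudes this task exhibits (thousands of ms); effects of tens of ms are
not resolvable by any estimator at these replicate counts and are not
asserted.

## Known limitations

* The linear probability treatment of per-trial correctness can fit cell
  means outside [0, 1] in extreme cohorts.
* The mixture model assumes one shared isotropic sigma; anisotropic or
  component-specific imprecision is not modelled (the task reports a single
  imprecision metric).
* The permutation null's upper tail is compressed by the item-separation
  coupling (see above); only the rejection region is claimed calibrated.
* Carryover/period-effect decomposition beyond the session term is out of
  scope, as is any EEG/imaging-based stratification.
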