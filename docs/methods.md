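# Methods

## Cohort data model

A cohort is three tables keyed by `subject_id`: baseline covariates
(gender; ages at event and admission in months; etiology as traumatic /
anoxic / other non-traumatic; length of first stay in days; days of
coma; event-to-discharge interval; decompressive craniotomy or
neurosurgery flag; epilepsy-during-stay flag), a long-format score table
(total FIM 18–126 and the selfcare 8–56 / mobility 5–35 / cognition
5–35 subscales at admission, discharge and yearly follow-ups Y1–Y7),
and one exit record per subject (last in-service timepoint plus reason:
still in service, death, exit on recovery, opt-out, or administratively
censored). Validation enforces the scale bounds, the exact
domain-sum identity, the presence of admission and discharge scores for
everyone, and that no score is observed after the recorded service
exit. Missing follow-up visits are absent rows; no sentinel values and
no imputation anywhere in the package.

Covariate screening computes all pairwise Spearman correlations
(p-values from the t approximation, Bonferroni-corrected over the number
of tested pairs) and retains a maximal set in which no retained pair is
both strong (|r| ≥ 0.5) and significant at the corrected 0.01 level.
Which member of a conflicting pair survives is controlled by an explicit
priority list (default: the clinical ordering gender, age at event,
etiology, age at admission, LOS, coma, DC/N, epilepsy), making the
selection deterministic and row-order invariant. On the synthetic cohort
this screen drops age-at-admission (collinear with age-at-event up to
the short admission delay) and keeps the rest.

## The joint latent-class model

The model is a latent-class growth model in the fixed-effects (Nagin)
sense — no subject-level random effects — extended with a
dropout equation:

* membership: multinomial logit of class on z-standardized covariates
  (binary covariates stay 0/1), class 1 as reference;
* trajectory: class-specific quadratic (degree configurable) in years
  since admission, Gaussian residual σ shared across classes (a
  class-specific-σ flag exists);
* exit: class-specific discrete-time hazards h\_{kj} over the seven
  yearly intervals. Exit reasons are collapsed to exit-vs-survive in the
  likelihood (no competing risks); censored and still-enrolled subjects
  contribute survival terms only. Dropout is therefore informative about
  class through the hazards but missing visits within the service are
  treated as missing at random.

Estimation is EM. Initialization draws per-subject responsibilities
from a flat Dirichlet, per start (seed = base seed + start index); the
best converged start by log-likelihood wins. The M-step solves
posterior-weighted least squares for β and σ, occurrence/exposure
ratios for the hazards (clipped to [1e−6, 1−1e−6]), and a damped-Newton
posterior-weighted multinomial logit for γ (warm-started, accepting only
steps that increase the weighted log-likelihood, so every EM iteration
is monotone; a 1e−10 ridge keeps the Hessian invertible under
collinearity). Convergence is declared at relative log-likelihood change
≤ 1e−6 (cap 500 iterations); a start whose class loses essentially all
posterior mass (< 1e−8) is abandoned rather than failing the fit.
Degenerate inputs (non-finite parameters, empty classes) raise
immediately; all mixture arithmetic is done in log space.

Classes are relabeled a posteriori in ascending order of the mean
model-implied trajectory averaged over the 0–7-year window
(`β_k · (1, 7/2, 49/3)` for a quadratic). This agrees with ordering by
the year-7 endpoint whenever endpoints are separated, but remains stable
when the two fast-responder curves converge near the scale ceiling by
year 7, where an endpoint ranking flips under estimation noise. Class 1
is always the floor-level non-responder curve and is the reference for
the reported membership coefficients, which are on the standardized
covariate scale. Fitted mean trajectories may leave the scale bounds
(the likelihood is an unbounded Gaussian); reported/predicted curves are
clamped to the bounds for display only.

Parameter count for BIC: (K−1)(p+1) membership + K(degree+1) trajectory
+ 1 residual scale (K if class-specific) + 7K hazards. The per-class
sharpness diagnostic is the mean maximal posterior among the subjects
assigned to each class. Ties in maximal-posterior assignment go to the
lower class index (determinism).

## Validation and cross design

The stability check randomizes the cohort into halves and compares a
constrained fit (one parameter set, i.e. the pooled fit) against an
unconstrained one (independent parameter sets per half, log-likelihoods
summed) with a likelihood-ratio test on df = one parameter set. "Fully
pooled vs fully free" is an interpretation: intermediate constraint
patterns are not implemented. Because EM can stop in local optima, each
half's log-likelihood is floored at the pooled parameters' likelihood on
that half — the pooled solution is an admissible per-half parameter
set — which enforces the nesting inequality by construction.

Cross-design labelling fits the model on each half and assigns the
other half with frozen parameters, so every subject's label comes from
a model that never saw it. Halves are harmonized through the canonical
ordering above; a Hungarian posterior-overlap matcher is available as a
robustness alternative.

## Discharge prediction

Features per subject: score at admission, discharge-minus-admission
delta (the strongest predictor on synthetic data, as in the clinical
setting this emulates), coma days capped at the event-to-discharge
interval, age at event, etiology dummies, gender, LOS, DC/N and
epilepsy flags. Nothing observed after first discharge enters the
table (asserted by test). The classifier is a multinomial logistic
regression on standardized features with ridge λ = 1e−4 (intercept
unpenalized; guarantees existence under separation; one-vs-rest
available behind a flag). Standardization statistics are learned on the
training folds only. The CV protocol mirrors the study design: two
randomized halves, k = 5 consecutive folds per half after a seeded
shuffle (unstratified by default, with a stratification flag), retrain
from scratch per fold, join the two halves' out-of-fold predictions
before computing metrics. Reported metrics: accuracy, macro
(unweighted) precision, Cohen's κ, per-class one-vs-rest AUC on the
class probability columns, raw and row-normalized confusion matrices,
and the share of errors between canonically adjacent classes.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:
600 subjects; four archetypes in canonical order with mixing
proportions 0.35 / 0.22 / 0.28 / 0.15 (non-responders, slow, low-start
fast, high-start fast); observation noise σ = 6 FIM points around
class-specific quadratic means; 61.2% male; admission a median 43 days
after the event; 5% intermittent missed follow-up visits (missing at
random given class, never past the service exit); declining
class-specific exit hazards with reason mixtures (recovery exits
concentrated in the high-functioning classes, opt-outs among slow and
non-responders, deaths at a low uniform rate); and administrative
censoring from staggered entry over a 16-year recruitment window.
Domain scores split the total in the 8/5/5 item-count proportions with
largest-remainder rounding, making the domain-sum identity exact while
respecting subscale bounds.

Trajectory anchors (admission → year 1 → year 7 totals) are
18→22→28 (non-responders), 25→40→85 (slow, reaching >80 by year 7),
30→60→115 (low-start fast) and 85→100→118 (high-start fast). Anchors
were chosen so that each interpolating quadratic stays inside the
18–126 scale over the whole window: a quadratic cannot represent a
rise-to-plateau that reaches near-ceiling by year 1 without overshooting
the ceiling mid-window, so the fast classes rise somewhat more gradually
than their clinical namesakes; the scale floor still truncates the
non-responder noise distribution, which biases that intercept upward by
roughly +2 points — within the recovery tolerance used in tests.
Class-conditional covariate distributions encode the qualitative
clinical pattern (responders older, shorter coma, fewer anoxic
etiologies; high-start fast responders shorter stays; slow responders
less epilepsy). Their separation was calibrated once so that the latent
structure is recoverable (4-class ARI ≈ 0.95, sharp posteriors) while
all pairwise covariate correlations stay below the 0.5 screening
threshold — stronger separation makes coma and LOS collinear enough
that the screen would remove coma, which the emulated study retains.

What the generator does not emulate: exact demographic margins
(cranial fractures, motor-impairment categories), calendar-time
effects, within-stay measurement dynamics (scores move on a yearly
basis plus one discharge point), informative intermittent missingness,
and any trajectory shape outside the polynomial family. Passing
recovery tests on this generator therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not
clinical validity on real cohorts.

Under these frozen conditions one acceptance property falls short of
its nominal bar: the 2-class fit's per-class mean posterior reaches
≈ 0.97 rather than ≥ 0.99. About 15% of subjects are never observed
past discharge (as in the emulated attrition pattern), and for them the
bounded in-stay score separation plus the covariate prior cannot push
the merged responders-vs-non-responders posterior to near certainty;
the corresponding strict test is intentionally left failing rather than
weakening the condition.

## Problem sizes and seeds

Default analyses use n = 600 with 10 EM restarts (a 4-class fit takes
~1–2 s). Replicated studies in the test suite are scaled down by
design: BIC model-selection calibration uses 20 replicates of n = 300
with 3 restarts per fit; stability-test calibration uses 20 replicates
of n = 400 two-class cohorts. All randomness flows from explicit seeds
(generator seed; EM seed + start index; stage seeds in the pipeline
derived from the master seed by fixed offsets), and refitting with the
same seed is bit-identical.
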