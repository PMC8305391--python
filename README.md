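# trajstrata

Trajectory stratification of long-term functional recovery after
pediatric acquired brain injury (ABI).

Children admitted to inpatient rehabilitation after an ABI respond very
differently to the same standardized program: some recover most function
within the first year, some improve slowly over many years, and some
never leave the floor of the scale. `trajstrata` is a toolkit for
clinicians and biostatisticians who want to (1) stratify a longitudinal
cohort of FIM/WeeFIM scores into latent recovery-trajectory classes while
accounting for informative dropout from the follow-up service, and
(2) predict, for a single new patient, the long-term trajectory class
from information available at first discharge.

## The model

For subject *i* with baseline covariates *x*, observed total (or domain)
FIM scores *y* at times *t* (years since admission; discharge at
LOS/365.25), and a service-exit record, the K-class joint latent-class
growth model couples three equations:

* membership — multinomial logit, class 1 (non-responders) as reference:
  `P(c_i = k | x_i) = softmax_k(γ_k' x_i)`;
* trajectory — class-specific polynomial with Gaussian residuals:
  `y_ij | c_i = k ~ N(β_k' (1, t_ij, t_ij²), σ²)`;
* service exit — class-specific discrete-time hazard over the seven
  yearly follow-up intervals: survival factors `(1 − h_kj)` for each
  interval completed in service and `h_kj` at the exit interval for
  subjects who left (death, exit on recovery, opt-out); administratively
  censored subjects contribute survival terms only.

The observed-data log-likelihood
`Σ_i log Σ_k π_k(x_i) · L_ik` is maximized by multi-start EM; missing
follow-up visits are simply omitted (no imputation). Classes are
relabeled a posteriori in ascending order of the mean model-implied
trajectory, the number of classes is chosen by BIC
(`−2·loglik + n_params·ln N`) together with a per-class posterior
sharpness diagnostic, stability is checked by a split-half
constrained/unconstrained likelihood-ratio test, and an unbiased class
label for every subject comes from a cross design (fit on one random
half, assign the other, and vice versa). Discharge-based prediction is a
ridge-stabilized multinomial logistic regression on first-admission and
first-discharge features only, evaluated with out-of-fold predictions
(k consecutive folds per randomized half) via accuracy, macro precision,
Cohen's κ, per-class one-vs-rest AUC and row-normalized confusion
matrices.

A synthetic-cohort generator with ground-truth class labels reproduces
the statistical structure such an analysis assumes — four trajectory
archetypes (non-responders 35%, slow 22%, low-start fast 28%, high-start
fast 15%), class-linked covariates, bounded noisy scores, and monotone
informative attrition — so the whole pipeline is exercisable offline.

## Worked example

```python
import numpy as np
from trajstrata import (GeneratorConfig, TrajectoryMixture,
                        generate_cohort, screen_covariates)

cohort, truth = generate_cohort(GeneratorConfig(seed=42))
selected, _ = screen_covariates(cohort.covariates)
model = TrajectoryMixture(n_classes=4, seed=7, n_starts=10,
                          membership_covariates=selected).fit(cohort)

print("marginal class probabilities:", np.round(model.marginal_probs_, 3))
print("year-7 mean outcome per class:", np.round(model.endpoint_means_, 1))
print("mean max posterior:", round(model.posterior_.max(axis=1).mean(), 3))
```

prints

```
marginal class probabilities: [0.351 0.212 0.304 0.133]
year-7 mean outcome per class: [ 27.7  84.4 115.5 116.8]
mean max posterior: 0.981
```

Class 1 is the floor-level non-responder class: its fitted marginal
share (35.1%) recovers the generating 35% mixture weight. The year-7
means separate non-responders (≈28 points, near the scale floor of 18)
from slow responders (≈84) and the two fast-responder classes (≈116,
near the ceiling of 126). The mean maximal posterior probability (0.98)
says subjects are assigned to their class almost deterministically. On
this cohort the maximal-posterior labels agree with the generator's
ground truth at adjusted Rand index 0.95.

The same analysis, end to end with stability tests, cross-design labels
and discharge prediction, runs from the shell:

```bash
trajstrata run --seed 42 --out report/
trajstrata simulate --seed 42 --out cohort/       # or stage by stage
trajstrata scan --cohort cohort/ --classes 2,3,4,5 --out bic.csv
```

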