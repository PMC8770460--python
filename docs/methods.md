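# Methods

This note records the models, defaults and design choices behind
`immunoprog`, and what the synthetic cohorts do and do not establish.

## Synthetic immunome cohorts

The generator emulates a serum AAb protein-microarray study of resected
early-stage NSCLC patients: 1627 analyte probes spotted in quadruplicate
plus positive-control probes, 157 patients labelled 92 survivors / 65
non-survivors, and a ~70/30 stratified split into a training and a
validation cohort (65+46 / 27+19).

**Intensity model.** Probe p draws a log-mean from a hyperprior
N(μ₀ = 6.0, 0.8); sample s adds biological log-noise N(0, 0.5) and a
sample-wide array effect N(0, 0.15) (the thing control-probe anchoring
removes); replicate spots add technical log-noise N(0, 0.1) around the
sample-probe true value. All values are therefore strictly positive and
right-skewed, matching fluorescence data. Control probes have a fixed
log-mean 8.0 and carry no biology.

**Planted markers.** A planted marker multiplies the intensity of a random
*penetrant* subset (fraction = penetrance) of one outcome group by a fixed
effect (≥ 1). This reproduces the penetrance structure the pFC filter
targets: only some patients respond, responders respond strongly. The mean
IFC of carriers converges to the effect multiplier (checked by test).

**Survival model.** Outcome labels are fixed by the configured group
sizes, as in the study design, so event times are drawn conditional on
outcome: non-survivors die before the 1825-day follow-up horizon with an
exponential time truncated at the horizon, whose log-rate is
`log(baseline) + hazard_link × burden` (burden = number of planted markers
the patient carries; baseline = log 2 / 365 day⁻¹ so a zero-burden
non-survivor has ~1-year median survival; hazard_link default 0.3).
Survivors are event-free with follow-up uniform on the printed 1195–2555
day range; `censoring_rate` (default 0.1) is the fraction of survivors
lost to follow-up early (uniform 180–1195 days). Times are recorded at
day resolution with a 1-day floor. The exponential form satisfies
proportional hazards, so Cox recovery is well-posed. The censoring
distribution and real event-time distribution are unreported for the
study; these parameters are free knobs of the simulator, not estimates.

**Clinical covariates** (age, gender, histology, IASLC stage, nodal
status, LVI, adjuvant chemotherapy) are drawn with mild outcome- and
stage-dependence so the multivariate Cox stage has non-trivial
competition; they are decoration, not a calibrated epidemiological model.

**Stratified split.** Per-group training counts are round(size ×
fraction), half away from zero, with any residual against the overall
target absorbed by the largest group; this reproduces 65+46 = 111 exactly
from 92/65 at fraction 111/157. Assignment within groups is seeded-random.

## Preprocessing

Replicates aggregate to the median; the replicate CV (sample SD/mean)
above 0.2 flags a cell, and an array with > 20% flagged analyte probes is
flagged as failed (a simple, published stand-in for a proprietary QC
pipeline). Normalization is two-stage "composite": (1) intensity module —
each sample is rescaled so its control-probe geometric mean equals the
grand geometric mean; (2) quantile module — analyte probes are
quantile-normalized across samples, ties receiving the mean of the target
quantiles their rank span covers. The referenced composite method is not
published in reconstructable detail; this two-stage form implements both
named modules with testable contracts (control anchoring to 1e-9,
idempotence, within-sample rank preservation). Whether the study
normalized before or after aggregation is unstated; this package
aggregates first.

## Penetrance fold-change filter

The identity of the IFC "control group" is unstated in the printed
definition; here it is the opposite outcome group of the direction under
test (non-survivors when asking for survivor-elevated markers, and vice
versa), configurable. The filter is exposed symmetrically
(`directions="both"`, union of the two directional passes) because a
one-directional reading of the printed criteria cannot plausibly retain
the reported ~83% of probes; the reported 1355-of-1627 pass count is not
reproducible from the printed criteria under any simulated condition we
generate, and is documented here rather than resolved. All comparisons
are inclusive; a pFC over an empty passer set is recorded as absent, not
zero. No multiple-testing correction is applied at this stage.

## Stability selection

Each RFE iteration i seeds `seed_base + i`, bootstraps the samples
(re-drawn until both classes are present), and alternates
random-forest fitting (default 500 trees, √p features per split) with
elimination of the lowest-importance 20% of probes down to the target
panel size. "Unsupervised iterations" is interpreted as re-seeded forest
randomness plus a bootstrap of samples per iteration. Stability rank
orders by (selection frequency desc, mean final-fit importance desc,
probe id asc) — a total order, so cumulative panels are reproducible.
The elastic-net corroboration fixes the mixing parameter at 0.9 and picks
the penalty by repeated 10-fold cross-validated deviance with the 1-SE
rule. Differential reactivity uses a rank-sum test with BH FDR at the
FC ≥ 2 / ≤ 0.5, q ≤ 0.05 cut-offs; a count-based differential-expression
model is a category error on continuous fluorescence data, so a valid
two-sample test is used at the same cut-offs.

## Additive panels and boosting

The boosted classifier is componentwise LogitBoost: each round fits a
one-variable weighted least-squares learner to the working responses and
adds half of the best one, scaled by a 0.1 learning rate; 100 rounds with
early stop when training deviance improves < 1e-6; probabilities clipped
to [1e-6, 1−1e-6] against separation. Default CV is stratified 5-fold
repeated 10 times (leave-one-out available). Every reported metric uses
only out-of-fold scores. Note that out-of-fold scores from different fold
models share no common scale, so even a separable probe only yields OOF
AUC 1.0 when the class margin dominates between-fold model variation.
The operating point maximizes Youden's J with ties toward higher
specificity; the positive class for sensitivity is the non-survivor
(prognostic event), configurable. The peak panel is the smallest k whose
AUC is within a tolerance of the curve maximum.

## AICc inference

Backward elimination drops the probe with the largest likelihood-ratio
p-value while it exceeds 0.05 (LR preferred over Wald for small samples;
configurable in principle via the fitter). AICc uses the standard
second-order form `AIC + 2K(K+1)/(n−K−1)` with K counting the intercept
(so the intercept-only model on balanced 10/10 labels gives
logL = 20 ln ½ = −13.8629 and AICc = 29.9481). Enumeration of subsets is
exhaustive up to a 2¹⁸-fit cap (the 18-marker stage's search space) and
falls back to a seeded genetic search past it; the logistic fits use a
vectorised Newton solver with a 1e-4 ridge retry on separation, verified
against statsmodels in tests. Whether the study's final model was a
global minimum over all subsets or a size-limited family is unstated;
both modes are provided (`max_subset_size`).

## Survival stratification

Risk score = logistic linear predictor of the final model. The cut-off is
the Youden-optimal threshold over midpoints of adjacent unique training
scores (ties: higher specificity, then lower cut-off; a
closest-to-(0,1) rule is available) and is learned on cohort 1 only.
KM estimation, the log-rank test and Cox regression (Efron tie handling,
backward elimination by Wald p) are delegated to lifelines; the 5-year
horizon is 1825 days to match the study's follow-up unit. Median survival
is absent when the curve never crosses 0.5.

## ROC machinery

AUC is the rank statistic with half credit for ties; variance, 95% CI and
curve comparisons use DeLong structural components (paired covariance when
the cohorts share samples). The comparison test for ROC curves is DeLong's
because the study does not name one.

## Problem sizes and numerical choices

The full-scale defaults (1627 probes, 100 RFE iterations, 500-tree
forests, 5×10 CV, 2¹⁸-fit enumeration) are what a real analysis would
run. The test suite and the acceptance script run the same code on scaled
study conditions chosen as this package's own desk-scale defaults:
200–250 probes (the post-filter scale), 15–20 RFE iterations with 50-tree
forests, 5×2 CV, 40 boosting rounds, and subset enumeration capped at
2048 fits — with 13 planted markers at effect 4× and penetrance 0.6 in
157-sample cohorts split 111/46. Tolerances: normalization idempotence
1e-9 relative; weight normalization 1e-12; Newton convergence 1e-10 on
the log-likelihood with divergence declared at |β| > 1000.

## What passing tests show — and don't

The simulator provides log-normal, exchangeable-noise arrays with planted
multiplicative effects and proportional-hazards survival. Passing tests
show the pipeline recovers such structure (≥ 10 of 13 planted markers in
the top-60 stability set, validation AUC ≥ 0.8, significant KM
separation) and that the arithmetic of every printed, data-free quantity
is exact. They do not establish performance on real serum arrays, where
batch effects, spatially structured artefacts, heavy-tailed
cross-reactivity and non-proportional hazards all exist and are out of
scope of the generator. The study's own headline values (cohort AUCs,
HR, 5-year survival of high expressors) are computed on unreleased
patient data and are not reproduction targets.
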