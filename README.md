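# immunoprog

Prognostic autoantibody-panel discovery for serum immunome protein arrays.

Serum autoantibodies (AAbs) against tumour antigens are measurable years
before clinical events, and high-density protein arrays (1600+ antigens
spotted in quadruplicate, read out as relative fluorescence units, RFU)
profile a patient's whole AAb repertoire from one sample. `immunoprog`
implements a complete discovery pipeline for turning such profiles into a
small prognostic panel that separates post-operative survivors from
non-survivors in early-stage non-small-cell lung cancer, together with a
synthetic-cohort generator so every stage is testable without patient data.

## The method

1. **Preprocessing.** Quadruplicate spots are collapsed to their median
   (replicate CV > 0.2 flags a measurement); composite normalization
   anchors each array's positive-control probes to a common geometric mean
   (intensity module) and then quantile-normalizes the analyte probes
   across samples (quantile module).
2. **Penetrance fold-change (pFC) filter.** For probe A and sample X,
   `IFC(A, X) = RFU(A, X) / mean RFU(A, control group)`. Within a group the
   *penetrance frequency* is the % of samples with IFC ≥ 2 and the *pFC* is
   the mean IFC of exactly those samples. A probe passes when the elevated
   group has pFC ≥ 2 and penetrance ≥ 10% while the other group's
   penetrance is ≤ 10% (all inclusive). This targets markers strongly
   elevated in a *subset* of one outcome group — the typical AAb response
   shape.
3. **Stability selection.** Seed-iterated recursive feature elimination
   with random-forest importance: each iteration bootstraps samples and
   repeatedly drops the least-important 20% of probes; a probe's stability
   is the fraction of iterations it survives. Elastic-net logistic
   regression (mixing parameter 0.9) and a fold-change + BH-FDR
   differential-reactivity test corroborate the stability set.
4. **Additive panels.** The top stable probes are accumulated (1st,
   1st+2nd, …) and each nested panel is scored with componentwise boosted
   logistic regression under repeated stratified cross-validation, always
   on out-of-fold scores; the panel curve's peak fixes the working panel.
5. **AICc multi-model inference.** After stepwise backward elimination
   (likelihood-ratio drop tests), candidate subsets are scored with
   `AIC = −2 logL + 2K` and `AICc = AIC + 2K(K+1)/(n−K−1)` (K counts the
   intercept); Akaike weights `exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)` quantify each
   model's relative evidence, and the lowest-AICc subset is the final
   parsimonious panel.
6. **Risk stratification.** The final model's linear predictor is each
   patient's continuous risk score; the training cohort's Youden-optimal
   ROC cut-off dichotomizes everyone into high/low expressors, compared by
   Kaplan–Meier curves, the log-rank test and multivariate Cox regression
   with clinical covariates (age, gender, histology, IASLC stage, nodal
   status, lymphovascular invasion, adjuvant chemotherapy).

All modelling choices (filter verdicts, ranking, peak panel, coefficients,
cut-off) are learned on cohort 1 (training) and applied unchanged to
cohort 2 (validation).

## Worked example

```python
import immunoprog as ip
from immunoprog.pipeline import PipelineSettings, run_pipeline

# a study-sized synthetic cohort: 157 patients (92 survivors, 65
# non-survivors), 250 probes, 13 planted markers at 4x effect in 60% of
# the non-survivor group
markers = tuple(
    ip.PlantedMarker(f"P{j:04d}", group=ip.NON_SURVIVOR, effect=4.0, penetrance=0.6)
    for j in range(13)
)
config = ip.SimulationConfig(
    n_samples=157, n_probes=250, n_control_probes=8, group_sizes=(92, 65),
    planted_markers=markers, seed=42,
)
matrix, annotation = ip.simulate_cohort(config)
annotation["cohort"] = ip.stratified_split(annotation, 111 / 157, seed=42)

settings = PipelineSettings(          # scaled-down stage parameters
    rfe_iterations=15, rfe_trees=50, stability_k=15, cv_scheme="5x2",
    boost_rounds=40, peak_tolerance=0.01, max_subset_size=8, enumeration_cap=2048,
)
result = run_pipeline(matrix, annotation, settings=settings, seed=42)

print(f"probes passing pFC filter : {len(result.passing_probes)}")
print(f"peak additive panel size  : {result.peak_k}")
print(f"final model               : {', '.join(result.best_model.probes)}")
print(f"cohort-1 AUC              : {result.roc_train.auc:.3f}")
print(f"cohort-2 AUC              : {result.roc_validation.auc:.3f}")
strat = result.stratification
print(f"log-rank p (high vs low)  : {strat.logrank_p:.2e}")
for g, km in strat.km.items():
    print(f"{g:>4} expressors: 5-y survival {km.survival_at_horizon:.1f}%")
```

prints

```
probes passing pFC filter : 72
peak additive panel size  : 11
final model               : P0006, P0008, P0001, P0005, P0004, P0007
cohort-1 AUC              : 1.000
cohort-2 AUC              : 0.986
log-rank p (high vs low)  : 1.56e-47
high expressors: 5-y survival 0.0%
 low expressors: 5-y survival 96.8%
```

The filter keeps the 13 planted markers plus some chance passers; the
additive curve peaks at 11 probes; backward elimination and AICc reduce
this to a 6-marker model (the planted markers are heavily collinear, so a
subset carries the signal); the model transfers to the held-out cohort
(AUC 0.986) and its risk score splits the cohort into groups with sharply
different 5-year survival.

The same stages are exposed as a CLI
(`immunoprog simulate|preprocess|pfc|select|panels|infer|score|survive|report`);
each stage writes a JSON manifest with its seed, parameters and input
hashes.

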