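# packmark

Territorial scent-marking analysis for pack-living carnivores, built
around a fully synthetic data generator with known ground truth.

African wild dog packs defend exclusive territories yet must also hunt,
and field observations suggest a spatial trade-off: packs mark more and
hunt less when they are near territory boundaries shared with
neighbors. `packmark` implements the complete analysis chain for this
question — kernel territory estimation, used/available resource
selection, along-follow marking probability, and an aggregated-follow
mixed model of the marking-versus-hunting trade-off — together with a
movement/behavior simulator so every estimator can be validated against
coefficients it is known to have generated.

## The three models

Covariates are distances (m) to roads, grassland, seasonal pans and
permanent water, plus territorial terms: distance to the own core area,
signed distance to the nearest neighboring territory boundary, the count
of overlapping neighbor territories, and residency (inside/outside the
own 95% isopleth). All continuous covariates are standardized before
fitting.

1. **Weighted used/available RSF** (`fit_rsf`). Scent-mark locations
   (used, weight 1) are contrasted with points sampled uniformly inside
   the pack's 95% kernel territory (available, weight 100, 15 per used
   point), in a weighted logistic regression with one fixed intercept
   per pack. Selection is interpreted through `exp(alpha_j + x beta)`;
   contrasts are reported as log relative selection strength (log-RSS).
2. **Along-follow marking probability (RPSF)** (`fit_rpsf`). Within a
   continuous behavioral follow, each recorded event is scent-mark (1)
   or other (0); a logistic model with one fixed intercept per
   pack-follow combination yields absolute marking probabilities.
   Follows with no marks are removed (their intercept is unidentified);
   a random-intercept variant via Gauss-Hermite quadrature is available.
3. **Trade-off mixed model** (`fit_logratio`). Each follow is collapsed
   to an aggregated row: marks/h and hunts/h (with continuity constant
   c = 0.5), the response `log((marks/h + c') / (hunts/h + c'))`, and
   first-minus-last covariate deltas. A Gaussian linear mixed model with
   a random pack intercept is fitted by closed-form profiled REML.

Candidate models always include the four habitat distances; optional
territorial terms and interactions obey two rules — interactions involve
only one territorial partner family per model, and no model co-includes
a pair flagged by the |r| >= 0.6 collinearity screen. Models within
2 AICc of the minimum are averaged with Akaike weights (absent
coefficients enter as zero). Predictive skill of the trade-off model is
scored by 10-fold cross-validated RMSE against a training-mean baseline
with a paired t-test, and the RPSF by rank-based AUC.

## Worked example

Everything is driven by one run configuration (seed, window lengths,
isopleth levels, availability ratio, continuity constant, fold count):

```bash
packmark report --seed 1 --out run1
```

prints (abridged):

```
[config f3534fe89894] wrote run1/rsf_report.json
[config f3534fe89894] wrote run1/rpsf_report.json
[config f3534fe89894] wrote run1/tradeoff_report.json
AUC (analysis 2): 0.728; CV RMSE model 0.806 vs baseline 0.782 (paired t p = 0.0951)
```

With the default synthetic truth (selection toward roads and pans:
beta_road = -0.8, beta_pan = -0.5 on the standardized scale), the
averaged RSF recovers the signal — from `run1/rsf_report.json`:

```
beta: dist_road -0.691, dist_pan -0.183, dist_grassland -0.168,
      dist_water 0.230, own_core_dist -0.125, ...
3 models within 2 AICc of the minimum (3974.5; null model 4079.6)
```

and the along-follow model (`run1/rpsf_report.json`) gives
`dist_road -0.688`, `dist_pan -0.441` with AUC 0.728 against 0.695 for
the intercept-only null. The trade-off model's cross-validation
(`run1/tradeoff_cv.csv`) shows the synthetic generator's aggregated
follows carry little delta signal at this sample size (model RMSE 0.806
vs baseline 0.782, p = 0.095) — the expected outcome when marks are
placed by habitat, not by boundary deltas.

The same stages are available individually (`packmark simulate`,
`territory`, `rsf`, `rpsf`, `tradeoff`) and from Python:

```python
from packmark.pipeline import RunConfig, run_pipeline
results = run_pipeline(RunConfig(seed=1), "run1")
results["rpsf"]["auc"]          # 0.728...
results["rsf"]["averaged"].beta # averaged coefficients
```

Runs are byte-reproducible: the same configuration always writes
identical report files.

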