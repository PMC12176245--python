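# Methods note

This note documents the estimators, numerical choices and synthetic
generator behind `packmark`, including the defaults and their units.

## 1. Territory estimation (`packmark.territory`)

**Kernel utilization distribution (UD).** For one pack, fixes inside a
time window `(anchor - w, anchor]` (default w = 90 days) feed a
bivariate Gaussian kernel density on a 256×256 grid padded 3.5 h beyond
the fix bounding box. The reference bandwidth is

    h = sigma * n^(-1/6),   sigma^2 = (var(x) + var(y)) / 2

the classical bivariate "href" rule. The kernel sum is renormalized
over the grid so the discrete UD mass is exactly 1; truncation outside
the padded extent is therefore absorbed into the normalization.

**Isopleths.** The p-isopleth (territory p = 0.95, core p = 0.50)
thresholds the grid by descending cumulative cell mass and traces the
boundary with marching squares on a zero-padded copy of the mask.
Multiple rings are assembled by even-odd composition, so holes and
multi-patch territories are represented correctly. A degenerate
single-cell region yields a small square polygon flagged `degenerate`
with a warning.

**Derived quantities.** `signed_boundary_distance` is negative inside
the polygon and positive outside (distance to the boundary line);
`count_overlapping_neighbors` counts neighbor polygons covering a point
(boundary counts as inside); `UDGrid.mass_inside` integrates UD mass
over grid nodes covered by a polygon.

## 2. Covariates (`packmark.covariates`)

Landscape layers are distance surfaces (m) on regular grids sampled
bilinearly; points outside the extent raise a named error. The
assembled covariate table adds `own_core_dist`, `residency` (0/1),
`neighbor_boundary_dist` (minimum signed distance over neighbors) and
`n_neighbors`. Standardization is (x - mean)/sd with ddof = 1, recorded
so fits are invertible to natural units; zero-variance columns raise
with the column named. The collinearity screen computes pairwise
Pearson r and flags |r| >= 0.6. Seasons: early flood Apr–Jul, late
flood Aug–Nov, rainy Dec–Mar.

Layers round-trip to GeoTIFF via `tifffile` with a JSON sidecar holding
origin and resolution (plain local metric coordinates, no CRS).

## 3. Follow processing (`packmark.follows`)

**Regularization** resamples a collar track to a fixed interval
(default 3 h): each slot takes the nearest fix within half an interval;
interior holes spanning at most 2 intervals are filled by linear
interpolation; longer gaps stay missing.

**Follows** are continuous observation sessions recorded by critical
incident sampling: a location is logged only when a behavior occurs, so
the behavioral state persists between records. `interpolate_follow`
densifies a follow to a fine step (default 1 min) with linear positions
and forward-filled states. Follows with fewer than two events are
dropped with a warning.

**Used/unused labeling** marks each event as scent-mark (1) or other
(0) and removes follows without any mark — under fixed pack-follow
intercepts such follows carry no information and their intercepts are
unidentified.

**Aggregation** collapses a follow to rates `(count + c)/duration_h`
with continuity constant c = 0.5 (configurable; c = 0 raises if a count
is zero), the response `log(marks_rate / hunts_rate)`, and
first-minus-last event covariate deltas, both raw and binarized
(strictly positive → 1, else 0; an exact zero delta is 0).

**Availability sampling** draws `ratio` (default 15) points per used
point uniformly by area inside the territory polygon via rejection from
its bounding box.

## 4. Estimators (`packmark.inference`)

All three models are fitted by code in this package; `statsmodels` is
used only as a cross-checking oracle in the test suite.

**Weighted used/available RSF.** Bernoulli log-likelihood with case
weights (used 1, available 100) maximized by Newton–Raphson with step
halving (monotone log-likelihood), tolerance 1e-10, max 100 iterations;
one fixed intercept per pack. Complete separation (perfect
classification with pinned probabilities and |beta| > 10) raises
`SeparationError`. Standard errors come from the inverse observed
information. Interpretation is exponential: `exp(alpha_j + x beta)` is
relative selection intensity, so only contrasts (log-RSS) are
meaningful.

**RPSF.** The same logistic machinery with one fixed intercept per
pack-follow combination; fitted probabilities are absolute. Pack-follow
groups with a single response class are dropped with a warning. The
random-intercept variant integrates a Gaussian follow effect by
Gauss–Hermite quadrature (31 nodes) and maximizes with BFGS.

**Trade-off LMM.** Gaussian mixed model `y = X beta + u_j + e`,
`u_j ~ N(0, tau^2)`, `e ~ N(0, sigma^2)`, estimated by REML profiled
over the variance ratio lambda = tau^2/sigma^2. With grouped data the
covariance inverse is closed-form,
`V_j^{-1} = I - (lambda/(1 + lambda n_j)) 1 1'`, so each profile
evaluation is O(n). The scalar search uses bounded Brent on
log lambda in (−12, 12); the lower boundary is reported as
`zero_variance` (OLS). Residual variance is floored at 1e-30 so
noiseless designs remain finite. Pack BLUPs shrink group mean residuals
by `lambda n_j / (1 + lambda n_j)`. The parameter count for AICc is
k = p_fixed + 2 (sigma^2 and tau^2).

## 5. Model selection and evaluation (`packmark.selection`)

Candidate sets: every (non-null) model carries the four mandatory
habitat distances; optional linear terms enter by powerset; interaction
terms may involve only one territorial partner family per model
(residency-family or neighbor-family, never both) and, by default, only
with their main effects present. A screen-flagged pair involving an
optional term is never co-included; a flagged pair of two mandatory
terms only warns, since mandatory terms are in every model by design.
The intercept-only null model is the empty tuple.

AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1); models within 2 of the minimum
are averaged with Akaike weights, absent coefficients entering as zero
(full averaging). log-RSS between two covariate configurations is
`beta_bar . (f(x1) − f(x2))` with interaction products expanded. AUC is
the rank-based Mann–Whitney form (ties count one half). k-fold CV
(default k = 10, fold sizes differing by at most one) refits and
re-averages the candidate models per training split and predicts with
averaged fixed effects plus weighted pack BLUPs (zero for unseen
packs); the baseline is the training-mean predictor; the comparison is
a classical paired t-test over folds.

## 6. Synthetic generator (`packmark.synthetic`)

What it emulates: a multi-pack territorial system with habitat-driven
scent marking. What it does not emulate: real Okavango geography,
seasonal movement shifts, demography, or boundary-seeking patrol
behavior (marks are placed by habitat covariates, not by deltas — so
the trade-off model's delta terms are null under the default truth).

- Landscape: point/line features per class (road 10 chords, pan 30,
  grassland 25, water 15, two woodland classes 18 each) on a 60 km
  extent; exact shapely distances evaluated on a 128-grid; "cover" is
  the pointwise minimum of the woodland distances; terrain is a sum of
  12 Gaussian bumps normalized to [0, 1].
- Movement: discrete-time mean-reverting (OU-type) walk
  `x_{t+1} = c + phi (x_t − c) + eps`, `eps ~ N(0, sigma^2(1−phi^2))`,
  so the stationary law is exactly `N(c, sigma^2)` (phi = 0.7,
  sigma = 4 km, 3-h fixes, 720 per pack). Pack centers sit on a ring
  with chord spacing 2.2 sigma, giving realistic territory overlap.
- Follows: start uniform inside the pack territory, wander by a
  Gaussian step walk (SD 350 m per 6-min event, 25 events/follow);
  scent-mark probability is `logistic(alpha_j + beta . z)` with default
  truth `beta_road = −0.8, beta_pan = −0.5` on covariates standardized
  by grid-wide constants (echoed in the truth record); non-marks are
  hunts with probability 0.2, else move/rest. Pack social attributes
  (adults 3–16, pup presence fair coin, pack age 0–8 y) are constant
  within packs.
- Reproducibility: named `SeedSequence` substreams (landscape 0,
  fixes 1, follows 2, misc 3; pipeline 99); identical seeds give
  byte-identical pipeline reports.
- Direct truth samplers for validation: `simulate_rsf_points`
  (rejection-sampled used points with intensity `exp(beta . z)`) and
  `simulate_aggregates` (rows straight from the LMM).

## 7. Resolved design questions

- Core isopleth level 0.50; territory 0.95.
- Fixed pack-follow intercepts by default in the RPSF; follow-constant
  social covariates are collinear with those dummies, so the pipeline
  enters them only through interactions with point-varying terms
  (`require_main_effects=False` for that candidate set). The
  random-intercept variant estimates social main effects directly.
- Availability is area-uniform within the 95% territory.
- AUC is reported in-sample on the averaged RPSF, with the null-model
  AUC alongside for reference.
- Continuity constant c = 0.5 (standard continuity correction),
  configurable per run.
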