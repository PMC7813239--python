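# Methods

`refugia` implements a presence-background habitat-suitability workflow
for screening candidate translocation sites: predictor engineering from
raster grids, a hinge-feature maximum-entropy model, repeated k-fold
cross-validation with AUC-weighted ensembling, limiting-factor maps,
and a resampling null test for hold-out sites. This note records the
model, its assumptions, the defaults and why, and the choices made
where the design was genuinely open.

## The maximum-entropy model

Given m presence records and N background points with feature vectors
f(x) ∈ [0,1]^J, the model is the Gibbs distribution over background
locations

    q(x) = exp(η(x)) / Z,     η(x) = Σ_j λ_j f_j(x),

whose coefficients minimize the penalized log-loss

    L(λ) = −(1/m) Σ_i η(x_i)  +  log Σ_x exp(η(x)) − log N
           + Σ_j r_j |λ_j| ,          r_j = β √(s²_j / m),

where s²_j is the sample variance of feature j over the presences and
β is the global regularization multiplier (default **2.5**). The
objective is convex; the solver is cyclic coordinate descent with a
per-coordinate Newton step and soft-thresholding of the L1 penalty,
sweeping all coordinates until the relative change of the full
objective falls below `convergence_tol` (default 1e-7). Steps are
capped at ±2 per update and the cap is halved if a sweep ever
increases the objective (the local quadratic model of a log-sum-exp
can overshoot); the exponentiated background scores are refreshed from
scratch every sweep so multiplicative drift cannot accumulate. The fit
is deterministic given its inputs.

Two numerical safeguards matter and are deliberate:

- **Penalty floor.** The presence standard deviation in r_j is floored
  at 0.05 (features live in [0,1]). A hinge whose knot lies above all
  presence values is constant over the presences, and the unfloored
  rule would give it zero penalty and let its coefficient run away;
  with the floor, a very large β provably zeroes every coefficient.
- **Samples added to background.** `train()` appends the presence rows
  to the background before fitting (the reference Maxent default).
  Without this, any feature that separates the presences from the
  sampled background perfectly makes the objective unbounded below.
  Normalization statements ("raw predictions over the training
  background sum to 1") refer to this union.

### Features

Only hinge features are used. For each variable, knots are placed at
`knots_per_variable` (default **30**) evenly spaced quantiles of the
pooled presence+background values, with one forward hinge
max(0, x−t)/(max−t) and one reverse hinge max(0, t−x)/(t−min) per
knot. Quantiles are taken with the closest-observation rule so knots
are observed data values and duplicate knots on low-cardinality
variables collapse; knots at the variable's min or max are dropped,
and constant variables contribute no features. Features are clamped to
[0,1] when predicting outside the training range. Because knots are
quantiles and hinges are normalized by the variable range, multiplying
a predictor by a positive constant changes nothing.

### Outputs

The raw output q is a relative occurrence rate summing to 1 over the
training background. The logistic output

    p(x) = τ e^H q(x) / (1 − τ + τ e^H q(x)),

with H the entropy of q over the training background, maps it to an
interpretable (0,1) suitability; τ (default **0.3**) is the assumed
prevalence at an average site. τ affects only this transform, never
the fit.

Response curves sweep one variable over its observed range with all
other variables held at their presence means. The limiting-factor map
replaces, per cell and per variable, the cell's value by that
variable's presence mean and recomputes p; the limiting variable
maximizes (replaced − actual), with ties (including the all-zero case)
resolved to the earliest variable in canonical layer order.

## Predictors

Six predictors in canonical order: terrain roughness (max − min
elevation over the 3×3 neighbourhood, computed at fine resolution and
mean-aggregated to the analysis grid; neighbourhoods truncate at edges
and nodata, needing ≥ 2 valid cells), percentage of north-facing fine
cells (aspect from central differences, one-sided at edges; "north" is
the [315°, 45°) compass quadrant, configurable; flat cells have no
aspect and leave both numerator and denominator; an all-flat block is
nodata), woodland and grassland cover fractions (excluded classes —
water, cleared land — leave the denominator entirely; a block with no
valid cells is nodata), and two pass-through climate layers (minimum
temperature of the coldest month, mean annual precipitation).
Collinearity is screened with Spearman's rank correlation at an
explicit point set, because the coefficient depends on which points
(presences, background, or all cells) are used; constant predictors
give NaN, not 0.

## Evaluation and ensembling

AUC is the rank-based Mann–Whitney estimate (ties count one half); TSS
is max over thresholds of sensitivity + specificity − 1 with
background as absences, scanning all unique scores and reporting the
smallest maximizing threshold. Cross-validation partitions presences
and background independently into k folds (default **k = 10**),
repeats the partition (default **10** times), and fits one model per
training split; each repeat's best fold-model by held-out AUC enters
the ensemble, weighted ∝ max(AUC − 0.5, 0) (uniform fallback with a
warning if no member beats chance). Skill-above-chance weighting is
used because raw-AUC weights barely differ between members. Variable
importance is the mean AUC drop over seeded permutations of one
variable across the evaluation points, clipped at zero and normalized
to sum to 1.

## Hold-out null test

The suitability of g hold-out sites (default **g = 9**) is compared to
B random groups (default **B = 10 000**) of g distinct cells drawn
uniformly from a background extent; groups are distinct within, drawn
independently across groups. The p-value is the add-one form
p = (1 + #{null ≥ observed}) / (B + 1), which cannot reach 0 under
finite resampling. Both the normal-approximation 95% CI of the mean of
group statistics and the empirical 2.5/97.5 percentiles are reported,
since a narrow CI of the mean and a wide percentile band answer
different questions. The test is monotone (raising hold-out
suitability cannot raise p) and its type-I error is calibrated: with
hold-out groups drawn from the null itself, rejection at α = 0.05
occurs at the nominal rate (checked over 500 seeded replicates).

## Synthetic landscapes and the virtual species

The generator emulates the statistical structure of the real inputs —
a spatially autocorrelated DEM (smoothed Gaussian noise rescaled to
[0, 1500 m], smoothing σ = 2.5 fine cells, i.e. ~600 m, chosen so
roughness spans well past the saturation point below), a winter
minimum-temperature field (11 °C base, 6.5 × 10⁻³ °C/m lapse,
southward cooling of 0.035 °C per km, noise sd 0.4 °C), an annual
precipitation field (450 mm base + 0.55 mm per m elevation orographic
term + weak latitudinal gradient, noise sd 30 mm), and a smoothed
categorical vegetation mosaic (40% woodland, 30% grassland, 15% heath,
5% water, 10% cleared; the last two excluded from cover
denominators). The default domain is 120×120 coarse cells of 1 km
with a 4×4 fine subgrid (250 m); everything is reproducible from a
seed.

The virtual species' ground truth is

    logistic(−14 + 12·min(rough, 220)/220 + 2·bump(precip; 800, 500–1100)
             + 1·bump(tmin; 5 ± 4 °C) + 0.8·woodland),

i.e. a saturating terrain-roughness response with its knee at 220 m, a
unimodal precipitation response falling to zero at 500 and 1100 mm, a
unimodal cold-month temperature response peaked at 5 °C, and a linear
woodland effect. The coefficients deliberately make roughness dominant
and the species sparse (mean truth ≈ 0.13), so that a correct analysis
must rediscover the saturating shape, the unimodal climate responses,
and the dominance of roughness in permutation importance — which the
recovery tests check across 20 seeded end-to-end runs (the ranking per
run; the curve shapes on the pointwise-mean fitted curve across runs,
because single-run curves are noisy where data beyond the saturation
knee are sparse). Occurrences are sampled ∝ suitability with
replacement at cell centers (optional jitter), with configurable
fractions of exact duplicates and of >1 km-uncertainty records for the
filter to remove.

What the generator does **not** emulate: real geography and landform
(ridgelines, valleys, coasts), sampling bias toward roads and towns,
spatial clustering of records beyond what suitability induces,
non-stationary climate-elevation relationships, and realistic
vegetation-terrain dependence. In this landscape tmin and precip are
strongly negatively correlated (both are driven by elevation), unlike
field datasets where the two can correlate positively. Passing tests
therefore demonstrate correctness of the machinery and recoverability
of known signal — not that the method overcomes observational biases
absent from the simulation.

## Pipeline determinism and problem sizes

Every stochastic stage derives its seed as crc32(master_seed ":"
stage_name), so rerunning with one master seed reproduces every
numeric output byte-for-byte, and skipping an optional stage cannot
shift another stage's randomness. The full default configuration
(10 000/30 000 background points, 10×10-fold CV) mirrors the field
design; the `RunConfig.desk()` profile (2 000/4 000 background,
5-fold × 2 repeats, 10 knots, B = 1000 null groups, ~1 200
occurrences) is the package's quick profile used by the test suite and
the acceptance script, sized to keep a complete two-design run in a
few seconds while leaving all qualitative behaviour intact.

## Known limitations

- Reprojection is out of scope; all inputs must share one equal-area
  grid, and only block aggregation is provided for resolution changes.
- The solver matches the published penalty form, not the reference
  Java implementation's interpolation tables; coefficient-level
  agreement with other Maxent software is not a goal.
- Only hinge features exist (by design); the feature abstraction
  admits other classes but none are implemented.
- The null test draws spatially unconstrained groups; it does not
  match the hold-out group's internal spatial clustering.
- Background is sampled with replacement across cells, so duplicate
  background points occur on small extents.
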