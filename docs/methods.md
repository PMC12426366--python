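# Methods

`camtrap_eval` evaluates a multiclass wildlife detector's output on
camera-trap images against verified annotations, at the image level.
Bounding-box localization is deliberately never scored: what matters for
ecological use is whether each image's species labels and animal counts are
right, not where the boxes sit. This note records the models, conventions,
and numerical choices behind each stage, and what the synthetic study does
and does not emulate.

## Evaluation model

### Empty-image filtering (binary stage)

All animal classes are collapsed to a single "animal" label. Each reviewed
image gets a score equal to the maximum confidence over its animal-class
predictions; at a threshold *t* the image is predicted-animal iff that score
is ≥ *t* (inclusive comparison throughout the package). Against the
reviewed truth (a reviewed image with no annotations is confirmed empty),

    sensitivity = TP / (TP + FN),    specificity = TN / (TN + FP)

are swept over the default grid 0.25–0.95 by 0.10. Images whose only
content — true or predicted — is human/vehicle, and images with more than
one true class, are excluded by default (`keep_nonanimal=True` retains them
as "no animal"). Two detectors covering the same reviewed subset can be
cross-tabulated into a 2×2 agreement table stratified by true state.

### Species classification (multiclass stage)

Evaluation is one-vs-rest per species *s* at the image level. Within an
image, each class is represented by its highest-scoring box (the per-class
maximum; an alternative reading that thresholds the whole image on its
single top score is available via `score_rule="image-max"`). After removing
predictions below *t*:

* **TP** — images confirmed to contain *s* whose surviving predicted label
  set includes *s*;
* **FN** — images confirmed to contain *s* whose surviving set does not;
* **FP** — every other image whose surviving set includes *s*.

True negatives are undefined. Precision, recall and F1 follow the usual
formulas; the sweep grid is 0.25–1.0 by 0.05 (16 points, generated from
integer steps so endpoints like 0.65 and 1.0 are exact and inclusive
comparisons never flip on float accumulation).

**Threshold averaging.** The per-class "average precision/recall/F1" is the
unweighted mean over the grid. Grid points where a metric's denominator is
zero (e.g. no surviving predictions of the class) are *omitted* from that
metric's mean rather than imputed as zero: a prediction-free threshold
carries no information about precision. The harsher convention is available
with `undefined_as_zero=True`. Macro metrics are unweighted means over
classes with at least 10 training *and* 10 test images (`min_class_images`);
when no training-count table is supplied, eligibility uses test-set size
only. Multi-species truth images contribute independently to each of their
true classes.

**Size effects.** Ordinary least squares relates each class's threshold
averages to its number of training images, or the log10 thereof, with 95%
slope intervals from the t distribution on n−2 degrees of freedom. Fits use
the macro-eligible classes.

### Species richness

Richness at a station is the number of distinct species labels with at
least one qualifying detection at any of the station's images — from
verified annotations (no threshold) and from predictions at each threshold
on the 0.25–0.95 by 0.10 grid. Non-species labels (`human`, `vehicle`,
`unknown` by default) never count. Concordance is an OLS fit of predicted
on observed richness (slope, intercept, R²), plus the additive bias
predicted − observed summarized by its mean and sample SD over stations.
All stations are retained, including those with zero observed species; the
fit requires ≥3 stations and nonzero variance in observed richness.

### Animal counts

Count models use only images whose truth holds exactly one species and
whose surviving predictions include that species (true-positive,
single-species images). `count_pred` counts surviving boxes of the true
species only; misclassified boxes of other labels are ignored, because
counts are species-specific in the annotation model. Three models:

* **difference** — cell means of `count_true − count_pred` per class
  (no global intercept, so each coefficient is directly the class's mean
  additive undercount), 95% CIs from the pooled residual variance; a
  single-record class reports a coefficient but no CI;
* **ratio** — same design with response `count_pred / count_true`; a
  coefficient of 0.78 reads as a 22% mean undercount;
* **Poisson GLM** — `count_true ~ exp(a_i + b_i ln count_pred)` with a
  nested per-class intercept and slope (log link), fitted by iteratively
  reweighted least squares (statsmodels) to tolerance 1e-8, Wald 95% CIs.
  The nested form is used (rather than a main-effect + interaction
  parameterization, which is equivalent up to reparameterization) because
  the per-class prediction curve `exp(a_i + b_i ln x)` is the quantity of
  interest. A class whose predicted counts never vary has an inestimable
  slope and is rejected with an error naming it — in practice the
  slope-varying model applies to group-living species only.

## Synthetic study and detector-error model

The generator produces a station grid (`n_stations ×
deployments_per_station × images_per_deployment` images, exactly), marks
each image empty with probability `empty_fraction` (camera false triggers),
and otherwise assigns one species by abundance weight and a group size from
that species' distribution — fixed *k*, or zero-truncated geometric with
mean *m* (success probability 1/*m*), a one-parameter family with the long
right tail seen in real group-size data.

The detector model treats every individual animal as an independent
Bernoulli detection with a per-species probability; each detected
individual's label is drawn from a row-stochastic confusion matrix and its
score from the true-positive score distribution. Empty images receive
Poisson false boxes with labels from a false-positive class distribution
and scores from a separate distribution. Scores are Beta by default —
true positives Beta(5, 1.5) (mass near 1), false positives Beta(1.5, 4)
(mass near 0) — giving the score separation that makes high thresholds
informative; degenerate point-mass scores support exact identity tests.
Independence per individual keeps image-level recall in closed form:

    recall(t) = 1 − (1 − p_det · C[s,s] · S_tp(t))^g

for group size *g*, which is the analytic oracle the recovery tests check
the simulator against (within 3 binomial standard errors at n = 2000).

**Default study conditions** (`default_study_config`): 20 stations × 2
deployments × 60 images (2400 images), half empty; a 10-species long-tailed
community (weights 0.30 down to 0.015, mirroring the order-of-magnitude
class imbalance typical of camera-trap datasets); group-living species
(baboon, guineafowl, buffalo, eland, elephant, zebra) with zero-truncated
geometric group sizes, means 1.4–2.3, matching reported mean group sizes
for such taxa; per-animal detection probabilities 0.75–0.95; 92%
self-confusion with the remaining 8% on one visually similar class; 0.08
false boxes per empty image. These sizes keep every stage's statistics
stable while the whole pipeline runs in seconds.

**What the generator does not emulate:** image bursts and temporal
autocorrelation, day/night covariates, per-image detection correlation
(occlusion within a group), multi-species images (one species per occupied
image, matching the count models' restriction), and false boxes on occupied
images (off by default; a switch enables them). Tests passing on this
generator therefore demonstrate the *evaluation machinery* is correct under
the stated error model — not that any real detector satisfies that model.

## Review planning

Mirroring practical review workflows: every image with an animal prediction
above a floor (default 0.25) is selected; within any deployment-by-class
stratum larger than `overflow_trigger` (default 2000) images, a random
`bin_sample_target` (default 50) per score bin (0–0.25, 0.26–0.50,
0.51–0.75, 0.76–1.0) replaces exhaustive review; and up to
`empty_sample_target` (default 100) predicted-empty images are sampled per
deployment, all of them when fewer exist. Selection is deterministic given
the seed.

## Numerical choices

* Threshold grids are generated from integer steps and compared
  inclusively (≥ t); the t = 1.0 point keeps only scores exactly 1.0.
* Undefined metrics (zero denominators) are `None`, never silently 0;
  writers serialize them as empty cells.
* OLS fits are closed-form; a constant response is reported as slope 0 with
  R² defined as 0; a constant predictor is an error.
* Cell-means CIs pool the residual variance across classes
  (t quantile, N − k degrees of freedom).
* Result CSVs are written at full float precision and sorted by
  (class, threshold), so re-reading reproduces values to ≥12 significant
  digits and identical runs are byte-identical.
* All randomness flows through `numpy.random.default_rng(seed)` with sorted
  iteration orders, so identical (config, seed) gives identical output.

## Known limitations

* The detection-CSV dialect is this package's own interchange definition;
  no Pascal VOC or full COCO schema support.
* The binary stage's exclusion rules (human/vehicle-only and multi-class
  images) follow one defensible reading of standard practice; the
  `keep_nonanimal` switch exposes the alternative.
* The Poisson GLM reports Wald intervals, which are poor for classes with
  very few records; the cell-means models are the more robust summary
  there.
* Degenerate inputs (no reviewed images, zero observed-richness variance,
  classes absent everywhere) raise errors rather than returning silent
  defaults.
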