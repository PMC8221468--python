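# Methods

## The estimand and the design

Let `I` denote an intervened (impact) pixel and `C_1..C_n` its matched
control pixels; `B` and `A` the sets of analyzed years before and after the
intervention started. With μ the arithmetic mean over the listed values
(temporal for the impact pixel, temporal-and-spatial over controls), the
per-pixel BACI contrast is

    contrast = (μCA − μCB) − (μIA − μIB).

Under an additive data model

    index(pixel, year) = baseline(pixel) + year_effect(year) + δ·1[impact, post] + ε

the year effects — interannual rainfall, drought, phenology shared by
impact and controls — cancel exactly and E[contrast] = −δ. This is the core
identification assumption: *controls experience the same temporal
environment as the impact pixel*. Control matching within pre-intervention
vegetation clusters exists to make that assumption credible; it cannot
repair controls that respond differently to the same weather.

Sign conventions: negative contrast = the impact pixel improved more than
its controls. For the bare-soil index (BSI), where "improvement" is a
decrease, the contrast is multiplied by −1 so map legends and group
statistics read identically across services.

The relative contrast, contrast / μIB × 100, expresses the effect against
the pixel's own pre-intervention baseline. It is reported as undefined when
|μIB| < 0.01 index units: near-zero baselines produce arbitrarily large
percentages that carry no information.

## Ecosystem-service models

Field indicators (stratified vegetation cover %, green biomass kg m⁻²,
spekboom cover %) are regressed on one spectral index, linear or quadratic,
optionally with additive terrain terms. The candidate family is
deliberately small — the only nonlinear form admitted is a degree-2
polynomial of a single index, and multi-predictor forms are single index +
one terrain layer — because with ~32 plots of data anything richer is noise.
Multi-predictor candidates with any VIF ≥ 5 are screened out before
fitting. Quadratic single-index forms are exempt from the screen: x and x²
are collinear by construction and the screen targets between-predictor
redundancy, not polynomial bases.

Ranking uses AIC = n·ln(RSS/n) + 2k with k counting all estimated
coefficients. Constant terms cancel within a run, which is the only place
the AIC is used; a small-sample AICc (`corrected_aic=True`) is available.

Cross-validation is 5-fold, re-randomized over 100 repeats, with per-fold
R² scored as the squared Pearson correlation between held-out observations
and predictions. That convention (the one the caret ecosystem uses) is
nearly unbiased at fold sizes of a few dozen, where the 1 − SSres/SStot
form is systematically pessimistic. Std.RMSE divides the repeat-mean RMSE
by the observed indicator range (Ymax − Ymin).

Plots are 900 m², i.e. exactly one 30 m pixel, so a plot takes the index
value of the pixel containing its center — no areal averaging. Rows with a
missing indicator are dropped per service (spekboom cover is recorded on
fewer plots than the other indicators).

The three published calibrated models ship as `published_models()`:

    StrVC = 56.36·BSI² − 36.66·BSI + 6.06
    GB    = 47.62·NBR² + 55.55·NBR + 8.71
    SbC   = 12.24·MSAVI + 0.01·Elevation − 10.49

Predictions are never clipped to physical ranges; the out-of-range fraction
is logged instead, keeping the model's raw behavior auditable.

## Spectral indices

The ten indices use the six reflective bands. Normalized-difference forms
are masked (not zeroed) at zero denominators — an undefined ratio is a data
gap, not a value. EVI uses G = 2.5, L = 1, C1 = 6, C2 = 7.5. SAVI defaults
to the conventional L = 0.5 and is configurable; the soil-adjustment
literature also uses L = 1, and nothing downstream depends on the choice.
BSI is parenthesized as ((SWIR1+Red) − (NIR+Blue)) / ((SWIR1+Red) +
(NIR+Blue)), the standard definition, which keeps it in [−1, 1]. Output
pixels are invalid wherever any required input band is invalid.
Reflectance outside [0, 1] (atmospheric-correction artifacts) is retained
and surfaced through a QA report rather than masked, since masking would
silently change index values.

## ISODATA trajectory clustering

Pixels are described by their index trajectory over the pre-intervention
scene archive (T dates; ten in the reference setting) and clustered in
Euclidean trajectory space. The classic desktop implementations of ISODATA
are proprietary, so this is a textbook version with every knob explicit:

* initialization — K centroids spread along the first principal axis of
  the trajectories at the 5th–95th percentile of the projections
  (deterministic; no random restarts needed for this data shape);
* assignment/update — k-means iterations, which never increase the total
  within-cluster sum of squares;
* discard — clusters below min_size = max(10, 0.1·m/K) members are
  dissolved and their pixels reassigned;
* split — while fewer than K clusters, the cluster with the largest
  per-feature standard deviation splits along its widest feature if that
  deviation exceeds the overall feature SD of the data;
* merge — centroid pairs closer than the merge threshold coalesce. The
  default threshold is the mean pixel-to-centroid distance (the typical
  within-cluster scatter): duplicate centroids merge, separated clusters
  never do. A fixed threshold can be supplied instead. An earlier
  candidate default, half the median inter-centroid distance, was
  rejected because with K roughly equally spaced clusters it merges
  genuinely distinct neighbors;
* convergence — stop when the fraction of pixels keeping their label
  reaches the convergence limit (default 1.0, i.e. fully stable) or at
  max_iter = 50.

Pixels missing any date are left unclustered (label 0) by default, with
optional per-date mean imputation; a cloud-free archive never triggers
either. After convergence clusters are renumbered 1..K by decreasing mean
centroid value, so cluster 1 is the densest vegetation for a vegetation
index. Clustering is done per service index (configurable), since each
service is tracked by its own index.

## Scene filtering and selection

Scenes with strictly more than 5 % invalid pixels in the control area are
excluded (integer-count comparison, so exactly 5.0 % survives); retained
scenes keep their per-pixel masks. Per analyzed year, the scene maximizing
the spatial-mean vegetation index (or minimizing mean BSI) over valid
study-area pixels is selected whole — no per-pixel compositing — with exact
ties going to the earliest date. Periods default to 3 before- and 3
after-years; interventions too close to the start of the archive simply get
fewer before-years (two in the reference setting's 1990 interventions), and
scenes in the start year count as "before" iff acquired before the
intervention date at day resolution.

## Controls and p-values

Controls are drawn uniformly without replacement from {control-eligible ∧
same cluster ∧ valid in every period scene}, independently per intervened
pixel; reuse across pixels is allowed (tens of thousands of draws of 20
would otherwise exhaust the pool). The random stream is keyed by
(seed, row, col), making every pixel's draw reproducible and independent of
processing order. In strict mode a pool smaller than n is an error naming
the cluster; `allow_fewer` records the actual count instead.

The per-pixel p-value is a design choice of this package (the upstream
literature reports per-pixel significance without specifying a test). The
default is a rank test: the impact pixel's temporal change μIA − μIB is
ranked by absolute deviation from the group mean within the null population
formed by the n control changes plus its own; p = (1 + #{|d − mean| ≥
|d_impact − mean|}) / (n + 1). It is distribution-free and exact, with a
floor of 2/21 ≈ 0.095 at n = 20 — appropriate honesty about what 20
controls can resolve. A Welch-style prediction t-test (`method="welch"`)
is offered where a continuous p is preferred.

## Group comparisons

Pixel samples are thinned to ≥ 60 m center-to-center spacing (so pixels two
columns apart qualify) by greedy rejection over a seeded random
permutation — a maximal-effort, not maximum, independent set; the upstream
procedure names the distance but no algorithm. Location per group is the
Hodges-Lehmann pseudo-median (median of all Walsh averages (xᵢ+xⱼ)/2,
i ≤ j), dispersion the IQR. Kruskal-Wallis (tie-corrected, via scipy) tests
overall differences; Games-Howell pairwise comparisons use the Welch
statistic with Welch–Satterthwaite degrees of freedom against the
studentized-range distribution, implemented here directly (an independent
implementation cross-checks it in the tests). Shapiro-Wilk per group is
recorded as the pre-check that motivates the nonparametric route. Compact
letters assign one letter per maximal clique of the
not-significantly-different graph, so two groups share a letter iff no
pairwise test separates them at α — the insert-and-absorb shortcut was
rejected because it can orphan valid pairs. Slope/elevation associations
are simple least-squares of contrast on the covariate over a seeded 10 %
pixel sample, reported as R²; soil comparisons use the five parent-material
classes with the largest intervened coverage (ties alphabetical). Aspect
is discretized into 8 compass octants plus "flat" below 2° slope.

## Synthetic landscapes

The generator emulates exactly the structure the design assumes, nothing
more: K_true row-banded archetype baselines (densest at the top), a
pre-intervention archive of 10 scenes across two years, two acquisitions
per analyzed year with fixed seasonal offsets, shared year effects drawn
N(0, 0.05), i.i.d. pixel noise N(0, 0.02), an additive post-intervention
effect δ (default +0.1 index units on revegetation, 0 on exclusion), cloud
blobs grown to an exact control-area fraction, and optional SLC-off
diagonal stripes. Reflectance bands are back-solved so the target index is
achieved exactly (one index at a time; uninvolved bands held at plausible
constants; for negative MSAVI targets the red band is lifted adaptively to
keep NIR nonnegative). Defaults mirror the reference study's stated scale:
30 m pixels, 100×100 grid, 5 clusters, 3+3 years, 20 controls.

What it deliberately does not emulate: spatially correlated noise,
cluster-specific climate response, sensor calibration drift, topographic
illumination, mixed pixels at site boundaries. Passing tests therefore
demonstrate the *estimator's* correctness under the design's assumptions,
not robustness of the design to violations of those assumptions on real
imagery.

Field plots are simulated from the published model equations plus Gaussian
noise (SDs 3 % cover, 1 kg m⁻², 1.5 % cover — realistic plot-scale
measurement error), floored at 0. Index values are sampled widely
(emulating purposive plot selection), with the spekboom-cover sampling
coupled to elevation so the noiseless truth is always nonnegative and the
physical floor never distorts calibration-recovery checks.

## Numerical and engineering choices

* Grids are 0-based row/col; a pixel's representative point is its center;
  CRS must be projected (metric) because the 30/60 m rules are metric.
* Raster I/O is single-band GeoTIFF via tifffile with ModelPixelScale /
  ModelTiepoint / GeoKeyDirectory tags; round-trips are bit-exact.
* All randomness flows from explicit seeds; the BACI engine keys its
  stream per pixel, the pipeline hashes its tabular outputs into the run
  manifest so nondeterminism is detectable.
* Exclusion accounting always satisfies: intervened pixels = analyzed +
  unclustered + invalid + control-shortfall.
* Problem sizes in the test suite (grids of 50–100 pixels a side, ~1,000
  impact pixels, 1,000-replicate null calibrations) are chosen to make the
  statistical assertions sharp at interactive runtimes.

## Known limitations

* The BACI contrast is identified only under shared-year-effect additivity;
  multiplicative responses leave a residual bias (a multiplicative effect
  option exists in the generator for robustness exploration).
* The rank p-value's resolution is limited by n_controls; n = 20 cannot
  yield p < 0.095, so per-pixel "significance" maps should be read with
  that floor in mind.
* ISODATA here is a faithful textbook implementation, not a bit-exact
  reproduction of any proprietary desktop tool.
* Greedy distance thinning reduces, but does not model, spatial
  autocorrelation between sampled pixels.
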