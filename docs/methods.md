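# Methods

`thermoview` decomposes and corrects multi-view canopy-temperature (CT)
measurements: per-image, per-plot temperatures of a replicated field trial
recorded by a nadir-oriented, uncalibrated thermal camera on a drone.  This
note documents the models, the estimation procedure, the synthetic-data
generator that stands in for flight data, and the numerical and design
choices a maintainer would want to know about.

## The measurement model

Every record is one plot seen on one image.  The stage-1 model decomposes the
measured value additively:

    y = mu + g_i + t_k + (gt)_ik + r_n [+ (tr)_kn] + p_p
        + s(row(p), col(p)) + f_spl(j) + e

with genotype `g`, treatment `t`, genotype-by-treatment interaction,
replicate `r`, plot `p`, a spatial field `s` over the plot grid, a smooth
temporal trend `f_spl` over the ordered trigger events `j` of each flight,
and a record-level residual `e`.  The temporal trend is dominated by thermal
drift of the uncooled microbolometer (wind cools the sensor body, radiation
warms it; a warming sensor *lowers* the apparent target temperature).  The
spatial field follows a separable AR(1)xAR(1) covariance over grid rows and
columns — one smooth field covers the 1-D row/column trends and the 2-D
surface together (reported row/column effects are its marginal means).

Absolute temperatures are never interpreted; an uncalibrated sensor only
supports relative differences between plots (see the grey-body arithmetic
below for why: a 0.01 emissivity error shifts the absolute reading by
~2.9 K).

### Estimation

Identifiability: every effect family is centred to sum to zero and the grand
mean carries the level.  Genotype, interaction, plot and spatial terms are
random (shrunken); treatment and replicate are fixed.  Estimation runs in
two phases:

1. **Warm-up** (3 backfitting sweeps): cyclic partial-residual updates of
   the design families (shrunken/plain level means on plot-level means),
   the per-flight P-spline, and the spatial-field BLUP.  During these sweeps
   the adaptive hyperparameters are estimated: shrinkage ratios
   sigma_e^2 / sigma_family^2 (moment estimates), the spline penalty by
   generalized cross-validation, and the spatial variance parameters
   (sigma_s^2, rho_row, rho_col, sigma_plot^2) by marginal maximum
   likelihood (Nelder-Mead on log/atanh-transformed parameters).
2. **Joint solve**: with hyperparameters frozen, all coefficients — design
   levels, per-flight spline coefficients, and the combined plot-level
   random effect v = spatial + plot — are obtained from one penalized
   least-squares system (sparse normal equations, dense solve).  v carries
   the prior precision `sigma_e^2 (sigma_s^2 K + sigma_phi^2 I)^{-1}`; the
   solution is split back into the smooth field and the white plot effect by
   their prior covariances.  The variance parameters are refreshed once from
   the first joint solution and the solve repeated; iteration stops when the
   largest effect change falls below `tol` (default 1e-6 K), which the
   frozen-parameter fixed point guarantees.

   The joint solve exists because pure backfitting converges very slowly
   here: a serpentine flight samples plots in spatial order, so the temporal
   spline and the spatial field are strongly confounded and Gauss-Seidel
   contraction rates approach 1.

Numerical guards: a tiny ridge (1e-10 per record) on otherwise unpenalized
design columns fixes the intercept/indicator collinearity; `sigma_e^2` is
floored at 1e-8 times the data variance so penalty ratios remain
numerically meaningful when residuals vanish (e.g. one record per plot);
AR correlations are clipped to |rho| <= 0.985.

### Spline

Cubic B-splines over the integer trigger index, one knot segment per
`spline_knot_spacing` triggers (default 10 images), second-difference
coefficient penalty, penalty weight chosen by GCV from a log-spaced grid
(1e-4..1e5).  Campaigns (several consecutive flights) are pooled into one
fit with a separate spline (and flight offset) per flight and shared design
and spatial structure.  Flights shorter than 5 triggers fall back to a
linear basis; a single trigger to a constant.

### Prediction chain and deflation

* `mean`   — raw per-plot mean over all its images (no model; baseline);
* `t_c`    — temporally corrected: all terms except the spline;
* `ts_c`   — temporally and spatially corrected: spatial terms also omitted;
* `t_defl` — `ts_c` minus the plot's own treatment effect, leaving genotype,
  genotype-by-treatment interaction, plot and replicate signal.  (A literal
  subtraction of the unweighted mean over treatment levels would be a no-op
  under sum-to-zero centring; removing the per-plot treatment effect is
  what makes the per-treatment means coincide, which is the point of
  deflation.)  Unweighted treatment means are used when treatments are
  nested in replicates.

The spatial trend is exactly `t_c - ts_c`.  Border plots participate in the
fit (additive genotype/treatment effects only, no interaction) but are
excluded from all predictions.

### Stage 2: PLSR on residuals

Stage-1 residuals retain viewing-geometry structure (vignetting, canopy-
cover viewing-angle effects, sun-direction gradients, path-length
attenuation).  They are regressed on the 20 linearized geometric covariates
by PLS1 (NIPALS, via scikit-learn, unit-variance covariate scaling).
Reported coefficients are on the scaled covariates, so their magnitudes are
comparable.  Per flight, the relative magnitudes |b_i| / sum|b_i| sum to
one; across flights the per-covariate median summarises importance, and a
supervised backward elimination repeatedly drops the covariate with the
lowest median (ties resolve to covariate-table order) until a survivor
count (default 9) remains.  Explained variance is reported both in-sample
and 10-fold cross-validated; noise-floor checks use the CV value, which may
be slightly negative on pure noise.  "auto" component selection maximises
CV explained variance over 1..5 components.

## Viewing geometry

Planar ENU frame (x east, y north, z up, metres), azimuths clockwise from
north, nadir camera with the image +y axis on the (constant) heading.  The
plot-to-drone planar offset is decomposed along the sowing-row direction and
the sun-azimuth direction; "longitudinal" is the along-direction component
(positive with the drone ahead of the plot), "lateral" the perpendicular
component (positive to the right).  Viewing angles are
atan2(component, height); the drone elevation is atan2(height, planar
distance).  Angles are degrees at interfaces, radians internally.  The plot
centre (not the polygon) is the reference point; earth curvature and
refraction are ignored at survey scales.  Solar position uses the standard
NOAA low-accuracy algorithm (a few hundredths of a degree — far below the
±0.5° the covariates need).

The sun-path interaction covariate is the longitudinal sun-direction
distance times the sine of the drone elevation; without it, positions in
front of and behind the drone along the sun direction would be
indistinguishable.

## Aggregation and vignetting

Plot pixels inside the inward-buffered region of interest (0.25 m buffer
against georeferencing error) are reduced to one value per image by a
percentile (linear interpolation between order statistics — the convention
is pinned by tests).  The percentile is chosen by maximising an intraclass
repeatability sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_rep) computed after
replicate and linear row/column adjustment, with genotypic and residual
variances separated by one-way random-effect moments.  Warm soil
contaminates the upper pixel tail, pushing the optimum to low percentiles
when canopy cover is poor.  One percentile per experiment-year is chosen by
majority vote over flights; all ties resolve to the lower percentile.

The vignetting correction is an ex-ante flat field: frames of a uniform
target are averaged per pixel and centred to zero mean; subtracting the
correction image from every frame removes the lens-induced radial pattern
(edges read cooler).  Thermal frames are 16-bit single-band TIFFs encoding
°C x 1000; the correction image is a 32-bit float TIFF in kelvin.

## Traits

Vegetation indices follow the standard formulas (DVI, EVI, NDVI, SAVI) on
reflectance fractions; fractional canopy cover is the plant-pixel share of
all segmented pixels; yield is normalized to 15 % gravimetric water content.
Reference traits are spatially corrected with the same stage-1 machinery
minus the temporal component.  Correlations between CT and traits are only
computed at matched correction levels (raw CT with raw traits, corrected
with corrected, deflated with deflated) — a mismatch raises.  Treatment
deflation matters because a shared treatment response can drive a
correlation that carries no genotypic information, and conversely a strong
treatment contrast can mask a genotypic link.  Ordinal ratings (leaf
rolling, senescence) are compared by pairwise two-sided rank-sum tests with
significance tiers; the significance threshold for correlations defaults to
p <= 0.01.

## The synthetic-data generator

The generator emulates the study conditions: a row/column plot grid
(default plot pitch 1.5 m x 7 m, rows along east) with either nested
blocking (genotype blocks nested in treatment replicates, as in a variety
trial) or side-by-side treatment halves (as in a fertilization trial);
centred Gaussian effect families; an AR(1)xAR(1) spatial field; a
serpentine flight plan from the standard photogrammetric overlap formulas
(defaults: 40 m height, 22.5°/18.5° half-angles, 80 % overlaps, 3 m/s —
about 7-8 min and >= 9 images per plot on a 270-plot field); drift as a sum
of three random-phase sinusoids with periods of at least a third of the
flight, zero time-mean, rescaled to a peak amplitude; vignetting zero at
the image centre and cooler toward the edges; a canopy-cover viewing-angle
effect linear in |lateral row-direction angle| (K per radian, negative:
oblique views across rows see more canopy and less warm soil); a
sun-direction gradient (K per metre); i.i.d. Gaussian noise.  One integer
seed fans out to all draws via `numpy.random.SeedSequence`.

Default magnitudes are field-realistic: genotype SD 0.3 K, treatment SD
0.3 K, replicate 0.1 K, plot 0.2 K, spatial SD 1.0 K with rho 0.8 (smooth
moisture-style gradients), noise SD 0.3 K, drift amplitude 1.5 K.
Experiments that specifically probe a drift-dominated regime raise the
drift amplitude (to ~5 K peak, matching plot-mean variances of several K²)
and experiments probing the strong-fertilization case plant a ±2.4 K
treatment contrast.

What the generator does **not** emulate: pixel-level image formation (plots
are constant patches; optional TIFF export only), radiative transfer or
canopy energy balance, BRDF anisotropy beyond the empirical covariates,
weather-driven target-temperature change, georeferencing error, or
non-Gaussian sensor noise.  Passing tests therefore show that the
correction chain recovers known structure of this statistical data model —
not that it handles real imagery artefacts.

The fan-experiment emulator is a first-order relaxation of the sensor-body
temperature toward event-dependent setpoints (lamp heats, fan cools;
configurable time constant), with the apparent target temperature moving
opposite to the sensor temperature and hot objects in the field of view
raising only the pixel standard deviation, only while present.  Only the
qualitative shape is modelled.

## Problem sizes used in the checks

Simulation-based checks run at 270 plots (27 x 10; 30 genotypes x 3
treatments x 3 replicates) where full-scale geometry matters (variance
ordering, drift-spline recovery, genotype-effect recovery), and at 48-96
plots for checks that are size-insensitive (PLSR amplitude response,
treatment masking, campaign pooling).  Seed counts follow the experiment
design: 100 seeds for the variance ordering, 50 for genotype recovery, 20
for pooling and the PLSR ladder.  The campaign-pooling experiment uses 60 %
overlaps and stronger drift, i.e. the sparse-sampling regime in which a
single flight's spatial trend is unreliable and pooling three flights pays
off; with dense sampling both estimates are already near-ceiling and the
comparison is uninformative.

## Known limitations

* The genotype/spatial/plot split rests on the AR-field prior; fields with
  sharp non-smooth heterogeneity will leak into plot (and partially
  genotype) effects.
* Treatment contrasts on spatially contiguous treatment blocks are
  confounded with one realization of the spatial field; nested/scattered
  blocking identifies them much better than side-by-side halves.
* Variance components come from marginal ML on plot-level means, not full
  REML; their point values are indicative, and the package's contracts are
  about recovery of effects, not about variance-component equality with
  any particular mixed-model solver.
* The percentile-choice repeatability is an intraclass proxy; only the
  argmax over percentiles is consumed downstream.
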