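# Methods

This note documents the statistical model behind `centrex`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the numerical conventions needed to reproduce results
bit for bit.

## Degree centrality

Binary degree centrality of voxel *i* is the count of other in-mask voxels
whose time-series Pearson correlation with *i* is **strictly greater** than
the threshold (default 0.25; only positive correlations contribute). The GM
mask includes voxels with probability **≥** 0.20 (inclusive, so boundary
behaviour is well defined). Correlations are computed on mean-centred series
normalized by their Euclidean norm; the n-vs-(n−1) normalization choice is
irrelevant to r but fixed so the brute-force oracle matches exactly.
Zero-variance voxels are removed from the mask with a warning rather than
assigned degree 0, keeping r well defined everywhere.

Degree maps are standardized before group modelling. The default
`z_standardized` transform subtracts the within-mask mean and divides by the
within-mask sample SD per subject: the purpose of the classical
"Fisher-Z" step in centrality toolchains is to remove inter-individual scale,
and a literal Fisher transform of an integer count is ill-posed. A
`fisher_like` mode (atanh of degree rescaled by V−1, with the ratio clipped
just below 1 so saturated degrees remain finite) is retained for fidelity
experiments against toolchains that do apply it. Note a consequence of scale
removal: a hub elevation that is purely multiplicative between groups is
invisible after standardization; group differences must be differences in
*pattern*, which is what the generator plants.

## Group GLM

Second-level inference is a single pooled-error OLS per voxel: map value
regressed on intercept, treatment-coded group indicators and age/sex/scanner
covariates; t = cᵀβ̂ / SE with dof = n − rank(X). One-sided contrasts are
emitted per direction. Cluster thresholding applies the uncorrected voxel
threshold first, then removes 18-connected components (faces + edges; common
voxel-wise practice) smaller than k. The display threshold is p < 0.001 with
k = 20; the association input uses p < 0.01 with k = 1 — lenient on purpose,
to sample enough voxels for the downstream regression. Conjunctions use the
minimum statistic over the conjunction null (for "less" contrasts the
maximum, i.e. the least extreme value in the tested direction), so
thresholding the conjunction equals intersecting the individually thresholded
supports. Random-field or permutation-based family-wise correction is out of
scope: all downstream analysis consumes uncorrected maps.

## Donor-atlas preparation

Preparation order is fixed: **restrict → select probes → normalize**.
Restriction keeps samples with x < 0 (strictly; midline samples are
excluded) because only a minority of donors are sampled across both
hemispheres in real atlases. Probe selection pools each probe's values over
all donors' samples and keeps the probe minimizing |adjusted Fisher–Pearson
sample skewness| (bias-corrected, `scipy.stats.skew(bias=False)`), ties
broken by smallest probe id; pooling (rather than per-donor skewness then
combination) is a documented choice. Normalization is per gene, per donor:
z = (x − x̄)/σ with the sample SD over that donor's retained samples, so
z-scores reflect the analysed sample set; genes constant within a donor are
flagged missing for that donor only.

Image sampling reads the lightly thresholded t-map at each tissue
coordinate: the raw value is the mean of voxels whose centres fall inside the
axis-aligned cube of edge 5 mm (inclusive bounds) and that carry a finite map
value. Sub-threshold voxels contribute as *missing*, not zero — zeros would
dilute t-values with an arbitrary constant. Samples with empty windows are
dropped; retained raw values are z-scored within donor.

## Spatial association

Donors are sampled at donor-specific coordinates, yet one PCA must run across
donors; common observation units are therefore built by parcellating the
volume into regular blocks (default edge **2 voxels**). Per gene, the unit ×
donor matrix X holds each donor's mean z-scored expression in the parcel; the
image value y is the mean z-scored image value over all contributing samples,
and the weight w is the contributing sample count. The 2-voxel edge (rather
than a coarser 3) is deliberate: with a desk-scale grid and six donors,
coarser parcels leave too few donor-complete units for a stable fit with up
to six regressors. A `per_sample` mode bypasses parcelling when donors share
coordinates (exact-recovery and calibration experiments).

PCA is column-centred over the donor dimension; k is the smallest number of
components whose cumulative explained variance reaches 95 %. The regression
is weighted least squares of y on [1, scores]; R² uses weighted sums of
squares about the weighted mean, and the reported statistic is the usual
small-sample adjustment 1 − (1 − R²)(n − 1)/(n − k − 1) with n = units. The
reported direction is the sign of the weighted correlation between y and the
across-donor mean expression.

The **chance likelihood** permutes the rows of X (all donor columns
together — a spatial shuffle that preserves the expression distribution and
donor covariance while breaking image–expression alignment), reruns
PCA + WLS per resample, and reports the fraction of 1000 resamples with
R² **strictly greater** than the observed R². Unadjusted R² is compared on
both sides; k is free to differ between resamples. No
spatial-autocorrelation-preserving null is used. Implementation note: row
permutation leaves column means unchanged, so X is centred once and the 1000
resamples are evaluated with batched SVDs and grouped normal-equation
solves — this is what keeps 100 genes × 1000 resamples at a few seconds.

The **donor autocorrelation** is the mean Pearson correlation over all
unordered donor pairs of the gene's unit profile (zero-variance columns skip
their pairs). The final filter is `chance likelihood < 0.001` (strict) ∧
`autocorrelation ≥ 0.2` ∧ `adjusted R² ≥ 0.15` (both inclusive).

## Enrichment and cell types

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) with population N = |background|, successes K = |set ∩ background|,
draws n = |hits|. The background is the gene list fed into the association
stage — not the genome — and Bonferroni multiplies by the number of sets
tested within a namespace, with significance declared at adjusted p < 0.05
(strict). One-tailed over-representation only.

Cell-type matrices are quantile-normalized across columns (columns share the
cross-column mean of order statistics; ties within a column receive the mean
of the tied reference values — with ties the per-column sorted vectors can
therefore differ from the reference, which is inherent to tie handling).
Profiles report per-type mean and SEM over replicates (single replicate: SEM
reported as 0 and flagged undefined), a +0.001 offset for log display,
specificity (type mean over summed type means) and enrichment
(mean-in-type / mean-out-of-type — the conventional reading of that
measure).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes,
at desk scale:

* **Cohorts** — each subject is Gaussian noise (σ = 1); hub voxels
  additionally share one latent time series scaled by the group gain and a
  Gaussian spatial envelope (peak gain 1.5 in patients, 0 in controls;
  envelope sigma 0.6 × hub extent). The envelope matters: it makes the
  planted contrast spatially *graded*, as real group t-maps are. A flat hub
  block would make the t-map white inside the region, and point samples vs
  5-mm window averages of a white field decorrelate, severing the very
  coupling the association stage must detect. Covariates are drawn
  independently of group by default (a confounded mode exists for testing
  adjustment).
* **Donor atlases** — six donors, 800 samples each by default, coordinates
  uniform over the volume per donor (a flag shares coordinates across donors
  for exact tests). Coupled genes: expression = β × map(nearest voxel) +
  N(0, σₑ); with β = 1, σₑ = 1 and a unit-variance map this is a per-donor
  population R² of 0.5. Each gene has 2 probes; the representative probe
  carries the untransformed signal, siblings are skewed through the monotone
  tilt (exp(s·x) − 1)/s, which reduces to the identity at s = 0.
* **Gene sets / cell types** — one deliberately enriched set among uniform
  draws; marker genes with 10-fold elevated expression in one cell type.

Not emulated: hemodynamics, motion or scanner-specific noise, spatial
autocorrelation of the *noise* (only the signal is smooth), realistic
regional sampling density of post-mortem atlases (uniform by design), probe
intensity filtering, and gene–gene co-expression structure. Passing tests
therefore demonstrate correctness and calibration of the *procedure* under
its stated assumptions, not performance on real acquisitions.

## Problem sizes and numerics

Default study: 10×10×10 voxels at 2 mm, 120 timepoints, 20 + 20 subjects,
6 donors × 800 samples, 100 genes (20 coupled), 1000 bootstrap resamples —
the full pipeline runs in a few seconds on one CPU. Calibration experiments
use 6³-voxel null cohorts (50 replicates) and shared-coordinate atlases with
~50 left-hemisphere units. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawns (one independent stream per gene in the
association), so every output is bit-reproducible; NIfTI outputs are written
uncompressed (or with a pinned gzip mtime) to keep reruns byte-identical.
Degenerate inputs fail loudly and specifically: empty masks name the
threshold, rank-deficient designs list the collinear columns, constant maps
and zero-variance image vectors raise rather than propagate NaN.

## Known limitations

* The parcel-based donor alignment is one reading of how a cross-donor PCA
  can be made well-defined when donors are sampled at different coordinates;
  platforms that aggregate anatomically will differ numerically.
* The regression weights (contributing sample counts) are a design choice;
  "weighted multiple regression" admits others.
* The bootstrap null is a plain permutation: under strong spatial
  autocorrelation of real maps it is anti-conservative compared with
  spin-style nulls, which are deliberately out of scope.
* With 1000 resamples the smallest nonzero chance likelihood is 0.001, so the
  pass criterion `CL < 0.001` effectively requires the observed R² to exceed
  every resample.
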