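# Methods

This note documents the models, conventions and numerical choices behind
`pollenmat`, and what the synthetic-data tests do and do not demonstrate.

## The transfer function

The Modern Analog Technique assumes that compositionally similar pollen
assemblages derive from comparable vegetation. Assemblages are compared as
normalized proportion vectors with the squared-chord distance
d(p, q) = Σ(√pₖ − √qₖ)², which ranges over [0, 2] and weights rare taxa
more evenly than Euclidean distance. For each fossil sample the k nearest
calibration entries are selected (k = 8 by default), entries with d > T are
discarded (T = 0.3), and the prediction is the weighted mean of the
retained analogs' cover values.

Two conventions are not dictated by the method and were fixed here:

- **Analog weights** are inverse dissimilarity, w = 1/max(d, ε) with
  ε = 1e-9. A zero-distance analog therefore dominates the average, which
  is the behavior users of classical MAT toolchains expect. Ties at the
  k-th rank are all included (then thresholded), so results do not depend
  on calibration-set ordering.
- **Standard error** is the sample standard deviation (n − 1 denominator)
  of the retained analogs' covers divided by √n. With a single retained
  analog the SE is reported missing, not zero: one analog carries no spread
  information.

A fossil sample whose nearest analog exceeds T is flagged no-analog and its
prediction is missing. Cross-validation is offered as leave-one-out (also
usable as a k-selection sweep) and repeated random half-splits; r² is the
squared Pearson correlation between predicted and observed, RMSEP the root
mean square prediction error in cover points. Distance-based exclusion
(h-block) cross-validation is deliberately not offered: land cover is
spatially fragmented at short ranges and the test is ill-suited to this
response variable.

## PFT conversion

Taxa are grouped into plant functional types before matching; scores follow
the biomisation-style affinity sum score(PFT) = Σ √(max(0, p − θ)) with
θ = 0.5 % by default. Taxa eligible for several PFTs (the *Betula*
tree-vs-shrub case) are assigned wholly to the eligible PFT with the larger
score computed from the other taxa; exact ties split the contribution
equally. This makes the context rule deterministic. Chord distances operate
on the normalized PFT vector, since the squared-chord distance is defined
on proportions. Arboreal-pollen (AP) percentages sum woody taxa excluding
dwarf shrubs and vines; unflagged taxa count as non-arboreal and are
logged.

## Cover extraction and screening

Extraction is a Gaussian-weighted mean over land pixels whose centers fall
within the search radius (50 km); water and no-data pixels are excluded
from numerator and denominator alike, so the effective weights renormalize
over the included pixels and, around lakes, weight shifts automatically to
the shoreline and beyond. Distances are great-circle meters on the authalic
sphere (R = 6,371,007.2 m) — adequate because window sizes are ≪ Earth's
radius. Pixels are included by center-in-circle and the kernel is evaluated
at pixel centers.

The "small lake surrounded by forest" rule needs an operational criterion
the source material leaves open: a lake < 20 ha counts as forest-surrounded
when the σ = 500 m extraction at the sample point exceeds 40 % (the same
trigger as the dense-forest rule). Lake area comes from sample metadata,
not from raster geometry, which is resolution-fragile. The tree-height
screen applies only to wide-kernel (σ = 10 km) lacustrine samples inside
the land-class coverage: they are dropped when the median vegetation height
within 1σ is zero.

## Quality control

Modern-pool rules are conjunctive, so the surviving set is order
independent: duplicate removal (identical coordinates and assemblage, first
kept), location error > 100 m, |sample − DEM elevation| > 200 m, riverine
and estuarine contexts, terrestrial count not above 100 grains (strictly
greater-than retained, with a configurable strictness flag), land-class
consistency in both directions (15 % cover limit, zero/positive median
height), and the AP/cover rule (AP > 80 % with cover < 25 %), from which
extensive treeless contexts are exempt because long-distance arboreal
pollen dominates sparse pollen rain. Samples with *missing* location error
are retained to avoid depopulating the analog pool. Fossil series receive
only the count rule.

## Bias correction

Quantile mapping between modeled and observed cover, resampled with 5-point
windows placed uniformly at random along the modeled axis (10 per
iteration) to counter the predominance of open-landscape samples; window
quartiles of both margins, paired by rank, are pooled and reduced to
empirical quantiles at the odd percentiles 1, 3, …, 99. A smoothing spline
(λ by generalized cross-validation, overridable) is fitted to the
quantile–quantile pairs, evaluated on a dense grid, projected onto the
monotone cone by isotonic regression and clamped to [0, 100]; beyond the
quantile support the curve continues linearly with unit slope before
projection. Windows with fewer than four pairs are skipped.

One intrinsic limit is worth knowing: quantile mapping rescales additive
noise by the inverse of the compression factor, so where the systematic
bias is small relative to the noise (the lowest cover class, squeezed
against zero), the class-median residual can drift slightly rather than
shrink. The correction contract — absolute median residual reduced in every
10-point class — holds in the bias-dominated regime the correction exists
for.

## Timeslices and interpolation

Centers run every 250 years from 12,000 to 0 BP (49 slices); a sample of
age a joins the slice with center c when a ∈ (c − 125, c + 125], i.e.
boundary ages go to the younger slice. The terminal window is asymmetric:
it accepts ages down to −60 BP (AD 2010) and therefore spans 185 years
centered on 0 BP.

Gridding uses a thin-plate radial-basis interpolant (r² log r kernel,
degree-1 polynomial tail, ridge smoothing on the kernel diagonal) over
scaled coordinates: by default 1,000 m of elevation and one 250-year slice
step weigh like one horizontal degree, which keeps realistic vertical and
temporal spacings commensurate with horizontal site spacings. Each output
slice is fitted in 4-D from sites within ±2 slices; the 0 BP slice is
fitted spatially in 3-D because its sample distribution around the 0 BP
mark is one-sided. Per-site slice values are the mean over the site's
samples in the slice; exact duplicates in scaled space are averaged;
coordinates constant across all sites (flat terrain, single-slice fits)
are dropped from the fit rather than left to make the polynomial part rank
deficient. Smoothing is 0 (interpolation) by default, or "gcv", which picks
the ridge parameter by leave-one-out error over a log-spaced grid — viable
because per-slice site counts are small. Cover and AP fields are clamped to
[0, 100]; cells farther than 250 km (configurable) from every contributing
site are masked, as are water cells of the static land mask; slices with
fewer than 6 sites are skipped with a report.

Error grids are produced coarse (1°): the per-sample analog SE is
interpolated, and the uncertainty of the interpolation itself is estimated
by a delete-one-site jackknife of the cover prediction at each coarse cell;
the two terms are added. A resampling estimate was chosen because it is
implementation independent, unlike internal spline variance estimators.

## Regional summaries

Regional means weight cells by cos(latitude); the reported spread is
inter-cell variability, not reconstruction error. Elevation-band summaries
use contiguous 200-m bands with everything below 400 m as one band, period
caps (2,400 m before 11,000 BP, 2,600 m to 10,000 BP, 2,800 m after) that
flag rather than drop capped bands, and a threshold track defined as the
upper edge of the highest band whose mean cover exceeds 50 % — a simple
timberline-ecotone indicator. Series comparison re-bins point
reconstructions to the reference's window width (200 yr default) and
reports Pearson r, mean absolute difference and the least-squares line,
overall and for the Early (11,700–8,100), Mid (8,100–4,100) and Late
(4,100–0 BP) Holocene.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, not
its biology. The cover field is Gaussian-filtered white noise rescaled to
[0, 100]; the kernel width is set so the configured correlation length is
the field's 1/e decorrelation distance. Tree height is a monotone function
of cover plus noise (optionally with a tall-shrubland patch of positive
cover and zero height to exercise the height screen); the land-class raster
discretizes cover at the 15 % open-forest limit; lakes are small blobs
carrying a reserved water code distinct from no-data. The pollen forward
model sets the expected arboreal share to
(1 − λ)·FC/100 + λ·background, with λ the long-distance-transport fraction
(default 0.1) and a background arboreal share of 0.4; within the arboreal
and herbaceous pools taxa split by fixed productivity multipliers, and
counts are multinomial at 400 grains. Expected AP therefore increases
strictly with true cover whenever λ < 1, which is what the recovery tests
lean on. Metadata defects (location error, elevation mismatch, low counts,
riverine context) are injected into a configurable fraction of modern
samples with labels retained. Fossil cores sample irregular ages over
12,000–0 BP from a prescribed history; the default history rises from
sparse late-glacial cover to a plateau between 8,500 and 6,000 BP and then
declines by 45 %.

What passing tests show: the pipeline's numerics are correct against
independent oracles, its rules match their specifications exactly, and the
full chain can recover a known history through realistic plumbing (noise,
defects, filtering, gridding). What they do not show: performance on real
pollen data, whose taxonomic richness, productivity heterogeneity,
chronological error and spatially structured no-analog problems the
generator deliberately omits; cross-validation skill on synthetic worlds
(r² ≈ 0.9) is far above what heterogeneous real calibration sets support.

## Problem sizes

The test and acceptance runs use desk-scale worlds — a ~4° × 3° domain at
~3 km resolution, 140 modern samples, 12 fossil sites of ~55 samples,
two-fold CV at 60–99 iterations and quantile mapping at 199 iterations on
2,000 pairs — chosen so the whole suite and the acceptance script each
finish in minutes while every stage still runs at non-trivial size.
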