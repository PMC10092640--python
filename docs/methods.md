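# Methods

## Inputs and conventions

The pipeline consumes (1) a table of segmented nuclear centroids — x, y, z
in µm and volume in µm³, as exported by commercial nuclear segmentation —
and (2) a single-channel F-actin intensity stack with known voxel
dimensions. Plane 0 is the basal-most plane (acquisition starts beneath
the substrate) and physical z = plane index × z-spacing; z-spacing should
be ≤ 0.5 µm (a warning is logged otherwise). Densities are reported in
10³ cells/mm². Ingestion never filters, reorders, or rescales beyond the
declared unit conversion; the volume filter is a separate, logged stage.

## The classification model

The classifier assumes an epithelial field can be summarized by two 1D
functions of apical-basal position: the nuclear count histogram (1 µm
half-open bins from z = 0) and the lateral sum of actin intensity,
normalized to peak 1.

**Volume filter.** Cutoff = mean − k·SD of the per-field volumes (sample
SD, ddof = 1), k = 1.5 by default, k = 1 for cultures with pyknotic
nuclei; records with volume ≤ cutoff are excluded, and there is no upper
cutoff because very large nuclei occur naturally. When the SD is zero the
filter removes nothing: the rule targets outlying debris, which cannot
exist without variance. Filtering is monotone in k by construction.

**Layer bounds.** The bottom of the layer is the first upward crossing of
the normalized actin profile above a peak fraction chosen from 20–50 %,
the top the last crossing above a fraction from 60–80 %; both crossings
are linearly interpolated between z samples, which removes grid bias
(nearest-plane snapping would be bounded by the z-spacing anyway). The
fractions increase linearly with nuclear density between anchors at 2 and
8 × 10³ cells/mm² (clamped to their ranges): denser fields carry more
lateral actin relative to the basal signal, so higher thresholds are
needed to avoid placing the bottom below the layer. Density here is the
filtered nucleus count over the field area, computable before bounds
exist. A detected layer thinner than one z-spacing is rejected as a spike.

**One vs. two nuclear Gaussians.** Both models are least-squares curve
fits to the (bin center, count) pairs, weighted by the per-bin counting
noise σ_i = √max(c_i, 1). The weighting matters: unweighted fits let the
two-component model absorb the large Poisson fluctuations of peak bins,
and the model comparison then rejects the single Gaussian about four times
more often than its nominal level. The two-component fit uses a fixed
multi-start initialization — second mean at the histogram mode ± {3, 6,
9} µm, a start at the two tallest distinct histogram maxima, and a
degenerate start at the one-component solution (which also guarantees the
nested-model inequality RSS₂ ≤ RSS₁) — keeping the lowest-RSS result, so
the procedure is deterministic. Models are compared with the
extra-sum-of-squares F-test, F = ((RSS₁−RSS₂)/3)/(RSS₂/(n−6)), and the
two-component model is selected iff p < α (default 0.05). The test is
approximate (the null hypothesis sits on the boundary of the parameter
space), but its measured false-selection rate is within the binomial ±3 SE
band of α at n = 200 nuclei.

**Organized vs. Disorganized.** A single component is Organized iff
σ ≤ `wide_sigma_um` (default 3 µm, about half a mature layer height: a
monolayer's nuclei cannot span more than the layer itself). For a
two-component fit the guiding principle is that *organized* means a
discernible monolayer exists at the bottom, whatever sits on top of it —
a second layer, a clump, or a pyramid of cells — while *disorganized*
means nuclei spread over many z positions. Concretely:

* Organized (with apical cells) if the components are separate
  (µ₂ − µ₁ ≥ `separation_factor`·(σ₁+σ₂), factor 1.0) **and** the basal
  component is monolayer-sharp (σ₁ ≤ `monolayer_sigma_um`, default half of
  `wide_sigma_um` = 1.5 µm).
* Organized (single) if the two components merged back into one
  distribution would still be sharp (mass-weighted mixture SD ≤
  `wide_sigma_um`) — this is the signature of a least-squares split of a
  single sharp peak, not of genuine multilayering.
* Organized (with apical cells) if the basal component alone is
  monolayer-sharp even when the upper component overlaps it — a broad or
  decaying mass of cells resting on an intact monolayer.
* Otherwise Disorganized.

A rule based purely on peak separation misclassifies all three corner
cases above; the sharp-basal-peak formulation handles them uniformly and
is exposed through two interpretable cutoffs.

**Maturity.** Immature layers have poorly defined lateral surfaces: the
actin peak lies at/below the nuclear peak (the fitted mean of the basal
component) or strictly closer to the layer bottom than the top (ties are
not Immature). Otherwise the actin profile is smoothed by a moving average
spanning 1 µm and differentiated (central differences); local maxima with
prominence ≥ 5 % of the window maximum are found in the window from
`bottom − derivative_basal_pad_um` to `top`. Two peaks whose right/left
value ratio exceeds 1 mean a lateral shoulder followed by a brighter
apical band: Mature. A single peak or ratio ≤ 1: Intermediate. The basal
pad (default 2 µm) exists because at high density the bottom fraction
reaches 50 % of peak, which places the detected bottom *past* the steepest
part of the basal actin rise; restricting the derivative strictly to
[bottom, top] would then delete the left peak and misread Mature profiles
as Intermediate. If more than two derivative peaks appear, the two most
prominent are used, ordered by z.

**Membership.** With two components, each nucleus joins the component with
the higher fitted curve value at its z; the basal component is the layer.
With one component (including merged splits), nuclei above µ + 3σ are
apical. The two counts always partition the filtered table.

**Subregions.** Tiles are laid out from the field origin with half-open
boundaries; each tile is classified independently on its own nuclei and
laterally cropped stack. The field summary is the modal tile label,
excluding Insufficient tiles; ties break toward the more mature label
(Disorganized < Immature < Intermediate < Mature) for deterministic
reporting. Fields smaller than one tile are rejected.

## In-plane shape

The junctional plane is the plane of maximum lateral actin inside the
layer bounds, excluding the apical-most 20 % so a Mature layer's apical
band is not mistaken for junctions. Cells are segmented by marker-based
watershed on that plane (junctional actin is bright, so borders are
ridges), seeded at the centroids of in-layer nuclei; when the plane's
relative contrast falls below `junction_contrast_threshold` (Immature
layers have weak lateral actin) a centroid-Voronoi tessellation is used
instead. Area is pixel count × voxel²; the perimeter is the length of the
marching-squares boundary polygon lightly smoothed along the contour
(window 3), which keeps a rasterized disk within ~1 % of its true
perimeter where the raw polygon overshoots by ~6 %; circularity is
4πA/P², clipped to 1. The same estimator is used in tests and production
because circularity is estimator-sensitive. Cells touching the field
border are excluded from summary means — truncated outlines bias both
area and circularity.

## Fluidity

Frames are normalized to zero mean and unit population SD; the correlation
strength at lag k is the average over all frame pairs separated by k of
the pixel-averaged elementwise product, giving C ∈ [−1, 1] with C(0) = 1
by construction. The half-life comes from a nonlinear least-squares fit of
exp(−λt) over positive lags on the linear scale (long-lag values can be
near zero or slightly negative, so a log-linear fit is unusable); λ ≤ 0 or
λ·T_max < 10⁻⁸ is flagged as non-decaying and reported as an infinite
half-life. Lag 0 is included in the curve but excluded from the fit. An
optional per-frame Gaussian blur is available as preprocessing; movies are
never registered or resampled.

## Synthetic data

The generator emulates exactly the features the classifier reads, with
reference presets per class chosen at the centers of the observed
density/height ranges: Immature 2 × 10³ cells/mm² and 4.5 µm; Intermediate
5 and 6.5; Mature 8 and 7; Disorganized 8 with nuclear σ = 5 µm; the three
extreme organized configurations (double layer; sharp basal peak plus a
tall broad Gaussian clump; sharp basal peak plus an exponential pyramid)
at density 8. Defaults: 300 × 300 µm fields, 0.3 µm lateral and 0.23 µm
axial voxels, layer bottom at 1 µm, nuclear volumes N(500, 50²) µm³ with
debris at ~120 µm³.

Lateral positions sit on a jittered grid at the target density; z
positions are sampled per class with rejection below 1 µm (a centroid
cannot sit below half a nuclear height; clipping instead of rejection
would pile mass into a spurious sharp basal bin). Actin stacks are
separable: a class-specific z template times a lateral field — Voronoi
boundary ridges of the in-layer centroids for junctional actin, uniform
for basal/apical sheets — plus optional additive Gaussian noise (clipped
at zero). The Mature template is a lateral plateau at ~0.65 of peak with a
dominant apical band, reflecting the strong apical actin enrichment of
mature layers; the Intermediate template is a single smooth dome-weighted
peak; the Immature template is basally weighted. Movies evolve by an AR(1)
rule with ρ = exp(−λΔt), so the expected lag-t correlation is exp(−λt)
exactly.

What the generator does **not** emulate: PSF blur, shot noise, uneven
illumination, segmentation errors other than small-volume debris, cell
shape variability beyond Voronoi geometry, or z-dependent attenuation.
Passing recovery tests therefore certify the decision rules against their
own feature definitions, not robustness to microscope physics.

## Test problem sizes

Recovery and calibration tests run on 150 × 150 µm fields with 1.0 µm
lateral voxels and 0.25 µm z-spacing — preset densities, heights and σ
values unchanged — which gives ~45–180 nuclei per field and keeps the full
suite to a few minutes. Model-selection calibration uses 200 replicates of
200 nuclei; class recovery uses 50 seeds per scenario; the extreme
configurations use 20 seeds each. Dynamics tests use 64² pixels × 100
frames at 10 min intervals across a 10× range of decay rates.

## Known limitations

* At realistic sample sizes a wide (σ ≈ 5 µm) nuclear spread occasionally
  produces a histogram with a sharp basal bump and decaying tail —
  indistinguishable from the pyramid configuration, which must be classed
  Organized; measured Disorganized recovery is 96 % rather than 100 %.
* The F-test calibration is approximate near the nominal level (boundary
  null); measured ~8 % at α = 5 %, within ±3 SE.
* Bound fractions vs. density use a linear map between two anchors; other
  culture types will need the anchors (and possibly `wide_sigma_um`,
  `monolayer_sigma_um`) recalibrated — all are exposed in
  `AnalysisConfig`. No Caco-2-specific calibration is shipped.
* Neighbor-exchange (T1) counting is not implemented; fluidity is read out
  solely through the autocorrelation half-life.
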