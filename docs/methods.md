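# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, and what the synthetic-data experiments do and
do not demonstrate.

## Problem setting

Astrocytic tumors are graded by histology: diffuse astrocytoma (WHO grade
II), anaplastic astrocytoma (III) and glioblastoma (IV). On a digitized
H&E slide a pathologist annotates ROI polygons with one of five
*characteristic pathological feature* categories — diffuse astrocytoma,
anaplastic astrocytoma, and the three glioblastoma hallmarks (tumor cell
area, necrosis area, microvascular proliferation area). A patch
classifier labels fixed-size tiles with these categories; a nucleus
instance segmenter produces integer label masks. This package implements
everything downstream of those two models: tiling, the case-level
decision rule, morphometry, comparison statistics and feature-importance
weighting. The classifiers themselves, slide formats and stain handling
are out of scope.

## ROI tiling

Patches are `patch_size` × `patch_size` squares (default 512 px) on a
stride lattice (default 256 px, half-overlap) in slide coordinates, using
0-based half-open pixel conventions. Candidate origins are the lattice
tiles covering the ROI bounding box snapped outward to stride multiples;
anchoring the lattice to slide coordinates makes tiling invariant to
translating an ROI by stride multiples, which is tested. A candidate is
kept iff area(patch ∩ polygon) / patch_size² ≥ `min_intersection_fraction`
(default 0.5), with the boundary value kept — "less than 50%" is
excluded, exactly 50% is not. Intersections use continuous polygon
clipping (shapely), never rasterization; the test suite checks
equivalence against an independent Sutherland–Hodgman/shoelace oracle on
random star-shaped polygons. Patches are attributed to the ROI that
generated them, so overlapping ROIs may produce coincident patches under
different ROI ids. Degenerate (zero-area or self-intersecting) polygons
are rejected at construction.

## Case-level classification

Per case, the five category counts are normalized to ratios (three-decimal
rounding is display-only; decisions always use unrounded ratios). Under
inclusion criterion τ the passing set is {i : ratio_i ≥ τ} for τ > 0 and
{i : ratio_i > 0} for τ = 0 — an absent category never decides, and
"reaching" the criterion is read boundary-inclusive. The predicted
diagnosis is the highest WHO grade mapped from the passing set, where all
three glioblastoma hallmark categories map to glioblastoma (grade IV) >
anaplastic astrocytoma (III) > diffuse astrocytoma (II). Ties within a
grade are broken by the larger ratio, which can only matter among the
three hallmark categories and never changes the diagnosis. If τ admits no
category (possible only for τ > 0.2 with five categories), the
argmax-ratio category decides. The highest-grade-wins rule is the unique
simple rule consistent with all 27 decisions (9 cases × 3 criteria) of
the packaged reference cohort, which the acceptance tests reproduce
exactly, including the criterion-driven flips (three diffuse-dominated
cases from glioblastoma at 0.00 to diffuse astrocytoma at 0.02/0.05, and
one anaplastic-dominated case to anaplastic astrocytoma at 0.05 only).

## Nuclear morphometry

Inputs are integer label masks (0 = background) with an optional 8-bit
grayscale channel, at a physical scale of `mpp` microns per pixel
(default 0.46, a typical 20× scan). Per nucleus:

* **axis ratio** — ratio of major to minor axis of the ellipse with the
  same second central moments as the pixel set; ≥ 1 by construction,
  robust to boundary noise, and exact for ellipses. Feret diameters were
  deliberately not used.
* **circularity** — |pixel_set ∩ C| / |pixel_set| where C is the disk
  centered at the centroid with the nucleus's own area. This
  normalization yields 1.0 for a disk and values in (0, 1] generally.
* **entropy** — Shannon entropy, base 2, of the 256-bin histogram of the
  nucleus's gray values (bins and base are parameters). Constant
  intensity gives 0; L equiprobable levels give log2 L.
* **area** — pixel count × mpp².
* **irregularity** — population variance of the Euclidean distances (µm)
  from the centroid to each boundary vertex, in µm², unnormalized by mean
  radius (a documented convention).
* **perimeter** — length of the closed sub-pixel contour (marching
  squares at level 0.5), in µm. The raw marching-squares contour
  staircases around smooth boundaries and overestimates length by 5–9%;
  a 5-vertex circular moving average removes this bias (disks within
  0.5%, squares within 1%). Irregularity uses the raw vertices, where
  staircase noise adds variance far below the signal scale.

Boundaries come from `skimage.measure.find_contours` on the per-instance
crop, so touching nuclei with distinct labels are handled correctly.
Nuclei touching the image border are counted for cellularity (they occupy
area) but excluded from shape features (truncation biases every shape
descriptor); instances under 5 px or with degenerate (collinear) pixel
sets are flagged and excluded.

**Cellularity** is nonzero-pixel count / total pixels per unit (mask
area, not detection-box area; box-area is not implemented). **Moment
summaries** per aggregation unit use the n−1 variance, Fisher skewness
and excess kurtosis (normal → 0); with n < 4 or zero variance the higher
moments are flagged undefined rather than reported as 0.

## Group statistics

Cellularity is compared between all C(5,2) = 10 category pairs with
Welch's unequal-variance t-test (Welch–Satterthwaite degrees of freedom);
p-values are Bonferroni-multiplied by the number of pairs actually tested
and declared significant at family-wise α = 0.05, two-sided. Groups with
n < 2 are skipped with a warning. Each moment of each feature is compared
across categories by classical one-way ANOVA; all-constant input is
flagged (NaN or infinite F) instead of silently propagating a 0/0.

Confidence intervals use the percentile bootstrap: resample items with
replacement at full size, 50 times by default, and read the 2.5/97.5
percentiles; the point estimate is the full-sample statistic. Fifty
resamples is far too few for BCa-style corrections, so the plain
percentile method is the honest choice at this resample count. A
resample on which the statistic is undefined is redrawn (bounded
retries, so degenerate inputs fail loudly). Accuracy-type CIs resample
patches (items); case-level resampling is available by passing case-level
items instead.

## Feature model and importance

A multiclass XGBoost classifier (histogram tree method, depth 6, 100
trees, learning rate 0.3, fixed seed — defaults, not tuned claims) maps
the seven-descriptor vectors (cellularity + six feature means per unit)
to categories. Importance is the "weight" type — the integer count of
tree splits per feature, 0 for features never split on (e.g. constant
columns) — with gain-based importance behind a flag. The 95% CI refits
the model on each of 50 bootstrap resamples of the units and reads
percentile bounds; ranks come from the full-data fit. Planted-signal
tests verify that when one feature carries the dominant class signal and
a second a weaker one, the top-2 split-count ranking recovers the plant
in ≥ 90% of seeded runs.

## Synthetic data generator

The generator emulates the three real input kinds with recoverable
ground truth.

**Nucleus fields.** Each nucleus is a radially perturbed ellipse in polar
form r(φ) = s · r_e(φ) · (1 + ε sin(kφ + φ₀)): area is lognormal with the
profile's mean/sd (µm²); the axis ratio is 1 + Gamma with exact target
mean and sd (support ≥ 1 without the truncation bias a clipped normal
would add); ε is the profile's `boundary_noise`, k ∈ {3..6}; orientation
is uniform. The scale s is set by quadrature so the continuous area
equals the sampled target, and rasterization uses the exact pixel-center
membership test of the polar form, making pixel-count areas unbiased
estimates of the analytic areas. Placement is rejection sampling with a
cap of 100 tries per nucleus (density is approximate by design; failures
are counted and reported, never looped on); the nucleus count per field
is Poisson around density × field area / 10⁴ µm², with an optional exact
override. Centers are uniform over the field, so border-clipped nuclei
occur and are flagged in the truth table. Intensities inside a nucleus
are drawn equiprobably from `texture_levels` distinct gray levels on a
pale background, making the target entropy exactly log2(texture_levels)
(the plug-in estimator is biased low by ≈ (L−1)/(2N ln 2) bits at N
pixels, visible at realistic nucleus sizes and accounted for in tests).

**Class profiles.** Defaults place the five categories at cohort-scale
magnitudes: mean nuclear areas 13.7–30.5 µm², axis-ratio means 1.44–1.73,
and densities chosen so expected cellularity (density × mean area / 10⁴)
ranks tumor cell (~0.195) > anaplastic (~0.18) > microvascular
proliferation (~0.12) > diffuse (~0.05) > necrosis (~0.003). Texture
levels 26–30 put entropy targets at 4.70–4.91 bits. These profiles are
stand-ins: they reproduce orderings and rough magnitudes of real cohorts,
not exact published values.

**Patch-count tables.** Per simulated case, the category composition is
Dirichlet-sampled and counts are multinomial. Default concentrations put
weight 50 on the true diagnosis's own categories (split across the three
hallmarks for glioblastoma) and 0.1 on each other category, so the
expected spill-over ratio per wrong category is ≈ 0.1/50.4 ≈ 0.002 — the
per-mille scale seen in real per-case prediction tables. Occasional
larger spills arise naturally from the small-α Dirichlet tail, so a
synthetic cohort classified at τ = 0.02 shows high but imperfect accuracy,
qualitatively like a real cohort.

**What passing tests show.** Parameter recovery (area and axis-ratio
means within 5%, cellularity within 10% for classes with ≥ 50 nuclei per
field, the cellularity class ordering) demonstrates that the measurement
chain is unbiased on non-overlapping, smoothly bounded, well-separated
nuclei. Real tissue violates these assumptions — touching and overlapping
nuclei, segmentation errors, stain variation, H&E color — so passing here
validates the quantification pipeline, not segmentation robustness.

## Problem sizes and determinism

Every stochastic component takes an explicit seed or `numpy` Generator
and is bit-reproducible. The validation suite uses field sizes of
512–1024 px, 200–1000 nuclei per class for recovery checks (at 1000
nuclei the lognormal area spread leaves ~1.7% sampling noise in the mean,
well inside the 5% band), 100 random polygons for tiling-oracle
equivalence, 1000 simulation replicates for the family-wise error check
(Bonferroni is conservative; observed rates run ~3–4.5% against the 5%
bound plus Monte-Carlo slack), and 20 seeded runs for planted-importance
recovery.

## Known limitations

* The inclusion-criterion boundary (≥ τ) is untestable at the printed
  ratio precision of the reference cohort — no published ratio sits
  exactly on a criterion — and is documented as a convention.
* Split-count importance depends on the pinned hyperparameters; gain
  importance can rank differently and is provided as an option.
* The ANOVA treats the three glioblastoma hallmark categories as
  independent groups even though they share cases, mirroring common
  practice; the non-independence is noted, not modeled.
* Bootstrap intervals from 50 resamples have coarse (±2.5 percentile)
  resolution; the percentile method can produce intervals not containing
  the point estimate in pathological cases.
* The generator does not simulate touching nuclei, H&E appearance or
  stain deconvolution; cellularity at very high densities saturates
  below its analytic target because rejection sampling jams.
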