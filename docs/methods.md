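# Methods

This note documents the models, numerical choices and known limitations of
`bolipore`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Measured quantities

For one specimen, measurement is restricted to a region of interest (ROI)
of area A (µm²) containing n pores of individual areas a_i:

* pore density PD = n / A (pores/µm²),
* mean pore size MPS = (Σ a_i) / n (µm²; undefined and reported NaN when
  n = 0),
* porosity = 100 · Σ a_i / A (% of ROI area).

The identity porosity = 100 · PD · MPS holds to machine precision for every
specimen record by construction. It does **not** hold for cohort means of
the three parameters (a mean of products is not a product of means); the
suite asserts both facts. Location summaries report mean, sample SD
(n−1 denominator) and SEM = SD/√n; with a single specimen SD and SEM are
reported missing rather than zero.

## Ontogenetic size normalisation

Pore density increases with each newly added chamber as the test's
surface/volume ratio falls, so specimens at different growth stages are
comparable only over a fixed window of their oldest chambers. The ROI is
the smallest prefix of ontogenetically oldest chambers whose cumulative
area reaches 50,000 µm²; if that prefix exceeds 70,000 µm² the window is
unattainable, and specimens totalling under 50,000 µm² are rejected. Whole
chambers only — the window binds on area, never on the chamber count, and
no partial chamber is ever cropped. Both bounds are configurable
(`roi.DEFAULT_WINDOW`, `RunConfig.window`).

Chamber ordering uses explicit ontogeny ranks when the chamber map carries
them, else increasing centroid distance from the apex coordinate.

A pore belongs to the ROI iff its centroid pixel falls inside the ROI mask,
and an included pore contributes its full area. The centroid rule keeps
expected counts unbiased at chamber boundaries and makes PD additive over
chamber unions; the alternatives (clipping pore bodies, or any-overlap
inclusion) bias areas down or counts up respectively.

## Classical segmentation

The deterministic reference chain is:

1. **Test detection** — global Otsu on a lightly smoothed image, largest
   bright connected component, holes filled. A contrast-free dark frame is
   an error ("no specimen found"); a uniformly bright frame is treated as
   all-specimen. The mask is eroded 2 px before thresholding to keep the
   silhouette boundary out of the pore search.
2. **Illumination flattening** — subtraction of a 20 µm Gaussian background
   estimate, then min–max normalisation of the masked values to [0, 1].
   Because thresholds are computed on normalised data, the labelling is
   invariant to rescaling all intensities by a positive constant.
3. **Dark-pixel thresholding** — Otsu on the masked values, with two
   robustness devices. (a) If the spread between the shell level (median)
   and the dark tail (0.2nd percentile) is under 4 robust standard
   deviations (1.4826·MAD), there is no resolvable pore class and the
   result is empty — this is what a poreless or noise-only frame looks
   like. (b) If Otsu lands within the top 20% of that spread it has
   collapsed into the shell mode (this happens at strong class imbalance,
   i.e. very low porosity); the threshold falls back to the quantile
   midpoint `p0.2 + 0.55·(median − p0.2)`. The 0.55 factor places the cut
   near the half-contrast pore boundary; it was chosen on synthetic images
   to keep per-pore area errors small and is part of `SegConfig`
   (`hysteresis_weak` additionally allows growing threshold cores toward a
   weaker level; default off).
4. **Despeckling** — connected components under 3 px are dropped. A size
   floor is used instead of a morphological opening because any opening
   with a ≥3×3 structuring element also destroys the smallest legitimate
   pores (3–4 px across at 1 µm/pixel), which would make exact noise-free
   recovery impossible.
5. **Optional watershed splitting** of touching pores on the distance
   transform, with seed separation 2·√(min_pore_area/π)/pixel_size to
   avoid over-splitting single ellipses (off by default; the generator
   spaces pores, and real *B. spissa* pore fields are well separated).
6. **Filters and labelling** — area within [min_pore_area, max_pore_area]
   (defaults 1–500 µm²) and solidity ≥ 0.65 (removes arcs and rims), then
   consecutive 8-connected labels. 8-connectivity matches the rendering of
   anti-aliased ellipses and is the blob-detection standard.

`min_pore_area` defaults to 1 µm², well under the smallest mean pore size
observed in these species (~6 µm²), so that the known failure mode on
very-small-pored species (*B. argentea*) is reproducible rather than
silently masked.

## Trainable segmenter

The learned route is a neural pixel classifier: each pixel carries a
9-feature multiscale descriptor (intensity; Gaussians at σ = 1, 2, 4 px;
two difference-of-Gaussians; Sobel gradient magnitude; local SD at σ = 2;
a σ = 16 flat-field residual), standardised and classified pore/non-pore by
a single-hidden-layer MLP (16 units) trained with minibatch SGD, one
shuffled pass per epoch, 1500 pore + 1500 background pixels sampled per
training image. The probability map is cut at 0.5 (ties to background) and
post-processed by the identical chain as the classical route, so the two
segmenters are directly comparable against ground truth. Training and
inference are CPU-only and deterministic for a fixed seed; the model
records its training pixel size and warns when applied at another scale,
since the filter bank is scale-sensitive. Fewer than 8 training images
warns (useful for overfit sanity checks); `epochs=0` returns an untrained
model that warns and predicts nothing.

Feature-bank pixel classification was chosen over a deep encoder–decoder
deliberately: at these image statistics (high pore/shell contrast, additive
noise) it reaches the same ground-truth parity while training in seconds on
one CPU and keeping the training loop fully reproducible.

## Artifact correction

`remove_artifacts` emulates the manual correction step in which unwanted
surface particles are erased before measurement: every pore component
touching the artifact mask is removed whole (a contaminated pore is not
trusted), labels are recompacted, and the count never increases. On
synthetic cohorts the corrected and uncorrected cohort-mean pore densities
are compared with a two-sample t-test; the difference is non-significant,
because spurious detections (dark debris specks counted as pores) are rare
relative to true pores and to between-specimen variance.

## Synthetic specimen generator

The generator builds a physical scene in µm and only then rasterises:

* **Chambers** — n (default 12) axis-aligned ellipses of aspect 3.0 in
  alternating left/right bands growing geometrically (ratio 1.12, first
  chamber 3,200 µm²), each overlapping the previous by 14% of its height so
  the silhouette is a single connected test; suture wedges are closed and
  assigned to the nearest chamber. With these defaults the ten oldest
  chambers cover ≈56,000 µm², inside the normalisation window, and the
  whole test ≈77,000 µm² — a schematic megalospheric biserial bolivinid.
* **Pores** — per chamber, round(PD_target · area) elliptical pores with
  log-normal areas (mean = MPS target, CV 0.25, floored at 6 µm² and capped
  at 3× the mean), eccentricity uniform in [0, 0.6], random orientation.
  Placement is rejection-sampled largest-first with a 2 µm minimum gap
  between pore boundaries and a 3 µm clearance from chamber edges
  (enforced by testing the pore's margin circle against the chamber
  ellipse); geometrically impossible densities raise an error naming the
  limiting chamber. The achieved ROI-level density lands within a few
  percent of target (rounding only).
* **Intensities** — 8-bit by default: background 60, shell 185, pores
  60–140 below shell via 3×3-subsampled coverage (anti-aliasing), additive
  Gaussian noise (σ = 8 default). Optional multiplicative cosine shading
  toward the test edge emulates curvature falloff (off by default, as flat
  specimens are the recommended input).
* **Debris** — by default 4 particles per specimen, each either a bright
  multi-lobed adhered particle with a dark rim shadow (it occludes pores it
  covers: occluded pores are swallowed into the debris footprint, removed
  from the ground truth and flagged) or a small dark surface speck placed
  clear of real pores — the latter is exactly the artifact class an
  automated analysis miscounts as pores until corrected.
* **Ground truth** — a pore's true area is *defined* as its rendered pixel
  count × pixel_size², so pore-level accuracy is scored without annotation
  ambiguity; chamber maps, debris masks and per-chamber tallies are exact.

Because all random draws happen in physical units before rasterisation, the
same seed reproduces the same specimen at any pixel size; PD and porosity
agree within 2% between 1.0 and 0.5 µm/px renders, which the suite asserts
end-to-end through segmentation.

Cohorts draw per-specimen (PD, MPS) targets from truncated normal
distributions per location preset (Gulf of Guayaquil PD
0.0043 ± 0.0008 pores/µm², MPS 17.13 ± 4.37 µm²; Sea of Okhotsk
0.00524 ± 0.0010 and 20.67 ± 3.54 — its PD mean derived from porosity/MPS
via the identity; Mexican margin 0.0045 ± 0.0010 and 18.5 ± 3.8 and
core-top 0.0055 ± 0.0008 and 17.5 ± 3.5, chosen consistent with the overall
means and the nitrate relation where no direct location values are
printed; "default" uses the overall means 0.004 ± 0.001 and 17.83 ± 3.83).
Draws are truncated marginally at PD ∈ [0.0015, 0.009], MPS ∈ [6, 47.62]
and jointly at implied porosity ∈ [2.5, 17]% — slightly wider than the
observed 2.66–16.03% envelope so the joint guard rarely binds; cohort
means still converge to the preset parameters within 3 SEM at n = 500.
First-chamber areas jitter ±~10% so ROI selections vary realistically.

What the generator does **not** emulate: curvature distortion of pore
shapes (only brightness falloff), chamber sutures and wall texture, charging
and detector artifacts, partial pore occlusion (occlusion is all-or-none),
and microspheric/megalospheric dimorphism. Passing tests therefore
demonstrate correctness of the measurement machinery under a controlled
image model, not segmentation performance on difficult real SEM material.

## Statistics

`ols_fit` is closed-form simple OLS; the slope p-value uses the t
distribution with n−2 df (for simple regression the slope t-test and the
regression F-test are the same test, so one p is reported). The test suite
checks it against an independent normal-equations matrix solve and against
statsmodels. The t tests (pooled and Welch), Wilcoxon rank-sum and
Shapiro–Wilk delegate to scipy.stats behind the package's result types; the
Wilcoxon statistic is reported as the rank sum W of the first group, using
the exact permutation null for combined n ≤ 20 without ties (the switch
point is configurable) and the tie-corrected, continuity-corrected normal
approximation otherwise. The exact path is verified against full
enumeration for every tie-free configuration with n ≤ 10, the approximate
path against a seeded permutation oracle, and Shapiro–Wilk against a value
frozen from R's `shapiro.test` plus a type-I-error simulation. All p-values
are two-sided and no multiple-testing correction is applied.

Manual-vs-automated agreement uses the manual count as the reference
denominator: per-specimen difference = 100·|manual − auto|/manual. The two
mean pore densities are compared with an unpaired Student's t (the group
means are the published comparison), and a paired t is reported alongside
because the specimens are matched.

## Nitrate calibration

The transfer function is fit as unweighted OLS of bottom-water nitrate on
location-mean pore density — this direction matches how the equation is
applied, and the published coefficients are reproduced by an unweighted fit
on location means. Location SEMs are carried but not used as weights.
Prediction at pore density p returns a·p + b with
SE² = [p, 1] Σ [p, 1]ᵀ + a²·SEM(p)², where Σ is the coefficient
covariance; with a refitted model the SE is smallest at the calibration PD
mean and grows away from it, as it must. The shipped
`PUBLISHED_CALIBRATION` carries a = −3896 ± 350, b = 61 ± 1 with a
*diagonal* covariance, because only marginal SEs are published; refit when
the covariance matters. t-based prediction intervals including residual
variance are intentionally left out of the default output, which reports
1 SE.

Applicability is a species whitelist (*B. spissa*, *B. subadvena*);
*B. subadvena accumeata* and *B. argentea* sit far off the line and are
refused at prediction time unless explicitly overridden (the override still
warns). This is a scientific constraint, not a numeric one, so it is
enforced structurally.

`covariate_screen` regresses pore density on nitrate, oxygen, temperature,
salinity and water depth across jointly-keyed locations and flags the
strongest covariate; a constant covariate is reported as a degenerate-x
error without failing the others. The packaged
`data/coretop_env.csv` carries the bottom-water conditions of the nine
core-top calibration sites (Costa Rica, Sagami Bay and seven Peru-margin
stations). Since the per-site specimen pore-density means are not freely
available, `synthetic_coretop_points` inverts the transfer function at each
site's measured nitrate and adds residual nitrate scatter (SD 0.8 µmol/kg,
sized to reproduce a slope SE near ±350 at these nine sites); this
supports self-consistency recovery tests and screening demonstrations, not
a re-derivation of the published fit from raw data.

## Problem sizes and reproducibility

The acceptance checks run at the sizes the analyses state: 50-specimen
cohorts for segmentation recovery, 40 training + 12 held-out images
(10 epochs, seed 7) for the learned route, 31 specimens for the
manual-vs-automated comparison, 100 random OLS fixtures, exhaustive
Wilcoxon enumeration to n = 10, 1,000 Shapiro–Wilk samples and 500
calibration replicates of 9 points. Every stochastic component takes an
explicit seed; cohort generation spawns per-specimen child seeds from one
master generator, so whole runs are bit-reproducible, and pipeline runs
emit a manifest (config snapshot, seeds, input hashes, timings) sufficient
to replay them.

## Known limitations

* Chamber maps come from the generator or user annotation; automatic
  chamber segmentation from raw images is out of scope, as is modelling the
  ontogenetic pore-density trend itself.
* The classical threshold logic assumes pores darker than the shell and a
  roughly unimodal shell intensity; heavily charged or curved specimens
  violate this (use flat, well-mounted specimens).
* The learned segmenter is trained and validated on synthetic imagery here;
  applying it to real SEM images requires retraining on manually segmented
  examples of the target species, at the target pixel size.
* Pore perimeter/circularity indices and multi-class segmentation are not
  computed; porosity-vs-oxygen calibrations for epifaunal taxa are out of
  scope.
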