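# Methods

This note documents the models, parameter choices and numerical contracts
behind `chorioquant`, and what its synthetic-data validation does and does
not establish about real OCT/OCTA data.

## Ocular magnification

OCT devices convert scan angle to lateral distance assuming a reference
eye. We use Bennett's abbreviated axial-length correction: the lateral
scale factor of an eye of axial length `AL` relative to the device's
assumed eye (default 24.385 mm, configurable) is

```
scale = (AL − 1.82) / (AL_ref − 1.82)
```

where 1.82 mm approximates the distance from the cornea to the second
nodal point of the reduced eye. Only the lateral pixel spacing is
rescaled; axial spacing is set by optical path length and is treated as
AL-independent. Areas therefore scale linearly, not quadratically, with
the factor (one corrected dimension × one fixed dimension). The corrected
scale also sizes the 6-mm structural region of interest (ROI) and the
2.5-mm choriocapillaris circle.

## Structural pipeline: binarization and area measurement

**Band convention.** A column's choroid band is the half-open pixel
interval `[upper, lower)`, so the per-column pixel count equals
`lower − upper` and the subfoveal thickness `SFCT = (lower − upper) ×
axial spacing` is consistent with the measured areas. The ROI spans the
half-open column interval `[fovea − w, fovea + w)` with
`w = round(3 mm / corrected lateral spacing)`.

**Despeckle.** Before binarization the band is mirror-padded column-wise
(the band content is reflected over the retina and sclera) and a 5-px
median filter is applied. The mirror padding matters: without it the
median filter drags retinal and scleral intensities into the band's edge
rows and biases the lumen call there. Set `despeckle_px=0` to binarize
raw images.

**Niblack threshold.** A pixel is lumen iff `I < μ_w + k·σ_w`, with the
windowed mean and SD computed over band pixels only (masked statistics;
windows truncate at image borders). Ties are stroma — a conservative
lumen call that makes tests exact. The comparison uses a relative
tolerance of 1e−9 so that floating-point round-off in the windowed mean of
a perfectly flat region cannot create spurious lumen pixels.

Defaults are a 201-px window (~1.2 mm laterally at 5.86 µm/px) and
`k = −0.18`, calibrated on synthetic scenes with known luminal fraction.
The window must be large enough that essentially every local window
contains both lumen and stroma: when a window is homogeneous, an adaptive
threshold splits its pixels around their own mean and drags the estimated
vascularity toward 50%. Small classic windows (tens of pixels) show
exactly this bias on speckled choroid bands — up to ~10 percentage points
of CVI error at high vascularity in our validation — while the default
setting keeps the error below 2.5 points over true CVI 45–75%. Both
parameters are exposed in the configuration.

**Areas.** Lumen and stroma partition the band pixels inside the ROI, so
`TCA = LA + SA` is an exact integer-pixel identity, not an approximation.
`CVI = 100·LA/TCA`. Per-meridian metrics are combined as the arithmetic
mean of each field; the averaged CVI is the mean of per-meridian ratios,
which is the literal reading of a meridian-mean procedure (the pooled
alternative — ratio of summed areas — was rejected to keep the averaged
CVI consistent with its per-meridian definition).

## Choriocapillaris pipeline

**Slab.** The choriocapillaris en-face image is the depth-mean over
`[BM + offset, BM + offset + thickness)` with a 20-µm default thickness
starting at the basal border of the RPE–BM complex.

**Compensation.** Two artifacts are handled, each validated only against
the synthetic generator's truth (the vendor algorithm is proprietary, so
this is a functional surrogate authored here):

* *Shadowing* — the slab image is divided by a Gaussian-smoothed
  co-registered inner-retina reference normalized to its global median
  (σ = 10 px default). Attenuation that appears in both images cancels.
  A non-positive smoothed reference is an error.
* *Projection* — pixels under the projection mask are replaced by the
  median of non-masked pixels in a surrounding annulus (radii 3–9 px
  default), removing the bright retinal-vessel tails without inventing
  texture.

Compensation runs before thresholding; the order is a package decision
(the device's internal order is not public).

**Flow deficits.** A compensated pixel is a deficit iff its intensity is
strictly below `multiplier × σ_ref` (defaults 1.5 and 30 gray levels, an
absolute 45-gray cut on 8-bit images; ties perfused). σ_ref stands for a
normative-database signal SD and is configurable, never hard-coded into
results. ROI membership is by pixel center — no anti-aliased partial
pixels — which keeps counts integral; the discrete circle area agrees
with πr² to well under 1% for fields ≥ 256 px.

## Synthetic data

The generators exist to give every estimator a pixel-counted ground
truth; their defaults are fixed study conditions, not tuning knobs.

* **B-scans** (default 1280 × 256 px at 5.86 × 3.9 µm/px, emulating a
  12-mm line scan): a smoothly undulating choroid band (~270 µm, ±8%
  lateral thickness modulation) at stroma gray 200 holds elliptical vessel
  lumens (gray 40, radii 15–70 µm, eccentricity ≤ 2, overlap counted
  once) placed by rejection sampling until the realized luminal fraction
  of the 6-mm ROI band is within ±0.05 of target (200-attempt cap, then a
  parameter error). The render is multiplied by unit-mean gamma speckle
  (shape 4, a first-order surrogate for fully developed OCT speckle) and
  quantized to 8 bits; truth masks and areas are computed before noise,
  over the same ROI the quantifier measures.
* **Angiograms** (default 512 px ≈ 3 mm field): perfused texture
  (180 ± 5 gray) with dark deficit disks (gray 5, radii 15–60 µm) placed
  until the deficit fraction inside the evaluation circle is within ±0.02
  of target. Optional artifacts: a disk-shaped multiplicative shadow and
  bright vertical projection stripes, both recorded in the truth together
  with the artifact-free render and a co-registered inner-retina
  reference carrying the same dip and stripes.
* **Cohorts**: two groups (adults, children), one visit per near-work
  duration (20/40/60 min), pre and post values per metric. Subject
  baselines are drawn from the groups' baseline distributions (e.g. adult
  LA 990 ± 229.3 ×10³ µm², CVI 62.45 ± 3.08%) with a small per-visit
  wobble (20% of the baseline SD) so repeat visits agree without being
  identical; post = pre + Normal(effect mean, effect SD) with
  per-(group, metric, duration) effects such as adult 20-min SFCT
  −5.1 ± 6.5 µm. Durations with no detectable effect use mean 0 with the
  metric's typical change SD. Metrics are drawn independently — the
  cohort table models the statistical layer, so TCA is its own column
  rather than the per-subject sum of LA and SA. Axial length is drawn per
  subject (adults 25.00 ± 1.05 mm, children 24.56 ± 0.67 mm).

**What passing tests show.** Recovery of CVI within 2.5 points and CcFD
within 1.5 points demonstrates that the estimators are unbiased under
this noise model, at these contrasts, with exact boundary input. Real
data add segmentation error, non-gamma detector noise, vessel-wall
partial volume, motion and defocus, none of which the generators emulate;
recovery there must be established separately.

## Cohort statistics

* **Change scores.** Per subject and duration, `delta = post − pre` and
  `percent change = 100·(post − pre)/pre` (pre = 0 is an error). Percent
  changes are computed per subject and then analyzed, not derived from
  group means.
* **Paired tests.** One-sample t of the deltas; Bonferroni multiplies by
  the number of post-hoc comparisons actually performed within each
  group × metric family (the three durations, recorded in the output),
  capped at 1.
* **Repeated-measures ANOVA.** One-way within-subject F with
  Greenhouse–Geisser correction: Box's epsilon from the double-centered
  sample covariance of the k levels, `ε = tr(S̃)²/((k−1)ΣS̃²)`, clamped
  to `[1/(k−1), 1]`; both degrees of freedom are multiplied by ε. For
  k = 2, ε = 1 identically. Degenerate inputs are pinned: zero
  residual and zero effect give F = 0, p = 1. The implementation is
  validated against pingouin to machine precision.
* **Group contrast.** The between-group comparison of percent changes
  adjusted for axial length is a linear model `change ~ group + AL
  (+ duration + group×duration)` estimated by OLS with cluster-robust
  (sandwich) variance by subject. With one observation per
  subject-duration and a cluster-constant group indicator this targets
  the same adjusted mean-difference estimand a GEE would report; full
  working-correlation machinery is deliberately out of scope. When
  several durations are present the reported contrast averages the group
  effect over durations. Zero-variance AL is dropped with a warning
  rather than crashing the fit.
* **Repeatability.** ICC is the two-way, absolute-agreement,
  single-measure form `(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)`
  (equals pingouin's ICC(A,1) to machine precision); zero total variance
  is an error. Bland–Altman reports the mean difference and
  `bias ± 1.96·SD` limits.
* **Normality.** Shapiro–Wilk p values of the change scores are computed
  and reported but never gate the pipeline, keeping runs deterministic.

## Pipeline and determinism

A single validated YAML config (pydantic models; invalid fields are
named) drives simulate → quantify → analyze. Per-file seeds are derived
from the run seed by a fixed affine map mod 2³¹−1, so one integer
reproduces every image, table and report byte for byte; the manifest
records the config, its hash, and every file with its seed. Logs go to
stderr and `run.log`. CSVs are written with fixed float formatting to
keep byte-level determinism.

Default validation problem sizes — 20 B-scan scenes, 20 angiograms,
2000/500 replicate calibration of the paired test, n = 500 repeatability
simulations — were chosen so the whole suite and the acceptance script
each complete in well under a minute on a single core while keeping
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

* Boundary segmentation is an input; the package never segments.
* The compensation algorithm is a documented surrogate, validated only on
  synthetic artifacts.
* The speckle model is first-order (multiplicative gamma); no coherent
  imaging physics, 3-D vessel topology, or motion artifacts.
* The GEE surrogate reports the adjusted group mean difference; it does
  not reproduce a specific working-correlation structure.
* Sattler/Haller sublayer separation and deficit-size distributions are
  out of scope.
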