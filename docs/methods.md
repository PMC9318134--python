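# Methods

## Estimands and estimators

The measurand throughout is the stained-area fraction of a field: the
percentage of pixels belonging to specifically stained (DAB-brown) tissue.

**Point-grid estimator (MC).** A grid of `n_rows × n_cols` points (default
27 × 22 = 594) is realized on the raster. Systematic placement puts point
(i, j) at `((i+0.5)·H/n_rows, (j+0.5)·W/n_cols)` — every cell sampled at its
center, half-cell margins, nothing on the border. Uniform-random placement
draws points i.i.d. over the raster; under it, with an exact hit rule, the
estimate `100·hits/n` is unbiased with variance `p(1−p)/n` (binomial
sampling). A continuous point maps to its nearest integer pixel with the
half-*down* tie rule `idx = ceil(coord − 0.5)`, clipped to the raster; the
tie rule only matters on exact `.5` boundaries and is fixed so results are
bit-reproducible. Hit classification is either `oracle_mask` (read the
ground-truth mask — the idealized observer used for estimator-property work)
or `color_rule` (pixel within a tolerance of a reference color — a fallible
observer surrogate whose reference and tolerance can be perturbed).

**Color-range estimator (DC).** A selection criterion is one or more sampled
RGB reference colors plus a fuzziness tolerance F (default 100 on the 8-bit
scale). A pixel's distance to the *nearest* sampled color is Chebyshev
(max per-channel difference) by default — the closest published analogue of
per-channel tolerance semantics in commercial color-range tools — with
Euclidean as an option. Hard falloff (default) selects at `d ≤ F` and counts
binary membership, matching a histogram pixel count; linear falloff weights
pixels `clamp(1 − (d − F/2)/(F/2), 0, 1)` and sums weights, provided because
graded (anti-aliased) selections are what interactive editors actually
produce and the counting convention for them is not standardized. At F = 0
linear falloff degenerates to exact-color membership. The criterion
serializes to YAML/JSON so one saved selection can be applied across slides.
No claim of bit-compatibility with any proprietary implementation is made;
the declared metric and falloff are the contract.

## Agreement statistics

**ICC.** One-way random-effects, single-measure: with n subjects measured
k = 2 times, `ICC = (MSB − MSW)/(MSB + (k−1)·MSW)` from the one-way ANOVA
mean squares; variance components `σ²_between = (MSB − MSW)/k`,
`σ²_error = MSW`; p-value from the F test `MSB/MSW` on (n−1, n(k−1)) df.
Constant data raise an error rather than reporting a coefficient that is
undefined there. Reliability labels follow Fleiss: `> 0.75` excellent,
`0.40–0.75` good (boundaries inclusive), `< 0.40` poor. The one-way form was
chosen because the study design it serves treats the two measurements of a
field as interchangeable repeats; a two-way absolute-agreement ICC on the
same data differs negligibly at these sample sizes (the pingouin ICC1
cross-check in the test suite agrees to 1e-9).

**Bland–Altman.** Differences are `B − A` (DC − MC, and T2 − T1) — the sign
convention is fixed and recorded in every output. Bias is the mean
difference, limits of agreement `bias ± 1.96·SD` (sample SD, n−1), and
coverage the percentage of differences inside the limits, boundary points
counted inside. The multiplier is configurable; 1.96 corresponds to 95%
normal-theory content, which the calibration test verifies empirically.

**Pearson.** Plain product-moment correlation, plus a `diff_vs_mean` mode
correlating `(B − A)` with `(A + B)/2` — the proportional-bias check that
accompanies a Bland–Altman plot. Both are exposed because reliability
studies report both, and a near-zero difference-vs-mean correlation is the
meaningful "no trend" statement for agreeing methods.

## Cohort comparison

Unit of analysis is the patient: the 4 field values per patient, marker and
method are averaged before testing, so an 11-vs-11 design yields n = 11 per
group. Field-level testing is available but explicitly labeled — it inflates
the effective sample size by ignoring within-patient correlation.

- **Mann–Whitney U** (PI vs PD per marker and method): exact p by full
  enumeration of group assignments when `n_a + n_b ≤ 12` with no pooled
  ties, otherwise normal approximation with tie and continuity corrections.
- **Wilcoxon signed-rank** (MC vs DC per marker, paired on patients): zero
  differences excluded; exact p by enumerating all 2^n sign assignments
  (midranks for tied absolute differences, computed by convolution) when
  n ≤ 15 after exclusion, else the continuity-corrected normal
  approximation. All-zero differences are surfaced as a degenerate condition
  in the results table, never silently swallowed.
- **D'Agostino–Pearson K²** is reported per marker/method as a descriptive
  normality check (n ≥ 8 required); it does not gate the analysis — the
  nonparametric tests are used unconditionally.

α defaults to 0.05 with no multiplicity correction across the 7 markers,
mirroring common practice in small histomorphometry cohorts; Bonferroni or
Benjamini–Hochberg adjustment within each test family is available via the
``correction`` argument but off by default.

## The synthetic-field generator

What it emulates: DAB-brown stained cell clusters (random ellipses, semi-axis
scale 9 ± 3 px on a 512 × 512 default field) on a hematoxylin background with
nucleus ellipses and eosin-pink patches, at a controlled true fraction; and a
paired NOISE regime adding diffuse brown haze (a smoothed random field
covering ~45%·intensity of the image, blend strength growing with intensity)
plus small high-opacity brown speckles (~600·intensity per 512² field) to
background pixels only.

Key constructed properties:

- the stored `true_fraction` is *exactly* the mask's pixel fraction; the last
  blob is truncated pixel-wise so the achieved count equals the rounded
  target (within one pixel, i.e. ≲ 0.0004 pp on the default extent);
- palette separability: stained pixels are the stain RGB (120, 66, 18) ± 10
  per channel, and every background color sits at Chebyshev distance > 100
  from the stain (the discriminating channel differs by ≥ 122 even after
  background jitter), so a fuzziness-100 selection seeded on the stain
  recovers the truth exactly in the GOOD regime;
- noise orthogonality: noise is applied only where the mask is 0, so ground
  truth and every stained pixel are byte-identical across the regime pair;
  speckle opacities (0.50–0.95) put their colors astride the fuzziness-100
  boundary, which is what makes the digital count both overcount and become
  sensitive to the exact reference color on NOISE fields.

Study fixtures draw true fractions uniform on [1%, 30%] — inflammatory
markers occupy a minority of tissue area, and a wide spread gives the ICC a
realistic between-field variance. Cohort simulation is hierarchical:
per-marker baseline (3–8%) + group effect (+6 pp CD68, +8 pp CD138 in PI by
default — macrophage/plasma-cell elevation large enough that an 11-vs-11
Mann–Whitney has > 90% power) + patient effect N(0, 2²) + field effect
N(0, 1.5²) + per-method noise N(0, 0.6²), clipped to [0, 100].
Paired-difference simulation adds N(bias, sd) to a base sample, clips
likewise and counts the clip events.

What it does **not** emulate: real nuclear/membrane morphology per marker,
stain spectral physics or color deconvolution, scanner optics, or continuous
color gradients between stain and background. Consequently, passing tests
demonstrate estimator and statistics correctness under controlled separable
colors — not segmentation performance on real slides, where DC's GOOD-regime
error would be larger than the near-zero values seen here.

## The study runner

Two observers × two timepoints measure every field with both estimators.
Observer variability is injected explicitly, since without it every ICC is
identically 1:

- DC: each observer-timepoint samples its own reference color — the true
  stain color plus N(0, 8²) per-channel jitter, rounded and clipped — and
  reuses that saved selection across all fields (one eyedropper act per
  session). On GOOD fields the jitter is far smaller than the color margins,
  so selections coincide; on NOISE fields haze/speckle pixels near the
  tolerance boundary flip in and out with the reference color, degrading
  interobserver agreement — the regime ordering the design predicts.
- MC: the oracle-mask read with a per-point lapse probability (default 0.02):
  each of the 594 point classifications flips independently with that
  probability. A lapse model, rather than a perturbed color rule, is used
  because the human counter's defining property here is *regime blindness* —
  they discriminate haze from true stain — and a color-rule observer would
  wrongly degrade on NOISE. Note the symmetric flip pulls estimates toward
  50% by `ε·(1 − 2p)` (~+1.4 pp at p = 0.15), which is why the simulated
  MC-vs-DC comparison shows a nonzero bias; this is a documented property of
  the error model, not a bug.

Interobserver ICC pairs each observer's mean over the two timepoints, per
field, within a regime; intraobserver ICC pairs T1 with T2 per observer over
all fields. Bland–Altman and Pearson compare per-field method means (over
observers and timepoints) per regime, differences DC − MC. Wall-clock per
measurement is logged in the summary as informational metadata only. All
randomness descends from one master seed through named seed-sequence spawns,
so identical configurations produce byte-identical CSV outputs.

## Numerical choices and degenerate inputs

- Point-to-pixel rounding: half-down via `ceil(x − 0.5)`, clipped at edges.
- Exact-test gates: Mann–Whitney exact iff tie-free and total n ≤ 12;
  signed-rank exact iff n ≤ 15 post zero-exclusion (ties handled by midrank
  enumeration). The method actually used is reported with every p-value.
- ICC on data with MSW = 0 but subject spread returns exactly 1 with p = 0;
  fully constant data raise.
- Bland–Altman on identical pairs returns degenerate limits [0, 0] with 100%
  coverage.
- `target_fraction` 0 and 100 produce the empty and the full mask exactly;
  an unreachable target (pathological blob constraints) raises with the
  constraint named.
- All simulation values are clipped to [0, 100] and clip events counted.

## Problem sizes in the test suite

The suite exercises full-scale design counts where they are the point
(200 fixtures, 11 + 11 patients, 594 points, 10⁴ Monte-Carlo replicates and
10⁴ simulated pairs) and reduced field extents (48–256 px) or field counts
(12–30 per regime) where only relative behavior is asserted; these sizes are
the package's declared simulation choices and are stated in the tests.

## Known limitations

- The synthetic palette is linearly separable by construction; DC accuracy
  on GOOD fields is therefore an upper bound, not a prediction for real
  slides.
- The observer models (color jitter, point lapses) are simulation knobs with
  declared defaults, not quantities fitted to human data; only orderings and
  calibrations that are robust to their exact values are asserted.
- The ICC is implemented for k = 2 repeated measures; multi-rater
  generalizations are out of scope.
- No multiple-testing correction is applied by default across markers; users
  comparing many markers should enable their own correction downstream.
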