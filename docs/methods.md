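# Methods

## Scope and data model

`nucleogate` analyzes 2D multi-channel fluorescence fields that stand in
for maximum-intensity projections of 3D spheroid co-cultures. All
per-nucleus metrics (marker sums/means, 2D projected area, condensation
ratio) are defined on 2D projections; there is no z-stack segmentation.
Coordinates are 0-based `(row, col)`; areas are reported in px² and µm²
through the pixel size (default 0.65 µm/px, a typical 10–20× sampling).

## Synthetic scenes

The generator emulates the statistical structure the downstream analysis
assumes, not the optics of any particular microscope.

**Geometry.** Spheroids are laid out on a jittered grid; nuclei are placed
inside each spheroid disk by random sequential (dart-throwing) placement
with a minimum center distance of 2.2× the mean radius of the largest
planted class; after 10⁴ rejected darts placement fails with an error.
Fibroblast nuclei are scattered outside the spheroid footprints. Nuclei are
ellipses with axis ratio U(1.0, 1.3), radius N(4.5, 0.5) µm (clipped), and a
per-subpopulation area multiplier (below).

**Markers.** Per-nucleus marker levels are log-normal: γH2AX as an
integrated (sum) level painted at uniform density S/A inside the mask,
DRAQ7 and Ki67 as mean levels painted flat. The log-normal location is set
so the distribution mean equals the configured mean exactly
(μ = ln m − σ²/2; σ defaults to 0.5, giving the right-skewed per-nucleus
distributions typical of immunofluorescence). γH2AX and DRAQ7 are drawn
from **independent** streams, which is what makes 90th-percentile gating of
an untreated cohort produce an expected 0.9² = 81% low/low fraction. The
log-normal family is a modeling choice — the assay does not pin down the
marker distribution — and only quantile/mean structure matters downstream.

**Planted effects.** Treatment presets scale the configured marker means by
the planted fold; paired arms share the root seed, so the underlying
standard-normal draws coincide and the truth-table mean ratio equals the
fold exactly, while imaging noise perturbs only the measured values. The
calibrated "treated" gating preset instead shifts each marker's log-location
by σ·(z₀.₉ − z₁₋ₚ) with p = 1 − √0.69, so each marker exceeds the untreated
population's true 90th percentile with probability p and the expected
low/low fraction is (1−p)² = 0.69 under independence.

**Chromatin texture.** Each nucleus is a soft euchromatin base plus hard
heterochromatin disks (radius 1.6 px) covering a per-subpopulation area
fraction at a per-subpopulation contrast; the base level is chosen so the
mask mean equals the configured DNA level regardless of coverage. The true
noiseless P80/P20 of this texture increases strictly with the contrast
parameter (verified by test). Class coupling follows the observed
phenotypes: area multipliers (1.0, 1.25, 1.5, 1.8) across (low/low,
high-damage/low-death, low-damage/high-death, high/high) — area rises with
damage and death — and blob contrasts (2.6, 2.1, 1.7, 1.4) — damage and
death decondense chromatin, death more strongly. Magnitudes are
configurable; a "separable" preset widens the spacing for classifier
ceiling studies.

**Optics and noise.** One Gaussian PSF blur (σ = 0.8 px), a flat per-channel
background, Poisson shot noise at unit gain, Gaussian read noise (σ = 2
counts), and clipping at zero (camera offset behavior). No PSF tails,
photobleaching, depth attenuation, or spatial background structure — so
passing tests demonstrate correctness of the measurement and inference
chain under the assumed statistics, not robustness to real-microscope
artifacts such as uneven illumination or out-of-focus haze.

**Determinism.** One root `SeedSequence` spawns six child streams in fixed
order (placement, class assignment, geometry, markers, texture, noise);
identical configs give byte-identical images and tables.

## Segmentation and measurement

Background is estimated by a rolling ball of radius 4× the expected nucleus
radius. For speed the ball runs on a 4× down-scaled copy and the estimate
is resized back — a standard approximation that is exact for background
varying slower than the downscale factor. Segmentation: Gaussian smoothing
(σ = 1 px), Otsu threshold, hole filling, distance-transform watershed with
1.5× radius peak separation, minimum area filter, contiguous relabeling.
Spheroids are connected components of the morphologically closed (radius
1.5× nucleus radius) union of nucleus masks with at least 5 member nuclei;
other nuclei are fibroblast-like singletons and are excluded from
cancer-cell statistics by default.

Intensity summaries (sum, mean, P20, P80) use background-subtracted pixels
clipped at zero; percentiles are linear-interpolation percentiles
(`numpy.percentile` default), the same convention used for the gating
thresholds and the condensation ratio. Whether the original assay
background-subtracted its per-nucleus sums is not documented; we subtract
and record the choice (an additive offset common to both arms largely
cancels in normalized fold changes anyway).

Cell typing thresholds the CellTracker channel once with Otsu; a nucleus is
receptor-negative (A431) when ≥ 50% of its 2 px-dilated mask is
tracker-positive. If the tracker-positive area of the whole field is
negligible the scene is treated as unmixed.

## Gating

γH2AX uses the **sum** per nucleus and DRAQ7 the **mean** per nucleus,
each normalized by the mean of that same summary over untreated
receptor-positive reference nuclei (so the reference normalized mean is 1).
Thresholds are the 90th percentiles of the normalized reference values.
Gating is strict (`>`); ties gate low — conservative and reproducible.
"Positive" fractions per spheroid reuse the same thresholds; the assay does
not define a separate positivity cut. Reference pooling is per experiment
by default (per-gel gating is possible by fitting separate models).

## Features

22 features per nucleus across size/shape, DNA intensity and texture (list
in `features.FEATURE_COLUMNS`). Numerical choices: boundary curvature is
computed on the contour resampled to 1 px arc steps, smoothed with a
periodic Gaussian (σ = 2 px) and differentiated centrally; co-occurrence
texture uses 32 gray levels after per-nucleus min–max scaling, offsets
{1, 2} px averaged over 4 directions, with co-occurrences involving
out-of-mask pixels discarded. Per-nucleus min–max normalization makes all
texture features invariant to intensity rescaling; only `dna_sum` and
`dna_mean` are scale-equivariant. Undefined features (degenerate per-nucleus
Otsu on uniform texture, zero P20) flag the row; flagged rows are excluded
from classification, never imputed.

## Classifier

Random forest, 500 trees by default (√p features per split, unlimited
depth, fixed seed), stratified five-fold CV, pooled out-of-fold predictions,
balanced accuracy = macro-averaged recall. Marker-derived columns are
rejected by a substring blacklist so the classifier sees morphology and
chromatin only. Class floor: ≥ 100 nuclei per subpopulation. Folds are
stratified at nucleus level; grouping folds by spheroid would be stricter
against spatial leakage and is left to the caller (synthetic nuclei are
exchangeable within an arm, so leakage is not an issue for the shipped
studies). Chance studies use 200 trees — the permutation null does not
depend on ensemble size and this halves the study's cost.

## Validation studies and problem sizes

The shipped studies use: 2000 cancer nuclei per arm for the 81%/69% gating
fractions, 1000 per arm for fold-change recovery (planted 2.1× γH2AX,
1.9× DRAQ7, 1.3× Ki67, 12× γH2AX for HDAC-inhibitor + radioligand, 28×
DRAQ7 for chromatin-modifier + radiotherapy against the ≥ 25× bound),
50 spheroids per arm for the 1.7× actin-spread ratio (base spread factor
0.08, where the area-ratio metric is still near-linear in the planted
factor), 400 balanced nuclei and 20 permutations for the 25% chance
calibration, and 200 nuclei per class for the directional area/condensation
rank tests. These sizes give Monte-Carlo error comfortably inside each
check's tolerance while keeping any single study under a few minutes.

## Known limitations

- The feature bank is a documented re-creation of the three named axes
  (size, curvature, texture); importance *rankings* are therefore only
  qualitatively comparable to any particular original feature list.
- The actin-spread definition (out-of-mask actin-positive area within 3×
  the equivalent radius, normalized by spheroid area) is
  implementation-defined; only fold comparisons between conditions are
  meaningful.
- Segmentation is classical (no learned model); it is tuned for the
  generator's contrast regime and for roughly convex, moderately packed
  nuclei.
- Uptake tables model three compartments per condition; no decay
  correction or dosimetry.
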