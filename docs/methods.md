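# Methods

This note records the models and procedures `cordquant` implements, the
assumptions and defaults behind them, what the synthetic generators do and
do not emulate, and the choices made where the underlying workflow left the
design open.

## Image preprocessing

**Flat-fielding.** Illumination artifacts (stitching seams, bubbles, lamp
falloff) vary slowly across a micrograph compared with stained somata. The
white top-hat transform — image minus its morphological opening with a flat
disk — removes every structure larger than the disk while passing compact
bright objects. The default element radius is 25 px (>= 2x the largest
expected soma radius at 1 um/px, so somata survive); it is configurable.
The opening is computed with an exact "crosses" decomposition of the disk,
verified bit-identical to the full-kernel erosion/dilation and ~20x faster.
The top-hat output is non-negative and pointwise bounded by the input, and
is idempotent on structure-free images.

**Orientation and quadrants.** Rotation angle and central-canal location
come from a blinded human rater (a landmark CSV); there is no automatic
dorsal-root-entry-zone detection. Rotation is about the image center
(positive = counterclockwise on screen); exact multiples of 90 degrees use
the lossless grid rotation, arbitrary angles bilinear (images) or
nearest-neighbour (masks) resampling. Quadrants are defined by straight
vertical/horizontal lines through the rounded canal pixel; pixels exactly
on a dividing line go to the dorsal and ipsilateral sides (a fixed,
documented tie rule — any consistent rule would do). Whether real anatomy
would warrant a curved midline is ignored: straight lines are assumed.

**Rostrocaudal position.** Sections are cut at 20 um into a 7-slot staining
series, so consecutive same-stain sections are 140 um apart:
position = (index - epicenter index) x 20 x 7 um, rostral negative. The
epicenter index is user-supplied per animal (it is identified
anatomically); `suggest_epicenter` proposes the section with maximal
detected damage area as a starting point.

## Histology quantification

**Optical density.** The cutoff is the arithmetic mean intensity of a
contralesional region of interest on the flat-fielded image (the original
workflow did not state whether raw or corrected intensities were used;
corrected is assumed throughout). The default ROI is a 40 x 40 px square
mirrored across the canal line, configurable, since the original placement
was a rater's choice. OD is the mean of pixels *strictly* above the cutoff
("above" was not defined in the source workflow; strict is fixed and
documented), reported with the above-threshold pixel count; an empty
selection reports a missing mean, not zero.

**Neuron counting.** NeuN+ objects are 4-connected components above
threshold. The printed size bins "23-115" and "116-345" um^2 are
interpreted as contiguous on the continuous area scale — small [23, 116),
large [116, 345] — because areas are non-integer for pixel sizes other than
1 um and a gap would silently drop real cells. Areas below 23 um^2 are
debris; above 345 um^2, excluded-by-size. The detection threshold defaults
to the contralesional-ROI rule; an explicit threshold can be configured
instead. Note a limit of the ROI rule on flat-fielded images with zero-mean
additive noise: the ROI mean then sits in the middle of the background
distribution and roughly half the background exceeds it, so closed-loop
count tests under noise use an explicit threshold (half the known soma
amplitude). On real tissue the ROI contains baseline stain and the rule
lands above background.

**Damage exclusion.** The original workflow excluded lesion
autofluorescence with an interactively trained deep-learning segmenter;
this package substitutes a classical morphological detector. Damage is
defined as regions simultaneously bright (> 0.1 x the robust cross-channel
99.9th-percentile maximum) in >= 2 channels — genuine stains light up one
channel, lesion autofluorescence bleeds into all — closed with a 5 px disk,
keeping only components larger than 4x the maximum neuron area so no soma
can qualify. The detector applies its own top-hat with an 80 px element
first: the soma-scale 25 px element would remove the lesion-scale blobs
along with the illumination. An externally supplied exclusion mask (e.g.
from the original segmenter) can be passed instead wherever an `exclusion`
argument is accepted. Exclusion can only remove detections, never add.

**Vacuolization.** Entirely this package's construction (the source
workflow reports vacuole counts without a formula, which is flagged here
prominently): myelin-positive pixels are those above half the channel
median (robust to lesion hyperintensity; scale-invariant), vacuoles are
connected components of fill-holes-minus-mask of at least 10 px, assigned
to the section side containing their centroid, and reported as a count and
as vacuole area / myelin-positive area per side. The default analysis
window is +/- 2 mm around the epicenter; +/- 3 mm is available by
configuration, neither privileged.

**Profiles.** Per-side OD is binned at the 140 um series spacing over
+/- 10 mm by default, pooling animals with mean, SD and n per bin.

## Plethysmography

**Segmentation.** The source workflow names the ventilation metrics but not
a segmentation rule, so the rule here is the package's own: a Schmitt
trigger on the flow signal with hysteresis band 0.1 x the 95th percentile
of |flow| detects upward zero crossings; each opens a breath that runs to
the next. Inspiratory time ends at the first downward zero crossing;
breaths with inspiration shorter than 0.05 s are discarded. TV integrates
the positive flow (trapezoid) times the chamber calibration, making it
insensitive to the exact trigger sample; traces are assumed pre-calibrated
(no barometric temperature/humidity correction — the Drorbaugh-Fenn
correction is out of scope). Window summaries default to the final 300 s.

**Clustering.** The published clustering method behind the four waveform
categories is not recoverable in detail, so it is reconstructed as: resample
each breath to 64 points by linear interpolation over its own duration
(duration-normalized, amplitude in mL/s), z-score per feature — per feature
rather than per breath so amplitude differences between categories remain
discriminative — and run k-means (10 restarts, seeded) for k in [2, 8],
choosing k by maximum mean silhouette. Degenerate inputs (all breaths
identical) fall back to one category. Centroids are reported in physical
units as means of the unscaled member rows. Category matching across
sessions is one-to-one Hungarian assignment on centroid distances, and
prevalence is expressed relative to the reference (pre-injury) session.

## Gas arithmetic

Standard constants throughout: 760 mmHg/ATA, 47 mmHg water vapor at body
temperature, PaCO2 40 mmHg, respiratory quotient 0.8, zero
alveolar-arterial gradient, solubility 0.003 mL O2/dL/mmHg. The iso-oxic
pressure-control fraction matches inspired *dry-gas* products
(f x P_ATA = 0.21), which yields exactly 10.5% at 2 ATA; matching
water-vapor-corrected pressures instead gives slightly *less* O2 (10.17% at
2 ATA, because the fixed 47 mmHg vapor bite shrinks relatively as pressure
rises) and is available as `isooxic_fraction_wet`. Published dissolved-O2
figures for such protocols (~0.5 / 2.3 / 7 mL per 100 mL at ~100 / >500 /
>2000 mmHg) imply solubilities between 0.0035 and 0.005 and are mutually
inconsistent with any single alpha, so the standard 0.003 is used and those
figures are not asserted anywhere.

## Synthetic data: what it emulates, what it does not

Somata are **hard intensity disks** (not Gaussian blobs) so the true
rasterized area — pixels whose centers fall within the radius — is
unambiguous and every count/size test has an exact oracle. The illumination
field is a product of cosines with spatial period 160 px (>= 5x the
flat-field element) and random phase, amplitude 400 on an offset of 2000,
in a 16-bit-like intensity range at 1 um/px (acquisition bit depth and
pixel size were unstated in the source; both configurable). Cells peak at
8000 counts; damage regions are flat-topped disks with a cosine rim,
brighter (15000) and >= 4x larger in radius than somata, rendered into all
channels; vacuoles are zero-intensity holes in an otherwise bright myelin
channel. Breaths are half-sine inspirations followed by volume-balancing
half-sine expirations; the four archetypes (sniff: short/low-amplitude;
small and large tidal; sigh: ~2x the large-tidal amplitude) have
adult-rat-like defaults (TV ~1.6-3 mL, tidal rate ~90-100/min) with 5%
amplitude/duration jitter and optional additive noise.

Not emulated: tissue texture, anatomically shaped gray/white matter, 3-D
stacks, scanner noise models, breath-to-breath autocorrelation, or apnea
events. A green closed-loop test therefore establishes that the algorithms
recover what the stated generative world planted — not that they are robust
to every property of real micrographs or real breathing.

The clustering benchmark uses equal archetype prevalences, n = 400 breaths
and reduced (2%) jitter: at the default 5% duration jitter the zero-crossing
columns of the resampled matrix carry enough within-category variance that
the closest archetype pair is no longer "well separated" in the benchmark's
own sense and silhouette merges categories. The benchmark test verifies its
separation premise (minimum between-centroid distance >= 6x the largest
within-category per-coordinate RMS) before asserting recovery.

## Statistics

Shapiro-Wilk on within-group residuals and Levene's test (both alpha 0.05,
configurable) guard the one-way ANOVA; failure of either switches the
omnibus to Kruskal-Wallis (the source states only that the rank test was
used when "ANOVA assumptions" failed; the concrete checks are this
package's choice). Post-hoc families run only when the omnibus p < 0.05:
Tukey-Kramer for all-pairs (histology-style outcomes), Dunnett for
many-to-one against the intact control (breathing-style outcomes), selected
per outcome in the pipeline configuration. Groups with fewer than two
observations are excluded with a log message.

## Numerical and degenerate-input choices

- Strict `>` at every threshold; equal-to-cutoff pixels never count.
- Empty OD selections and breathless windows report missing (NaN/None) and
  are logged, never silently zeroed.
- Zero-variance inputs: Shapiro/Levene p treated as 1 (ANOVA retained,
  which then reports p = 1); z-scoring holds no-variance columns at zero
  rather than amplifying rounding noise.
- A flat flow trace yields an empty breath list, not an error; a trace
  shorter than 1 s is an error.
- Seeds: every stochastic component takes an explicit seed; cohort
  generation derives per-animal seeds from one root seed, and the pipeline
  records all of them in its manifest together with SHA-256 fingerprints
  of every input file.

## Known limitations

- The damage detector is a stand-in for the original trainable segmenter;
  its contract (bright in >= 2 channels, lesion-scale size) is tuned to the
  synthetic world's geometry and should be revalidated on real tissue.
- The vacuole score has no published reference formula; absolute fractions
  are only comparable within this package.
- Optical density depends on the ROI placement convention; cross-study
  comparisons require the same convention.
- The breath clustering reconstruction fixes distance metric (Euclidean on
  z-scored resampled flow) and k selection (silhouette); other reasonable
  choices could split or merge categories differently.
- No stereological correction is applied to counts from 20 um sections, and
  cresyl-violet lesion morphometry is out of scope.
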