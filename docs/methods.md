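# Methods

## The assay model

All cell-fate readouts in this package are pixel ratios, not cell counts.
The underlying assumption is that in a 3D culture imaged as a z-stack, the
total foreground area of a stain across slices is proportional to the
amount of stained biological material, and that ratios of such areas
(nuclear vs dead-marker, EdU vs nuclear) are robust to cell size, stack
depth, and field placement.  Slices are analyzed independently in 2D and
aggregated by summing — no 3D connected components, no instance
segmentation — which is what makes the method usable on thick, scattering
samples where nucleus boundaries cannot be resolved reliably.

## Illumination correction

Wide-field images of thick samples carry a smooth, center-bright additive
bias (stray light, matrix autofluorescence shaped by the illumination
cone).  The correction subtracts a Gaussian blur of each plane from itself
and clamps negatives to zero.  Subtraction removes *additive* bias exactly
(a constant plane maps to exact zero — the flat-field identity); it cannot
remove a multiplicative attenuation of the signal itself, which would
require a division-based flat-field calibrated on reference images and is
out of scope.  The blur scale must sit far above the nucleus scale or
nuclei are absorbed into their own background estimate: the default
`sigma_px = 50` suits 512–2048 px planes and a warning fires below 5 px or
below twice the expected nucleus radius.  The test suite uses
`sigma_px = 25` for its 96–224 px planes, keeping the same ratio of blur
scale to plane size.  Reflective padding avoids dark rims at plane edges.
One caveat measured during development: the foreground itself leaks into
the blurred background estimate, so in very dense fields the correction
slightly over-subtracts around bright objects; at the cell densities used
here (1–7% foreground) the effect is negligible.

## Thresholding

Yen's maximum-correlation criterion is computed on a 256-bin equal-width
histogram spanning [0, max observed].  Writing `N_k = P_k²/S_k` for the
squared class probability over the class's sum of squared bin
probabilities, the criterion is `TC = ln N_1 + ln N_2`, maximized over all
interior cuts with ties resolved toward the lower cut; the returned
threshold is the bin edge at the cut, and masks use strict `>`.  The
implementation is vectorized but is held equal, histogram for histogram, to
an exhaustive brute-force maximization in the tests, and is cross-checked
against an independent library implementation on shared pixel data.

Two rules harden the threshold for 3D stacks:

- **Central-slice estimation.** The histogram is pooled from the centered
  block of `ceil(central_fraction × n_slices)` slices (default 0.2,
  minimum one slice) and the resulting threshold is applied to *every*
  slice.  Out-of-focus halos concentrate in the extreme slices; estimating
  there, or per-slice, lets the dim halo intensities pull the cut down and
  hallucinate foreground.  Pooling was chosen over a median of per-slice
  thresholds (both are defensible; pooling needs no tie-break policy and
  uses all central pixels) and the alternative remains a one-line change.
- **Signal absence.** A stack whose threshold is less than `signal_fold`
  (default 10) times its background mean — defined as the mean of pooled
  central-slice pixels strictly below the threshold, a self-contained
  definition requiring no extra pass — is declared signal-free and
  contributes an empty mask.  Exactly ten-fold passes; the comparison is
  `threshold ≥ 10 × background`.  On pure-noise stacks the Yen cut lands
  within a few noise standard deviations of the background mean, far below
  ten-fold, so blank wells reliably report no signal.

A robust-background backend (trimmed mean + 2 trimmed SDs, 5% tails
pro-rated across histogram bins) is provided as an alternative
thresholding method for parity with spreadsheet-era processing; it is not
the default.

## Scoring

Each image contributes `ln(numerator_px / max(denominator_px, 1) + 1)`.
The integer pseudocount keeps the logarithm finite when a marker channel is
empty and is negligible against realistic areas (10³–10⁶ px).  Viability
uses nuclear over overlap-corrected dead pixels; the two death markers
label overlapping cell populations (late-apoptotic cells acquire both), so
their intersection is subtracted once, slice-wise, before the ratio.
Proliferation defaults to EdU over nuclear: with that orientation the
normalized score *falls* as S-phase is suppressed, matching how
dose-response plots are read; the reversed orientation is available as a
flag and logged when used.  Natural log is used throughout; because scores
are ratios of means of log-ratios, the base cancels.

Treatment scores divide the per-treatment mean by the vehicle-control mean
(control ≡ 1).  The SEM is the per-image SD/√n scaled by the control mean,
treating the control mean as a constant — i.e. control uncertainty is not
propagated into treated wells' error bars, matching the usual
"normalized to control, mean ± SEM" presentation.  Images whose *nuclear*
channel failed the signal rule are excluded (no cells in view); empty
marker channels stay in with zero area.  Dividing each image's ratio by the
control mean before averaging would give identical means and slightly
different SEMs; the means-ratio form was adopted.

In co-culture mode the GFP lineage's pixels are removed by subtracting the
*intersections* (GFP ∩ Hoechst from the nuclear area, GFP ∩ EtHd from the
dead area) rather than the raw GFP area: intersections cannot drive a count
negative when the GFP mask bleeds outside the nuclear mask through
misregistration or halo.  Raw-area subtraction (clamped at zero) is
available behind `subtract_mode="raw"` for parity studies.

## Statistics

Each row (dose level) is tested with Welch's unequal-variance two-sample t
test — no SD is pooled across rows — and the family of raw p-values is
adjusted with the Holm-Šidák step-down procedure
(`adj_(i) = 1 − (1 − p_(i))^(m−i+1)` on the ascending sort, running-max
monotonicity, step-down stopping rule), delegated to
`statsmodels.stats.multitest.multipletests` and verified against the closed
form in the tests.  At n = 3 per group Welch's test runs conservative
(observed null size ≈ 0.035 at nominal 0.05); the family-wise error rate in
all-null simulation sits correspondingly below α.  Stars follow adjusted p:
`*` < 0.05, `**` < 0.005, `***` < 0.0005.

## The synthetic-stack generator

The generator exists so every stage has a ground truth.  What it emulates,
and what it deliberately does not:

- **Geometry.** Cells are solid balls of radius `nucleus_radius_px`
  (default 4 px) placed by hard-sphere rejection sampling (minimum
  separation 1.6 radii; nuclei are mutually exclusive volumes — without
  this, coincident nuclei create intensity pile-ups above twice the nominal
  peak that destabilize any histogram thresholder).  Anisotropy is explicit:
  `z_step_px` (default 3) is the slice spacing in xy-pixel units, matching
  ~2 µm steps against sub-µm pixels.
- **Rendering.** A slice cutting a ball renders a full-intensity Gaussian
  disk with half-max radius equal to the ball's cross-section
  (`blob_sharpness` generalizes to super-Gaussians).  Slices beyond the
  ball render out-of-focus halos: peak `halo_scale^(d/r)` of the in-focus
  peak at physical defocus distance `d` — exactly `halo_scale` (default
  0.3) at one radius — broadening with distance and cut off below 5% of
  peak.  The Gaussian skirt gives histograms the smooth heavy tail
  characteristic of fluorescence images; that tail is what makes Yen's
  criterion sit well above the background level.
- **Photometry.** Per-channel fate-dependent expression (Hoechst in every
  cell, EtHd in membrane-dead, an Apopxin membrane annulus at 1.1
  cross-section radii, EdU in S-phase cells, H2B-eGFP in the tagged
  lineage), a center-bright additive background bias
  (`background × V(x, y)` with `V` a centered Gaussian field, 1 at center,
  `1 − strength` at corners), Gaussian read noise, rounding and clipping to
  16-bit.  Not modeled: photon (Poisson) noise, spectral bleed-through,
  PSF-accurate defocus, collagen fiber texture, photobleaching.  Passing
  tests therefore demonstrate the pipeline's logic and its robustness to
  the modeled effects — halos, bias, read noise, blank wells — not
  performance on every artifact of real microscopes.
- **Fates.** Death categories (EtHd-only / Apopxin-only / both) are one
  multinomial draw per scene; vehicle-treated cultures carry a baseline
  death total of 0.2 (3D collagen cultures show appreciable baseline death,
  and the death channels of control wells must carry real signal for
  control normalization to be stable).  Planted kill fractions compound
  with the baseline as `1 − (1−b)(1−k)`.  S-phase is drawn independently
  for every cell — EdU incorporated during S phase persists in cells that
  later die within the incubation window.  GFP-lineage cells are drug
  insensitive with a fixed 5% EtHd rate.
- **Ground truth.** The planted foreground of a channel is the set of
  voxels whose noiseless, bias-free rendering is *strictly brighter than
  the brightest out-of-focus structure* (`halo_scale × nucleus_mean`): the
  region a threshold that "captures only in-focus nuclei" should recover.
  Fate counts, per-cell flags, and per-well planted fractions are recorded
  alongside.
- **Dose plates.** One well per dose, several positions per well, each
  position an independent scene seeded from `SeedSequence([seed, well,
  position])`; kill and S-phase fractions follow four-parameter logistics
  of dose or are planted explicitly.  Plates can be written to disk as
  single-plane TIFFs with a layout YAML and truth CSV, in the same filename
  grammar the discovery module parses.

Everything is deterministic given the seed, down to file bytes.

## Numerical and engineering choices

- Histograms: 256 equal-width bins over [0, max observed]; scale
  equivariance (intensities × c ⇒ threshold × c, masks bit-identical) holds
  because binning is relative to the observed maximum.
- Degenerate histograms (fewer than two occupied bins) yield
  `has_signal = False` with threshold +∞ inside the batch pipeline, logged
  rather than raised; the same condition raises `NoContrastError` when the
  thresholder is called directly.
- All area and intersection arithmetic is integer; inclusion-exclusion and
  intersection-based subtraction cannot produce negatives by construction.
- Parallelism is process-per-position via joblib with results merged in
  sorted key order, so output files are byte-identical for any worker
  count; per-position failures are quarantined with their error message
  and the run continues.
- Test and acceptance problem sizes (8–12 slices, 96–224 px planes,
  15–300 cells, 2–6 positions per well) were chosen so pixel-ratio
  statistics are stable across seeds while the full suite runs on one CPU
  in minutes; they scale the study design down, not the physics.

## Known limitations

- Pixel areas conflate cell number with cell size; a treatment that swells
  nuclei without killing changes the viability score.
- The ten-fold signal rule is a hard gate: marker channels with very few
  positive cells near the detection limit flicker between "measured" and
  "absent", adding variance at low kill fractions (mitigated in the study
  conditions by realistic baseline death).
- Blur-subtraction correction removes additive bias only; multiplicative
  shading of the signal survives it.
- The CellProfiler-style robust-background threshold is provided for
  comparison but has no central-slice or signal-absence hardening of its
  own beyond what the pipeline applies around it.
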