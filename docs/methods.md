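# Methods

## The measurement model

The package treats a cochlear cross-section as a one-dimensional object: the
epithelial band crossed by the duct-floor path running from the medial to the
lateral luminal edge.  Marker intensity along the path's arc length *s* is
modelled as a plateau per radial domain (IS, MS, LS, OS) joined by sigmoidal
transitions,

> v(s) = p_IS + Σ_b (p_after(b) − p_before(b)) · Φ((s − s_b) / σ),

with Φ the standard normal CDF, s_b the true boundary position and σ the
transition half-width (default 3 µm).  Because Φ(0) = ½, the half-maximum
crossing of a min-max-normalized profile coincides exactly with the true
boundary; thresholding normalized profiles at a fixed fraction is what makes
fluorescence levels comparable across sections.  Medial-band markers (PORCN,
Ki67, PRDM16) are a single plateau falling off at a stated fraction of the
total width.

Measurements are deliberately one-dimensional where the underlying
quantifications are (boundary positions, widths, compartment fractions) and
two-dimensional only for thresholded area/total intensity, where area is
pixel count × pixel size² inside the epithelium mask and intensity the sum of
above-threshold pixel values.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure of embryonic cochlear
imaging: per-domain marker plateaus with smooth boundaries, shared
multiplicative lognormal cell texture (CV 0.15), additive Gaussian noise
(s.d. 5% of the maximum plateau), per-section lognormal channel gain
(imaging/staining variability), and cohort-level variation of total width and
domain fractions drawn from truncated normals (±2.5 s.d., symmetric about the
mean so cohort means stay unbiased).  Wholemounts plant one aligned IHC row
(8 µm spacing, endpoints pinned so first-to-last distance equals the true
length), three OHC rows 20/30/40 µm lateral, and Poisson-distributed ectopic
IHCs displaced 10 µm medially from a distinct aligned partner.

It does **not** emulate: nuclei-level cell structure, optics (PSF, bleed-
through, depth attenuation), 3-D confocal stacks (orthogonal sections are
generated directly as 2-D images), tissue deformation, or segmentation-
confounding artefacts like folds and debris.  Passing recovery tests
therefore demonstrates that the measurement chain is correct and unbiased
under the stated noise model — not that it is robust to every failure mode of
real microscopy.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `threshold_frac` | 0.5 | of normalized range | half-maximum; coincides with the sigmoid midpoint, hence the true boundary |
| `boundary_transition_sigma` | 3 | µm | sub-resolution of domain widths; makes half-max crossings well defined |
| `band_halfwidth` | 5 | µm | perpendicular averaging band; suppresses single-pixel noise in profiles |
| `smoothing_window` | 5 | grid points | moving average before crossing detection |
| `grid_points` | 101 | – | common grid for cross-sample averaging; far finer than the smallest domain |
| area threshold | 0.2 × robust max | a.u. | relative threshold keeps area/intensity gain-invariant; robust max = 99.5th percentile inside the tissue mask |
| `pairing_distance` | 12 | µm | ~1.5 IHC spacings; a "doublet" is an ectopic IHC paired with its nearest aligned IHC within this longitudinal distance (greedy, one partner each) |
| `tolerance_row` | 4 | µm | half a cell radius; aligned vs ectopic decision, boundary-inclusive toward aligned |
| `pixel_size` | 0.5 (sections), 1.0 (wholemounts) | µm/px | resolution typical of 20–40× confocal acquisitions |
| `epithelium_thickness` | 40 | µm | free rendering parameter; areas scale with it equally in all cohorts |
| `medial_fraction` | 0.55 | of total width | the absolute medial/lateral compartment split is not published; explicit free parameter |

## Calibration of the preset distributions

Preset **means** carry the published cohort measurements directly (total
width 192.2 → 177.9 µm at E14.5; IS fraction 71% → 52% at E14.5 and
57% → 38% at E15.5; Ki67 width 45% → 40%; PRDM16 50% → 40%; per-region
doublet means 1.3/3.1/6.1, 11.5/20.33/15.4 and 8.2/24.83/47.8; cochlear
lengths 6000/5543/5100 µm giving the −15% and −8% contrasts).

Preset **spreads** are derived from the published *t*-test p-values rather
than the printed ± values: the two are mutually inconsistent (reading the ±
values as s.e.m. implies per-section spreads two times larger than the
printed p-values allow), and the p-values pin down the pooled per-section
s.d. directly via sd = Δ / (t⁻¹(p/2, df) · √(1/n₁ + 1/n₂)).  This gives
total-width s.d. 8.8 µm and IS-fraction s.d. 9.5 points at E14.5, IS-fraction
s.d. 8.0 points at E15.5, Ki67/PRDM16 band-extent s.d.s of 4.6/3.9 points,
and combined fluorescence CVs of ~14% for Ki67 and JAG1.  Fluorescence CV is
decomposed: the geometric components (band width, total width) already
contribute ~10–12%, so the per-channel gain CV carries only the residual.

Three published effects are *measured* quantities whose encoding must account
for the measurement itself:

- **Ki67 total fluorescence −22%.**  Total fluorescence is gain × band area.
  With the width shrinking 45% → 40%, the Ki67 plateau gain is set to
  0.78 × 45/40 = 0.8775 so that gain and width jointly produce the −22%.
- **SOX2 area +18% (E15.5) and +47/+33/+20% (E18.5 base/mid/apex).**  At the
  0.2-of-max threshold a sigmoidal-edged plateau measures
  σ·Φ⁻¹(0.842) ≈ 3 µm wider per edge than its true width.  The free layout
  fractions (E15.5 `ls_fraction` = 0.698; E18.5 cKO IS fractions
  0.3876/0.5071/0.5682) are solved analytically from
  (w_cko + 6 µm)/(w_ctrl + 6 µm) = published ratio, so the planted effect, as
  measured by the stated procedure, equals the published change.  The SOX2
  channel gain supplies the remainder of the published intensity changes.
- **Doublet totals.**  The published per-region cKO means sum to 80.8, not
  the published total of 78.5 ± 6.3; the generator follows the per-region
  means, so recovered totals converge to ~80.8, inside the published
  uncertainty.

## Numerical choices

- Sub-grid boundary positions by linear interpolation between the two
  samples bracketing the threshold crossing; most-medial rising crossing for
  JAG1/E-cadherin, most-lateral falling crossing for SOX2 (tie-break rules).
- Piecewise-linear interpolation throughout (resampling, averaging): monotone
  safe, cannot overshoot the [0, 1] normalization bounds.
- Constant (zero-range) profiles normalize to all zeros with a `constant`
  flag instead of dividing by zero; boundary calling on them raises a
  `NoBoundary` error naming the marker.
- Degenerate t-tests (zero pooled variance) return p = 1 for equal means and
  p = 0 with a `degenerate` flag otherwise.
- Quantiles are type-7 (linear interpolation), recorded in report metadata.
- Blob detection: negated scale-normalized Laplacian of Gaussian at the spot
  scale, local maxima with suppression radius 0.6 × IHC spacing, sub-pixel
  refinement by intensity-weighted centroid of the local response window.
- Row fitting: per-100 µm window, y values are clustered at gaps > 6 µm;
  clusters below 60% of the largest cluster's size (sparse ectopics) are
  ignored and the most medial remaining cluster's median is taken, followed
  by a 3-window median filter — tolerant of ≥ 30% ectopic outliers.
- Cohort seeds derive from `(seed, index)` via `numpy.random.SeedSequence`,
  so cohorts are reproducible, mutually independent, and stay below 2³¹.
- Percent changes report both the s.e.m. of the normalized treated values
  and a delta-method standard error that additionally propagates the control
  mean's sampling uncertainty (`se_change`); the latter is the honest
  uncertainty of the ratio-of-means estimate.

## Design choices where the design was open

- The MS-LS boundary uses the rising E-cadherin edge by default (JAG1 and
  E-cadherin are complementary); a `both` mode reports the midpoint of the
  E-cadherin rise and JAG1 fall and flags divergence beyond 2 µm.
- An alternative MS measurement mode derives the IS-MS boundary from the
  rising SOX2 edge (equivalent to SOX2 width minus LS width).
- Area/intensity thresholds operate on raw intensities with a per-image
  relative default; an absolute threshold can be passed for FIJI-style fixed
  thresholds shared across a comparison.
- Sections are treated as replicates in the statistics (matching the
  published sampling unit); aggregating per cochlea first is the
  statistically conservative alternative and can be done on the tidy tables.
- Base/mid/apex are equal thirds of the measured aligned-row length; no
  anatomical landmark information exists in the images.
- E12.5-style sections for the JAG1-fluorescence comparison reuse the E14.5
  layout with a JAG1 gain of 0.29 in the knockout, since only total
  fluorescence — independent of the layout — is measured at that stage.

## Problem sizes

The test suite and the acceptance script run cohorts at the published sample
sizes (15/19, 24/24, 22/21, 18, 8/8, 32/37 sections; 12/9/14 wholemounts);
single sections are ~470 × 160 px × 8 channels and wholemounts
~6000 × 110 px, so a full acceptance run finishes in well under a minute on
one CPU.  Distributional checks use 100–200 generator draws; the type-I-error
calibration uses 2000 simulated null t-tests.

## Known limitations

- Total width is measured between Otsu mask edges, which is stable for the
  synthetic band but, on real images, would inherit any DAPI background
  streaks; no illumination correction is implemented (the measured protocol
  applies none).
- The thresholded-area tail term (~3 µm per edge) means absolute areas are
  slightly larger than true domain areas; all published comparisons are
  ratios, which the calibration accounts for.
- Doublet pairing is an operational definition (the underlying publications
  never define one); counts at other `pairing_distance` values can differ.
- With fewer than ~5 detectable cells, or preparations where ectopics
  outnumber aligned cells locally by more than ~40%, the row fit degrades and
  raises `row not identifiable` rather than guessing.
- The statistics module implements exactly the published machinery (Student's
  t, Bonferroni, ANOVA + Tukey); it does not model section-within-animal
  correlation (no mixed effects).
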