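# Methods

## Quantification model

All quantification operates on analyte-to-reference intensity ratios of
**summed** ROI spectra: `r = Σ I_analyte / Σ I_lipid` over the ROI's pixels.
Summing before ratioing (rather than averaging per-pixel ratios) keeps the
statistic well-defined at pixels with near-zero reference signal and gives
each pixel weight proportional to its material content.  The endogenous
phosphatidylcholine transition (m/z 782.6 → 184.1) serves as the reference
because it is abundant, homogeneously distributed in homogenates, and
subject to the same per-pixel desorption and suppression factors as the
analyte.

Calibration is ordinary unweighted least squares of per-level mean ratio
against nominal concentration with a free intercept.  Replicate ratios
(n = 3 per level) are averaged before fitting so every level carries equal
weight.  Weighted regression is deliberately not offered: on ratio data
with shared multiplicative noise, the level means are already roughly
homoscedastic, and the free intercept absorbs the constant chemical
background.  The line is not forced through zero for the same reason.

Detection limits follow the blank-variability convention:
`LOD = 3·SD_blank/slope`, `LLOQ = 5·SD_blank/slope`, with `SD_blank` the
sample (n − 1) standard deviation of the blank replicate-ROI ratios — three
whole blank wells, one summed ratio each, matching the triplicate blank
preparations of the experimental design.  Small-n sample SD (ddof = 1) is
used throughout the package.

**Below-LOD exclusion.**  Calibration levels whose nominal concentration is
below the current LOD are removed and the curve refit; the exclusion set is
recomputed from the full ladder on every pass until it is stable (a
fixpoint), rather than applied once.  The fixpoint choice makes the
procedure idempotent: rebuilding a calibration from its own included levels
changes nothing.  Exclusion leaving fewer than three levels is reported as
a calibration failure carrying the offending LOD.  The ULOQ is the highest
included level; back-calculated concentrations are flagged `below_lod`,
`below_lloq`, `above_uloq`, or `ok` accordingly, with `nd` reserved for
channels that are absent or zero everywhere (a transition not acquired).

**QC characterization.**  Precision is `100·SD/mean` of the replicate
concentrations and accuracy `100·mean/nominal`.  The acceptance thresholds
default to precision ≤ 15 % RSD (≤ 20 % when the nominal level is at or
below the LLOQ) and accuracy in 80–110 % — the bioanalytical
"−20 % to +10 %" reading — and are configurable via `QcCriteria`.

**Cell-density correction.**  `r_corrected = r · d_cal / d_ROI`, where
`d_ROI = cell count / n_pixels` over the ROI and `d_cal` is the homogenate
cell density of the calibration wells.  The reference lipid signal scales
with intact-cell density while drug content per gram of tissue does not, so
an ROI sparser than the homogenate has an inflated raw ratio in exactly the
proportion this factor removes.  No standard arithmetic exists for this
correction in the literature; the formula is isolated in one operation
(`cell_corrected_ratio`) so an alternative convention is a one-line change.

**ROI summary flags.**  Replicate ROIs (three disjoint masks per region)
are quantified independently; the region is reported as mean ± sample SD.
The summary flag classifies the replicate *mean* against the curve's
limits, except that any single replicate beyond the ULOQ taints the whole
region (`above_uloq`), since its mean would extrapolate the line.

**Fold differences and LC-MS concordance.**  Pairwise regional folds are
reported as larger/smaller with the direction recorded, full precision
retained, and one-decimal display rounding; flagged or zero-valued pairs
are skipped with a note.  Concordance with LC-MS results that are published
only as concentration ranges uses the nearest-bound rule: a value inside
the range scores fold 1, otherwise the ratio to the nearest bound — the
conservative reading when the reference is an interval, and folds are ≥ 1
by construction.

## Synthetic data generator

The generator emulates the study conditions, not mass spectra: channels are
already-integrated MRM transition intensities on a raster.

* **Geometry.**  A 20 × 20 mm gelatin block with 3 × 3 mm square wells at
  2 mm spacing on a 4 × 4 grid whose bottom-right corner stays empty as the
  orientation marker (15 usable positions).  The default fill is 8 ladder
  levels (12.5, 25, 50, 125, 250, 500, 1250, 2500 µg/g), 3 blanks, and one
  well per QC level (25 and 1250 µg/g), assigned to positions by a seeded
  random permutation to avoid leverage; two positions stay unfilled.
  Rasterization is 100 µm by default (30 × 30-px wells); the test suite and
  acceptance script use 200 µm (15 × 15-px wells, 225 px/well) to keep
  seeded Monte-Carlo runs fast.
* **Signal model.**  Each pixel carries an intact-cell density `d`
  (homogenate default 50 cells/pixel).  Expected intensities are
  `lipid = g·d` and `analyte = s·c·g·d²/d_cal` with lipid gain
  `g = 100` counts per cell-density unit and response slope
  `s = 0.001` ratio units per µg/g per analyte channel (absolute counts are
  arbitrary units; only ratios are quantified).  In calibration wells
  (`d = d_cal`) the expected summed ratio is exactly `s·c`; in tissue the
  raw ratio scales with `d/d_cal`, which the cell-density correction
  inverts exactly.
* **Noise.**  One *shared* unit-mean log-normal field per pixel
  (CV = `pixel_rsd`, default 0.2 to match the ~20 % pixel-to-pixel RSD
  observed for the lipid channel in liver sections) multiplies every
  tissue-derived channel: it models desorption efficiency and ion
  suppression, which act on analyte and reference alike — the physical
  basis of ratio normalization.  Each channel additionally receives an
  independent half-normal chemical baseline (scale `baseline_noise_sd`,
  default 5 counts): intensities are counts and never negative, and because
  the baseline's positive mean is spatially constant it is absorbed by the
  calibration intercept, so blanks and undosed regions back-calculate to
  ≈ 0.
* **Diffusion.**  Migration of homogenate material into the gelatin
  corridor is a Gaussian blur (`diffusion_sigma_mm`, default 0) of the
  expected concentration and cell-density fields before noise.
* **Dosed sections.**  A label map (lesion / connective / parenchyma /
  background; demo truth 500 / 75 / 240 µg/g) and an optional cell-density
  map generate tissue with the same signal model; background pixels carry
  baseline only.  Replicate ROIs interleave a region's pixels in raster
  order, mimicking triplicate extraction from one section.
* **Determinism.**  All draws come from one `numpy` generator seeded from
  `SimParams.seed` in a fixed channel order; identical inputs reproduce
  grids bit for bit.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: mass-spectral structure (isobaric
interference, fragmentation efficiency), cryosectioning artifacts and
section-to-section thickness variation, spatially structured suppression
that the lipid does *not* share (the real reason the paper-style lipid
correction is imperfect in heterogeneous liver), registration error between
H&E and MSI rasters, and detector saturation.  Synthetic QC precision is
accordingly much tighter than the ~11–14 % RSD typical of real arrays.

## Diffusion check

Corridor contamination per channel is
`max(0, (mean_corridor − mean_background) / D)` where the corridor is every
non-well pixel inside the well bounding box at least `corridor_margin_px`
from any well, the far background is every pixel outside the bounding box
at least twice that margin from any well, and `D` averages over corridor
pixels the within-well mean intensity of each pixel's nearest well
(Euclidean distance transform).  Defining the background by distance from
the wells (not by the block outline) matters: on a 20 mm block that is
mostly wells, a rim just outside the array also receives diffusion and
would cancel the corridor excess.  The fraction is ≈ 0 without diffusion
and grows with the diffusion length because corridor pixels sit closer to
the wells than the far background does.

## Instrument/mode comparison

`summarize_mode` runs the identical calibration + QC chain per compound for
each instrument/mode dataset and reproduces characterization-table
conventions: QC levels whose nominal concentration falls below that mode's
LOD are rendered `<LOD` with precision/accuracy suppressed, and calibration
failures become failed rows rather than aborting the table.  `rank_modes`
orders modes by (1) number of criteria passed (precision and accuracy at
both QC levels, 0–4), (2) lower LOD, (3) higher R², with ties kept in input
order and logged; the ranking key is a declared convention, configurable by
reordering, not a published algorithm.

## Numerical and design notes

* OLS is delegated to `scipy.stats.linregress`; a constant response
  (zero y-variance) short-circuits to slope 0, R² 0 rather than a 0/0
  correlation.  The test suite checks equivalence against a hand-rolled
  normal-equations oracle to 1e-10.
* Registration uses nearest-neighbor pixel mapping with de-duplication and
  no intensity interpolation — MRM counts are per-pixel integrals and
  interpolation would fabricate signal.  Out-of-grid pixels are dropped
  with a logged count; an ROI empty after clipping is an error.
* Grid TSV reading uses round-trip float parsing, so write∘read preserves
  real intensities exactly.  Readers reject NaN, negative, duplicate, and
  out-of-bounds entries; a declared channel absent from the TSV reads as
  all-zero with a warning.
* The ladder length is configurable (default 8 levels); blank wells default
  to 3; QC wells contribute replicate ratios via three disjoint vertical
  strip sub-ROIs per well, while blank replicates are whole wells.
* Degenerate inputs (zero reference sum, zero ROI cell density, fewer than
  3 levels, < 2 blanks or QC replicates, singular registration) raise typed
  exceptions from `qmsi.errors` naming the offending object.

## Problem sizes

Tests and the acceptance script rasterize at 200 µm (100 × 100-px block,
225 px/well, ~5 000-px sections) and use 100–200 seeded replicates for
Monte-Carlo checks (pixel-RSD recovery, slope/QC parameter recovery,
end-to-end regional recovery); these sizes make each seeded run cheap while
keeping per-well pixel counts above the ~100–150 pixels per calibration
point that the workflow assumes.

## Known limitations

* The cell-density correction assumes the lipid reference is strictly
  proportional to intact-cell count; real lipid distributions are only
  approximately so, and the correction convention itself is a package
  choice.
* The LOD uses pooled blank-well SD at n = 3; per-replicate alternatives
  are not implemented.
* imzML support is import-only (continuous or processed, summed m/z
  windows); vendor raw files, HDI exports, and imzML writing are out of
  scope, as are H&E segmentation and cell detection (cell densities are an
  input).
* Absolute intensity scales are arbitrary; only ratio-scale quantities are
  meaningful.
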