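# Methods

This note documents the measurement models, the synthetic-data
generator that stands in for undeposited microscopy, the numerical
choices, and the limits of what the validation shows.

## Coverage measurement

The coverage protocol is deliberately simple so it can be reproduced
bit-exactly. The threshold is derived only from control tissue: each WT
vessel contributes the median αSMA intensity over its mask, and the
threshold is half the median of those per-vessel medians (the median of
an even count is the midpoint of the two central values). One global
threshold is derived from all WT vessels and applied unchanged to every
group; this matches the "set threshold" protocol and avoids per-cohort
drift. The threshold comparison is inclusive (`≥`): common
histogram-threshold tools include the lower bound, and the choice is
fixed here so area fractions are exactly reproducible.

The minimum-signal ROI uses a constant square window (default
500 × 500 μm). Every pixel is a candidate center (stride 1); the window
is clipped at the raster border and scored only on mask∩window pixels;
the criterion is the lowest **mean** masked intensity, since the mean is
the quantity the regional analysis reports. Scoring uses exact `int64`
summed-area tables, so equal windows produce bit-equal means and the
documented tie-break — smallest (row, col) center — is well defined.
An exhaustive per-pixel search is the oracle in the test suite.

## Centerline profiling and Sy.x

The centerline is an input polyline (emulating a manually traced
segmented line). Length is the sum of Euclidean segment lengths times
the pixel size, reported in mm. Intensity profiles are sampled at
uniform arc-length steps (default: one pixel) by bilinear
interpolation, which is exact on affine intensity fields.

Sy.x is the residual SD about the fitted mean-only model. Because that
model has a single parameter, Sy.x reduces to the sample standard
deviation with n − 1 degrees of freedom — an identity the tests assert
directly. The sampling step is recorded alongside each Sy.x value:
profiles are spatially autocorrelated, so variance estimates depend
(weakly) on sampling density, and comparisons should hold the step
fixed.

## 3D turnover pipeline

Stacks are (z, y, x) arrays with anisotropic voxel sizes; all distances
in the pipeline are physical (μm). Stages:

1. **Sheath**: αSMA threshold, then one-voxel binary closing to bridge
   speckle gaps.
2. **Masking**: the nuclear channel is zeroed outside the sheath, which
   removes luminal/peri-lymphatic distractor nuclei before segmentation.
3. **Nuclei**: threshold → Euclidean distance transform (anisotropic
   sampling) → seeded watershed. Seeds are local maxima of the distance
   map, lightly smoothed (0.6 μm Gaussian) so each convex body yields a
   single ridge maximum, then greedily suppressed to a minimum pairwise
   separation of one seed diameter (3.50 μm), highest distance first.
   The commercial tool whose workflow this reproduces does not document
   its seeding algorithm, so correctness is asserted against generator
   ground truth, not against that tool.
4. **Filters**: objects below `min_volume_um3` (default 20 μm³, about a
   3.4 μm sphere) or below a median-intensity "quality" cutoff are
   removed. "Quality" is operationalized as median in-object intensity
   (default cutoff 1.5× the channel background median) — the filter the
   protocol itself describes as "filtered by median".
5. **BrdU**: a nucleus is BrdU⁺ when its median BrdU intensity clears
   the channel threshold and the above-threshold voxel cluster inside
   the nucleus clears a volume floor (default: a quarter of the nucleus
   volume floor).
6. **Rate**: `100 · (N_BrdU⁺/N_total) / weeks`; an empty stack yields a
   missing value with a warning rather than a zero.

Automatic thresholds are background-referenced: channel median plus
10 × robust SD (1.4826 × MAD). This choice is deliberately conservative
so that a pure-noise (isotype-control-like) BrdU channel produces
essentially no false positives (tested: ≤ 0.25 %/week), at the price of
requiring clearly separated signal — which the generator provides and
real data may not. Long stacks can be processed in halves and merged;
`merge_nucleus_lists` deduplicates objects whose centroids fall within
one seed diameter across the cut.

## Statistics

- One-way ANOVA computes F from explicit sums of squares with
  `scipy.stats.f`; degenerate inputs are resolved explicitly (all
  values identical → F = 0, p = 1; zero within-group variance with
  separated means → p < 1e-10). Tukey–Kramer pairwise p-values use the
  studentized-range distribution with the unequal-n standard error.
- Two-way ANOVA uses OLS with Type-II sums of squares (the designs of
  interest are unbalanced, e.g. 16 vs 10 vs 10 limbs, and Type II is
  the standard choice absent a significant interaction), with Tukey
  comparisons over cell means.
- Kruskal–Wallis uses the tie-corrected H. For total n ≤ 10 the global
  p is the exact permutation tail (all group assignments enumerated);
  the χ² approximation is substantially off at such sizes. Dunn's
  pairwise tests are z-tests on mean ranks with the tie-corrected
  variance; the family correction is Bonferroni over all k(k−1)/2
  comparisons — the common software default for Dunn — and is recorded
  in the output.
- Shapiro–Wilk and OLS regression delegate to scipy (Royston
  approximation; slope t-test p).
- Per-limb aggregation averages the two vessels of a limb; single-vessel
  limbs (a normal anatomical variant) pass through; other counts are
  input errors.
- The significance harness redraws cohorts from printed (mean, SD, n)
  summaries and reports, per pairwise comparison, the median adjusted p
  and the rejection fraction at α over seeded replicates (default 200).

## Synthetic-data generator

The generator defines the study conditions for all validation.

**2D vessels.** Default geometry: 5 mm centerline, 100 μm width,
1 μm/px. The vessel width and scanner pixel size are not published;
100 μm matches the scale bars of typical whole-mount figures and
1 μm/px is an explicit assumption, both configurable. Foreground /
background intensities default to 40 000 / 2 000 AU with additive
Gaussian noise (SD 1500), placing the WT half-median threshold
(≈20 000 AU) > 10 noise SDs from both classes so that measured coverage
equals the generator's exact pixel bookkeeping and recovery tests probe
the measurement code rather than the noise model. Two patterns:
`banded_heterogeneous` (WT-like; exponential-length bands and gaps with
exact pixel-count adjustment, giving high along-length variance) and
`uniform_dim` (disease-like; spatially uniform Bernoulli foreground at
`dim_fraction` × fg intensity, default 0.45, giving low Sy.x). With the
default `dim_fraction` the dim signal falls below the WT-derived
threshold — modelling signal loss; analyses that instead need the dim
foreground to remain detectable (e.g. reproducing a ~61 % measured
coverage in a disease group) set `dim_fraction = 0.6`, as
`analysis/02_coverage_patterning.py` does. Ground truth records the
exact foreground fraction of the emitted mask, the centerline, and the
arc length.

**3D stacks.** The αSMA sheath is a planar slab (12 μm thick) rather
than a curved tube — sufficient for testing masking, exclusion, and
separation logic, but not vessel curvature. Nuclei are axis-aligned
ellipsoids with per-axis diameters uniform on 3.5–7 μm (so the short
axis always exceeds the 1.417 μm z-step and every nucleus spans ≥ 2
z-planes); centers are dart-thrown with a minimum physical separation of
max(1.5 × 3.50 μm, sum of the two largest semi-axes + 0.8 μm), so
rendered nuclei never touch and the ground-truth label count equals the
connected-component count. Requests too dense to honor the separation
for more than 5 % of nuclei raise an error. Exactly
`round(frac_brdu · n_inside)` in-sheath nuclei carry BrdU signal;
distractor nuclei sit above/below the slab with clearance and carry no
αSMA overlap. Channel intensities (30 000/25 000 AU signal over
300–1000 AU backgrounds) are well separated, by design: the pipeline's
recovery numbers certify the geometry/bookkeeping chain, not robustness
to realistic SNR. No optics are modelled (no PSF, no bleed-through).

**Cohorts.** Normal draws from (mean, SD, n) with optional
resample-below-zero truncation, used because several printed SDs exceed
their means for nonnegative quantities (e.g. 0.81 ± 1.0
contractions/min). Truncation shifts the realized mean upward relative
to the printed mean; this is intentional (the alternative — clipping —
distorts the shape more) and is visible in the turnover analysis
driver.

All generation is bit-reproducible from an integer seed via
`numpy.random.SeedSequence`.

## Problem sizes and numerical choices

The acceptance computation uses 200 replicates per cohort comparison,
12 stacks of 200 nuclei for turnover recovery, and a 30-vessel 5 mm
cohort for coverage recovery; the test suite uses shorter vessels
(0.3–1 mm) and smaller stacks (40–200 nuclei) for the same code paths.
A 30-vessel cohort drawn from the WT distribution (85.0 ± 10.8 %,
clipped to [0, 100]) has a clipped-population mean near 84.6 % and a
standard error near 1.9 points, so its realized mean varies by a few
points across seeds; the recovery tolerance (±3 points) reflects that
sampling width, not measurement error — the per-vessel measurement is
exact under the default intensity model.

Coordinates are 0-based (row, col[, z]); physical positions are in μm
and lengths in mm. p-values are reported to machine precision; the
significance thresholds used for flags elsewhere are 0.05 / 0.01 /
0.001 / 0.0001.

## Known limitations

- The generator certifies bookkeeping and geometry, not realism:
  passing recovery tests does not demonstrate performance on real
  microscopy with uneven illumination, bleed-through, or touching
  nuclei beyond the modelled separation.
- The sheath model is planar; curved vessels could place distractors
  inside the convex hull of the sheath in ways the slab cannot.
- Background-referenced thresholds assume the background dominates each
  channel's histogram; stacks dominated by signal need explicit
  thresholds.
- The Dunn family correction and the Type-II convention are documented
  choices; other software defaults (e.g. Holm, Type III) will give
  different adjusted p-values on the same data.
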