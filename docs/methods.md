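# Methods

This note documents the models, parameters and numerical choices behind
`metresponse`. Nothing here is an empirical claim about real patients;
all quantitative statements refer to the synthetic generator and to
properties verified by the test suite.

## 1. Study setting being modelled

A small cohort (default n = 20) of patients with multi-site abdominal
metastatic ovarian cancer is imaged by CT at three timepoints: baseline
`t0`, week 4 `t1` (end of monotherapy arm, "arm 1"), and week 12 `t2`
(after 8 weeks of combination therapy, "arm 2"). Lesions are segmented
and each is assigned to one of 15 anatomical sites:

| region | codes |
|---|---|
| peritoneal | 2, 3, 5, 6, 7, 9, 20, 21 |
| lymph node | 13, 14, 15, 16, 17 |
| other | 11 (liver), 19 (lung) |

The taxonomy is fixed and shipped as `data/site_taxonomy.json`; unknown
codes are rejected at validation time.

## 2. Data model

Two tidy tables are the interchange format:

- **Lesion table**: one row per (patient, timepoint, site, lesion) with
  volume in mm³ and a physical centroid (x, y, z in mm). Validation
  enforces taxonomy membership, positive volumes, the `t0/t1/t2`
  timepoint enumeration, and uniqueness of
  (patient, timepoint, site, lesion_index).
- **Clinical table**: one row per (patient, assessment week) with the
  RECIST category, plus per-patient constant PFS and enrollment
  durations in weeks. Weeks must be strictly increasing per patient and
  include week 4.

Per-site observations used by the spatial layer are volume-weighted
centres of mass of the site's lesions, in physical millimetres.

## 3. Synthetic cohort generator

Licensed imaging cannot be redistributed, so the generator produces
cohorts whose *distributional* structure matches the study setting. Its
defaults **are** the study conditions; they were fixed before any test
outcomes were inspected and are not tuned.

Per patient:

- **Latent class**: responder with probability `responder_fraction`
  (default 0.65).
- **Number of occupied sites**: drawn from a categorical distribution
  over 1..10 (`DEFAULT_SITES_PER_PATIENT_PROBS`), median 4; sites are
  sampled without replacement from the 15 codes.
- **Lesions per site**: 1 + Poisson(2.5), capped at 10.
- **Baseline lesion volume**: lognormal(mean log 800, σ 0.8) mm³,
  clipped to [50, 8000].
- **Volume dynamics**: each site's volume is multiplied per arm by a
  class-conditional lognormal factor —
  arm 1: responder 0.6 ± 0.1, non-responder 1.0 ± 0.1;
  arm 2: responder 0.55 ± 0.15, non-responder 1.0 ± 0.15
  (mean ± σ of the factor). Whole sites disappear with class-dependent
  probability per arm (responder 0.08/0.25, non-responder 0.0/0.03).
- **Clinical outcomes**: PFS and enrollment durations are
  class-conditional lognormals (responder: log 70 / log 75 weeks;
  non-responder: log 22 / log 30); week-4 and week-12 RECIST categories
  are drawn from class-conditional categorical distributions.
- **Placement**: lesions are placed by rejection sampling around fixed
  anatomical site centres (`SITE_CENTERS_MM`), keeping a clearance of
  the two lesions' bounding radii plus three voxel diagonals, so that
  rendered lesions never touch.

`CohortConfig.lr_probability()` gives the analytic long-responder rate
implied by the PFS mixture; the generator is tested against it.

### Voxel renderer

Each lesion is rasterised as the N voxels closest to its centroid under
a random anisotropic quadratic metric (axis log-ratios uniform in
[log 0.7, log 1.4], random rotation), with
N = round(volume / voxel_volume). This guarantees the rendered volume
matches the requested volume to within half a voxel (default spacing
2×2×2 mm → 4 mm³). CT intensity inside lesions is Gaussian
(60 ± 20 HU) on a −1000 HU background. Overlap or same-site 26-adjacency
between distinct lesions raises `RenderError`. Randomness is
deterministic per (patient, timepoint) via
`default_rng([seed, crc32("pid|tp")])`, so rendering order is
irrelevant.

**What the generator does *not* emulate**: organ shapes or boundaries,
realistic CT texture/noise spectra, respiratory or positioning
variability, partial-volume effects, segmentation error, or
inter-reader variability.

## 4. Imaging layer

- **I/O**: NIfTI via nibabel. Internally, image index (i, j, k) maps to
  physical mm through the affine; SimpleITK images are constructed with
  direction = normalised affine columns and origin = affine translation.
- **Resampling**: intensities with Welch-windowed sinc
  (`sitkWelchWindowedSinc`), labels with nearest neighbour; default
  target spacing (0.801, 0.801, 3.764) mm. The windowed-sinc kernel is
  not exactly partition-of-unity off-grid: a constant image is
  reproduced only to ≈0.2% relative error, which is why the relevant
  test asserts rtol 5e-3 rather than exactness. Resampling near lesion
  boundaries mixes in background (−1000 HU) ringing; feature tests that
  need an exactly constant ROI therefore resample on the native grid.
- **Connected components**: `scipy.ndimage.label` with 26-connectivity
  by default (6/18 available). Components are ordered by descending
  voxel count, ties broken by lexicographically smallest voxel index —
  a canonical order so lesion indices are reproducible. The
  implementation is verified against a brute-force flood fill on 1000
  random masks.

## 5. Stratification

- **RECIST 1.1**: target lesions are selected as the largest up to 5
  overall and 2 per organ, nodal targets require short axis > 15 mm,
  and every involved organ is represented. Categories: CR (all targets
  gone, nodes < 10 mm), PR (sum of diameters ≤ −30% from baseline), PD
  (≥ +20% from nadir **and** ≥ +5 mm absolute), else SD. The +5 mm term
  makes PD deliberately not scale-invariant (it is an absolute length).
- **Assessments**: `er_4wk` (CR/PR at week 4), `bor_responder` (CR/PR at
  any assessment), `lr` (PFS > 39 weeks, strict), `lte` (enrollment
  > 52 weeks, strict), `vol_responder` (total-volume change t0→t1
  ≤ −30%, inclusive; undefined when baseline volume is 0 — such
  patients are excluded from confusion matrices with a warning).
- **Confusion matrices** report integer counts and nearest-integer row
  percentages.

## 6. Spatial dissemination

A patient's anatomical network is the fully connected graph over their
occupied sites. The default convention counts **ordered** pairs, so k
sites give k(k−1) edges (4 → 12, 10 → 90, 1 → 0); the unordered
convention (k(k−1)/2) is available via `convention="unordered"`.
Cohort networks sum patient networks: node and edge weights are patient
counts, and edge weights coincide with the co-occurrence matrix
off-diagonal (tested as an identity). Dissemination metrics per patient
and timepoint: number of sites, number of lesions, lesion/site ratio,
and total and maximum pairwise Euclidean distance between site centres
of mass (mm).

## 7. Burden

Per patient: total volume per timepoint (0 when absent), peritoneal
volume fraction (NaN at zero volume), interval percentage changes and
per-week rates using `ARM_WEEKS = {t0→t1: 4, t1→t2: 8, t0→t2: 12}`.
Two denominators are supported for the arm-2 change: the interval start
(`denominator="interval"`, default, bounded below by −100%) and the
baseline (`denominator="baseline"`, which can go below −100% when arm-1
growth is followed by near-disappearance). Waterfall tables sort
patients by descending change and drop undefined rows with a warning;
scatterpie tables decompose each patient's per-arm volume change into
per-site signed deltas with shares |Δsite| / Σ|Δ|.

## 8. First-order radiomics

ROI intensities are discretised with fixed bin width 25 HU, bins
anchored at `floor(min/width)·width` (so features are invariant to
shifting by whole bin widths). Features per (patient, timepoint, site):

- energy = Σ (xᵢ + c)², with shift c = 0 by default;
- entropy = −Σ p log₂ p (bits);
- uniformity = Σ p².

Closed forms used as oracles: constant ROI → entropy 0, uniformity 1;
n equiprobable bins → entropy log₂ n, uniformity 1/n. Per-patient
aggregation across sites: median, range, sum, and site count.

## 9. Statistics

- **Paired longitudinal**: Wilcoxon signed-rank
  (`zero_method="wilcox"`, exact when ≤ 25 nonzero differences without
  ties, else normal approximation); the reported statistic is
  min(T⁺, T⁻), verified against a brute-force oracle. Patients missing
  either timepoint are excluded and listed.
- **Group comparisons**: Kruskal–Wallis (also for two groups),
  tie-corrected H verified against a brute-force oracle.
- **Correlation**: Pearson r (≥ 3 pairs required).
- Degenerate inputs (all differences zero, all values identical, zero
  variance) yield flagged results with p = 1 or NaN rather than raised
  errors, so the assembled suite never aborts on a constant metric.
- **Suite**: for each metric, Kruskal–Wallis per assessment ×
  timepoint plus Wilcoxon per timepoint pair. Significance is read at
  raw p ≤ 0.05 (matching small-cohort exploratory practice — no
  multiplicity correction for the primary read-out), but a
  Benjamini–Hochberg column (`p_bh`, via
  `scipy.stats.false_discovery_control`) is always reported alongside.
  Calibration is tested empirically: over 200 null cohorts (n = 20,
  labels independent of metrics) the pooled Kruskal–Wallis rejection
  rate at 0.05 must lie within the 99% binomial band around 0.05.

## 10. Problem sizes and runtimes

The test suite runs in under ten minutes single-threaded: the largest
components are the n = 2000 generator-distribution checks, the
rendering round trips (3-patient cohorts on 2 mm grids), the 1000-trial
oracle-equivalence battery, and the 200-cohort null calibration
(~2 minutes). `scripts/acceptance.py` runs in seconds.

## 11. Limitations

- Synthetic cohorts reproduce marginal and class-conditional
  distributions, not joint anatomical realism; spatial metrics computed
  on them inherit the fixed site-centre geometry.
- Volume dynamics are per-site multiplicative and independent across
  sites given the class; real lesions are correlated within patients in
  ways the generator does not model.
- The renderer's ellipsoidal lesions and Gaussian texture make
  first-order features well-defined but are not a substitute for real
  CT texture; higher-order (GLCM/GLRLM) features are out of scope.
- Windowed-sinc resampling is quantitatively accurate but not exact on
  constants (≈0.2% relative), and boundary ringing against the −1000 HU
  background affects ROI intensities on resampled grids.
- With n ≈ 20, the nonparametric tests have limited power; results are
  exploratory and reported with and without BH adjustment.
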