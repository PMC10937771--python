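# Methods note

## Model and procedure

### Leave-one-out quality control

Given a normative database (NDB) of *n* spatially normalized, modulated GM
density maps on a common grid, each scan *i* is scored against the other
*n − 1* scans:

- z-map: *z_i(v) = (x_i(v) − μ_{−i}(v)) / s_{−i}(v)*, with *μ_{−i}* and
  *s_{−i}* the leave-one-out mean and sample SD (ddof = 1, i.e. variance
  denominator *n − 2*). Computed on maps smoothed exactly as for analysis.
- metrics over the GM mask: `z_sum` = Σ|z|, `z_max` = max|z|,
  `n_significant` = #{|z| > 2.5} (strict inequality).
- flagging: for each metric, Tukey's upper fence *Q3 + k·IQR* with
  *k = 1.0*; scans with metric **≥** fence are flagged (inclusive, so ties
  with the fence are caught; when IQR = 0 the comparison is strict, so a
  perfectly homogeneous database flags nothing). A scan flagged on at least
  `min_metrics_flagged` metrics (default 1 — the union rule) is an outlier.
- cleaning: one pass; all outliers are removed together. An error is raised
  if fewer than 3 scans would remain. No iterative re-cleaning is performed:
  a single pass is the method, and re-running the fence on an already
  cleaned database would progressively trim the tail of a healthy sample.

Assumptions: maps are registered to a common space and comparable in scale;
the database is a single population (the fence is not a mixture model);
*n* ≥ 4 so that quartiles are meaningful.

### Single-subject VBM

The subject map is prepended to the NDB stack; the design matrix has columns
[group indicator (1 for the subject), intercept, mean-centered age,
mean-centered TIV]. The GLM is fitted voxelwise with pooled residual
variance, df = (n + 1) − rank(X). The group coefficient's t is thresholded
one-sided (atrophy = subject lower) at p = 0.005; suprathreshold voxels are
labelled with 18-connectivity, clusters ordered by size, and the atrophy
volume is suprathreshold-voxel count × voxel volume. The pooled-variance
single-case t is the Crawford–Howell test when no covariates are used.

### Group comparison

Welch's t with voxelwise Satterthwaite df, one-sided thresholds in each
direction at p = 0.005, and an inclusive minimum cluster extent of 296
voxels (= 1 ml at 1.5 mm isotropic). Voxels where both groups have zero
variance get t = 0 and the conservative df *n_a + n_b − 2*.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `smooth_fwhm_mm` | 8 | mm | standard VBM kernel; matches analysis smoothing |
| `z_cut` | 2.5 | z | deviation threshold for `n_significant` |
| `k` (fence) | 1.0 | IQR | sensitive fence; 1.5 is the conventional mild-outlier value and is available |
| `min_metrics_flagged` | 1 | metrics | union rule — any metric suffices |
| `p` | 0.005 | — | one-sided voxel threshold for clinical reading |
| `covariates` | age, TIV | — | dominant nuisance sources for GM density |
| `connectivity` | 18 | — | face+edge neighbours, the common VBM default |
| `min_extent_voxels` (group) | 296 | voxels | 1 ml at 1.5 mm isotropic |
| `sd_eps` | 1e-6 | GM density | guards the LOO division; such voxels get z = 0 |

## Synthetic generator

`vbmqc.synthetic` emulates, at desk scale, the statistical structure of a
modulated GM cohort on a 24³ grid at 1.5 mm: an ellipsoid-shell "cortex"
template (peak density 0.8), per-subject smooth Gaussian random fields
(SD 0.05, 6 mm smoothness — between-subject anatomical variation), a linear
age effect (−0.002/yr), TIV coupling (N(1370, 150) ml, coupling 0.3), and
optional per-scanner bias fields. Outlier injections model the observed
failure modes: `global_scale` (segmentation/scaling failure), `focal_lesion`,
`lobar_shift` (registration failure), `acquisition_bias` (smooth
multiplicative field). Atrophy injections multiply a spherical region
(default radius U(6, 10) mm, amplitude U(0.15, 0.35)) into a subject map and
return the ground-truth mask.

It does **not** emulate: real cortical geometry or topology, non-Gaussian
intensity distributions, registration interpolation artifacts, spatial
nonstationarity of variance, or realistic brain size (the grid is ~3.6 cm —
a deliberate choice so the full 20-seed experiment runs in seconds).

Random streams use `numpy` `default_rng([seed, substream])` spawning, so any
subject is reproducible independently of cohort size.

## Numerical choices

- Quartiles: `numpy.quantile` default (type-7 linear interpolation).
- Smoothing: σ = FWHM/(2√(2 ln 2)) per axis in voxel units, `mode='nearest'`
  boundary, kernel truncated at 4σ. FWHM = 0 is the identity.
- LOO variance is computed by the closed-form sums-of-squares update and
  clipped at 0 to absorb cancellation error; SD below `sd_eps` ⇒ z = 0 and
  the voxel is counted as degenerate in the report.
- Cluster ordering is deterministic: descending size, ties broken by
  lexicographic peak-voxel index; the peak is the voxel of maximal |t|.
- Wilson score intervals (statsmodels `proportion_confint`) for all
  sensitivity/specificity values; for 37/37 the 95% lower bound is 0.906,
  reported as 0.91.

## Evaluation harness and a known limitation

`vbmqc.evaluate` runs the cleaned-vs-uncleaned contrast: an NDB of 20 scans
with three injected ×0.7 global outliers, 10 patients with injected atrophy
and 10 controls, all maps smoothed once up front. Maps are read by a fixed
rule (positive iff total suprathreshold volume ≥ 0.5 ml **and** largest
cluster ≥ 10 voxels). Over 20 seeds (as computed by
`scripts/acceptance.py`): mean sensitivity rises from 0.005 (uncleaned) to
0.515 (cleaned) and never decreases in any seed; patient atrophy volumes
grow by ~0.71 ml on average versus ~0.07 ml for controls.

Specificity, however, is 1.0 in **both** arms in only 75% of seeds, not the
≥ 90% one might expect. This is a property of the desk-scale setting, not a
calibration defect: the GLM's voxelwise type-I rate on an independent
Gaussian null is 0.0050 at nominal 0.005, but after 6 mm field smoothness
plus 8 mm analysis smoothing the 24³ brain contains only a few dozen
resolution elements, so roughly 3% of control subjects carry a single ~3 SD
smooth regional dip that forms one large cluster (e.g. 169 voxels, 0.57 ml,
peak t = −5.4) exceeding the reading rule. These events surface mainly in
the cleaned arm because the injected outliers inflate the uncleaned
normative SD and mask them — i.e. cleaning also raises sensitivity to
normal physiological variants, which in a clinical reading setting would be
adjudicated visually rather than counted as machine false positives. The
corresponding assertion in `tests/test_acceptance.py` is left in place and
fails, documenting the finding rather than hiding it.
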