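# Methods

This note documents the models implemented in `petquant`, the parameters
that matter, the synthetic-data design, and the numerical and statistical
choices made where the underlying analysis left the design open.

## Volumes and grids

All images are scalar fields on regular 3-D grids with a 4×4 index→world
affine (RAS+ millimetres, 0-based indices). Inter-volume operations demand
an exact grid match (shapes equal, affines within 1e-4 mm); nothing is
resampled implicitly. When grids differ, `resample_to_grid` must be called
explicitly — masks with nearest-neighbour (to stay binary), scalar images
trilinearly. The pipeline's default policy for mixed-resolution inputs is
to bring masks onto the PET grid rather than interpolate the PET data,
since interpolating counts changes the noise structure while
nearest-neighbour mask transport only moves boundaries by sub-voxel
amounts. Scalar volumes are written to NIfTI-1 as float32 and masks as
uint8; NIfTI-1 stores affines at float32 precision, which bounds round-trip
fidelity. NaN voxels are rejected on input and no operation produces them;
degenerate situations (empty VOI, zero reference mean, all-zero probability
map) raise instead of propagating NaN.

## VOI construction and spill-in-free erosion

Tissue VOIs are thresholded at a fraction of the *maximum* of the tissue
probability map (default 0.35), which makes the mask invariant to any
positive rescaling of the segmentation output.

The scanner resolution is modelled as an isotropic Gaussian PSF,
σ = FWHM/(2√(2 ln 2)), FWHM 8 mm by default. Blurring a binary mask with
the PSF yields, at each voxel, the fraction of the measured signal
originating from that tissue. A voxel of the white-matter VOI is kept in
the spill-in-free VOI iff the blurred gray-matter mask there is at most τ,
and symmetrically for gray matter; CSF is never treated as a contaminant
(its uptake is low, and the original analysis assumed zero CSF spill-in).
The numerical cut-off τ used in the source analysis is not recoverable, so
it is a configuration parameter; the default τ = 0.05 corresponds to
stripping ≈ 1.645 σ ≈ 5.6 mm from a flat boundary at FWHM 8 mm. Useful
monotonicities hold by construction: the eroded VOI grows with τ and
shrinks with FWHM.

Blur boundary handling is reflective (mirror), which conserves total mass
near grid edges and keeps blurred binary masks inside [0, 1]; anisotropic
voxels are handled with per-axis sigmas in voxel units. These choices make
results bit-for-bit reproducible.

## Quantification

SUV is the body-weight standardized uptake value with tissue density
1 g/mL: `SUV = C[kBq/mL] · weight[kg] / dose[MBq]` (the 1000 kBq/MBq and
1000 g/kg factors cancel). SUVt divides the SUV image by the mean SUV over
the bilateral-thalami label; by construction the thalamic SUVt mean is 1
to machine precision for every subject (SUVt volumes are held in float64
for this reason) and SUVt is invariant to any global multiplicative
calibration of the scanner. The per-subject report lists GM SUVt, WM SUVt
and their ratio; because the thalamic normalizer cancels, the WM/GM ratio
of SUVt means equals the ratio of SUV means.

## Group statistics

All tests target a 6-vs-6 design where asymptotics are unreliable:

* **Mann–Whitney U** is computed exactly: U by pair counting with half
  credit for ties, and the two-sided p by enumerating all C(n+m, n)
  assignments of the observed pooled values (valid under ties). Exact mode
  is limited to combined n ≤ 16 (≤ 12 870 assignments); beyond that the
  tie-corrected normal approximation (no continuity correction) is used.
* **ANCOVA** is OLS on `[intercept, group, age]` with the two-sided t of
  the group coefficient on n−3 df. Group is coded MS = 1 so positive t
  means MS > HV. Rank-deficient designs are rejected with the offending
  column named; a perfect fit is reported as p < 1e-12 rather than a
  division error. With a covariate orthogonal to both group and outcome
  the group coefficient and its standard-error structure coincide with the
  pooled two-sample t, apart from the n−3 vs n−2 residual df.
* **The voxel-wise GLM** applies the identical OLS per voxel (shared code
  path with the scalar ANCOVA, so single-voxel equality is exact) on
  subject SUVt images smoothed with a 12-mm FWHM kernel, within an
  analysis mask (intersection over subjects of the GM∪WM VOIs). Voxels
  with zero residual variance get t = 0 and are counted. Both contrast
  directions are produced; they are exact negations.
* **Cluster-level FWE** uses the permutation distribution of the maximum
  supra-threshold cluster size under group-label exchange. The
  cluster-forming threshold is the one-sided t quantile for voxel-level
  p < 0.001 (configurable), connectivity is 18-neighbour (configurable
  6/18/26). When at most `n_perm` distinct relabelings exist they are
  enumerated exhaustively and p is the plain proportion (the identity
  relabeling included, so p ≥ 1/N); otherwise `n_perm` Monte-Carlo draws
  are used with the (b+1)/(B+1) estimator. This replaces parametric
  random-field cluster correction deliberately: permutation inference is
  distribution-free and exact at these sample sizes, at the cost of
  discreteness (with 924 relabelings the smallest attainable p is 1/924).
* **Bonferroni** thresholds are explicit — `alpha/m` with m always passed
  by the caller (a 9-region comparison at 0.05 gives 0.00556).
* **Lesion correlations** are Pearson r with R² = r² and the two-sided p
  from t = r√((n−2)/(1−r²)). Hemispheric VOI means are treated as
  independent observations (2 per patient, 12 in total), mirroring the
  design this analysis replicates; statistically this ignores
  within-patient correlation and should be read as descriptive rather
  than strictly inferential.

The permutation test permutes group labels while age stays attached to its
subject. Under the null of no uptake–group and no uptake–age dependence
(which holds in the null phantom) the data are fully exchangeable and the
test is exact; with a real age effect on uptake it is approximate.

## The phantom

Geometry is deliberately schematic — nested ellipsoids, not anatomy —
because every quantitative property being validated concerns
quantification and statistics, not morphology: a CSF shell (semi-axes
54×64×50 mm), a cortical GM shell (48×58×44 mm), a WM core (30×40×28 mm),
two lateral-ventricle ellipsoids (CSF), and two thalamic ellipsoids of
roughly anatomical volume (≈ 6 cm³ each, counted as deep GM). Tissue
probability maps are the binary labels smoothed with a σ = 2 mm kernel and
jointly renormalised to sum ≤ 1, so the 35% threshold and erosion operate
on realistic soft boundaries. The default grid is 2 mm isotropic
(64×76×64); a reduced 32³ / 4-mm preset exists for simulation-heavy
calibration studies, and those are the problem sizes used throughout the
test suite.

Uptake is piecewise constant on the SUVt scale (thalamus ≡ 1): GM 1.04
(MS) vs 0.95 (HV); diffuse WM 0.87 (MS) vs 0.79 (HV); CSF 0.35. MS
subjects carry white-matter lesions — spheres of radius 6 mm with uptake
increment +0.6, per-hemisphere T2 counts Poisson(8) and T1 black holes
Binomial(T2, 0.5) — so the expected lesion load lifts the effective MS WM
level to ≈ 0.93 and per-hemisphere mean uptake rises with lesion count by
construction. Per-subject variability is a Gaussian jitter (sd 0.015) on
the GM and WM levels plus a lognormal global calibration factor
(sd 0.02 log-units) that SUVt must cancel; these magnitudes were set by a
power calculation so that lesion-driven and intrinsic variance are
comparable, which places the hemispheric uptake/lesion-count correlation
in the R² ≈ 0.4–0.6 regime reported for comparable clinical cohorts.
The simulated scan is the truth times the calibration factor, blurred with
the 8-mm PSF, plus additive Gaussian voxel noise with sd equal to 5% of
the HV WM level, exported in kBq/mL via the subject's (dose, weight) so
the SUV → SUVt chain is exercised end to end. Ages are Gaussian, MS mean
46 vs HV mean 58 (the deliberate confound); the absolute activity scale is
arbitrary since only relative (SUVt-level) quantities are checked.

Randomness discipline: one master seed; each (subject, stage) gets its own
`numpy.random.SeedSequence(seed, spawn_key=(subject, stage))` substream,
so cohorts are bitwise reproducible and changing one stage's draw count
cannot shift another's.

What the phantom does *not* emulate: attenuation, scatter and randoms,
reconstruction artefacts, anatomical cortical folding, partial-volume
structure finer than the PSF, registration error between PET and MRI, and
any real age dependence of uptake. Passing tests therefore demonstrate
correctness of the quantification and inference machinery under the stated
degradation model — not robustness to mis-registration or reconstruction
physics.

## Numerical choices

* float64 for all statistics and for SUVt/t-map volumes; float32 (scalars)
  and uint8 (masks) on disk.
* VOI means accumulate in float64 regardless of storage dtype.
* Mann–Whitney enumeration compares U values with a 1e-9 absolute guard to
  make tie handling robust to float noise.
* Zero-residual-variance voxels in the GLM: t = 0, counted and reported,
  never NaN.
* Empty spill-in-free masks warn (and are recorded) rather than abort: a
  thin structure may legitimately have no uncontaminated core at FWHM 8 mm.
* Cluster peaks are reported in world mm via the map's affine; cluster
  tables are sorted by size so corrected p values are non-increasing.

## Known limitations

* τ and the cluster-forming threshold are conventions, not estimated
  quantities; results should be reported together with both.
* The hemispheric correlation treats hemispheres as independent (see
  above).
* The exact Mann–Whitney is limited to combined n ≤ 16 by enumeration
  cost.
* Permutation p-values are discrete; with 12 subjects the smallest
  attainable cluster-FWE p is 1/924, and calibration experiments show the
  realised type-I error can sit mildly below the nominal 0.05 because of
  size ties in the null distribution.
* The pipeline assumes inputs are already co-registered and
  decay-corrected; no registration or motion handling is provided.
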