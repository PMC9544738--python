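# Methods

`connfinger` implements a resting-state connectivity-fingerprinting
analysis for volumetric fMRI: seed-based functional connectivity of the
dorsal anterior cingulate cortex (dACC), its overlap with regions recruited
for intuitive physical inference, and a within/between-subject
spatial-correlation MVPA that asks whether an individual's connectivity
pattern predicts that same individual's task activity better than other
people's. Because the scanner data the analysis was designed for are not
redistributable, every stage is validated against a synthetic cohort
generator with planted, subject-specific ground truth.

## Pipeline model

**Rest runs.** Each run is a 4D series on a shared grid (no resampling is
performed anywhere; mismatched grids are errors). The default chain is
Gaussian smoothing (4 mm FWHM) → zero-phase order-2 Butterworth band-pass
(0.009–0.08 Hz) → motion censoring → nuisance OLS regression → common-ACC
variance regression.

- *Censoring metric.* The sources the pipeline follows censor on
  "mm of movement" without defining the scalar. We use framewise
  displacement: the sum of absolute backward differences of the three
  translations plus the three rotations converted to arc length on a
  50 mm sphere (1° ≈ 0.8727 mm), the standard choice. Thresholds: 2 mm for
  rest, 3 mm for task. Censoring defaults to after filtering (a
  `censor_after_filtering=False` flag implements the other order; the run
  report records which was used).
- *Nuisance regressors.* The six motion parameters, their first backward
  differences (first row zero), and the white-matter and ventricle mean
  series. Motion regressors are band-passed with the data so the
  regression cannot reintroduce filtered frequencies.
- *Common ACC variance.* The mean of the 8 ACC parcel-mean series is
  regressed from every voxel, so each parcel's connectivity reflects its
  unique variance (a first-principal-component option sits behind
  `common_variance="pc1"`). The mean is the simplest shared component and
  matches the cited practice.

**Connectivity.** Per-voxel Pearson r with the dACC mean series, Fisher
z = atanh(r) (|r| clipped at 1−1e−7), and a one-sample group t-test of the
z maps against zero. Multiple comparisons are controlled by Monte-Carlo
cluster-extent correction: Gaussian null fields are simulated at the
estimated residual smoothness, thresholded at the primary voxel p (0.001,
two-sided — connectivity maps carry meaningful negative correlations; a
one-sided flag exists), and the critical extent is the smallest cluster
size whose null exceedance probability is ≤ α = 0.05. Clusters use
face adjacency (6-connectivity). Exact reproduction of AFNI's 3dClustSim
tables is out of scope; the calibration experiment below checks the
familywise error rate directly.

- *Smoothness estimator.* Per axis, the lag-1 autocorrelation
  ρ̂ = 1 − var(Δx)/(2 var x) of a residual map is inverted under a
  Gaussian autocorrelation model, FWHM = voxel · sqrt(−2 ln 2 / ln ρ̂).
  Smoothness below one voxel is not identifiable on a lattice (white noise
  gives ρ̂ ≈ 0), so estimates are floored at the voxel size; the floor is
  continuous at ρ̂ = 1/4 where the formula itself returns one voxel.

**Task runs.** The task is a 23-block run of 18 s blocks (414 s, 207
volumes at TR 2 s): 10 physical-judgement and 10 colour-judgement blocks
plus rest at block positions 1, 12 and 23; the 20 task blocks are a
pseudorandom palindrome (second half mirrors the first), balancing
pairwise block-type transitions. Each task block holds two
cue(1 s)–movie(6 s)–response(2 s) triplets.

The GLM models only the 1-s cue events per condition — the literal reading
of the design description; movie/response variance is left to the residual
(a `whole_block` flag adds 18-s block regressors for sensitivity
analyses). Regressors are boxcars sampled at TR as the covered fraction of
each volume (the second cue in a block starts 9 s into it, off the 2-s
grid) and discretely convolved with a gamma-variate HRF
h(t) = (t/(pq))^p exp(p − t/q), p = 8.6, q = 0.547, which peaks at exactly
1 at t = pq ≈ 4.70 s. No source names a functional form for the HRF; this
parameterisation is chosen to place the peak at 4.7 s. Fitting is
voxelwise OLS without prewhitening: the mild AR noise at TR 2 s inflates
standard errors but leaves the physics − colour contrast point estimates
(all the fingerprint uses) unbiased. Runs are fit separately and subject
contrasts averaged (a concatenation flag exists).

**Overlap curve.** The group z-map is thresholded at 20 increasingly
stringent percentiles of the values inside a fronto-parietal search mask,
and per level the proportion of surviving voxels inside the physics
parcels is recorded. The described sweep ("99th to 100th percentile in
steps of 0.05" but "20 datasets") is internally inconsistent — that
arithmetic gives 21 levels and an empty-or-singleton top level; we
implement 20 levels, 99.00–99.95 inclusive, which matches the stated count
and keeps every level nonempty. Percentiles are computed within the search
mask (a flag computes them whole-brain first).

**Fingerprint MVPA.** For subject i and region R (the four physics ROIs:
L/R frontal, L/R parietal), within_z(i,R) = atanh r(conn_i, contrast_i)
across R's voxels and between_z(i,R) is the mean over j ≠ i of
atanh r(conn_i, contrast_j): correlations are Fisher-z transformed before
any averaging, uniformly across analyses. A two-way repeated-measures
ANOVA (condition: within/between × region, subject as random block, each
effect against its own subject-interaction error term) tests the
condition main effect. The ANOVA is the classical SS decomposition,
implemented directly so degenerate inputs (all cells equal) report F = 0
with a note; it is cross-checked in the tests against
`statsmodels` AnovaRM and a brute-force decomposition. A motion check
correlates, across subjects, mean framewise displacement with the mean
within − between gap.

The split-half variant divides each subject's rest run in two, computes
L and R dACC connectivity per half, and compares
within (half 1 vs half 2, same subject) to between (half 1 vs other
subjects' half 1) in a condition × hemisphere RM-ANOVA.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not scanner
realism. Geometry: a 20×20×20 grid of 3×3×3.5 mm voxels holding eight ACC
parcels (4 per hemisphere, one dACC each), four physics parcels of ≥ 200
voxels inside a fronto-parietal search-mask slab, and WM/ventricle boxes.
Defaults (the study conditions for all recovery experiments): TR 2 s,
150-volume rest runs (5 min), two 207-volume task runs, coupling a = 0.5,
activation β = 1, AR(1) noise with innovation SD σ = 1 and φ = 0.3
(stationary initialisation; φ mimics fMRI temporal autocorrelation),
displacement SD 6 mm, motion-spike rate 0.02/volume.

Per subject, a Gaussian displacement (SD 6 mm per axis) is rounded to
voxels and clipped so the displaced 4×4×4 voxel core of each physics
parcel stays inside the parcel; the same displacement drives both the rest
coupling targets and the task activation — this shared offset is the
planted fingerprint. Rest runs: all eight ACC parcels share a common
component g(t) (the signal the common-variance regression removes) plus a
per-parcel unique latent; the dACC-unique latent s(t) is shared by the two
dACC parcels, and each displaced core voxel carries a·s(t) on top of its
AR(1) noise, so after perfect nuisance removal the population correlation
of s with a planted voxel is a/√(a² + σ_eff²), σ_eff = σ/√(1−φ²) (≈ 0.43
at defaults). WM and ventricle confounds are mixed at weight 0.2a into all
grey voxels, so skipping nuisance regression measurably biases r. Task
runs add β times the convolved physics-cue regressor at the displaced
cores and β times the colour-cue regressor at a fixed disjoint control
set. Motion tables are smooth drift plus occasional > 2 mm translation
spikes.

What the generator does **not** emulate: haemodynamic nonlinearity,
physiological noise, spatially varying smoothness, image-space motion
artifacts (motion exists only in the tables and censoring logic),
between-subject anatomical variability beyond the rigid core displacement,
and real atlas geometry. Passing recovery experiments therefore
demonstrate that the code computes what it claims under the assumed
generative structure — not that the effect sizes or significance levels
would transfer to scanner data.

## Recovery experiments and problem sizes

All experiments (`connfinger.experiments`) run at desk scale, chosen so
the full suite completes in minutes on one core:

- *Fingerprint recovery*: 20 cohorts of 8 subjects; the mean within_z
  exceeds mean between_z in ≥ 95% of cohorts at default effect sizes, and
  with displacement SD 0 (no individual differences) the condition effect
  rejects at ≈ the nominal 5% rate.
- *Split-half power*: 20 cohorts of 10 subjects; condition effect
  significant at 0.05 in ≥ 90%.
- *Overlap endpoint*: planted connectivity lies wholly inside the physics
  parcels, so the final sweep level reaches overlap 1.0 in both
  hemispheres.
- *Cluster calibration*: 16³ grid, 9 mm-FWHM null fields (a realistic
  post-smoothing residual smoothness, and coarse enough that the discrete
  cluster-size distribution admits a critical extent near the nominal
  level), critical size from 200 Monte-Carlo fields, tested on 400 fresh
  fields; the familywise rate falls within the binomial band around
  α = 0.05.
- *Closed form*: mean planted-voxel r over 100 voxels at T = 10⁴ matches
  a/√(a² + σ_eff²) to < 0.03.

## Numerical choices and degenerate inputs

- NaN voxels are rejected at read/construction time, never propagated.
- Constant voxels get r = 0 with a warning count; constant seeds are
  errors; zero-variance voxels in group t-tests get a signed sentinel.
- |r| is clipped to 1 − 1e−7 before atanh.
- Rank-deficient design matrices raise errors naming the collinear
  columns; nuisance regression is idempotent by construction.
- The critical cluster extent is the smallest integer whose null
  exceedance is ≤ α (conservative under discreteness).
- Percentile thresholds use linear-interpolation percentiles over in-mask
  voxels with ≥-thresholding, making sweep levels nested.

## Known limitations

- Smoothness estimation assumes stationary Gaussian autocorrelation and a
  single FWHM per axis; heavy-tailed spatial ACFs (the motivation for
  AFNI's mixed-model variant) are not modelled.
- The RM-ANOVA requires a complete subject × condition × region layout;
  missing cells are an error rather than being imputed.
- Only OLS GLMs are provided; standard errors of single-subject betas are
  not used downstream and are not prewhitened.
- No spatial normalisation is implemented: all inputs must share a grid.
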