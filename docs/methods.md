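# Methods

This note documents what `roiconn` computes, the conventions it commits to
where the underlying analysis style leaves choices open, what the synthetic
cohort generator does and does not emulate, and the package's known limits.

## ROI definition and extraction

An atlas is an ordered list of spherical seeds (label, network, MNI center
in mm, radius; default 5 mm) over exactly three networks: CON
(cingulo-opercular: dACC, pre-SMA/SMA, frontal operculum, anterior insula),
DMN (precuneus, PCC, medial prefrontal, medial temporal, angular gyrus) and
OST (OFC, dorsal caudate, dorsal putamen, thalamus). The shipped table
`data/atlas_ost_con_dmn_synthetic.tsv` (7 + 8 + 8 bilateral-style seeds) is
a synthetic reconstruction with literature-style coordinates; users supply
their own TSV for real studies. Each network must hold ≥ 2 ROIs so every
within-network mean is defined over at least one pair.

Sphere membership uses the simplest reproducible convention: a voxel
belongs to a sphere iff the Euclidean distance from its **center's world
coordinate** (via the NIfTI affine) to the seed center is ≤ the radius. No
partial-volume weighting, no reorientation beyond the affine. Overlapping
spheres are allowed; shared voxels contribute to every covering ROI's mean.
Extraction is the arithmetic mean over mask voxels per frame, so it is
linear in the input volume and exact for block-constant synthetic volumes.

Framewise displacement follows the Power backward-difference convention:
FD(1) = 0, FD(t) = Σ|Δtrans| + ρ·Σ|Δrot| with head radius ρ = 50 mm
(configurable; the convention itself is a package choice since realignment
chains differ). Mean FD averages the full series including the leading
zero, which makes it invariant to frame ordering. No frame censoring is
performed; high-motion subjects are excluded, if at all, as cohort-table
rows.

## Connectivity reduction

Pearson correlation (≥ 3 frames, all columns non-constant — a zero-variance
column is an error naming the ROI), then z = atanh(r) per off-diagonal
cell. |r| ≥ 1 raises by default; an explicit `clamp=True` maps such cells
to atanh(1 − 1e−7), because a silent clamp would mask duplicated-signal
bugs. The diagonal is excluded from every average (z(1) is infinite).

The six metrics are means of z over pair blocks. Averaging each ROI's
intra-network z values first and then across ROIs equals the
unordered-pair mean exactly (both equal the ordered-pair mean), so the
pair-set mean is the only implementation and the equivalence is asserted by
a test. Between-network blocks average all k_X·k_Y cross pairs and are
symmetric in the network order by construction.

## Group inference

Per metric: OLS fit of `metric ~ group + covariates` with dummy coding (HC
reference; the omnibus F is coding-invariant, asserted by test), default
covariates age (years) and mean FD (mm), no interactions. The group F is
the nested-model RSS comparison, df = (G−1, N−G−C); η²ₚ =
SS_group/(SS_group+SS_error), identical to F·df₁/(F·df₁+df₂). Rank-deficient
designs (e.g. a constant covariate) and error df < 1 are errors, not
warnings.

Adjusted group means are model predictions at the **whole-sample**
covariate means with model-based standard errors — the standard estimated
marginal means convention. Pairwise contrasts are Fisher's protected LSD:
unadjusted two-sided t tests on adjusted-mean differences using the
model's coefficient covariance and the omnibus error df. The protection
gate (omnibus p < α, α = 0.05) is reported on every contrast rather than
enforced, so downstream consumers see all three pairs and the gate state.

The BH-FDR family is exactly the six metric-level omnibus p-values;
post-hoc p-values are never family-adjusted. Severity correlations are
Pearson r with pairwise deletion and per-row n (CYBOCS scoped to the OCD
group, MASC/OCI-R to all groups with data). Two sensitivity re-analyses are
built in: adding a binary depressive-disorder covariate (df₂ drops by one)
and excluding subjects older than 18 (df recomputed from the reduced N).

## Synthetic cohorts

The generator emulates a three-group female pediatric resting-state study:
groups OCD/AC/HC of sizes 23/26/44, T = 200 frames at TR = 2 s, ages
uniform on 8–21 y, mean FD log-normal (median 0.15 mm, σ_log = 0.4)
realised exactly by a sign-alternating translation walk, CYBOCS only in the
OCD group (mean 23.03, SD 6.41), MASC with an 11/93 missingness rate, and a
sparse depressive-disorder flag. Defaults for the two metrics with real
group differences are within-CON z = 0.54/0.43/0.46 and OST–CON z =
0.40/0.30/0.33 (OCD/AC/HC); the other four metrics are group-equal
plausible values (within-DMN 0.45, within-OST 0.35, OST–DMN 0.25, CON–DMN
0.30), so under defaults only two true effects exist.

Per subject, the six block z values are the group targets plus a global
shift (SD 0.08 z) shared by all blocks plus independent per-block noise
(SD 0.05 z). The split matters: a shared shift moves within- and
between-network correlations together and essentially preserves positive
semidefiniteness of the block matrix, whereas independent per-block noise
of the combined magnitude would routinely produce infeasible matrices. The
total between-subject SD (≈ 0.094 z) plus Fisher sampling noise at T = 200
reproduces group-mean standard errors of the order reported in such
studies (≈ 0.02–0.03 at n ≈ 23–44).

The subject's correlation matrix sets within-network off-diagonals to
tanh(z_within) and cross-network cells to tanh(z_between). If the matrix is
not PSD it is repaired by eigenvalue clipping (floor 1e−6) and diagonal
renormalisation; the maximum elementwise shift is recorded per subject in
the cohort table and an error is raised if it exceeds `psd_tolerance`
(default 0.10 — large enough to pass benign jitter-tail repairs, small
enough to reject structurally infeasible target sets). Under defaults
repair touches ~1 % of subjects with shifts ≤ ~0.05. Time series are T iid
draws from a zero-mean multivariate normal via the symmetric matrix square
root; an optional AR(1) coefficient (default 0) adds temporal
autocorrelation with unit marginal variance, since real BOLD
autocorrelation inflates z variance. All randomness flows from one master
seed through `SeedSequence` spawning; identical seeds give bit-identical
cohorts and files.

What the generator does **not** emulate: hemodynamics, scanner drift and
spike artifacts, spatial noise correlation, distance-dependent motion
artifacts, non-normal metric distributions, and any correlation between
severity (or covariates) and connectivity — severity is null by
construction, matching the style of study the defaults describe. Passing
recovery and calibration tests therefore demonstrates correctness of the
estimator arithmetic and honest type-I control under idealised signals,
not robustness to real-data artifacts.

Volume export embeds each ROI's series in its sphere voxels (overlap cells
get the mean of contributing ROIs) with seeded Gaussian background noise,
so sphere-mean extraction inverts the embedding exactly for non-overlapping
atlases — the round trip is tested to float32 precision.

## Numerical choices and problem sizes

- Correlation matrices are symmetrised ((A+Aᵀ)/2) and clipped to [−1, 1]
  before the Fisher transform; symmetry tolerance 1e−10.
- Time-series TSVs are written at %.17g and read with round-trip float
  parsing, so the table round trip is bit-exact.
- Design matrices are checked for rank before fitting; statsmodels OLS
  provides the fit and coefficient covariance.
- Monte-Carlo suites use 100 seeded replicates for recovery/power and
  200–400 for null calibration at the full cohort size (93 subjects,
  T = 200, 23 ROIs); one replicate costs ~0.1 s, the full statistical
  suite a few tens of seconds. Over 400 sequential seeds the null
  rejection rate of the within-CON omnibus test is 0.043 with a uniform
  p-value distribution.

## Known limitations

- No preprocessing (realignment, normalisation, nuisance regression,
  filtering): inputs must be preprocessed volumes or tables.
- No partial correlation, covariance shrinkage, or edgewise inference; the
  analysis is exactly the six block means.
- The LSD gate is advisory; consumers wanting strictly protected tests
  must filter on `omnibus_significant`.
- EMM standard errors are model-based (homoscedastic OLS); no
  heteroscedasticity-robust option.
- The bundled atlas is a synthetic stand-in; scientific use requires real
  coordinates.
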