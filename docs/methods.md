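# Methods

`hubspoke` re-implements, as one tested pipeline, the analysis chain used to
dissociate input-modality coding from amodal semantic coding in anterior
temporal cortex: block-design GLM, cross-modal searchlight MVPA with group
inference against chance, seed-based resting-state connectivity with CompCor
nuisance regression, and meta-analytic spatial-map decoding. Because the
original human data are not available in reusable raw form, every stage is
validated against a synthetic phantom whose generative ground truth embodies
the hub-and-spoke hypothesis. This note records the models, the parameter
choices that matter, and what the phantom does and does not establish.

## The phantom

**Anatomy.** A `RegionAtlas` places six quasi-spherical regions of exact
voxel counts on an axis-aligned grid (default 28³ voxels at 2 mm isotropic,
matching the analysis resolution): a *semantic hub*, a *modality region*,
auditory and visual *spokes* inside an ellipsoidal brain mask, and WM/CSF
compartments outside it. Regions are grown deterministically as the n
nearest in-pool lattice points to a configured center (ties broken
lexicographically), so requested sizes are exact and regions are disjoint by
construction; impossible packings raise a configuration error.

**Task ground truth.** Each region responds to condition
c = (format ∈ {spoken, written}) × (feature ∈ {AUD, VIS, NON}) with

    response_c(v) = a_feat(R) · p_R^feat(c)(v) + a_fmt(R) · p_R^fmt(c)(v) + m_R(c)

where the p's are fixed zero-mean unit-norm voxel patterns drawn once per
subject, and m_R(c) is a small uniform (univariate) offset. The hub has
a_fmt = 0 and m depending only on feature type; the modality region has
a_feat = 0 and m depending only on format; the spokes carry both codes. This
is the hypothesis under test expressed generatively: only the hub carries
format-independent meaning information, only the modality region carries
meaning-independent format information.

**Effect-size defaults.** Baseline is 100 arbitrary units, so signal units
read as percent BOLD. Defaults are a_feat(hub) = 1.0, a_fmt(modality) = 1.0
(patterns are unit-norm, so per-voxel pattern amplitudes are ~0.1%), uniform
offsets ≤ 0.3%, white-noise sd 1.0 with AR(1) coefficient 0.35, and a 4-unit
peak-to-peak linear drift. These values put region decoding in the moderate
regime (mean sphere accuracy roughly 0.6–0.8 with nonzero between-subject
variance) rather than at ceiling — the regime in which the reported human
analyses of this kind operate — because a saturated phantom (every subject
at accuracy 1.0) has zero between-subject variance and degenerates the group
t statistic. The tSNR implied by these defaults (~100, with regional noise
scaling available in the config) matches usable cortical values.

**Design.** Four runs of 12 blocks (6 conditions × 2 repetitions), block
duration 18 s (the span from the first to the last item of a block), jittered
4–8 s inter-block rest, pseudo-random order with no immediate condition
repeats, built by rejection sampling with a retry cap. TR is 2 s for task
runs (~160 volumes) and 3 s for rest runs (180 volumes).

**Rest ground truth.** Rest signal is Σ_k L_k(v) · λ_k(t) + C(v) · φ(t) +
white noise. Two latent networks λ_k are independent unit-sd Gaussian
processes band-limited to 0.01–0.08 Hz (an assumption: the band the
analysis filters retain); each loads (L_k = 1) on a disjoint territory
anchored at the hub (network 1) and the modality region (network 2). The
physiological confound φ is a 0.01–0.10 Hz process loading 1.5 on WM/CSF
and 0.5 on all gray matter — the shared noise source CompCor exists to
remove. Motion parameters are smooth random walks used only as confound
regressors; motion *correction* is out of scope (phantom data are generated
aligned).

## GLM

Condition regressors are microtime boxcars (16 samples per TR) convolved
with a double-gamma HRF (peak 6 s, undershoot 16 s, unit dispersions, ratio
1/6, 32 s support; gamma shapes are delay/dispersion + 1 so each lobe's mode
falls exactly at its configured delay). The convolution kernel is
gain-normalized (unit sample sum) so a sustained block plateaus at 1 and
betas are in raw signal units. High-pass filtering is a DCT cosine drift
basis with K = floor(2 · T · cutoff) columns at the 0.01 Hz cutoff — the
standard re-implementable equivalent of FSL's Gaussian-weighted running-line
filter. Fitting is voxelwise OLS (no autocorrelation prewhitening; AR noise
is absorbed by the permutation-based group level); condition and drift
regressors are fit jointly, not orthogonalized. tSNR is temporal mean over
residual sd (dof-corrected); voxels with zero residual variance are flagged
undefined and excluded from summaries. Percent signal change uses the
max-of-regressor scaling convention, PSC = 100 · β_c · max(X_c) / β_0, and
is undefined where the intercept is ≤ 0. Runs are combined by an unweighted
beta mean, which coincides with variance-weighted fixed effects for
equal-length identically structured runs.

## MVPA

Betas are z-scored per voxel within each run across all six condition maps
(regardless of which scheme is later run); zero-variance voxels are zeroed
and flagged. Searchlight spheres contain all voxels whose center-to-center
distance is ≤ 6 mm (123 voxels on the 2 mm grid; 33 at 3 mm), clipped to the
analysis mask with a 2-voxel minimum. Two cross-classification schemes are
defined: *semantic-feature* (train AUD-vs-VIS on spoken words, test on
written, and vice versa; the two directions averaged) and *perceptual*
(train spoken-vs-written on non-words, test on all four word conditions).
Folds are leave-one-run-out: training uses the train-side conditions of the
three training runs (3 samples per class), testing the test-side conditions
of the held-out run only — the strictest reading of run-independent testing;
with 4 runs the semantic scheme performs 8 train/test evaluations and the
perceptual 4, and fold × direction accuracies are averaged unweighted.

The classifier is a linear soft-margin C-SVM with C = 1, solved by the
LIBSVM backend bundled with scikit-learn, called through its low-level
binding: a searchlight study fits the classifier ~10⁶ times on 6-sample
problems where the high-level estimator's per-call validation dominates
runtime by two orders of magnitude. The wrapper is verified in the tests
against `sklearn.svm.SVC` and against a brute-force dual quadratic program.
A decision value of exactly 0 predicts the lexicographically first class and
is counted (probability ~0 with continuous data).

Accuracy maps are smoothed with a validity-aware Gaussian (6 mm FWHM,
sigma = FWHM/√(8 ln 2) per axis, renormalized over valid voxels so invalid
voxels neither contribute nor receive). Group inference is a voxelwise
one-sample t of (accuracy − 0.5) converted to z, cluster-formed at z ≥ 2.3
(26-connectivity), with family-wise-error corrected p values from the
max-cluster-mass distribution over random sign flips of the per-subject
difference maps (default 1000 permutations, seeded; a request below 100 is
honoured but recorded as a warning). Permutation replaces Gaussian-random-
field correction, which is not re-implementable bit-exactly; nominal error
rates are preserved and checked by simulation. Voxels with zero
between-subject variance (e.g. all subjects at ceiling) have no defined t
and are excluded from the map — one more reason the phantom avoids
saturation. The regional dissociation is tested by a 2×2 within-subject
ANOVA (region × classifier) on region-mean accuracies; for two-level
factors each F(1, n−1) equals the squared paired t of the corresponding
contrast score (verified against an independent RM-ANOVA implementation),
with paired t tests for the two simple effects. Identical values in all
cells make the error variance zero and the F's are reported undefined.

## Connectivity

Seeds are spheres of explicit radius: 3 mm ("6 mm diameter") for
connectivity seeds, 6 mm radius for univariate PSC ROIs — the two
conventions are preserved, not harmonized. CompCor variance-normalizes each
WM∪CSF voxel time series (the anatomical CompCor variant), applies PCA, and
returns the top-k (default 5) orthonormal component time courses, sign-fixed
for determinism and truncated with a recorded warning if the compartment
rank is below k. Confound regression removes [components + 6 motion +
intercept] by OLS projection (collinear columns dropped with a warning),
followed by FSL-style Gaussian temporal filtering (high-pass sigma 100 s,
low-pass sigma 2.8 s); cleaning precedes seed extraction (the alternative
ordering is not modelled). No global signal regression is performed. Seed
maps are Fisher-z transformed Pearson correlations of each voxel with the
mean seed time course; |r| = 1 voxels are capped at atanh(0.999999) and
seed-interior voxels flagged. Paired seed contrasts reuse the same sign-flip
cluster machinery at reference level 0 (one implementation, tested once),
run in both directions to mirror one-sided contrast pairs. Template overlap
reports |map ∩ template| and its share of the map per named template.
WM/CSF segmentation is out of scope: phantom compartments are ground truth
and real-data users supply masks.

## Decoding

A statistic map is Pearson-correlated with every map of a term library over
the intersection of validity masks (whole-volume if no mask is given; at
least 10 voxels required), and the top-k (default 15) positively and
negatively correlated terms are returned, ties broken by term name. The real
meta-analytic database is not shipped; `make_synthetic_term_maps` builds an
orthogonalized smooth random basis (optionally prepending maps of known
structure) for tests and demos.

## Validation studies and problem sizes

`hubspoke.studies` packages the cohort-level checks; sizes were chosen as
the smallest that leave the Monte-Carlo error well below the effects being
verified:

- *Null calibration*: 200 independent 4-run sessions on the default 28³
  grid with all condition-dependent amplitudes zero; the mean sphere
  accuracy over the hub-region searchlight must sit within 3 standard errors
  of chance. `scripts/acceptance.py` recomputes exactly this quantity.
- *FWE calibration*: 200 null cohorts of 12 subject maps (smoothed Gaussian
  noise around chance on a 14³ grid, 200 sign-flip permutations); the
  fraction of cohorts with any corrected cluster must not exceed 0.05
  beyond Monte-Carlo error. Simulated subject maps stand in for full
  searchlight cohorts here because the property under test belongs to the
  group machinery, and 2400 searchlight sessions are not desk-feasible.
- *Dissociation recovery*: 20 cohorts of 12 subjects on a compact 20³
  atlas; success requires each scheme's significant clusters to cover ≥ 50%
  of its own region and ≤ 20% of the other, a significant interaction, and
  both simple effects in the planted directions, in ≥ 90% of cohorts.
- *Connectivity recovery*: 20 cohorts of 12 rest subjects; seed contrasts
  must recover ≥ 50% of each network's exclusive territory at corrected
  p < .05, and CompCor must reduce mean off-network |z| (paired across
  cohorts).
- *Decoder recovery*: the generative term ranks first among 50 synthetic
  terms in ≥ 95 of 100 seeds.

## What the phantom does and does not show

The phantom has the statistical structure the analysis assumes — linear
superposition of HRF-convolved responses, stationary AR(1) noise, planted
patterns stable across runs, band-limited latent networks with a linear
confound — and none of the things real data add: susceptibility dropout and
spatially varying tSNR (only region-wise noise scaling is configurable),
motion-induced artifacts (motion is simulated solely as confound traces),
physiological aliasing, imperfect registration, and between-subject
anatomical variability (all subjects share one atlas). Passing recovery
tests therefore establishes that the pipeline is *correct and calibrated*
— it finds exactly what was planted, at the stated error rates — not that
any particular real dataset would yield the same maps. Numerical edge cases
are handled explicitly rather than silently: zero-variance voxels in
z-scoring, tSNR, the group t map and seed correlation are flagged or
excluded, SVM decision ties resolve deterministically, and every stochastic
step (design order, patterns, noise, permutations) is seeded, making every
result in the package bit-reproducible from one master seed.
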