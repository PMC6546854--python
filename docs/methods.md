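# Methods

This note documents the models, numerical conventions and design choices
behind `metastate`: what the synthetic generator simulates, how the three
feature maps are defined at the bin/voxel level, how the wrapper selection
and permutation test are specified, and what the package's tests do and do
not establish about real data.

## Study design being modeled

A paired two-condition resting-state fMRI experiment: 24 subjects, each
scanned once hungry and once satiated; 170 volumes per run at TR = 2 s
(Nyquist 0.25 Hz); analysis restricted to the 90 cortical/subcortical
regions of the AAL atlas (cerebellum excluded), yielding one 48 × 90
samples-by-regions table per feature kind.  These values are encoded as the
`study2019` preset and as the generator defaults.

## Synthetic BOLD model

Raw data for this design are not publicly available, so the generator
targets the statistical structure the three features measure rather than
scanner realism.  For subject s, region g and condition c, a voxel v carries

    y_v(t) = w_gc · u_{s,g,c}(t) + g_c · h_{s,c}(t) + σ · ε_v(t)

- u is a region-level latent signal: a sum of 3 sinusoids (count
  configurable) with frequencies drawn uniformly from 0.01–0.08 Hz and
  random phases, normalized to unit variance.  Three components are enough
  to guarantee all latent energy lies inside the passband while keeping the
  spectrum non-degenerate.
- h is a brain-wide shared component of the same construction, weighted
  g (default 0.5); it gives every voxel pair a baseline correlation so
  degree centrality has non-trivial structure.
- ε is white Gaussian voxel noise, σ = `noise_sd` (default 1, arbitrary
  units).
- The paired design enters through the latents: the two runs of a subject
  share a fraction `subject_rho` (default 0.5) of latent variance,
  u = √ρ·u_shared + √(1−ρ)·u_run.  The study is within-subject; 0.5 is a
  moderate within-subject dependence chosen once as a realistic default —
  the underlying publication does not model this explicitly.

Condition effects are injected only in the declared informative regions, in
the hunger condition, by one multiplicative modulation (1 + δ):

| `effect_kind`     | modulated term          | targeted feature |
|-------------------|-------------------------|------------------|
| `amplitude`       | latent amplitude w·u    | fALFF            |
| `local_coherence` | voxel–latent coupling w | ReHo             |
| `global_coupling` | shared-component weight g | DC             |

`amplitude` and `local_coherence` act on the same product w·u; they differ
in which feature the requested effect size refers to.  δ is calibrated by
bisection so that the *targeted region-mean feature* realizes the requested
Cohen's d: a Monte-Carlo proxy simulates a 27-voxel cluster (plus a
reference cluster for the DC case) under both conditions with common random
numbers from a fixed internal seed, computes the standardized mean
difference of the cluster-mean feature, and bisects δ until it matches.  The
proxy measures the unsmoothed feature; spatial smoothing across region
borders attenuates realized effects, so calibrated effect sizes refer to
fwhm = 0 extraction.  The calibration for the DC case is approximate (the
proxy's degree is computed against a miniature 4-region brain, not the full
mask).  The generator's test asserts the amplitude calibration to ±0.3 at
d = 2 with 200 subjects.

A toy parcellation partitions a rectangular grid into `n_regions` contiguous
rectangular blocks of ≥ 27 voxels each by backtracking recursive bisection
(balanced splits along the longest feasible axis).  The default pipeline
grid (18, 15, 9) tiles exactly into ninety 3×3×3 blocks.  The partition is a
deterministic function of its arguments.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical inputs reproduce cohorts bit-identically
(the calibration uses its own fixed internal seed and is cached, so it never
perturbs the generation stream).

What the generator does *not* emulate: head motion, physiological noise,
scanner drift, spatial autocorrelation of noise, hemodynamic convolution,
or any of the upstream preprocessing chain (denoising, realignment,
normalization).  Passing tests therefore demonstrate correctness of the
*pipeline machinery* under a known signal model, not performance on real
scanner data.

## Feature definitions and numerical conventions

Frequency bins are centered at k/(n·TR) Hz, k = 0..⌊n/2⌋.

- **Band-pass** (applied before ReHo and DC, never before fALFF): demean,
  zero every Fourier bin with center outside the closed band
  [0.01, 0.08] Hz, invert.  An ideal spectral mask rather than an IIR filter
  keeps the operation exactly consistent with the fALFF bin conventions and
  passes on-bin sinusoids untouched (asserted to 1e-10).  Band-edge
  membership uses a 1e-12 relative tolerance.
- **Smoothing**: Gaussian kernel, σ = FWHM / (2√(2 ln 2)) / voxel size
  (study: 6 mm at 3 mm voxels → σ ≈ 0.85 voxels).  4D runs are smoothed per
  time point.  3D maps (the ReHo path) use normalized, mask-weighted
  convolution so out-of-mask values never bleed inside; support equals the
  mask.
- **ReHo**: Kendall's W over the 3×3×3 cluster centered at each masked
  voxel, written to the center.  Clusters truncated at mask or volume
  boundaries use their actual size K (down to 1 at an isolated voxel, where
  the formula degenerates gracefully to 1 for untied series), keeping the
  map's support equal to the mask.  Ties get average ranks with no tie
  correction term; inputs with > 10 % tied values are flagged with a logged
  warning.  Under the no-tie null, E[W] = 1/K; the map's interior mean on
  white noise is asserted against a brute-force Monte-Carlo oracle.
- **DC**: Pearson correlation between all masked voxel pairs in double
  precision on demeaned series; adjacency r_ij ≥ 0.25; the self-connection
  (r_ii = 1) is *excluded*, so degrees range over 0..N−1.  A literal reading
  of the degree sum Σ_{j=1..N} d_ij would include j = i and shift every
  degree by +1; the graph-theoretic convention is used here and documented
  as such.  Zero-variance voxels have no defined correlation and are
  removed from the map's mask with a logged warning.
- **fALFF**: amplitude spectrum = |FFT| of the demeaned series; ratio of
  the amplitude sum over bins in [0.01, 0.08] to the sum over bins in
  (0, Nyquist].  The k = 0 bin is excluded from both sums by default —
  demeaning makes it ≈ 0 and excluding it keeps the ratio invariant under
  positive rescaling; `include_dc_bin=True` restores a dialect that keeps
  it in the denominator.  All-zero series get fALFF = 0 with a warning
  (0/0 guard).  For n = 170, TR = 2: 24 in-band bins of 85, so white noise
  gives ≈ 0.28.
- **Pipeline order** (fixed per feature): ReHo = band-pass → map → smooth
  the map (smoothing first would manufacture neighborhood concordance);
  DC = smooth run → band-pass → map; fALFF = smooth run → map on
  unfiltered data (band-passing first would push the ratio to 1).
- **Region vectors**: arithmetic mean of the map over each region's masked
  voxels, in region-table order; a region with no masked voxels is an
  error naming the region.

## Classifier and criterion

The wrapper criterion is the leave-one-out misclassification rate of a
linear soft-margin SVM (hinge loss, C = 1 by default) on the subset's
columns, with z-scoring computed from each training fold and applied to the
held-out sample.  C and the scaling are configuration, echoed into every
report, because no principled value is singled out by the problem; C = 1
with standardized features is the common default.  Hunger is the fixed
positive class; a decision value of exactly 0 predicts hunger,
deterministically.

Two equivalent engines solve the SVM: an in-package numba-compiled dual
coordinate-descent solver (deterministic cyclic sweeps, projected-gradient
stopping at 1e-8, intercept as a regularized bias feature) and scikit-learn's
`LinearSVC(loss="hinge")`, which optimizes the identical objective.  The
fast engine exists because sequential selection and the permutation null
evaluate the criterion tens of thousands of times; the test suite asserts
the two engines produce identical held-out predictions on random tables.

Fold unit: the default is leave-one-*sample*-out (48 folds), matching the
48-sample confusion matrices of the reference analysis.  This leaks paired
information — the held-out sample's twin (same subject, opposite label)
remains in training — which on null data biases the error *above* chance
(measured ≈ 0.66 at ρ = 0.5; the anti-learning phenomenon).  A
leave-one-*subject*-out mode (`folds="subject"`) holds out both conditions
of a subject and restores a chance-centered null (≈ 0.50 measured).  The
permutation p-value is calibrated in both modes because the observed error
carries the same bias as the null; the type-I rate is verified at ≈ 5 %.
A related boundary case: on a completely uninformative (constant) feature
with balanced classes, LOOCV error is 1.0, not 0.5 — every training fold's
majority is the held-out sample's opposite class (the classic leave-one-out
majority-rule pathology).

## Sequential selection

- **SFS**: start from the best singleton; repeatedly add the region that
  minimizes the criterion; stop when no addition strictly decreases it or
  the subset reaches `max_k`.
- **SFFS** (floating, Pudil scheme): after each addition, repeatedly test
  conditional exclusion — remove the member (other than the one just added
  on the first test) whose removal is strictly better than the best subset
  recorded at the reduced size; continue until the frontier at `max_k` is
  stable or the evaluation budget (10,000 criterion calls) is exhausted,
  which is flagged in the trace.
- The final subset is the argmin over the best-per-size record; ties go to
  the smaller size, then the lexicographically smaller subset.  All
  tie-breaks (including candidate order: ascending region label) are
  deterministic; selection contains no randomness.
- "Strictly better" uses a 1e-12 tolerance — error rates are multiples of
  1/n_samples, so this guards floating-point refactors without changing
  semantics.
- `max_k` defaults to 10: reported subsets in this literature have ≤ 5
  regions, and the budget caps worst-case floating oscillation.

On tables small enough to enumerate, SFS and SFFS are verified never to
beat exhaustive search at any size, and a constructed nesting-trap table
(two regions that separate only jointly through a shared nuisance
component, plus a seductive singleton) is solved by SFFS and provably not
by SFS.

A caveat the tests quantify: at study scale (48 samples, 90 candidate
regions, d = 1.5 in 5 regions) the LOOCV criterion is optimistically biased
for searched subsets, so SFFS typically returns a small subset mixing 2–3
truly informative regions with chance regions whose noise happens to
separate the sample.  Recovering ≥ 3 of 5 true regions occurs in roughly
two-thirds of simulated cohorts — a property of wrapper selection at this
sample size, not of the implementation (the selected subsets' criterion
values are at or below the true subset's in almost every cohort).

## Permutation test

Labels are permuted within subject (each pair swapped with probability 1/2),
the exchangeability unit of a paired design; free permutation over all
samples is available behind `scheme="free"`.  The p-value uses the add-one
estimator p = (1 + #{null ER ≤ observed}) / (1 + n_perm), which cannot
return 0 and equals 1/10,000 when the observed error beats 9,999
permutations.  Two modes:

- `post_selection` (default): the evaluated subset is held fixed across
  permutations.  Cheap (matches the 10,000-permutation scale of the
  reference analysis), but anti-conservative when the subset was selected
  on the same data — the test suite demonstrates the inflation empirically
  against a pre-fixed subset.
- `full_pipeline`: selection is re-run inside every permutation, keeping
  the p-value calibrated for the selected-subset question; refused above
  2,000 permutations with guidance, since each permutation costs a full
  SFFS run.

## Reported problem sizes

The test suite and acceptance script exercise the study-scale quantities at
the sizes stated with each result: 1,000 random instances for the Kendall-W
oracle, 50 enumerable tables for the selection-optimality check, 25
simulated cohorts for the recovery experiment, and 200 null datasets × 199
permutations for the calibration experiment.  Full-volume checks run on toy
grids (6³ to 18×15×9 voxels) whose blocks still contain complete 3×3×3
neighborhoods; all map-level operations are grid-size agnostic.

## Known limitations

- The generator's effect calibration is Monte-Carlo (±a few percent) and,
  for the DC case, approximate in N.
- Degree centrality is O(N²) in masked voxels (chunked matrix products);
  fine for toy grids, not tuned for full-resolution brains.
- Sample-level LOOCV on paired designs is reported faithfully but is a
  biased estimator of generalization; prefer `folds="subject"` for
  inference about new subjects.
- The SVM solver assumes dense float64 features of modest dimension (≤ a
  few hundred), which is the regime of region vectors.
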