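# Methods

## Scope and model

`megfusion` implements the multivariate analysis chain used to track
rapid visual recognition with MEG and fMRI: time-resolved pairwise
decoding of condition identity from sensor patterns, summarization of the
resulting representational dissimilarity matrices (RDMs), temporal
generalization, rank-correlation fusion of MEG and fMRI representational
geometries, and nonparametric inference (bootstrap latencies,
sign-permutation cluster-size tests, FDR). Because raw human recordings
are not part of the package, every stage is exercised on synthetic
cohorts whose generative model mirrors the structure the analyses assume.

### Generative model of the synthetic cohorts

A trial of condition *c* for subject *s* is

    x(t) = a_id(t) · p_sc + a_cat(t) · q_s,cat(c) + ε(t)

where `p_sc` (one per condition) and `q_s,cat` (one per category) are
unit-norm Gaussian spatial patterns drawn once per subject, `a_id` and
`a_cat` are Gaussian temporal envelopes parameterized by onset, peak,
FWHM and amplitude (truncated to zero before onset), and ε is i.i.d.
Gaussian sensor noise of standard deviation `noise_sd` per sample and
channel. Unit-norm patterns make `amplitude / noise_sd` the single-trial
SNR, independent of channel count.

Defaults mirror the emulated study design: 24 conditions split into two
categories of 12, 30 trials per condition, 306 channels, a −300…900 ms
window at 1 kHz. The identity envelope defaults to onset 40 ms / peak
100 ms / FWHM 100 ms, the categorical envelope to onset 90 ms / peak
170 ms / FWHM 140 ms with a smaller amplitude (0.6 vs 1.0): identity
information rises earlier and categorical structure later, the ordering
the decoding analyses are designed to resolve. `noise_sd` defaults to
1.0, i.e. single-trial SNR 1 for the identity component, which puts
pseudo-trial decoding in the informative mid-range (neither chance nor
ceiling) at the default group size of 3.

What the generator deliberately does **not** emulate: 1/f sensor noise,
spatially correlated noise covariance, forward-model field spread,
trial-to-trial latency jitter, and cross-subject latency variability.
Passing tests therefore demonstrate the correctness and calibration of
the *analysis chain* under its own assumptions, not robustness of the
method to real MEG noise.

### fMRI pattern embedding

`generate_fmri_patterns` turns a target dissimilarity geometry
(interpreted on the 1 − Pearson scale) into voxel patterns by classical
scaling: the implied correlation matrix C = 1 − D is eigendecomposed,
negative eigenvalues are clipped (with a warning — the closest
embeddable geometry is returned), and the factor is projected onto
random orthonormal voxel directions orthogonal to the constant vector.
The orthogonality to the constant vector makes every pattern row exactly
zero-mean, so the sample Pearson RDM of the noiseless patterns
reproduces the target exactly, not just asymptotically. Geometries with
entries above 2 (e.g. Euclidean ground-truth geometries) are first
rescaled onto [0, 2]; the map is monotone, so rank-based fusion is
unaffected. Voxel noise is additive Gaussian.

## Preprocessing

The default order is baseline correction → peak-to-peak rejection →
low-pass smoothing, recorded in the output's history. Rejection uses a
strict `>` at the threshold (a trial spanning exactly the threshold is
kept), making the boundary rule deterministic. The smoother is a
4th-order Butterworth applied forward-backward (`sosfiltfilt`, reflect
padding), i.e. zero-phase: symmetric pulses keep their peak sample, which
matters because latencies are the downstream quantities of interest.
Whether smoothing precedes or follows baseline correction is immaterial
for data whose baseline window is signal-free (the two orders agree to
machine precision once the filter transient has decayed; a test pins
this at 1e−9 of the data scale).

## Decoding

Within each repetition, trials of every condition are randomly grouped
(size 3 by default) and averaged into M pseudo-trials; remainder trials
are dropped for that repetition (the randomness across the default 100
repetitions recycles them). For each condition pair and time point a
linear SVM (libsvm via scikit-learn, fixed C = 1, no feature
normalization by default) is scored by M-fold cross-validation in which
each fold holds out one pseudo-trial of *each* class (2 test vectors)
and trains on the remaining 2(M−1). This fold structure keeps training
sets balanced; it is an interpretive choice where the source description
of the leave-one-out assignment is ambiguous. Fold accuracies are
averaged within a repetition, then across repetitions; with unequal
per-condition counts each pair uses the smaller M. A test vector exactly
on the decision boundary counts as incorrect (conservative,
deterministic). The per-pair accuracies fill a symmetric
conditions × conditions × time grid with an undefined diagonal — the
time-resolved MEG RDM.

Temporal generalization reuses the identical repetition/fold stream
(same seed ⇒ same pseudo-trials) and evaluates each trained classifier
at every test time, so its diagonal reproduces the time-resolved
decoding exactly. Direct category decoding trains face-vs-object
classifiers with leave-one-exemplar-pair-out folds, so test exemplars
never occur in training and identity information cannot masquerade as
category information.

Chance-level behavior: pairwise decoding of a *fixed* random label
permutation is not exactly 50% in expectation — the permuted "conditions"
are finite mixtures of true conditions and retain slightly different
mixture means. The residual is small (a few tenths of a percent at the
default trial counts) and is covered by the Monte-Carlo error band used
in the calibration check.

## RSA and fusion

fMRI RDMs are 1 − Pearson between condition pattern vectors; searchlight
RDMs use spherical neighborhoods (center-to-center Euclidean distance
≤ radius in voxel units, boundary inclusive, truncated at mask edges,
centers with < 2 in-mask voxels skipped). Fusion vectorizes both RDMs
over the strictly-lower triangle in a fixed row-major order and computes
Spearman's rho with average ranks; MEG decoding-accuracy slices are used
directly as dissimilarities (rank correlation needs only monotonicity).
Time points where either vector is constant are recorded as missing
rather than zero. MDS uses SMACOF stress majorization initialized from
the deterministic classical-scaling solution, centered, with each axis's
sign fixed by its largest-magnitude coordinate — identical input yields
identical coordinates.

## Inference

* **d′** = z(hit rate) − z(false-alarm rate); rates of 0/1 are replaced
  by 1/(2N) and 1 − 1/(2N).
* **Signed-rank**: exact null for n ≤ 25 without ties, normal
  approximation with tie correction otherwise; zero differences dropped;
  all-zero differences give p = 1.
* **Bootstrap latencies** (default 1000 resamples): subjects are
  resampled with replacement, the latency of each resampled average is
  extracted, and the 2.5/97.5 percentiles form the 95% CI (plain
  percentile, no BCa — the CI is the empirical distribution's central
  band and need not bracket the plug-in point estimate). Peak = argmax
  within the search window. Onset is not a primitive of the data, so it
  is defined operationally: the point estimate is the start of the
  earliest significant cluster; within bootstrap replicates (where
  nested permutation is infeasible) it is the first run of ≥ 5
  consecutive samples above the point-wise threshold computed once on
  the original data. Latency differences use independent (or paired)
  resampling; p = 2 · min(tail masses), floored at 1/n_boot.
* **FDR**: Benjamini–Hochberg step-up at q = 0.05.
* **Cluster-size inference**: subject effects (already centered on their
  null value) are sign-flipped (1000 permutations by default); the
  per-cell cluster-defining threshold is the (1 − 0.05) permutation
  quantile, clusters are connected supra-threshold cells (1-D adjacency;
  4-connectivity for 2-D maps), the statistic is cluster size in cells,
  and corrected p-values compare against the permutation distribution of
  the maximum cluster size with the observed data included, so
  p ≥ 1/(n_perm + 1). A known property of size-based inference with a
  permutation-quantile threshold: for a near-noiseless effect that is
  homogeneous across cells and subjects (rank-one), high-sign-count
  permutations reproduce full-extent clusters and the corrected p
  saturates near the cluster-defining threshold instead of reaching the
  floor; with subject-level noise of realistic magnitude this does not
  occur. A t-based point-wise threshold is a possible alternative; the
  permutation quantile is implemented.

## Pipeline

`run_pipeline` sequences simulate → prep → decode → fuse → stats →
report from one validated YAML config. Per-stage seeds derive from the
global seed by `SeedSequence([global_seed, stage_index])` (substreams add
a third counter), so stages are individually reproducible. Every output
file is hashed (SHA-256) into the manifest; HDF5 datasets are written
without timestamps, so identical configs give bit-identical artifacts.
The fusion stage embeds fMRI pattern sets from the cohort's ground-truth
geometry at each configured ROI latency — the synthetic analogue of
region-specific response geometries — and fuses them with the
subject-averaged decoded MEG RDM. The report renders latency,
fusion, behavioral and cluster tables from the persisted JSON artifacts
only (no timestamps), so regeneration is byte-identical.

## Problem sizes used in the checks

Statistical checks run at desk scale, chosen to keep each protocol's
Monte-Carlo error well inside its decision margin: chance calibration
uses 2 subjects × 8 conditions × 12 trials × 100 time points × 10
repetitions; latency recovery uses 100 cohorts of 10 subjects with 4
conditions and a 10 ms decoding stride (the 100/170 ms true peaks lie on
that grid); cluster calibration uses 200 null simulations at 500
permutations; fusion recovery uses 100 embeddings at 80 voxels with
voxel noise at half the per-voxel signal amplitude (~1/√n_voxels). The
rapid-presentation analogue compares three envelope settings — identity
FWHM 100/50/25 ms at amplitude 1.0/0.8/0.6 with categorical peaks
150/200/250 ms — across 20 replicate cohorts each. Faster presentation
is emulated as a shorter *and* weaker identity response (backward
masking truncates stimulus processing, so response amplitude falls with
duration) with a later categorical component; sensor noise is set to
SD 5 (single-trial SNR 0.2, realistic for unaveraged MEG), which the
20 Hz smoothing and pseudo-trial averaging bring back to mid-range
decodability where amplitude differences are measurable — a width-only
manipulation would be nearly invisible to decoding because a 4th-order
Butterworth is flat well below its cutoff. Onset is measured on the
replicate-averaged series as the first sustained excursion above chance
(58%, i.e. > 4 Monte-Carlo SEs of the averaged series), and the
division peak within a 100–320 ms search window.

## Known limitations

* The SVM is refit per pair × time × fold × repetition; wall-clock is
  dominated by libsvm call overhead (~0.7 ms per fold), which bounds
  practical problem sizes more than memory does.
* The synthetic noise model is white; calibration under correlated
  noise is untested (see generator non-goals above).
* Onset estimation inside bootstrap replicates reuses the original
  data's point-wise threshold, slightly understating CI width when the
  resampled cohort is much noisier than the original.
* Searchlight fusion (per-voxel fusion maps) is out of scope; fusion is
  ROI-based.
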