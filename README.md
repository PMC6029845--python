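# megfusion

Time-resolved multivariate decoding of MEG, representational similarity
fusion with fMRI, and the accompanying nonparametric inference — as a
tested, reusable pipeline driven by a synthetic-data generator with
known representational ground truth.

## Who this is for

Researchers analyzing rapid visual recognition experiments (e.g. rapid
serial visual presentation, RSVP) who need the standard MEG/fMRI
multivariate analysis chain as composable, seeded, testable library
code: epochs in, decoding matrices, fusion time courses, latency
estimates and cluster statistics out. Because every stage can be fed
from the built-in generator, the whole chain is verifiable end-to-end
without access to raw recordings.

## The analysis in brief

* **Time-resolved pairwise decoding.** Trials of each condition are
  randomly sub-averaged in groups of 3 into M pseudo-trials; for every
  condition pair and time point *t* a linear SVM (fixed C = 1) is scored
  by M-fold cross-validation (one held-out pseudo-trial per class per
  fold), averaged over 100 random sub-averaging repetitions. The
  accuracies populate a symmetric conditions × conditions decoding
  matrix at each *t* — the MEG representational dissimilarity matrix
  (RDM) — with chance at 50%.
* **Summaries.** Partition means over within-face, within-object and
  between-category pairs; the categorical division (between − within), an
  index of category clustering; temporal generalization (train at *t*,
  test at *t′*); direct category decoding with leave-exemplar-pair-out
  folds; 2-D MDS embeddings of RDM slices.
* **fMRI RDMs and fusion.** Condition pattern vectors per ROI (or
  4-voxel-radius searchlight spheres) give 1 − Pearson RDMs; fusion
  rank-correlates (Spearman) the time-resolved MEG RDM with each
  subject's fMRI RDM, yielding a time course of MEG–fMRI
  representational similarity per ROI.
* **Inference.** Behavioral d′ = z(hit) − z(false alarm) with
  signed-rank comparisons; bootstrap (1000×) peak/onset latencies with
  percentile 95% CIs and difference p-values; Benjamini–Hochberg FDR;
  sign-permutation cluster-size inference (1000 permutations, 0.05
  cluster-defining threshold, 0.05 cluster threshold) for series and
  train × test maps.

See `docs/methods.md` for the generative model, numerical conventions
and design decisions.

## Worked example

```python
import numpy as np
from megfusion.synthgen import SyntheticSpec, generate_meg_subjects
from megfusion.epochs_prep import preprocess
from megfusion.mvpa import (DecodingParams, PairPartition,
                            pairwise_decoding_timecourse,
                            partition_mean, categorical_division)

spec = SyntheticSpec(n_subjects=1, n_conditions=8, n_trials_per_condition=12,
                     n_channels=32, time_start_ms=-100, time_stop_ms=400,
                     noise_sd=1.0, seed=0)
subs, truth = generate_meg_subjects(spec)
clean, rejected = preprocess(subs[0])          # baseline, reject, 20 Hz low-pass
rdm = pairwise_decoding_timecourse(
    clean, DecodingParams(group_size=3, n_repetitions=5, seed=0, time_stride=20))
part = PairPartition.from_categories(spec.category_of, "face", "object")
grand = partition_mean(rdm, part.within | part.between)
division = categorical_division(rdm, part)
i, j = int(np.argmax(grand)), int(np.argmax(division))
print(f"grand-mean decoding peak: {grand[i]:.1f}% at {rdm.time_axis[i]:.0f} ms")
print(f"categorical division peak: {division[j]:.1f} points at {rdm.time_axis[j]:.0f} ms")
```

prints

```
grand-mean decoding peak: 100.0% at 120 ms
categorical division peak: 53.0 points at 200 ms
```

The grand mean peaks (here at ceiling — the 20 Hz smoothing removes most
of the white sensor noise) shortly after the identity envelope's 100 ms
peak, while the categorical division — how much better pairs straddling
the face/object boundary decode than pairs within a category — peaks
later, tracking the categorical envelope (true peak 170 ms; the 20 ms
decoding grid and single cohort put the sample argmax at 200 ms).

The same chain runs end-to-end from a YAML config:

```sh
megfusion run-all -c config.yaml -o out/
# or stage by stage: simulate, prep, decode, generalize, fuse, stats, report
```

which writes epochs/RDMs (HDF5), partition means and fusion series
(CSV), latency and cluster records (JSON), a SHA-256-hashed run
manifest, and a markdown report with the latency/fusion/d′ tables.

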