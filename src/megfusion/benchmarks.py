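"""Reference protocols exercised by the acceptance checks.

These functions define fixed study conditions (cohort sizes, envelope
settings, noise levels) under which the pipeline's statistical behavior
is measured: chance calibration of the decoder on label-permuted data,
and parameter recovery of known latencies. They are ordinary library
code — the same calls a user would script — collected here so tests and
reproduction scripts share one definition.
"""

from __future__ import annotations

import numpy as np

from .mvpa import DecodingParams, all_pairs, pairwise_decoding_timecourse
from .synthgen import Envelope, SyntheticSpec, generate_meg_subjects

__all__ = ["chance_calibration"]


def chance_calibration(
    seed: int,
    n_subjects: int = 2,
    n_conditions: int = 8,
    n_trials_per_condition: int = 12,
    n_times: int = 100,
    n_repetitions: int = 10,
) -> dict:
    """Grand-mean decoding accuracy on label-permuted synthetic epochs.

    Generates a cohort with the standard signal components, randomly
    permutes each subject's condition labels (destroying the
    label-signal association), runs the full sub-averaging + leave-one-out
    decoding procedure, and averages accuracy over all pairs, time points
    and subjects. Returns the grand mean (%), its Monte-Carlo standard
    error estimated from the per-subject-pair time-averaged accuracies,
    and the number of such values.
    """
    spec = SyntheticSpec(
        n_subjects=n_subjects,
        n_conditions=n_conditions,
        n_trials_per_condition=n_trials_per_condition,
        n_channels=32,
        time_start_ms=0.0,
        time_stop_ms=float(n_times - 1),
        noise_sd=1.0,
        identity_envelope=Envelope(10.0, 50.0, 60.0, 1.0),
        category_envelope=Envelope(20.0, 80.0, 60.0, 0.6),
        seed=seed,
    )
    subs, _ = generate_meg_subjects(spec)
    perm_rng = np.random.default_rng(seed + 1)
    values = []
    for s, ep in enumerate(subs):
        ep.labels = perm_rng.permutation(ep.labels)
        rdm = pairwise_decoding_timecourse(
            ep,
            DecodingParams(group_size=3, n_repetitions=n_repetitions, seed=seed + s),
        )
        for i, j in all_pairs(n_conditions):
            values.append(rdm.accuracy[i, j].mean())
    values = np.asarray(values)
    return {
        "mean_accuracy": float(values.mean()),
        "se": float(values.std(ddof=1) / np.sqrt(values.size)),
        "n_values": int(values.size),
    }
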