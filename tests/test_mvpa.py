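"""Decoding machinery: sub-averaging, pairwise decoding, partitions, TG."""

import numpy as np
import pytest
from dataclasses import replace

from megfusion.containers import EpochedRecording
from megfusion.mvpa import (
    DecodingParams,
    PairPartition,
    categorical_division,
    direct_category_decoding,
    pairwise_decoding_timecourse,
    partition_mean,
    subaverage_trials,
    temporal_generalization,
    all_pairs,
)
from megfusion.synthgen import Envelope, SyntheticSpec, generate_meg_subjects


def make_epochs(data, labels, start=0.0):
    data = np.asarray(data, dtype=float)
    t = start + np.arange(data.shape[2], dtype=float)
    return EpochedRecording(
        data=data,
        labels=np.asarray(labels),
        time_axis=t,
        sampling_rate=1000.0,
        baseline_window=(start, start),
    )


class TestSubaverage:
    @pytest.mark.parametrize(
        "n_trials,group,expected_m",
        [(30, 3, 10), (3, 3, 1), (7, 3, 2), (12, 4, 3)],
    )
    def test_pseudo_trial_count(self, rng, n_trials, group, expected_m):
        trials = rng.normal(size=(n_trials, 2, 5))
        pseudo = subaverage_trials(trials, group, rng)
        assert pseudo.shape == (expected_m, 2, 5)

    def test_three_trials_group_three_is_plain_mean(self, rng):
        trials = rng.normal(size=(3, 2, 4))
        pseudo = subaverage_trials(trials, 3, rng)
        assert np.allclose(pseudo[0], trials.mean(axis=0))

    def test_each_trial_used_at_most_once(self):
        # with mutually orthogonal one-hot trials, group sums reveal membership
        n = 9
        trials = np.eye(n)[:, :, None]
        rng = np.random.default_rng(3)
        pseudo = subaverage_trials(trials, 3, rng)
        usage = (pseudo > 0).sum(axis=0)  # how many pseudo-trials touch each trial
        assert usage.max() == 1

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            subaverage_trials(rng.normal(size=(2, 1, 3)), 3, rng)


def oracle_pairwise_m2(data_a, data_b, group_size, seed, n_repetitions=1):
    """Exhaustive fold enumeration with the hand-computed margin rule.

    Single-channel, M=2 decoding: each fold trains on one pseudo-trial per
    class, for which the maximum-margin boundary is the midpoint of the
    two training values; a held-out value is correct iff strictly nearer
    its own class's training value. Reproduces the decoder's random fold
    assignment from the seed, but classifies and scores independently.
    """
    rng = np.random.default_rng(seed)
    total = 0.0
    n_t = data_a.shape[2]
    for _ in range(n_repetitions):
        pa = subaverage_trials(data_a, group_size, rng)  # (2, 1, T)
        pb = subaverage_trials(data_b, group_size, rng)
        acc = np.zeros(n_t)
        for k in (0, 1):
            train_a = pa[1 - k, 0]
            train_b = pb[1 - k, 0]
            for t in range(n_t):
                for test, own, other in (
                    (pa[k, 0, t], train_a[t], train_b[t]),
                    (pb[k, 0, t], train_b[t], train_a[t]),
                ):
                    if abs(test - own) < abs(test - other):
                        acc[t] += 1.0
        total += acc * 100.0 / 4.0
    return total / n_repetitions


class TestPairwiseDecoding:
    def test_oracle_equivalence_single_channel_m2(self):
        """Full decoder must equal exhaustive fold enumeration exactly."""
        rng = np.random.default_rng(11)
        for trial_counts, group in (((2, 2), 1), ((4, 4), 2)):
            na, nb = trial_counts
            data = rng.normal(size=(na + nb, 1, 7))
            labels = np.array([0] * na + [1] * nb)
            ep = make_epochs(data, labels)
            params = DecodingParams(group_size=group, n_repetitions=3, seed=5)
            rdm = pairwise_decoding_timecourse(ep, params)
            expected = oracle_pairwise_m2(
                data[:na], data[na:], group, seed=5, n_repetitions=3
            )
            assert np.array_equal(rdm.accuracy[0, 1], expected)

    def test_noiseless_separable_patterns_decode_perfectly_at_peak(self):
        spec = SyntheticSpec(
            n_subjects=1,
            n_conditions=4,
            n_trials_per_condition=6,
            n_channels=8,
            time_start_ms=0.0,
            time_stop_ms=150.0,
            noise_sd=0.0,
            identity_envelope=Envelope(40.0, 100.0, 80.0, 1.0),
            category_envelope=Envelope(90.0, 140.0, 80.0, 0.5),
            seed=2,
        )
        subs, _ = generate_meg_subjects(spec)
        rdm = pairwise_decoding_timecourse(
            subs[0], DecodingParams(group_size=3, n_repetitions=1, seed=0, time_stride=50)
        )
        peak_slice = rdm.accuracy[:, :, 2]  # t = 100 ms
        off_diag = peak_slice[~np.eye(4, dtype=bool)]
        assert np.all(off_diag == 100.0)

    def test_symmetry_and_nan_diagonal(self, tiny_spec):
        subs, _ = generate_meg_subjects(tiny_spec)
        rdm = pairwise_decoding_timecourse(
            subs[0], DecodingParams(group_size=3, n_repetitions=1, seed=1, time_stride=50)
        )
        acc = rdm.accuracy
        assert np.array_equal(
            np.nan_to_num(acc), np.nan_to_num(acc.transpose(1, 0, 2))
        )
        assert np.all(np.isnan(acc[np.arange(4), np.arange(4), :]))
        defined = acc[~np.isnan(acc)]
        assert np.all((defined >= 0) & (defined <= 100))

    def test_seed_determinism(self, tiny_spec):
        subs, _ = generate_meg_subjects(tiny_spec)
        params = DecodingParams(group_size=3, n_repetitions=2, seed=9, time_stride=25)
        a = pairwise_decoding_timecourse(subs[0], params)
        b = pairwise_decoding_timecourse(subs[0], params)
        assert np.array_equal(np.nan_to_num(a.accuracy), np.nan_to_num(b.accuracy))

    def test_too_few_pseudo_trials_rejected(self, tiny_spec):
        spec = replace(tiny_spec, n_trials_per_condition=5)  # M = 1 < 2
        subs, _ = generate_meg_subjects(spec)
        with pytest.raises(ValueError, match="M < 2"):
            pairwise_decoding_timecourse(subs[0], DecodingParams(group_size=3))

    def test_constant_features_do_not_crash(self):
        data = np.zeros((8, 2, 3))
        ep = make_epochs(data, [0, 0, 0, 0, 1, 1, 1, 1])
        rdm = pairwise_decoding_timecourse(
            ep, DecodingParams(group_size=2, n_repetitions=1, seed=0)
        )
        assert np.all(np.isfinite(rdm.accuracy[0, 1]))

    def test_roi_decoding_is_channel_slicing(self, tiny_spec):
        """Decoding an ROI = the same op on the ROI's channel subset."""
        subs, _ = generate_meg_subjects(tiny_spec)
        ep = subs[0]
        roi = np.arange(6)
        params = DecodingParams(group_size=3, n_repetitions=1, seed=4, time_stride=50)
        sliced = ep.pick_channels(roi)
        direct = EpochedRecording(
            data=ep.data[:, roi, :],
            labels=ep.labels,
            time_axis=ep.time_axis,
            sampling_rate=ep.sampling_rate,
            baseline_window=ep.baseline_window,
        )
        a = pairwise_decoding_timecourse(sliced, params)
        b = pairwise_decoding_timecourse(direct, params)
        assert np.array_equal(np.nan_to_num(a.accuracy), np.nan_to_num(b.accuracy))


class TestPartitions:
    def test_pair_counts_for_24_conditions(self):
        cat = np.repeat([0, 1], 12)
        part = PairPartition.from_categories(cat)
        assert len(part.within_a) == 66  # 12*11/2
        assert len(part.within_b) == 66
        assert len(part.between) == 144
        assert len(part.within | part.between) == 276  # 24*23/2

    def test_partition_mean_constant_rdm(self):
        from megfusion.mvpa import TimeResolvedRDM

        acc = np.full((4, 4, 5), 60.0)
        rdm = TimeResolvedRDM(
            accuracy=acc,
            condition_ids=np.arange(4),
            time_axis=np.arange(5.0),
        )
        series = partition_mean(rdm, all_pairs(4))
        assert np.allclose(series, 60.0)

    def test_empty_pair_set_rejected(self):
        from megfusion.mvpa import TimeResolvedRDM

        rdm = TimeResolvedRDM(
            accuracy=np.zeros((3, 3, 2)),
            condition_ids=np.arange(3),
            time_axis=np.arange(2.0),
        )
        with pytest.raises(ValueError, match="non-empty"):
            partition_mean(rdm, set())

    def test_categorical_division_arithmetic(self):
        from megfusion.mvpa import TimeResolvedRDM

        cat = np.repeat([0, 1], 2)
        part = PairPartition.from_categories(cat)
        acc = np.empty((4, 4, 3))
        for i, j in all_pairs(4):
            val = 60.0 if cat[i] != cat[j] else 55.0
            acc[i, j, :] = acc[j, i, :] = val
        rdm = TimeResolvedRDM(
            accuracy=acc, condition_ids=np.arange(4), time_axis=np.arange(3.0)
        )
        assert np.allclose(categorical_division(rdm, part), 5.0)

    def test_division_near_zero_without_category_structure(self):
        """Exchangeable conditions: division fluctuates around zero.

        With no categorical signal component the between/within split is
        arbitrary, so the division's expectation is exactly zero; the
        cohort-level mean must sit within its own Monte-Carlo band.
        """
        cohort_means = []
        for rep in range(5):
            spec = SyntheticSpec(
                n_subjects=1,
                n_conditions=4,
                n_trials_per_condition=9,
                n_channels=8,
                time_start_ms=0.0,
                time_stop_ms=59.0,
                noise_sd=1.0,
                identity_envelope=Envelope(5.0, 30.0, 40.0, 1.0),
                category_envelope=Envelope(5.0, 30.0, 40.0, 0.0),  # no category signal
                seed=21 + rep,
            )
            subs, _ = generate_meg_subjects(spec)
            rdm = pairwise_decoding_timecourse(
                subs[0],
                DecodingParams(group_size=3, n_repetitions=4, seed=rep, time_stride=4),
            )
            part = PairPartition.from_categories(spec.category_of)
            cohort_means.append(categorical_division(rdm, part).mean())
        cohort_means = np.array(cohort_means)
        sem = cohort_means.std(ddof=1) / np.sqrt(cohort_means.size)
        assert abs(cohort_means.mean()) < 3.0 * sem + 1.0

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            PairPartition(
                within_a=frozenset({(0, 1)}),
                within_b=frozenset({(0, 1)}),
                between=frozenset({(0, 2)}),
            )


class TestTemporalGeneralization:
    def test_diagonal_equals_time_resolved_decoding(self, tiny_spec):
        subs, _ = generate_meg_subjects(tiny_spec)
        params = DecodingParams(group_size=3, n_repetitions=2, seed=6, time_stride=25)
        rdm = pairwise_decoding_timecourse(subs[0], params)
        tgm = temporal_generalization(subs[0], params)
        grand = partition_mean(rdm, all_pairs(4))
        assert np.allclose(np.diag(tgm.accuracy), grand)

    def test_sustained_pattern_generalizes_across_its_interval(self):
        # constant pattern over t in [10, 30): classifiers trained inside
        # the interval must transfer within it, not outside it
        rng = np.random.default_rng(8)
        pattern = np.array([1.0, -1.0, 0.5, 0.0])
        data = rng.normal(scale=0.4, size=(12, 4, 40))
        labels = np.array([0] * 6 + [1] * 6)
        data[labels == 1, :, 10:30] += pattern[None, :, None]
        ep = make_epochs(data, labels)
        tgm = temporal_generalization(
            ep, DecodingParams(group_size=2, n_repetitions=2, seed=0)
        )
        inside = tgm.accuracy[12:28, 12:28].mean()
        outside = tgm.accuracy[12:28, :8].mean()
        assert inside > 80.0
        assert inside - outside > 25.0

    def test_null_data_near_chance(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(12, 3, 10))
        ep = make_epochs(data, np.arange(12) % 2)
        tgm = temporal_generalization(
            ep, DecodingParams(group_size=2, n_repetitions=4, seed=1)
        )
        assert abs(tgm.accuracy.mean() - 50.0) < 12.0


class TestDirectCategoryDecoding:
    def test_strong_category_signal_decodes_at_peak(self):
        spec = SyntheticSpec(
            n_subjects=1,
            n_conditions=6,
            n_trials_per_condition=9,
            n_channels=12,
            time_start_ms=0.0,
            time_stop_ms=120.0,
            noise_sd=0.3,
            identity_envelope=Envelope(10.0, 60.0, 60.0, 0.2),
            category_envelope=Envelope(10.0, 60.0, 60.0, 1.5),
            seed=31,
        )
        subs, _ = generate_meg_subjects(spec)
        series = direct_category_decoding(
            subs[0],
            spec.category_of,
            DecodingParams(group_size=3, n_repetitions=2, seed=0, time_stride=30),
        )
        assert series[2] > 95.0  # t = 60 ms

    def test_null_data_near_chance(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(24, 4, 8))
        ep = make_epochs(data, np.arange(24) % 4)
        series = direct_category_decoding(
            ep,
            np.array([0, 0, 1, 1]),
            DecodingParams(group_size=2, n_repetitions=4, seed=2),
        )
        assert abs(series.mean() - 50.0) < 15.0

    def test_single_exemplar_category_rejected(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(12, 2, 5))
        ep = make_epochs(data, np.arange(12) % 3)
        with pytest.raises(ValueError, match="2 exemplars"):
            direct_category_decoding(
                ep, np.array([0, 0, 1]), DecodingParams(group_size=2, n_repetitions=1)
            )

    def test_detects_category_effect_alongside_division(self):
        """Both category readouts must flag the same synthetic effect."""
        spec = SyntheticSpec(
            n_subjects=1,
            n_conditions=4,
            n_trials_per_condition=9,
            n_channels=12,
            time_start_ms=0.0,
            time_stop_ms=100.0,
            noise_sd=0.5,
            identity_envelope=Envelope(5.0, 50.0, 60.0, 0.3),
            category_envelope=Envelope(5.0, 50.0, 60.0, 1.2),
            seed=41,
        )
        subs, _ = generate_meg_subjects(spec)
        params = DecodingParams(group_size=3, n_repetitions=2, seed=0, time_stride=25)
        rdm = pairwise_decoding_timecourse(subs[0], params)
        part = PairPartition.from_categories(spec.category_of)
        division = categorical_division(rdm, part)
        direct = direct_category_decoding(subs[0], spec.category_of, params)
        # both flag the effect inside the envelope's active window
        # (indices 1-3 = 25-75 ms) and neither fires before onset
        assert np.argmax(division) in (1, 2, 3)
        assert np.argmax(direct) in (1, 2, 3)
        assert direct[0] < 70.0
        assert division[0] < max(division[1:4])
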