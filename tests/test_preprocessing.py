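"""Preprocessing contracts: resampling, baseline removal, 3 s assembly,
rating annotation and split generation."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st

from crtnn.preprocessing import (
    LabelScheme,
    assemble_3s,
    assign_label,
    downsample,
    make_splits,
    preprocess_subject,
    remove_baseline,
    segment_1s,
)
from crtnn.synthetic import RawTrialSet, deap_spec, simulate_deap_like


def _raw(data, rate=128.0, baseline=0.0, layout="seed"):
    labels = np.zeros(data.shape[0], dtype=np.int64)
    return RawTrialSet(data, labels, rate, baseline, layout)


class TestDownsample:
    def test_512hz_trial_lands_on_8064_samples(self, rng):
        data = rng.normal(size=(2, 32, 512 * 63)).astype(np.float32)
        out = downsample(_raw(data, rate=512.0), 128.0)
        assert out.data.shape == (2, 32, 8064)
        assert out.rate == 128.0

    def test_equal_rate_is_identity(self, rng):
        raw = _raw(rng.normal(size=(1, 4, 256)).astype(np.float32))
        out = downsample(raw, 128.0)
        assert out.data is raw.data

    def test_sinusoid_peak_survives_decimation(self):
        t = np.arange(512 * 4) / 512.0
        data = np.sin(2 * np.pi * 10.0 * t)[None, None, :].astype(np.float32)
        out = downsample(_raw(data, rate=512.0), 128.0)
        spectrum = np.abs(np.fft.rfft(out.data[0, 0]))
        freqs = np.fft.rfftfreq(out.data.shape[-1], d=1 / 128.0)
        assert abs(freqs[spectrum.argmax()] - 10.0) < 0.5

    def test_upsampling_refused(self, rng):
        raw = _raw(rng.normal(size=(1, 2, 128)).astype(np.float32))
        with pytest.raises(ValueError, match="upsample"):
            downsample(raw, 256.0)


class TestBaselineRemoval:
    def test_constant_trial_cancels_exactly(self):
        segs = np.full((63, 32, 128), 3.7, dtype=np.float32)
        out = remove_baseline(segs)
        assert out.shape == (60, 32, 128)
        assert not out.any()

    def test_scalar_hand_example(self):
        """Baselines 1, 2, 3 (mean 2); stimulus 5 corrects to 3."""
        segs = np.array([1.0, 2.0, 3.0, 5.0]).reshape(4, 1, 1)
        out = remove_baseline(segs)
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(3.0)

    def test_deap_trial_yields_60_corrected_segments(self, deap_study):
        segs = segment_1s(deap_study[0].data[0], 128.0)
        assert segs.shape == (63, 32, 128)
        assert remove_baseline(segs).shape == (60, 32, 128)

    def test_linearity(self, rng):
        segs = rng.normal(size=(10, 4, 16))
        np.testing.assert_allclose(
            remove_baseline(3.5 * segs), 3.5 * remove_baseline(segs), rtol=1e-12
        )

    def test_too_few_segments_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            remove_baseline(rng.normal(size=(3, 2, 8)))


class TestAssemble3s:
    def test_60_segments_become_20_samples(self, rng):
        segs = rng.normal(size=(60, 32, 128))
        out = assemble_3s(segs)
        assert out.shape == (20, 3, 32, 128)

    def test_single_group_preserves_order(self, rng):
        segs = rng.normal(size=(3, 2, 8))
        out = assemble_3s(segs)
        assert out.shape == (1, 3, 2, 8)
        np.testing.assert_array_equal(out[0], segs)

    def test_lossless_reshape_round_trip(self, rng):
        segs = rng.normal(size=(12, 4, 16))
        back = assemble_3s(segs).reshape(12, 4, 16)
        np.testing.assert_array_equal(back, segs)

    def test_indivisible_count_names_trial(self):
        with pytest.raises(ValueError, match="trial 7"):
            assemble_3s(np.zeros((61, 2, 8)), trial=7)

    def test_full_deap_like_subject_yields_800_samples(self):
        spec = deap_spec(n_subjects=1, n_trials=40, stimulus_seconds=60.0, seed=0)
        seg = preprocess_subject(simulate_deap_like(spec)[0], LabelScheme(2, "arousal"))
        assert seg.samples.shape == (800, 3, 32, 128)  # 40 trials x 20 samples


class TestLabelAssignment:
    @pytest.mark.parametrize(
        "score,n_classes,expected",
        [
            (5.0, 2, 0),   # threshold itself is low
            (5.0001, 2, 1),
            (1.0, 2, 0),
            (9.0, 2, 1),
            (4.0, 3, 0),
            (6.0, 3, 1),   # medium band is (4, 6]
            (9.0, 3, 2),
            (6.0001, 3, 2),
        ],
    )
    def test_threshold_cases(self, score, n_classes, expected):
        scheme = LabelScheme(n_classes, "arousal")
        assert assign_label(score, scheme) == expected

    @pytest.mark.parametrize("score", [0.5, 9.5, -1.0])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError, match="outside"):
            assign_label(score, LabelScheme(2, "valence"))

    @given(st.floats(min_value=1.0, max_value=9.0), st.sampled_from([2, 3]))
    def test_total_function_partitions_rating_scale(self, score, n_classes):
        """Every rating gets exactly one class; class boundaries are the
        scheme's interval edges."""
        scheme = LabelScheme(n_classes, "valence")
        cls = assign_label(score, scheme)
        edges = scheme.edges
        lo, hi = edges[cls], edges[cls + 1]
        assert (score > lo or score == 1.0) and score <= hi

    def test_class_names_follow_dimension(self):
        assert LabelScheme(3, "valence").class_names == ("LV", "MV", "HV")
        assert LabelScheme(2, "arousal").class_names == ("LA", "HA")

    def test_latent_class_round_trips_through_ratings(self, deap_study):
        """Generator rating -> scheme class recovers the latent class exactly."""
        raw = deap_study[0]
        scheme = LabelScheme(2, "arousal")
        got = [assign_label(float(r[1]), scheme) for r in raw.labels]
        assert got == raw.latent.tolist()


class TestSplits:
    def test_folds_partition_everything(self):
        labels = np.tile([0, 1], 50)
        splits = make_splits(labels, folds=10, seed=3)
        test_sets = [set(te) for _, te in splits["folds"]]
        assert all(len(s) == 10 for s in test_sets)
        assert set().union(*test_sets) == set(range(100))
        for i, a in enumerate(test_sets):
            for b in test_sets[i + 1 :]:
                assert not (a & b)

    def test_holdout_is_80_20_and_stratified(self):
        labels = np.tile([0, 1], 50)
        splits = make_splits(labels, seed=0)
        assert len(splits["train"]) == 80 and len(splits["test"]) == 20
        assert np.bincount(labels[splits["test"]]).tolist() == [10, 10]

    def test_deterministic_under_seed(self):
        labels = np.tile([0, 1, 2], 20)
        a = make_splits(labels, seed=9)
        b = make_splits(labels, seed=9)
        assert np.array_equal(a["train"], b["train"])
        for (tr1, te1), (tr2, te2) in zip(a["folds"], b["folds"]):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_more_folds_than_samples_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_splits(np.zeros(5), folds=10)


class TestPipeline:
    def test_segment_set_shapes_and_provenance(self, deap_segments):
        assert deap_segments.samples.shape == (160, 3, 32, 128)  # 8 trials x 20
        assert deap_segments.labels.shape == (160,)
        assert set(deap_segments.subjects.tolist()) == {0}
        assert np.array_equal(np.unique(deap_segments.trials), np.arange(8))

    def test_seed_layout_pipeline_truncates_remainder(self, seed_study):
        seg = preprocess_subject(seed_study[0])
        assert seg.samples.shape == (15 * 7, 3, 62, 128)  # 21 windows -> 7 samples
        assert set(seg.labels.tolist()) == {0, 1, 2}

    def test_samples_are_consecutive_windows_of_the_trial(self, deap_study):
        """Flattening the 3 s samples reproduces the corrected segment stream."""
        raw = deap_study[0]
        seg = preprocess_subject(raw, LabelScheme(2, "arousal"))
        corrected = remove_baseline(segment_1s(raw.data[0], 128.0))
        flat = seg.samples[seg.trials == 0].reshape(-1, 32, 128)
        np.testing.assert_allclose(flat, corrected, atol=1e-5)
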