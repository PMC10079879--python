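"""Preprocessing, windowing, design arithmetic and channel selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegformer import (BETA_SPECS, DEPEEG_SPEC, MONTAGE_64, SEED_SPEC,
                       DatasetSpec, RecordingSet, count_trials, crop_trials,
                       detrend_normalize, expected_sample_count,
                       load_recording_set, save_recording_set, segment_trials,
                       select_channels)


class TestDetrendNormalize:
    def test_pure_ramp_maps_to_zero(self):
        t = np.arange(50, dtype=float)
        seg = np.stack([3.0 * t + 7.0, -0.5 * t + 2.0])
        out = detrend_normalize(seg)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_output_channels_are_zero_mean_unit_sd(self, rng):
        out = detrend_normalize(rng.standard_normal((5, 64)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-12)

    def test_detrend_matches_least_squares_fit_oracle(self):
        # 10 Hz sine sampled at 250 Hz: the removed trend must equal the
        # channel's own least-squares line (computed here with lstsq)
        t = np.arange(250) / 250.0
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        A = np.vstack([np.arange(250), np.ones(250)]).T
        coef, *_ = np.linalg.lstsq(A, x[0], rcond=None)
        resid = x[0] - A @ coef
        out = detrend_normalize(x)
        np.testing.assert_allclose(out[0], resid / resid.std(), atol=1e-9)

    def test_rejects_non_finite(self):
        seg = np.ones((2, 10))
        seg[1, 3] = np.nan
        with pytest.raises(ValueError, match="channel 1"):
            detrend_normalize(seg)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).standard_normal((3, 40))
        once = detrend_normalize(x)
        np.testing.assert_allclose(detrend_normalize(once), once, atol=1e-9)


class TestSegmentTrials:
    def test_window_count_is_floor(self, rng):
        recs = RecordingSet([rng.standard_normal((2, 750))], [0], [0],
                            ("O1", "O2"), 250.0)
        batch = segment_trials(recs, ratio=0.4)
        assert len(batch) == 7 and batch.segments.shape == (7, 2, 100)

    def test_short_trial_yields_zero_windows_with_warning(self, rng, caplog):
        recs = RecordingSet([rng.standard_normal((2, 99))], [1], [0],
                            ("O1", "O2"), 250.0)
        with caplog.at_level("WARNING"):
            batch = segment_trials(recs, ratio=0.4)
        assert len(batch) == 0
        assert "shorter than window" in caplog.text

    def test_labels_and_subjects_inherited(self, toy_recordings):
        batch = segment_trials(toy_recordings, ratio=0.3)
        per_trial = 90 // 30
        np.testing.assert_array_equal(
            batch.labels, np.repeat(toy_recordings.labels, per_trial))
        np.testing.assert_array_equal(
            batch.subject_ids, np.repeat(toy_recordings.subject_ids, per_trial))

    def test_windows_are_preprocessed(self, toy_recordings):
        batch = segment_trials(toy_recordings, ratio=0.3)
        np.testing.assert_allclose(batch.segments.mean(axis=2), 0, atol=1e-9)

    def test_non_overlapping_left_to_right(self, rng):
        x = rng.standard_normal((1, 60))
        recs = RecordingSet([x], [0], [0], ("Oz",), 100.0)
        batch = segment_trials(recs, ratio=0.3, preprocess=False)
        np.testing.assert_array_equal(batch.segments[0], x[:, :30])
        np.testing.assert_array_equal(batch.segments[1], x[:, 30:60])

    def test_rejects_too_short_window(self, toy_recordings):
        with pytest.raises(ValueError, match="too short"):
            segment_trials(toy_recordings, ratio=0.05)


class TestDesignArithmetic:
    def test_ssvep_benchmark_total_is_78000(self):
        assert expected_sample_count(list(BETA_SPECS), 0.4) == 78_000

    def test_depression_benchmark_total_is_42000(self):
        assert expected_sample_count(DEPEEG_SPEC, 0.4) == 42_000

    def test_emotion_benchmark_total_truncates_to_514687(self):
        # 15*3*15*305/0.4 = 514,687.5 -> truncated
        assert expected_sample_count(SEED_SPEC, 0.4) == 514_687

    def test_identity_case(self):
        assert expected_sample_count(
            DatasetSpec(1, 1, 1, 1, 10.0, 1.0), 1.0) == 1

    def test_rejects_nonpositive_ratio(self):
        with pytest.raises(ValueError):
            expected_sample_count(DEPEEG_SPEC, 0.0)

    @pytest.mark.parametrize("spec,expected", [
        (DatasetSpec(70, 4, 40, 64, 250.0, 3.0), 11_200),
        (DatasetSpec(1, 1, 1, 1, 10.0, 1.0), 1),
        (DatasetSpec(35, 1, 1, 6, 500.0, 480.0), 35),
    ])
    def test_trial_counts(self, spec, expected):
        assert count_trials(spec) == expected

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError):
            DatasetSpec(0, 1, 1, 1, 10.0, 1.0)
        with pytest.raises(ValueError):
            DatasetSpec(1, 1, 1, 1, -1.0, 1.0)

    def test_segmentation_count_matches_arithmetic_on_exact_multiples(self):
        """Windowing a set whose trial lengths are exact window multiples
        must produce exactly the count the design formula predicts."""
        rng = np.random.default_rng(0)
        specs = [DatasetSpec(2, 2, 3, 2, 50.0, 2.0),
                 DatasetSpec(3, 2, 3, 2, 50.0, 3.0)]
        trials, labels, subjects = [], [], []
        sid = 0
        for sp in specs:
            n = int(sp.tlpt * sp.sr)
            for s in range(sp.n_subjects):
                for _ in range(sp.epp * sp.tpe):
                    trials.append(rng.standard_normal((2, n)))
                    labels.append(0 if len(labels) % 2 else 1)
                    subjects.append(sid)
                sid += 1
        recs = RecordingSet(trials, labels, subjects, ("O1", "O2"), 50.0)
        batch = segment_trials(recs, ratio=0.5)
        assert len(batch) == expected_sample_count(specs, 0.5)


class TestChannelSelection:
    def _set64(self, rng, n_trials=2):
        return RecordingSet([rng.standard_normal((64, 50))
                             for _ in range(n_trials)],
                            np.zeros(n_trials), np.zeros(n_trials),
                            MONTAGE_64, 250.0)

    def test_named_subset_occ3(self, rng):
        out = select_channels(self._set64(rng), "occ3")
        assert out.montage == ("O1", "Oz", "O2")
        assert all(t.shape[0] == 3 for t in out.trials)

    def test_occ9_order_preserved(self, rng):
        out = select_channels(self._set64(rng), "occ9")
        assert out.montage == ("O1", "Oz", "O2", "Pz", "PO3", "PO5",
                               "PO4", "PO6", "POz")

    def test_cp32_has_32_channels(self, rng):
        assert select_channels(self._set64(rng), "cp32").n_channels == 32

    def test_full_montage_identity(self, rng):
        recs = self._set64(rng)
        out = select_channels(recs, list(MONTAGE_64))
        for a, b in zip(out.trials, recs.trials):
            np.testing.assert_array_equal(a, b)

    def test_rows_match_source_channels(self, rng):
        recs = self._set64(rng)
        out = select_channels(recs, ["Oz", "Fp1"])
        iz, ip = MONTAGE_64.index("Oz"), MONTAGE_64.index("Fp1")
        np.testing.assert_array_equal(out.trials[0][0], recs.trials[0][iz])
        np.testing.assert_array_equal(out.trials[0][1], recs.trials[0][ip])

    def test_missing_channel_named_in_error(self, rng):
        with pytest.raises(KeyError, match="XX9"):
            select_channels(self._set64(rng), ["Oz", "XX9"])

    def test_nested_selection_equals_direct(self, rng):
        recs = self._set64(rng)
        via = select_channels(select_channels(recs, "occ9"), "occ3")
        direct = select_channels(recs, "occ3")
        for a, b in zip(via.trials, direct.trials):
            np.testing.assert_array_equal(a, b)
        assert via.montage == direct.montage


class TestRecordingSetContainer:
    def test_alignment_enforced(self, rng):
        with pytest.raises(ValueError, match="align"):
            RecordingSet([rng.standard_normal((2, 10))], [0, 1], [0],
                         ("O1", "O2"), 10.0)

    def test_channel_count_enforced(self, rng):
        with pytest.raises(ValueError, match="expected"):
            RecordingSet([rng.standard_normal((3, 10))], [0], [0],
                         ("O1", "O2"), 10.0)

    def test_crop_removes_cue_and_offset(self, rng):
        x = rng.standard_normal((2, 100))
        recs = RecordingSet([x], [0], [0], ("O1", "O2"), 10.0)
        out = crop_trials(recs, pre_s=0.5, post_s=0.5)  # 5 samples each end
        np.testing.assert_array_equal(out.trials[0], x[:, 5:95])

    def test_hdf5_round_trip_bit_exact(self, toy_recordings, tmp_path):
        path = tmp_path / "fixture.h5"
        save_recording_set(toy_recordings, path)
        back = load_recording_set(path)
        assert back.montage == toy_recordings.montage
        assert back.sr == toy_recordings.sr
        np.testing.assert_array_equal(back.labels, toy_recordings.labels)
        np.testing.assert_array_equal(back.subject_ids,
                                      toy_recordings.subject_ids)
        for a, b in zip(back.trials, toy_recordings.trials):
            np.testing.assert_array_equal(a, b)
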