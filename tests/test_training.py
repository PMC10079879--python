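"""Training loop determinism, metrics, split protocols and the experiment
runners."""

import dataclasses

import numpy as np
import pytest

from eegformer import (ALL_COMBOS, EEGformer, MetricsReport, TrainConfig,
                       compute_metrics, kfold_splits, loso_splits,
                       run_ablation, save_reports, sweep_segment_length,
                       train)
from eegformer.training import reports_to_frame

FAST = TrainConfig(batch_size=8, max_epochs=2, val_fraction=0.0, seed=0)


class TestTrainLoop:
    def test_same_seed_identical_final_losses(self, tiny_model_cfg,
                                              toy_segments):
        hists = []
        for _ in range(2):
            model = EEGformer(tiny_model_cfg)
            hists.append(train(model, toy_segments.segments,
                               toy_segments.labels, FAST))
        assert hists[0]["train_loss"] == hists[1]["train_loss"]

    def test_lr_zero_leaves_parameters_unchanged(self, tiny_model_cfg,
                                                 toy_segments):
        model = EEGformer(tiny_model_cfg)
        before = model.state_dict()
        train(model, toy_segments.segments, toy_segments.labels,
              dataclasses.replace(FAST, lr=0.0))
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_history_records_every_epoch(self, tiny_model_cfg, toy_segments):
        model = EEGformer(tiny_model_cfg)
        h = train(model, toy_segments.segments, toy_segments.labels,
                  dataclasses.replace(FAST, max_epochs=3))
        assert len(h["train_loss"]) == len(h["train_acc"]) == 3

    def test_validation_monitoring_populates_history(self, tiny_model_cfg,
                                                     toy_segments):
        model = EEGformer(tiny_model_cfg)
        h = train(model, toy_segments.segments, toy_segments.labels,
                  dataclasses.replace(FAST, val_fraction=0.25, max_epochs=2))
        assert len(h["val_loss"]) == 2

    def test_label_outside_model_range_rejected(self, tiny_model_cfg,
                                                toy_segments):
        model = EEGformer(tiny_model_cfg)
        bad = toy_segments.labels.copy()
        bad[0] = 7
        with pytest.raises(ValueError, match="class range"):
            train(model, toy_segments.segments, bad, FAST)


class TestMetrics:
    def test_perfect_predictions_all_hundred(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = compute_metrics(y, y)
        assert rep.acc == rep.sen == rep.spe == 100.0

    def test_binary_counts_give_70_60_80(self):
        """TP=3, FP=1, FN=2, TN=4 (positive class = 1)."""
        true = np.array([1] * 5 + [0] * 5)
        pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        rep = compute_metrics(pred, true)
        assert rep.acc == 70.0
        assert rep.sen == 60.0
        assert rep.spe == 80.0

    def test_multiclass_matches_confusion_matrix_oracle(self, rng):
        true = rng.integers(0, 3, 60)
        pred = rng.integers(0, 3, 60)
        rep = compute_metrics(pred, true)
        # independent one-vs-rest counting oracle
        sens, spes, pooled = [], [], np.zeros(4)
        for c in range(3):
            tp = np.sum((pred == c) & (true == c))
            fp = np.sum((pred == c) & (true != c))
            fn = np.sum((pred != c) & (true == c))
            tn = np.sum((pred != c) & (true != c))
            pooled += (tp, fp, fn, tn)
            sens.append(tp / (tp + fn))
            spes.append(tn / (tn + fp))
        np.testing.assert_allclose(rep.sen, 100 * np.mean(sens), atol=1e-9)
        np.testing.assert_allclose(rep.spe, 100 * np.mean(spes), atol=1e-9)
        np.testing.assert_allclose(
            rep.acc, 100 * (pooled[0] + pooled[3]) / pooled.sum(), atol=1e-9)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 1]), np.array([0, 0]))

    def test_report_aggregation_and_serialization(self, tmp_path):
        rep = MetricsReport(config="demo", fold_acc=[80.0, 90.0],
                            fold_sen=[70.0, 80.0], fold_spe=[75.0, 85.0],
                            fold_plain_acc=[80.0, 90.0])
        row = rep.to_row()
        assert row["acc"] == 85.0
        np.testing.assert_allclose(row["acc_sd"], np.std([80, 90], ddof=1))
        save_reports([rep], tmp_path / "r.csv", tmp_path / "r.json")
        frame = reports_to_frame([rep])
        assert list(frame["config"]) == ["demo"]
        assert (tmp_path / "r.csv").exists() and (tmp_path / "r.json").exists()


class TestSplitters:
    def test_kfold_even_folds(self):
        folds = kfold_splits(10, k=5, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_kfold_partition_law(self):
        folds = kfold_splits(23, k=5, seed=1)
        allidx = np.concatenate(folds)
        assert len(allidx) == 23
        assert len(np.unique(allidx)) == 23     # disjoint and exhaustive

    def test_kfold_uneven_sizes(self):
        folds = kfold_splits(11, k=5, seed=0)
        assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 3]

    def test_kfold_too_few_samples(self):
        with pytest.raises(ValueError):
            kfold_splits(3, k=5)

    def test_loso_one_split_per_subject(self):
        subs = np.array([0, 0, 1, 1, 2, 2, 2])
        splits = loso_splits(subs)
        assert len(splits) == 3
        sizes = [len(test) for _, test in splits]
        assert sizes == [2, 2, 3]

    def test_loso_no_subject_leakage(self):
        subs = np.repeat(np.arange(5), 4)
        for train_idx, test_idx in loso_splits(subs):
            assert not set(subs[train_idx]) & set(subs[test_idx])
            assert len(np.intersect1d(train_idx, test_idx)) == 0

    def test_loso_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_splits(np.zeros(5))


class TestRunners:
    def test_ablation_report_contract(self, tiny_model_cfg, toy_segments):
        combos = [frozenset({"Temp"}), frozenset({"Syn", "Reg"})]
        reports = run_ablation(toy_segments, combos, tiny_model_cfg,
                               FAST, k=2)
        assert [r.config for r in reports] == ["Temp", "Syn + Reg"]
        for r in reports:
            assert len(r.fold_acc) == 2
            for v in r.fold_acc + r.fold_sen + r.fold_spe:
                assert 0.0 <= v <= 100.0

    def test_ablation_deterministic_for_repeated_combo(self, tiny_model_cfg,
                                                       toy_segments):
        combo = frozenset({"Temp"})
        reports = run_ablation(toy_segments, [combo, combo], tiny_model_cfg,
                               FAST, k=2)
        assert reports[0].fold_acc == reports[1].fold_acc

    def test_sweep_reports_one_entry_per_usable_length(self, tiny_model_cfg,
                                                       toy_recordings,
                                                       caplog):
        # 100 Hz recording: T=0.2 gives 20 samples < 28-sample conv support
        with caplog.at_level("WARNING"):
            reports = sweep_segment_length(toy_recordings, [0.2, 0.3, 0.45],
                                           tiny_model_cfg, FAST, k=2)
        assert [r.config for r in reports] == ["T=0.3", "T=0.45"]
        assert "skipped" in caplog.text

    def test_sweep_window_arithmetic(self):
        # T=0.5 at 250 Hz: 125-sample windows, Le = 125 - 27 = 98
        from eegformer import ConvConfig
        assert int(round(0.5 * 250)) == 125
        assert ConvConfig().out_length(125) == 98
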