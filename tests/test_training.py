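"""Training and evaluation: encoding, metrics, splits, cross-validation."""

from dataclasses import replace

import numpy as np
import pytest

from erpdecode.architectures import ModelSpec, build_model
from erpdecode.preprocess import EpochSet
from erpdecode.simulate import (
    StimulusClass,
    SubjectProfile,
    make_montage,
    simulate_trial,
    stimulus_classes,
)
from erpdecode.training import (
    PretrainConfig,
    SplitPlan,
    TrainConfig,
    confusion_view_split,
    evaluate,
    finetune,
    grand_average,
    leave_subjects_out_plan,
    one_hot,
    pool_epoch_sets,
    pretrain,
    repeated_two_fold,
    scores_report,
    trough_latency,
)
from erpdecode.vae import SyntheticSampleSet

EM = stimulus_classes("emotion_view")


def _epochs(data, labels, subject="s"):
    return EpochSet(data=np.asarray(data, dtype=float), labels=list(labels),
                    time_axis=(np.arange(data.shape[2]) - 50) / 250.0,
                    channel_names=tuple(f"C{i}"
                                        for i in range(data.shape[1])),
                    subject_id=subject, fs=250.0)


class TestOneHot:
    def test_single_class_row(self):
        np.testing.assert_array_equal(one_hot([2], 4), [[0, 0, 1, 0]])

    def test_rows_sum_to_one_and_roundtrip(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 50)
        enc = one_hot(labels, 4)
        np.testing.assert_array_equal(enc.sum(axis=1), np.ones(50))
        np.testing.assert_array_equal(enc.argmax(axis=1), labels)

    def test_stimulus_class_labels(self):
        enc = one_hot([EM[3], EM[0]], 4)
        np.testing.assert_array_equal(enc, [[0, 0, 0, 1], [1, 0, 0, 0]])

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            one_hot([5], 4)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3] * 10)
        proba = one_hot(y, 4) * 0.97 + 0.0075
        res = scores_report(y, proba, 4)
        assert res.accuracy == 1.0
        assert res.auc == pytest.approx(1.0)
        assert np.all(np.diag(res.confusion) == 10)

    def test_uniform_random_scores_near_chance(self):
        rng = np.random.default_rng(0)
        n = 100_000
        y = rng.integers(0, 4, n)
        proba = rng.random((n, 4))
        proba /= proba.sum(axis=1, keepdims=True)
        res = scores_report(y, proba, 4)
        assert res.accuracy == pytest.approx(0.25, abs=0.01)
        assert res.auc == pytest.approx(0.50, abs=0.01)

    def test_confusion_rows_sum_to_class_counts(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 200)
        proba = rng.random((200, 4))
        res = scores_report(y, proba, 4)
        counts = np.bincount(y, minlength=4)
        np.testing.assert_array_equal(res.confusion.sum(axis=1), counts)

    def test_empty_test_set_raises(self):
        model = build_model(ModelSpec.create("eegnet", C=4, T=64), seed=0)
        empty = _epochs(np.zeros((0, 4, 64)), [])
        with pytest.raises(ValueError):
            evaluate(model, empty)


class TestConfusionViewSplit:
    def test_diagonal_only_flagged(self):
        cs = confusion_view_split(np.diag([5, 5, 5, 5]), EM)
        assert cs.no_confusion
        assert cs.cross_view_confusion_mass == cs.within_view_confusion_mass == 0

    def test_all_confusion_within_upright_pair(self):
        cm = np.zeros((4, 4))
        cm[0, 2] = 7  # fear/upright mistaken for neutral/upright
        cs = confusion_view_split(cm, EM)
        assert cs.cross_view_confusion_mass == 0.0
        assert cs.within_view_confusion_mass == 1.0

    def test_hand_built_fractions(self):
        cm = np.array([
            [10, 3, 2, 1],
            [0, 10, 4, 2],
            [1, 0, 10, 5],
            [2, 1, 0, 10],
        ])
        # views are (up, inv, up, inv): cross-view cells are (0,1) (0,3)
        # (1,0) (1,2) (2,1) (2,3) (3,0) (3,2); within-view are (0,2) (1,3)
        # (2,0) (3,1)
        cross = 3 + 1 + 0 + 4 + 0 + 5 + 2 + 0
        within = 2 + 2 + 1 + 1
        cs = confusion_view_split(cm, EM)
        assert cs.cross_view_confusion_mass == pytest.approx(
            cross / (cross + within))
        assert cs.within_view_confusion_mass == pytest.approx(
            within / (cross + within))


class TestGrandAverage:
    def test_identical_trials_average_to_any_trial(self):
        trial = np.random.default_rng(0).standard_normal((3, 250))
        ep = _epochs(np.stack([trial] * 5), [EM[0]] * 5)
        ga = grand_average(ep)
        np.testing.assert_allclose(ga[EM[0]], trial)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 2, 250))
        b = rng.standard_normal((4, 2, 250))
        labels = [EM[0]] * 4
        ga_a = grand_average(_epochs(a, labels))[EM[0]]
        ga_b = grand_average(_epochs(b, labels))[EM[0]]
        ga_ab = grand_average(_epochs(a + b, labels))[EM[0]]
        np.testing.assert_allclose(ga_ab, ga_a + ga_b, atol=1e-12)

    def test_missing_class_raises(self):
        ep = _epochs(np.zeros((2, 2, 250)), [EM[0], EM[0]])
        with pytest.raises(ValueError, match="fear/upside-down"):
            grand_average(ep, classes=[EM[1]])

    def test_inversion_delay_recovered_from_simulated_trials(self):
        """Grand-average N170 troughs of inverted vs upright classes differ
        by the configured delay within one sample period."""
        prof = SubjectProfile("s", noise_scale_uv=3.0, artifact_rate=0)
        mont = make_montage()
        rng = np.random.default_rng(0)
        oz = list(mont.channel_names).index("Oz")
        data, labels = [], []
        for cls in (EM[0], EM[1]):
            for _ in range(100):
                data.append(simulate_trial(cls, prof, mont, rng))
                labels.append(cls)
        ep = EpochSet(data=np.asarray(data), labels=labels,
                      time_axis=(np.arange(250) - 50) / 250.0,
                      channel_names=mont.channel_names, subject_id="s",
                      fs=250.0)
        ga = grand_average(ep)
        lag = (trough_latency(ga[EM[1]][oz], ep.time_axis)
               - trough_latency(ga[EM[0]][oz], ep.time_axis))
        assert lag == pytest.approx(prof.inversion_delay_ms / 1e3,
                                    abs=1.0 / 250.0 + 1e-9)


class TestSplitPlans:
    def test_overlapping_subjects_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(training_subjects=["a", "b"], test_subjects=["b"])

    def test_oldest_and_ad_held_out(self):
        eps = [_epochs(np.zeros((1, 2, 250)), [EM[0]], subject=s)
               for s in ("c1", "c2", "old", "pat")]
        groups = {"c1": "control", "c2": "control", "old": "control_oldest",
                  "pat": "ad"}
        plan = leave_subjects_out_plan(eps, groups)
        assert plan.training_subjects == ["c1", "c2"]
        assert set(plan.test_subjects) == {"old", "pat"}
        assert plan.validation_fraction == 0.25

    def test_pool_tracks_trial_subjects(self):
        eps = [_epochs(np.zeros((2, 2, 250)), [EM[0], EM[1]], subject=s)
               for s in ("a", "b")]
        pooled = pool_epoch_sets(eps)
        assert pooled.trial_subjects == ["a", "a", "b", "b"]

    def test_pool_channel_mismatch_rejected(self):
        a = _epochs(np.zeros((1, 2, 250)), [EM[0]])
        b = _epochs(np.zeros((1, 3, 250)), [EM[0]])
        with pytest.raises(ValueError):
            pool_epoch_sets([a, b])


def _fake_synthetic(n_per_class, C=4, T=64, experiment="emotion_view"):
    rng = np.random.default_rng(0)
    sets = []
    for i, cls in enumerate(stimulus_classes(experiment)):
        pattern = np.zeros((C, T))
        pattern[i % C, :] = 1.0
        data = pattern[None] + 0.05 * rng.standard_normal((n_per_class, C, T))
        sets.append(SyntheticSampleSet(data=data.astype(np.float32),
                                       class_label=cls, generator_id="fake",
                                       seed=0))
    return sets


class TestPretrain:
    def test_split_sizes_1400_600_for_500_per_class(self):
        sets = _fake_synthetic(500)
        model = build_model(ModelSpec.create("eegnet", C=4, T=64), seed=0)
        cfg = PretrainConfig(epochs=1, patience=1, seed=1)
        pretrain(model, sets, cfg)
        assert model.pretrain_metrics["n_train"] == 1400
        assert model.pretrain_metrics["n_test"] == 600

    def test_missing_class_rejected(self):
        sets = _fake_synthetic(20)[:3]
        model = build_model(ModelSpec.create("eegnet", C=4, T=64), seed=0)
        with pytest.raises(ValueError):
            pretrain(model, sets, PretrainConfig(epochs=1))

    def test_fixed_seed_reproduces_split_and_history(self):
        sets = _fake_synthetic(30)
        cfg = PretrainConfig(epochs=2, patience=2, seed=3,
                             learning_rate=1e-3)
        m1 = build_model(ModelSpec.create("eegnet", C=4, T=64), seed=0)
        m2 = build_model(ModelSpec.create("eegnet", C=4, T=64), seed=0)
        pretrain(m1, sets, cfg)
        pretrain(m2, sets, cfg)
        assert m1.history["loss"] == m2.history["loss"]


class TestFinetune:
    def test_patience_bookkeeping(self):
        rng = np.random.default_rng(0)
        # pure-noise labels: validation loss cannot improve for long
        data = rng.standard_normal((32, 4, 64))
        labels = [EM[i % 4] for i in range(32)]
        tr = _epochs(data, labels)
        va = _epochs(rng.standard_normal((16, 4, 64)),
                     [EM[i % 4] for i in range(16)])
        model = build_model(ModelSpec.create("eegnet", C=4, T=64), seed=1)
        cfg = TrainConfig(epochs=100, early_stopping_epochs=5, seed=2,
                          batch_size=16)
        finetune(model, None, tr, va, cfg)
        h = model.history
        assert len(h["val_loss"]) <= 100
        if len(h["val_loss"]) < 100:  # stopped early
            assert len(h["val_loss"]) == h["best_epoch"] + 1 + 5

    def test_init_state_shape_mismatch_raises(self):
        m_small = build_model(ModelSpec.create("eegnet", C=4, T=64), seed=0)
        m_big = build_model(ModelSpec.create("eegnet", C=6, T=64), seed=0)
        tr = _epochs(np.zeros((8, 6, 64)), [EM[i % 4] for i in range(8)])
        with pytest.raises(ValueError):
            finetune(m_big, m_small.net.get_state(), tr, tr,
                     TrainConfig(epochs=1))

    def test_warm_start_tendency_over_seeds(self, cohort_epochs,
                                            pretrained_state):
        """Across 5 seeds, epoch-1 validation loss starting from pretrained
        weights is on average no worse than from random initialization."""
        pooled, _, _ = cohort_epochs
        spec, state, _ = pretrained_state
        rng = np.random.default_rng(0)
        idx = rng.permutation(pooled.n_trials)
        tr_i, va_i = idx[:96], idx[96:144]
        tr = replace(pooled, data=pooled.data[tr_i],
                     labels=[pooled.labels[i] for i in tr_i])
        va = replace(pooled, data=pooled.data[va_i],
                     labels=[pooled.labels[i] for i in va_i])
        diffs = []
        for seed in range(5):
            cfg = TrainConfig(epochs=1, seed=seed)
            warm = build_model(spec, seed=100 + seed)
            finetune(warm, state, tr, va, cfg)
            cold = build_model(spec, seed=100 + seed)
            finetune(cold, None, tr, va, cfg)
            diffs.append(cold.history["val_loss"][0]
                         - warm.history["val_loss"][0])
        assert np.mean(diffs) >= 0, diffs


class TestRepeatedTwoFold:
    def test_five_repeats_two_folds_yield_ten_runs(self, cv_report):
        assert len(cv_report.runs) == 10
        assert set(cv_report.runs["repeat"]) == set(range(5))
        assert set(cv_report.runs["fold"]) == {0, 1}

    def test_summary_equals_mean_of_runs(self, cv_report):
        summary = cv_report.summary()
        for col in summary.columns:
            assert summary[col].iloc[0] == pytest.approx(
                cv_report.runs[col].mean())

    def test_accuracies_are_probabilities(self, cv_report):
        for col in ("validation_acc", "control_acc", "alzheimer_acc"):
            assert cv_report.runs[col].between(0, 1).all()

    def test_confusion_rows_sum_to_test_counts(self, cv_report, cohort_epochs):
        _, tests, _ = cohort_epochs
        counts = np.bincount(tests["control"].class_indices(), minlength=4)
        cm = cv_report.confusions[(0, 0, "control")]
        np.testing.assert_array_equal(cm.sum(axis=1), counts)

    def test_same_seed_reproduces_partitions(self, cohort_epochs):
        pooled, tests, _ = cohort_epochs
        sub = replace(pooled, data=pooled.data[:64],
                      labels=pooled.labels[:64])
        sub.trial_subjects = pooled.trial_subjects[:64]
        spec = ModelSpec.create("eegnet", C=pooled.data.shape[1],
                                T=pooled.data.shape[2])
        cfg = TrainConfig(epochs=2, early_stopping_epochs=2, seed=0)
        a = repeated_two_fold(sub, tests, spec, cfg, repeats=1, seed=5)
        b = repeated_two_fold(sub, tests, spec, cfg, repeats=1, seed=5)
        assert a.runs.equals(b.runs)

    def test_subject_leakage_detected(self, cohort_epochs):
        pooled, tests, _ = cohort_epochs
        sub = replace(pooled, data=pooled.data[:32],
                      labels=pooled.labels[:32])
        # corrupt the provenance: claim some training trials belong to the
        # held-out control subject
        sub.trial_subjects = [tests["control"].subject_id] * 32
        spec = ModelSpec.create("eegnet", C=pooled.data.shape[1],
                                T=pooled.data.shape[2])
        with pytest.raises(RuntimeError, match="leakage"):
            repeated_two_fold(sub, tests, spec,
                              TrainConfig(epochs=1), repeats=1, seed=0)

    def test_k_below_two_rejected(self, cohort_epochs):
        pooled, tests, _ = cohort_epochs
        spec = ModelSpec.create("eegnet", C=17, T=250)
        with pytest.raises(ValueError):
            repeated_two_fold(pooled, tests, spec, TrainConfig(), k=1)
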